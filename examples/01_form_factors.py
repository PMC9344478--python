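"""Electron scattering factors of neutral vs charged pseudoatoms.

Builds the mini bank, evaluates the analytic Hansen-Coppens X-ray factor for
a carboxylate-type oxygen, converts it with the Mott-Bethe formula, and
prints where the electron factor changes sign.  A net-negative oxygen
scatters electrons with negative amplitude at low resolution — the physical
reason charged side chains can vanish or invert in electrostatic-potential
maps.
"""

import numpy as np
from scipy.optimize import brentq

from taamaps import bank as bankmod
from taamaps import fixtures, form_factors as ff

bank = fixtures.mini_bank()
carbox_o = bank.by_signature[("O", ("C",))]
neutral_o = bankmod.fallback_params("O")
z = np.array([0.0, 0.0, 1.0])

print(f"carboxylate O: P_val = {carbox_o.P_val}, "
      f"net charge = {carbox_o.net_charge:+.2f} e")
print(f"{'d (A)':>8} {'g (1/A)':>8} {'f_e charged (A)':>16} {'f_e neutral (A)':>16}")
for d in (50.0, 20.0, 10.0, 5.0, 2.0, 1.0):
    g = 1.0 / d
    fe_c = ff.taam_electron_ff(carbox_o, np.eye(3), g, z).real
    fe_n = ff.taam_electron_ff(neutral_o, np.eye(3), g).real
    print(f"{d:8.1f} {g:8.3f} {fe_c:16.4f} {fe_n:16.4f}")

crossover = brentq(
    lambda g: ff.taam_electron_ff(carbox_o, np.eye(3), float(g), z).real,
    0.02, 1.0)
print(f"\nsign change at g = {crossover:.4f} 1/A, i.e. d = {1/crossover:.2f} A:")
print("below this resolution the charged O contributes negative potential")
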