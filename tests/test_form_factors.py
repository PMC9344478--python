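"""Form-factor layer: Gaussian IAM, Mott-Bethe, Slater-Bessel transforms,
density-normalized harmonics and the aspherical Hansen-Coppens factors.

The heavyweight oracles here are independent numerical routes: adaptive
quadrature for the radial transforms, Legendre-function quadrature for the
harmonic normalizations, and a brute-force 3-D numerical Fourier transform of
the sampled pseudoatom density for the aspherical factors.
"""

import math

import numpy as np
import pytest
from scipy import integrate, special

from taamaps import bank as bankmod
from taamaps import fixtures, form_factors as ff
from taamaps.bank import radial_norm
from taamaps.constants import BOHR_RADIUS


# --------------------------------------------------------------------------
# IAM Gaussian tables

@pytest.mark.parametrize("el,Z", [("C", 6), ("N", 7), ("O", 8), ("H", 1)])
def test_xray_f0_is_electron_count(el, Z):
    t = ff.iam_table(el, "xray")
    assert ff.iam_ff(t, 0.0) == pytest.approx(Z, abs=0.01)


def test_iam_ff_decays_monotonically_to_tail():
    """Beyond the turnover the Gaussian part decays monotonically to the
    constant term of the IT92 representation (b = 0 Gaussian)."""
    t = ff.iam_table("O", "xray")
    tail = sum(a for a, b in zip(t.a, t.b) if b == 0.0)
    s = np.linspace(1.0, 6.0, 40)
    vals = ff.iam_ff(t, s)
    assert np.all(np.diff(vals) < 0)
    assert vals[-1] - tail < 0.05
    te = ff.iam_table("O", "electron")     # pure 5-Gaussian: true decay to 0
    vals_e = ff.iam_ff(te, s)
    assert np.all(np.diff(vals_e) < 0)
    assert vals_e[-1] < 0.05


def test_iam_ff_rejects_negative_s():
    with pytest.raises(ValueError):
        ff.iam_ff(ff.iam_table("C", "xray"), -0.1)


@pytest.mark.parametrize("el", ["C", "N", "O"])
def test_mott_bethe_consistency_with_electron_table(el):
    """Mott-Bethe applied to the X-ray Gaussian fit reproduces the published
    electron Gaussian fit within the documented cross-fit tolerance."""
    tx = ff.iam_table(el, "xray")
    te = ff.iam_table(el, "electron")
    Z = round(float(ff.iam_ff(tx, 0.0)))
    s = np.linspace(0.05, 2.0, 60)
    fe_mb = ff.mott_bethe(Z, ff.iam_ff(tx, s), 2.0 * s)
    fe_tab = ff.iam_ff(te, s)
    assert np.max(np.abs(fe_mb - fe_tab)) < 0.02


def test_mott_bethe_bare_proton():
    """Closed-form prefactor: f_e = 1/(2 pi^2 a0) for Z=1, f_x=0, g=1."""
    expected = 1.0 / (2.0 * math.pi**2 * BOHR_RADIUS)
    assert ff.mott_bethe(1, 0.0, 1.0) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.09573, abs=5e-6)


def test_mott_bethe_neutral_low_g_finite():
    """For a Gaussian family with sum(a_i) exactly Z the cancellation
    Z - f_x = O(g^2) keeps f_e finite down to g -> 0."""
    a = (2.0, 1.5, 1.5, 0.7, 0.3)      # sums to 6 exactly
    b = (20.0, 10.0, 1.5, 0.6, 0.1)
    t = ff.GaussianFF("C", 0, a, b, "xray")
    g = np.array([1e-4, 1e-3, 1e-2, 0.1])
    fe = ff.mott_bethe(6, ff.iam_ff(t, g / 2.0), g)
    assert np.all(np.isfinite(fe))
    assert np.all(fe > 0)
    # approaches the finite limit sum(a_i b_i)/(8 pi^2 a0)
    limit = sum(ai * bi for ai, bi in zip(a, b)) / (
        8 * math.pi**2 * BOHR_RADIUS)
    assert fe[0] == pytest.approx(limit, rel=1e-6)


def test_mott_bethe_rejects_g_zero():
    with pytest.raises(ValueError):
        ff.mott_bethe(6, 5.0, 0.0)


# --------------------------------------------------------------------------
# Slater Fourier-Bessel transforms

def test_sfb_trivial_values():
    # int r^2 exp(-zeta r) dr = 2/zeta^3
    assert ff.slater_fourier_bessel(0, 2.0, 0, 0.0) == pytest.approx(0.25, rel=1e-12)
    # l >= 1 vanishes at g = 0 since j_l(0) = 0
    for l in (1, 2, 3, 4):
        assert ff.slater_fourier_bessel(l, 3.0, l, 0.0) == 0.0


def test_sfb_closed_form_l0():
    """Symbolic result: int r^2 e^(-z r) j_0(t r) dr = 2 z/(z^2 + t^2)^2."""
    z = 5.5
    for g in (0.01, 0.3, 1.2, 3.0):
        t = 2 * math.pi * g
        expected = 2 * z / (z * z + t * t) ** 2
        assert ff.slater_fourier_bessel(0, z, 0, g) == pytest.approx(
            expected, rel=1e-12)


@pytest.mark.parametrize("n,z,l", [
    (0, 2.0, 0), (2, 8.6, 0), (2, 8.6, 1), (2, 8.6, 2),
    (3, 6.1, 3), (4, 6.9, 4), (1, 3.8, 1), (3, 22.4, 2),
])
def test_sfb_matches_adaptive_quadrature(n, z, l):
    """Closed-form recurrence/series vs adaptive quadrature, 1e-10 relative."""
    for g in (1e-4, 0.01, 0.08, 0.3, 0.9, 2.0):
        val = ff.slater_fourier_bessel(n, z, l, g)
        oracle, err = integrate.quad(
            lambda r: r ** (n + 2) * math.exp(-z * r)
            * special.spherical_jn(l, 2 * math.pi * g * r),
            0.0, 80.0 / z, limit=800, epsabs=1e-15, epsrel=1e-13)
        assert val == pytest.approx(oracle, rel=1e-10, abs=1e-14)


def test_sfb_integrability_guard():
    with pytest.raises(ValueError, match="integrability"):
        ff.slater_fourier_bessel(0, 2.0, 3, 0.5)


# --------------------------------------------------------------------------
# Density-normalized real spherical harmonics

def test_d00_value():
    assert ff.real_sph_harm_density(0, 0, [0.0, 0.0, 1.0]) == pytest.approx(
        1.0 / (4 * math.pi), rel=1e-12)


def test_dipole_parity():
    up = ff.real_sph_harm_density(1, 0, [0.0, 0.0, 1.0])
    down = ff.real_sph_harm_density(1, 0, [0.0, 0.0, -1.0])
    assert up > 0
    assert down == pytest.approx(-up, rel=1e-12)
    # the known maximum of the density-normalized dipole is 1/pi
    assert up == pytest.approx(1.0 / math.pi, rel=1e-10)


def _abs_norm_oracle(l, m):
    """int |d_lm| dOmega via scipy.lpmv and kink-split Gauss panels in theta.

    Independent route: explicit associated-Legendre/trigonometric factor
    rather than sph_harm_y; integration in theta, where the integrand is
    analytic between its zeros (in cos theta the |m| > 0 functions have
    square-root endpoint behavior that slows plain Gauss rules).
    """
    from scipy.optimize import brentq

    am = abs(m)
    norm = math.sqrt((2 * l + 1) / (4 * math.pi)
                     * math.factorial(l - am) / math.factorial(l + am))
    if m != 0:
        norm *= math.sqrt(2.0)

    def f_theta(theta):
        return norm * special.lpmv(am, l, np.cos(theta))

    thetas = np.linspace(0.0, math.pi, 4001)
    vals = f_theta(thetas)
    knots = [0.0]
    for i in range(len(thetas) - 1):
        if vals[i] == 0.0 and 0 < i:
            knots.append(thetas[i])
        elif vals[i] * vals[i + 1] < 0:
            knots.append(brentq(f_theta, thetas[i], thetas[i + 1], xtol=1e-15))
    knots.append(math.pi)
    x, w = np.polynomial.legendre.leggauss(80)
    theta_integral = 0.0
    for a, b in zip(sorted(set(knots))[:-1], sorted(set(knots))[1:]):
        tt = 0.5 * (b - a) * x + 0.5 * (a + b)
        theta_integral += 0.5 * (b - a) * np.sum(
            w * np.abs(f_theta(tt)) * np.sin(tt))
    phi_integral = 2 * math.pi if m == 0 else 4.0
    k = ff.density_norm_constant(l, m)
    # Condon-Shortley phases cancel under the absolute value
    return k * theta_integral * phi_integral


@pytest.mark.parametrize("l", [1, 2, 3, 4])
def test_density_normalization_is_two(l):
    """int |d_lm| dOmega = 2 for every l >= 1 multipole, to 1e-8."""
    for m in range(-l, l + 1):
        assert _abs_norm_oracle(l, m) == pytest.approx(2.0, abs=1e-8)


def test_harmonics_reject_non_unit_direction():
    with pytest.raises(ValueError, match="unit"):
        ff.real_sph_harm_density(1, 0, [0.0, 0.0, 2.0])


# --------------------------------------------------------------------------
# Aspherical Hansen-Coppens factors

def _directions(n, seed=5):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def test_spherical_limit_matches_and_is_isotropic(mini_bank):
    """With all P_lm = 0 and kappa = 1 the factor is the spherical transform,
    equals P_core + P_val at g = 0, and is direction-independent."""
    entry = bankmod.fallback_params("O")
    f0 = ff.taam_xray_ff(entry, np.eye(3), 0.0)
    assert f0.real == pytest.approx(entry.P_core + entry.P_val, abs=1e-4)
    g = np.full(8, 0.37)
    vals = ff.taam_xray_ff(entry, np.eye(3), g, _directions(8))
    assert np.allclose(vals, vals[0], atol=1e-12)


def test_friedel_symmetry_for_dipole(mini_bank):
    entry = mini_bank.by_signature[("O", ("C",))]     # carries a dipole
    d = _directions(6)
    g = np.full(6, 0.41)
    f_plus = ff.taam_xray_ff(entry, np.eye(3), g, d)
    f_minus = ff.taam_xray_ff(entry, np.eye(3), g, -d)
    assert np.allclose(f_minus, np.conj(f_plus), atol=1e-12)


def _density_value(entry, frame, xyz):
    """Hansen-Coppens density evaluated in real space (independent route)."""
    r = np.linalg.norm(xyz, axis=-1)
    rho = np.zeros_like(r)
    for c, n, z in entry.core_density:
        rho += c * r**n * np.exp(-z * r)
    k = entry.kappa
    for c, n, z in entry.valence_density:
        rho += entry.P_val * k**3 * c * (k * r)**n * np.exp(-z * k * r)
    kp = entry.kappa_prime
    local = xyz @ frame
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[..., None] > 0, local / r[..., None], 0.0)
    for (l, m), p in entry.P_lm.items():
        if p == 0.0:
            continue
        n_l, z_l = entry.deformation_radial[l]
        radial = radial_norm(n_l, z_l) * (kp * r)**n_l * np.exp(-z_l * kp * r)
        rho += p * kp**3 * radial * ff.real_sph_harm_density(l, m, unit)
    return rho


def _numeric_ft(entry, frame, g, direction, rmax=6.0, n_r=220, n_t=40, n_p=80):
    """Brute-force 3-D Fourier transform of the sampled density.

    f(h) = int rho(r) exp(2 pi i h.r) d^3r on a Gauss-Legendre (r, cos theta)
    x uniform-phi product grid.
    """
    xr, wr = np.polynomial.legendre.leggauss(n_r)
    r = 0.5 * rmax * (xr + 1.0)
    wr = 0.5 * rmax * wr
    xu, wu = np.polynomial.legendre.leggauss(n_t)
    phi = np.arange(n_p) * (2 * np.pi / n_p)
    R, U, P = np.meshgrid(r, xu, phi, indexing="ij")
    W = (wr[:, None, None] * wu[None, :, None] * (2 * np.pi / n_p)
         * R**2)
    st = np.sqrt(1 - U**2)
    xyz = np.stack([R * st * np.cos(P), R * st * np.sin(P), R * U], axis=-1)
    rho = _density_value(entry, frame, xyz.reshape(-1, 3)).reshape(R.shape)
    hvec = (g * np.asarray(direction))
    phase = np.exp(2j * np.pi * (xyz @ hvec))
    return np.sum(rho * phase * W)


@pytest.mark.parametrize("sig", [("O", ("C",)), ("N", ("C", "C", "H")),
                                 ("C", ("C", "O", "O"))])
def test_taam_ff_matches_numeric_fourier_oracle(mini_bank, sig):
    """Analytic aspherical factor vs the numeric FT of the sampled density,
    within 1e-3 e at 10 scattering vectors."""
    entry = mini_bank.by_signature[sig]
    frame = np.eye(3)
    rng = np.random.default_rng(42)
    dirs = _directions(10, seed=9)
    gs = rng.uniform(0.05, 0.6, size=10)
    analytic = ff.taam_xray_ff(entry, frame, gs, dirs)
    for i in range(10):
        oracle = _numeric_ft(entry, frame, gs[i], dirs[i], rmax=7.0)
        assert abs(analytic[i] - oracle) < 1e-3


def test_taam_ff_respects_rotated_frame(mini_bank):
    """Evaluating in a rotated local frame equals evaluating the fixed frame
    at the back-rotated direction."""
    entry = mini_bank.by_signature[("O", ("C",))]
    ang = 0.7
    Rz = np.array([[math.cos(ang), -math.sin(ang), 0.0],
                   [math.sin(ang), math.cos(ang), 0.0],
                   [0.0, 0.0, 1.0]])
    d = _directions(5)
    g = np.full(5, 0.3)
    f_rot = ff.taam_xray_ff(entry, Rz, g, d)
    f_back = ff.taam_xray_ff(entry, np.eye(3), g, d @ Rz)
    assert np.allclose(f_rot, f_back, atol=1e-12)


def test_electron_ff_sign_behavior(mini_bank):
    """Charged-oxygen electron factor: negative at low resolution, positive
    at high resolution, with a locatable sign change; neutral atoms positive
    everywhere."""
    from scipy.optimize import brentq

    entry = mini_bank.by_signature[("O", ("C",))]
    assert entry.net_charge < 0
    z = np.array([0.0, 0.0, 1.0])

    def fe(g):
        return ff.taam_electron_ff(entry, np.eye(3), float(g), z).real

    assert fe(0.02) < 0
    assert fe(1.0) > 0
    g_cross = brentq(fe, 0.02, 1.0, xtol=1e-10)
    assert 0.02 < g_cross < 1.0     # resolvable crossover, d = 1/g_cross
    neutral = bankmod.fallback_params("O")
    for g in (0.01, 0.1, 0.5, 1.5):
        assert ff.taam_electron_ff(neutral, np.eye(3), g).real > 0


def test_charge_perturbation_linearity():
    """+q and -q P_val perturbations of the same atom shift f_e by equal and
    opposite amounts at every g (linearity in P_val)."""
    from dataclasses import replace

    base = bankmod.fallback_params("O")
    plus = replace(base, P_val=base.P_val + 0.4)
    minus = replace(base, P_val=base.P_val - 0.4)
    g = np.array([0.05, 0.2, 0.7, 1.5])
    f0 = np.array([ff.taam_electron_ff(base, np.eye(3), gi).real for gi in g])
    fp = np.array([ff.taam_electron_ff(plus, np.eye(3), gi).real for gi in g])
    fm = np.array([ff.taam_electron_ff(minus, np.eye(3), gi).real for gi in g])
    assert np.allclose(fp - f0, -(fm - f0), atol=1e-12)
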