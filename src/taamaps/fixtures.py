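"""Deterministic synthetic fixtures: structures, the mini bank, SF pairs.

Everything here is generated in code — no external downloads — and identical
(spec, seed) pairs give bitwise-identical fixtures.  The mini bank's
parameter values are physically plausible but invented; they are validated
against internal oracles (normalization, Fourier transforms), never against
any published databank values.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .bank import (Bank, LocalFrameRule, MultipoleParams, default_deformation_radial,
                   element_densities)
from .constants import ATOMIC_NUMBERS
from .crystal import Atom, CrystalStructure, UnitCell, build_bonds
from .sf import StructureFactorSet


# --------------------------------------------------------------------------
# Mini pseudoatom bank

def _entry(label, element, sig_neighbors, p_val, kappa, kappa_prime,
           p_lm=None, frame=None) -> MultipoleParams:
    core, val = element_densities(element)
    return MultipoleParams(
        type_label=label,
        element=element,
        Z=ATOMIC_NUMBERS[element],
        P_val=p_val,
        kappa=kappa,
        kappa_prime=kappa_prime,
        P_lm=dict(p_lm or {}),
        core_density=core,
        valence_density=val,
        deformation_radial=default_deformation_radial(element),
        local_frame_rule=frame or LocalFrameRule(),
        signature=(element, tuple(sorted(sig_neighbors))),
    )


def mini_bank() -> Bank:
    """Fixture bank covering water, carboxylate/amide groups and the
    zwitterionic Gly-Asp dipeptide (first-shell connectivity signatures)."""
    bank = Bank()
    entries = [
        _entry("O_water", "O", ("H", "H"), 6.30, 0.985, 1.10,
               {(1, 0): 0.10, (2, 0): -0.05},
               LocalFrameRule(("H",), ("H",))),
        _entry("H_hydroxyl", "H", ("O",), 0.85, 1.15, 1.20,
               {(1, 0): 0.12},
               LocalFrameRule(("O",), ("*",))),
        # O bonded to one C: carboxylate/carbonyl oxygen, net negative
        _entry("O_carboxylate", "O", ("C",), 6.35, 0.982, 1.08,
               {(1, 0): -0.08, (2, 0): 0.06},
               LocalFrameRule(("C",), ("*",))),
        _entry("N_amide", "N", ("C", "C", "H"), 5.20, 1.000, 1.05,
               {(1, 0): 0.06, (2, 0): -0.04},
               LocalFrameRule(("H",), ("C",))),
        _entry("N_ammonium", "N", ("C", "H", "H", "H"), 5.30, 1.005, 1.05,
               {(3, 2): 0.08},
               LocalFrameRule(("C",), ("H",))),
        _entry("C_alpha_gly", "C", ("C", "H", "H", "N"), 4.05, 1.010, 1.00,
               {(3, 2): 0.12},
               LocalFrameRule(("N",), ("C",))),
        _entry("C_alpha", "C", ("C", "C", "H", "N"), 4.05, 1.010, 1.00,
               {(3, 2): 0.12},
               LocalFrameRule(("N",), ("C",))),
        _entry("C_sp3", "C", ("C", "C", "H", "H"), 4.10, 1.010, 1.00,
               {(3, 2): 0.12},
               LocalFrameRule(("C",), ("C",))),
        _entry("C_amide", "C", ("C", "N", "O"), 3.75, 1.005, 0.95,
               {(2, 0): -0.20, (3, 2): 0.10},
               LocalFrameRule(("O",), ("N",))),
        _entry("C_carboxyl", "C", ("C", "O", "O"), 3.70, 1.005, 0.95,
               {(2, 0): -0.22, (3, 2): 0.10},
               LocalFrameRule(("O",), ("O",))),
        # methyl/alkyl hydrogen
        _entry("H_alkyl", "H", ("C",), 0.90, 1.13, 1.20,
               {(1, 0): 0.10},
               LocalFrameRule(("C",), ("*",))),
        _entry("H_ammonium", "H", ("N",), 0.70, 1.18, 1.25,
               {(1, 0): 0.13},
               LocalFrameRule(("N",), ("*",))),
    ]
    for e in entries:
        bank.add(e)
    return bank


# --------------------------------------------------------------------------
# Internal-coordinate (z-matrix) placement

def _place(a, b, c, r, theta_deg, phi_deg):
    """Position of atom D bonded to c with angle b-c-D and dihedral a-b-c-D."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("collinear reference atoms in z-matrix placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([-r * math.cos(theta),
                        r * math.sin(theta) * math.cos(phi),
                        r * math.sin(theta) * math.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_peptide_fixture(cell_edge: float = 25.0) -> CrystalStructure:
    """Zwitterionic Gly-Asp dipeptide in a P1 cubic cell.

    Carries an ammonium N terminus, a backbone amide and two carboxylate
    groups (side chain and C terminus), so both signs of the Mott-Bethe
    charge divergence are exercised.  Every atom is covered by the mini bank.
    Heavy-atom B factors are protein-like (10-25 A^2); hydrogen B factors are
    left to :func:`taamaps.crystal.assign_hydrogen_b_factors`.
    """
    xyz = {}
    xyz["N"] = np.array([0.0, 0.0, 0.0])
    xyz["CA"] = np.array([1.47, 0.0, 0.0])
    # dummy out-of-line reference fixes the orientation of the first angle
    xyz["C"] = _place(np.array([0.0, 1.0, 0.0]), xyz["N"], xyz["CA"],
                      1.52, 111.0, 35.0)
    zm = [
        # name, bonded-to, angle-ref, dihedral-ref, r, theta, phi
        ("O",   "C",  "CA", "N",   1.23, 121.0,   0.0),
        ("N2",  "C",  "CA", "N",   1.33, 114.0, 180.0),
        ("CA2", "N2", "C",  "CA",  1.46, 121.0, 180.0),
        ("C2",  "CA2", "N2", "C",  1.52, 111.0, 150.0),
        ("OT1", "C2", "CA2", "N2", 1.25, 117.0,  20.0),
        ("OT2", "C2", "CA2", "N2", 1.25, 117.0, 200.0),
        ("CB",  "CA2", "N2", "C",  1.53, 110.0, -90.0),
        ("CG",  "CB", "CA2", "N2", 1.52, 113.0, 180.0),
        ("OD1", "CG", "CB", "CA2", 1.25, 118.0,   0.0),
        ("OD2", "CG", "CB", "CA2", 1.25, 118.0, 180.0),
        ("H1",  "N",  "CA", "C",   1.02, 109.5,  60.0),
        ("H2",  "N",  "CA", "C",   1.02, 109.5, 180.0),
        ("H3",  "N",  "CA", "C",   1.02, 109.5, 300.0),
        ("HA2", "CA", "N",  "C",   1.09, 109.0, 121.0),
        ("HA3", "CA", "N",  "C",   1.09, 109.0, 239.0),
        ("H",   "N2", "C",  "CA",  1.02, 119.0,   0.0),
        ("HA",  "CA2", "N2", "C2", 1.09, 109.0, -120.0),
        ("HB2", "CB", "CA2", "CG", 1.09, 109.0, 121.0),
        ("HB3", "CB", "CA2", "CG", 1.09, 109.0, 239.0),
    ]
    for name, b1, b2, b3, r, theta, phi in zm:
        xyz[name] = _place(xyz[b3], xyz[b2], xyz[b1], r, theta, phi)

    elements = {"N": "N", "N2": "N", "O": "O", "OT1": "O", "OT2": "O",
                "OD1": "O", "OD2": "O"}
    b_iso = {"N": 12.0, "CA": 12.5, "C": 13.0, "O": 15.0, "N2": 13.0,
             "CA2": 13.5, "C2": 16.0, "OT1": 18.0, "OT2": 18.5,
             "CB": 15.0, "CG": 17.0, "OD1": 20.0, "OD2": 21.0}
    cell = UnitCell(cell_edge, cell_edge, cell_edge)
    center = np.mean([p for n, p in xyz.items() if not n.startswith("H")], axis=0)
    atoms = []
    resid = {"N": 1, "CA": 1, "C": 1, "O": 1, "H1": 1, "H2": 1, "H3": 1,
             "HA2": 1, "HA3": 1}
    for name, pos in xyz.items():
        el = elements.get(name, "H" if name.startswith("H") else "C")
        cart = pos - center + cell_edge / 2.0
        res = "GLY1" if resid.get(name) else "ASP2"
        atoms.append(Atom(label=f"A/{res}/{name}", element=el,
                          frac=cell.frac @ cart,
                          b_iso=b_iso.get(name, 0.0),
                          occupancy=1.0))
    st = CrystalStructure(cell=cell, atoms=atoms)
    build_bonds(st)
    return st


def make_water_box(n_waters: int, cell: UnitCell | float = 20.0,
                   seed: int = 0, min_oo: float = 2.5,
                   max_tries: int = 20000) -> CrystalStructure:
    """P1 box of rigid waters (O-H 0.97 A, H-O-H 104.5 deg), random placement
    and orientation, B drawn uniform [10, 40] A^2 for O."""
    if isinstance(cell, (int, float)):
        cell = UnitCell(float(cell), float(cell), float(cell))
    rng = np.random.default_rng(seed)
    centers = []
    tries = 0
    while len(centers) < n_waters:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_waters} waters with O-O >= {min_oo} A")
        cand = rng.random(3)
        ok = True
        for c in centers:
            d = cand - c
            d -= np.round(d)
            if np.linalg.norm(d @ cell.orth.T) < min_oo:
                ok = False
                break
        if ok:
            centers.append(cand)
    atoms = []
    half = math.radians(104.5 / 2.0)
    for w, cfrac in enumerate(centers):
        # random orientation from a QR-decomposed Gaussian matrix
        M = rng.normal(size=(3, 3))
        Q, R = np.linalg.qr(M)
        Q *= np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 2] *= -1
        h1 = Q @ np.array([math.sin(half), 0.0, math.cos(half)]) * 0.97
        h2 = Q @ np.array([-math.sin(half), 0.0, math.cos(half)]) * 0.97
        b_o = rng.uniform(10.0, 40.0)
        ocart = cell.orth @ cfrac
        atoms.append(Atom(label=f"W/HOH{w + 1}/O", element="O",
                          frac=cfrac.copy(), b_iso=b_o))
        for k, h in enumerate((h1, h2), start=1):
            fr = cell.frac @ (ocart + h)
            atoms.append(Atom(label=f"W/HOH{w + 1}/H{k}", element="H",
                              frac=fr - np.floor(fr), b_iso=b_o))
    st = CrystalStructure(cell=cell, atoms=atoms)
    build_bonds(st)
    return st


def make_sheet_fixture(n_strands: int = 8, n_per_strand: int = 24,
                       n_layers: int = 3, seed: int = 11,
                       jitter: float = 0.12) -> CrystalStructure:
    """Protein-like globule of stacked, parallel strands (P1).

    Strand atoms are spaced ~1.45 A along x (covalent backbone distances),
    strands ~4.7 A apart in y and layers ~5.7 A apart in z — the pair-distance
    spectrum of beta-sheet-rich proteins.  This reproduces the characteristic
    non-monotonic Wilson-plot shape (local minimum near 7 A, local maximum
    near 4-5 A) that featureless random atom clouds do not show.
    """
    rng = np.random.default_rng(seed)
    step, dy, dz = 1.45, 4.7, 5.7
    pattern = ["N", "C", "C", "O", "C"]
    pts, els = [], []
    for iz in range(n_layers):
        for iy in range(n_strands):
            phase = rng.uniform(0, step)
            for ix in range(n_per_strand):
                pos = np.array([phase + ix * step,
                                iy * dy + 0.3 * math.sin(ix * 2.1),
                                iz * dz + 0.3 * math.cos(ix * 1.7)])
                pos += rng.normal(scale=jitter, size=3)
                pts.append(pos)
                els.append(pattern[ix % len(pattern)])
    pts = np.array(pts)
    span = pts.max(axis=0) - pts.min(axis=0)
    edges = span + 14.0          # solvent-style empty margin
    cell = UnitCell(*edges)
    offset = -pts.min(axis=0) + 7.0
    atoms = []
    for i, (p, el) in enumerate(zip(pts, els)):
        atoms.append(Atom(label=f"S/GLB1/{el}{i}", element=el,
                          frac=cell.frac @ (p + offset),
                          b_iso=float(rng.uniform(10.0, 30.0))))
    return CrystalStructure(cell=cell, atoms=atoms)


# --------------------------------------------------------------------------
# Synthetic structure-factor pairs with known scale and Delta-B

def make_sf_pair(base: StructureFactorSet, k: float, delta_b: float,
                 noise_sigma: float = 0.0, seed: int = 0):
    """(sf1, sf2) with sf2 = base and
    sf1 = k * exp(-delta_b s^2) * base * exp(eta), eta ~ N(0, noise_sigma).

    The inverse construction of the apparent-Delta-B fit; with zero noise
    fit_delta_b recovers (k, delta_b) exactly.
    """
    s2 = (0.5 / base.reflections.d) ** 2
    factor = k * np.exp(-delta_b * s2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        factor = factor * np.exp(rng.normal(0.0, noise_sigma, size=len(s2)))
    sf1 = base.copy_with(base.F * factor)
    sf2 = base.copy_with(base.F.copy())
    return sf1, sf2
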