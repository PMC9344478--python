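"""Comparison statistics: CC/CCr, covalent-radius averaging, Wilson plots,
R factors, FSC and the apparent Delta-B fit."""

import math

import numpy as np
import pytest
from scipy import stats

from taamaps import compare as cmp
from taamaps import fixtures, sf as sfmod
from taamaps.crystal import Atom, CrystalStructure, UnitCell
from taamaps.maps import DensityMap
from taamaps.sf import ReflectionSet, StructureFactorSet, generate_hkl


def _noise_map(rng, n=32, edge=16.0):
    return DensityMap(rng.normal(size=(n, n, n)), UnitCell(edge, edge, edge))


# --------------------------------------------------------------------------
# CC / CCr

def test_cc_identity_and_negation(rng):
    m = _noise_map(rng)
    neg = DensityMap(-m.data, m.cell)
    assert cmp.cc_around_mean(m, m) == pytest.approx(1.0)
    assert cmp.cc_around_mean(m, neg) == pytest.approx(-1.0)
    assert cmp.cc_rank(m, m) == pytest.approx(1.0)
    assert cmp.cc_rank(m, neg) == pytest.approx(-1.0)


def test_cc_zero_variance_rejected():
    cell = UnitCell(4.0, 4.0, 4.0)
    flat = DensityMap(np.ones((8, 8, 8)), cell)
    other = DensityMap(np.random.default_rng(0).normal(size=(8, 8, 8)), cell)
    with pytest.raises(ValueError, match="variance"):
        cmp.cc_around_mean(flat, other)


def test_cc_white_noise_null():
    """Independent white-noise maps (64^3 voxels): |CC| < 0.01 in the bulk of
    100 seeds (99%-confidence Monte-Carlo null)."""
    n = 64
    cell = UnitCell(16.0, 16.0, 16.0)
    exceed = 0
    for seed in range(100):
        r = np.random.default_rng(seed)
        a = DensityMap(r.normal(size=(n, n, n)), cell)
        b = DensityMap(r.normal(size=(n, n, n)), cell)
        if abs(cmp.cc_around_mean(a, b)) >= 0.01:
            exceed += 1
    # sd of CC under the null is 1/sqrt(N) ~ 0.002; 0.01 is 5 sigma
    assert exceed <= 1


def test_ccr_monotone_invariance(rng):
    """CCr is invariant under strictly monotone voxel transforms."""
    m = _noise_map(rng, n=24)
    warped = DensityMap(np.exp(2.0 * m.data) + 0.3 * m.data**3, m.cell)
    assert cmp.cc_rank(m, warped) == pytest.approx(1.0, abs=1e-12)
    neg_warp = DensityMap(-np.exp(m.data), m.cell)
    assert cmp.cc_rank(m, neg_warp) == pytest.approx(-1.0, abs=1e-12)


def test_ccr_equals_spearman_oracle(rng):
    """On heavy-tailed maps CCr equals the Spearman rank correlation from an
    independent sort-based implementation."""
    n = 16
    a = np.exp(3.0 * rng.normal(size=(n, n, n)))           # log-normal, heavy
    b = a * np.exp(0.8 * rng.normal(size=(n, n, n)))
    cell = UnitCell(8.0, 8.0, 8.0)
    ours = cmp.cc_rank(DensityMap(a, cell), DensityMap(b, cell))
    oracle = stats.spearmanr(a.ravel(), b.ravel()).statistic
    assert ours == pytest.approx(oracle, abs=1e-12)


# --------------------------------------------------------------------------
# Covalent-radius averaging

def test_sampling_point_counts():
    assert len(cmp.sampling_offsets(0.8, 0.1)) == 2103
    assert len(cmp.sampling_offsets(0.099, 0.1)) == 1      # center only
    assert len(cmp.sampling_offsets(0.12, 0.1)) == 7       # center + 6 faces
    # edge neighbors enter at 0.1*sqrt(2) = 0.1414..., strictly inside 0.15
    assert len(cmp.sampling_offsets(0.15, 0.1)) == 19


def test_point_count_independent_of_position(rng):
    """The visited count depends only on radius/spacing, never on where the
    atom sits (50 random positions, random map)."""
    cell = UnitCell(12.0, 12.0, 12.0)
    dmap = DensityMap(rng.normal(size=(40, 40, 40)), cell)
    for _ in range(50):
        st = CrystalStructure(cell=cell, atoms=[
            Atom(label="X/A1/C", element="C", frac=rng.random(3))])
        out = cmp.covalent_radius_average(dmap, st)
        assert out.loc[0, "n_points"] == 2103


def test_average_on_constant_map():
    cell = UnitCell(10.0, 10.0, 10.0)
    dmap = DensityMap(np.full((30, 30, 30), 4.25), cell)
    st = CrystalStructure(cell=cell, atoms=[
        Atom(label="X/A1/O", element="O", frac=np.array([0.3, 0.6, 0.1])),
        Atom(label="X/A1/H", element="H", frac=np.array([0.5, 0.5, 0.5]))])
    out = cmp.covalent_radius_average(dmap, st)
    assert np.allclose(out["mean"], 4.25, atol=1e-12)


def test_small_radius_warns():
    cell = UnitCell(10.0, 10.0, 10.0)
    dmap = DensityMap(np.zeros((20, 20, 20)), cell)
    st = CrystalStructure(cell=cell, atoms=[
        Atom(label="X/A1/C", element="C", frac=np.array([0.5, 0.5, 0.5]))])
    with pytest.warns(UserWarning, match="single-point"):
        out = cmp.covalent_radius_average(dmap, st, radii={"C": 0.05})
    assert out.loc[0, "n_points"] == 1


# --------------------------------------------------------------------------
# Wilson plots

def test_wilson_single_atom_decays():
    cell = UnitCell(14.0, 14.0, 14.0)
    st = CrystalStructure(cell=cell, atoms=[
        Atom(label="X/A1/O", element="O", frac=np.zeros(3), b_iso=0.0)])
    refl = generate_hkl(cell, 1.5)
    sf = sfmod.structure_factors(st, refl, "iam", "xray")
    shells = cmp.wilson_plot(sf)
    means = shells.table["mean_F2"].to_numpy()
    assert np.all(np.diff(means) < 0)


def test_wilson_b_factor_ratio():
    """Shell-mean ratio between B=8 and B=0 follows exp(-2 B s^2) at the
    per-shell mean of s^2 (closed form, within binning error)."""
    cell = UnitCell(14.0, 14.0, 14.0)
    refl = generate_hkl(cell, 1.5)
    st0 = CrystalStructure(cell=cell, atoms=[
        Atom(label="X/A1/O", element="O", frac=np.zeros(3), b_iso=0.0)])
    stb = CrystalStructure(cell=cell, atoms=[
        Atom(label="X/A1/O", element="O", frac=np.zeros(3), b_iso=8.0)])
    sf0 = sfmod.structure_factors(st0, refl, "iam", "xray")
    sfb = sfmod.structure_factors(stb, refl, "iam", "xray")
    w0 = cmp.wilson_plot(sf0).table
    wb = cmp.wilson_plot(sfb).table
    for row0, rowb in zip(w0.itertuples(), wb.itertuples()):
        s2 = row0.mean_inv_d2 / 4.0
        ratio = rowb.mean_F2 / row0.mean_F2
        assert ratio == pytest.approx(math.exp(-2 * 8.0 * s2), rel=0.02)


def test_wilson_protein_like_shape():
    """A sheet-like globule shows the characteristic local minimum in the
    5.5-10 A region followed by a local maximum in the 3.5-5.5 A region."""
    st = fixtures.make_sheet_fixture()
    refl = generate_hkl(st.cell, 1.9)
    sf = sfmod.structure_factors(st, refl, "iam", "xray")
    t = cmp.wilson_plot(sf).table
    d = 1.0 / np.sqrt(t["bin_center"].to_numpy())
    f2 = t["mean_F2"].to_numpy()
    low = f2[d > 10.0].max()
    dip = f2[(d > 5.5) & (d <= 10.0)].min()
    bump = f2[(d > 3.5) & (d <= 5.5)].max()
    assert dip < low / 3
    assert bump > 3 * dip


# --------------------------------------------------------------------------
# R factor

def test_r_factor_identity_and_scale(water_sf):
    assert cmp.r_factor(water_sf, water_sf) == 0.0
    doubled = water_sf.copy_with(2.0 * water_sf.F)
    assert cmp.r_factor(water_sf, doubled, scale="lsq") == pytest.approx(
        0.0, abs=1e-14)
    assert cmp.r_factor(water_sf, doubled) == pytest.approx(1.0)


def test_r_factor_hand_computed_toy():
    cell = UnitCell(10.0, 10.0, 10.0)
    hkl = np.array([[h, 0, 0] for h in range(1, 6)]
                   + [[0, k, 0] for k in range(1, 6)])
    refl = ReflectionSet(hkl, cell.d_spacing(hkl), 2.0, cell)
    a1 = np.arange(1.0, 11.0)
    a2 = a1.copy()
    a2[0] += 0.5
    a2[7] -= 1.0
    sf1 = StructureFactorSet(reflections=refl, F=a1.astype(complex))
    sf2 = StructureFactorSet(reflections=refl, F=a2.astype(complex))
    # R = sum|a1 - a2| / sum a1 = (0.5 + 1.0) / 55
    assert cmp.r_factor(sf1, sf2) == pytest.approx(1.5 / 55.0, rel=1e-12)


def test_r_factor_mismatched_lists():
    cell = UnitCell(10.0, 10.0, 10.0)
    h1 = np.array([[1, 0, 0], [2, 0, 0]])
    h2 = np.array([[1, 0, 0], [0, 2, 0]])
    sf1 = StructureFactorSet(
        reflections=ReflectionSet(h1, cell.d_spacing(h1), 2.0, cell),
        F=np.ones(2, complex))
    sf2 = StructureFactorSet(
        reflections=ReflectionSet(h2, cell.d_spacing(h2), 2.0, cell),
        F=np.ones(2, complex))
    with pytest.raises(ValueError, match="mismatch"):
        cmp.r_factor(sf1, sf2)


# --------------------------------------------------------------------------
# FSC

def test_fsc_identity_every_bin(peptide_sf):
    """FSC(model, same model) = 1 in every 0.1 A^-1 bin."""
    sf = peptide_sf[("taam", "electron")]
    shells = cmp.fsc(sf, sf)
    assert np.allclose(shells.table["fsc"], 1.0, atol=1e-12)


def test_fsc_negated_is_minus_one(water_sf):
    neg = water_sf.copy_with(-water_sf.F)
    shells = cmp.fsc(water_sf, neg)
    assert np.allclose(shells.table["fsc"], -1.0, atol=1e-12)


def test_fsc_random_phase_null():
    """Independent random phases, >= 1000 reflections per bin: |FSC| < 0.1."""
    cell = UnitCell(40.0, 40.0, 40.0)
    refl = generate_hkl(cell, 2.4)
    rng = np.random.default_rng(17)
    amp = rng.lognormal(0.0, 0.4, size=len(refl))
    F1 = amp * np.exp(2j * np.pi * rng.random(len(refl)))
    F2 = amp * np.exp(2j * np.pi * rng.random(len(refl)))
    sf1 = StructureFactorSet(reflections=refl, F=F1)
    sf2 = StructureFactorSet(reflections=refl, F=F2)
    shells = cmp.fsc(sf1, sf2)
    big = shells.table[shells.table["n"] >= 1000]
    assert len(big) >= 2
    assert np.all(np.abs(big["fsc"]) < 0.1)


def test_fsc_and_r_invariant_under_global_phase(water_sf):
    rot = water_sf.copy_with(water_sf.F * np.exp(1j * 0.83))
    rot2 = water_sf.copy_with(water_sf.F * np.exp(1j * 0.83))
    base = cmp.fsc(water_sf, water_sf).table["fsc"].to_numpy()
    rotated = cmp.fsc(rot, rot2).table["fsc"].to_numpy()
    assert np.allclose(base, rotated, atol=1e-12)
    assert cmp.r_factor(rot, rot2) == pytest.approx(
        cmp.r_factor(water_sf, water_sf), abs=1e-14)


# --------------------------------------------------------------------------
# Delta-B fit

def test_delta_b_exact_recovery(water_sf):
    sf1, sf2 = fixtures.make_sf_pair(water_sf, k=1.1, delta_b=2.0)
    fit = cmp.fit_delta_b(sf1, sf2, binned=False)
    assert fit.k == pytest.approx(1.1, abs=1e-6)
    assert fit.delta_B == pytest.approx(2.0, abs=1e-6)
    fit_b = cmp.fit_delta_b(sf1, sf2, binned=True)
    assert fit_b.delta_B == pytest.approx(2.0, abs=0.05)
    assert fit_b.k == pytest.approx(1.1, abs=0.02)


def test_delta_b_identity(water_sf):
    fit = cmp.fit_delta_b(water_sf, water_sf)
    assert fit.k == pytest.approx(1.0, abs=1e-12)
    assert fit.delta_B == pytest.approx(0.0, abs=1e-12)


def test_delta_b_antisymmetric(water_sf):
    sf1, sf2 = fixtures.make_sf_pair(water_sf, k=1.3, delta_b=-1.5)
    fwd = cmp.fit_delta_b(sf1, sf2)
    rev = cmp.fit_delta_b(sf2, sf1)
    assert rev.delta_B == pytest.approx(-fwd.delta_B, abs=1e-9)
    assert rev.k == pytest.approx(1.0 / fwd.k, rel=1e-9)


def test_delta_b_noise_recovery(deltab_base):
    """5% log-normal amplitude noise, 100 seeds: Delta-B recovered within
    0.1 A^2 and essentially unbiased.

    The ~1.5 A-resolution base set gives a predicted estimator sd of about
    0.02 A^2, making 0.1 A^2 a comfortable bound rather than a coin flip."""
    errs = []
    for seed in range(100):
        sf1, sf2 = fixtures.make_sf_pair(deltab_base, k=1.1, delta_b=2.0,
                                         noise_sigma=0.05, seed=seed)
        fit = cmp.fit_delta_b(sf1, sf2, binned=True)
        errs.append(fit.delta_B - 2.0)
    errs = np.asarray(errs)
    assert np.max(np.abs(errs)) < 0.1
    assert abs(errs.mean()) < 0.02


def test_delta_b_needs_three_bins():
    cell = UnitCell(10.0, 10.0, 10.0)
    hkl = np.array([[1, 0, 0], [0, 1, 0]])
    refl = ReflectionSet(hkl, cell.d_spacing(hkl), 5.0, cell)
    sf = StructureFactorSet(reflections=refl, F=np.ones(2, complex))
    with pytest.raises(ValueError, match="at least 3"):
        cmp.fit_delta_b(sf, sf)
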