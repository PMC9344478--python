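"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pytest

from taamaps import bank as bankmod
from taamaps import crystal, fixtures
from taamaps import sf as sfmod


@pytest.fixture(scope="session")
def mini_bank():
    return fixtures.mini_bank()


@pytest.fixture(scope="session")
def peptide():
    """Prepared Gly-Asp zwitterion: H B-factor rules and neutron X-H lengths."""
    st = fixtures.make_peptide_fixture()
    crystal.assign_hydrogen_b_factors(st)
    crystal.extend_xh_bonds(st)
    return st


@pytest.fixture(scope="session")
def peptide_assignment(peptide, mini_bank):
    asn = bankmod.assign_atom_types(peptide, mini_bank)
    return bankmod.normalize_charge(asn, 0.0)


@pytest.fixture(scope="session")
def peptide_refl(peptide):
    return sfmod.generate_hkl(peptide.cell, 1.8)


@pytest.fixture(scope="session")
def peptide_sf(peptide, peptide_refl, peptide_assignment):
    """The four model/radiation combinations on the peptide fixture (with B)."""
    out = {}
    for model in ("taam", "iam"):
        for radiation in ("electron", "xray"):
            out[(model, radiation)] = sfmod.structure_factors(
                peptide, peptide_refl, model=model, radiation=radiation,
                assignment=peptide_assignment)
    return out


@pytest.fixture(scope="session")
def water_sf():
    """Small water-box IAM X-ray set used as a generic amplitude carrier."""
    st = fixtures.make_water_box(8, 15.0, seed=3)
    refl = sfmod.generate_hkl(st.cell, 2.2)
    return sfmod.structure_factors(st, refl, model="iam", radiation="xray")


@pytest.fixture(scope="session")
def deltab_base():
    """Single-atom 1.5 A-resolution set used as the carrier for synthetic
    scale/Delta-B pairs: ~10^4 reflections give the log-ratio fit a
    predicted standard error of ~0.02 A^2 at 5% amplitude noise."""
    from taamaps.crystal import Atom, CrystalStructure, UnitCell

    cell = UnitCell(20.0, 20.0, 20.0)
    st = CrystalStructure(cell=cell, atoms=[
        Atom(label="X/A1/O", element="O", frac=np.array([0.3, 0.4, 0.6]),
             b_iso=15.0)])
    refl = sfmod.generate_hkl(cell, 1.5)
    return sfmod.structure_factors(st, refl, model="iam", radiation="xray")


@pytest.fixture()
def rng():
    return np.random.default_rng(20220714)
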