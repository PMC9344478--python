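"""Crystal and atomic data model, structure readers and preparation rules.

Fractional coordinates are used internally everywhere; orthogonal (Cartesian,
angstrom) coordinates appear only at I/O boundaries and for distances.
Structure preparation implements the protocol used for electrostatic-potential
map calculation from deposited models: riding-hydrogen B factors (120% of the
bonded heavy atom, 150% for methyl and water H), X-H bond extension to
neutron-like distances, and special-position handling on P1 expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (ATOMIC_NUMBERS, BOND_TOLERANCE, COVALENT_RADII,
                        NEUTRON_XH_LENGTHS, element_key)


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell geometry with cached orthogonalization and reciprocal metric."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    @property
    def orth(self) -> np.ndarray:
        """3x3 matrix M with cart = M @ frac (columns are the cell vectors)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def frac(self) -> np.ndarray:
        return np.linalg.inv(self.orth)

    @property
    def recip(self) -> np.ndarray:
        """Matrix with columns a*, b*, c* (Cartesian); s_vec = recip @ hkl."""
        return np.linalg.inv(self.orth).T

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.orth)))

    def d_spacing(self, hkl) -> np.ndarray:
        """Resolution d (angstrom) of reflections, vectorized over (..., 3)."""
        hkl = np.asarray(hkl, dtype=float)
        svec = hkl @ self.recip.T
        return 1.0 / np.linalg.norm(svec, axis=-1)

    def scattering_vectors(self, hkl):
        """(g, unit direction) of reciprocal vectors in the Cartesian frame."""
        hkl = np.asarray(hkl, dtype=float)
        svec = hkl @ self.recip.T
        g = np.linalg.norm(svec, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            direction = svec / g[..., None]
        return g, direction

    def min_image_cart(self, dfrac) -> np.ndarray:
        """Cartesian vector of a fractional difference under minimum image."""
        d = np.asarray(dfrac, dtype=float)
        d = d - np.round(d)
        return d @ self.orth.T

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")


@dataclass
class Atom:
    label: str
    element: str
    frac: np.ndarray
    b_iso: float = 0.0
    occupancy: float = 1.0
    type_label: str | None = None
    multiplicity: int = 1

    def __post_init__(self):
        self.frac = np.asarray(self.frac, dtype=float)
        if self.b_iso < 0:
            raise ValueError(f"atom {self.label}: B_iso must be >= 0")
        if not 0 < self.occupancy <= 1:
            raise ValueError(f"atom {self.label}: occupancy must be in (0, 1]")

    @property
    def Z(self) -> int:
        return ATOMIC_NUMBERS[element_key(self.element)]

    @property
    def is_hydrogen(self) -> bool:
        return element_key(self.element) in ("H", "D")


@dataclass
class CrystalStructure:
    """Unit cell, symmetry operators, atoms and bonds.

    Symmetry operators are (rotation, translation) pairs acting on fractional
    coordinates: x' = R @ x + t.
    """

    cell: UnitCell
    atoms: list
    symmetry: list = field(default_factory=lambda: [(np.eye(3), np.zeros(3))])
    bonds: list = field(default_factory=list)
    spacegroup: str = "P 1"

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            cell=self.cell,
            atoms=[replace(a, frac=a.frac.copy()) for a in self.atoms],
            symmetry=[(R.copy(), t.copy()) for R, t in self.symmetry],
            bonds=list(self.bonds),
            spacegroup=self.spacegroup,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


# --------------------------------------------------------------------------
# Bonds

def build_bonds(structure: CrystalStructure) -> list:
    """Distance-based bond list: d < r_cov(i) + r_cov(j) + 0.4 A (minimum image)."""
    atoms = structure.atoms
    n = len(atoms)
    if n == 0:
        return []
    radii = np.array([COVALENT_RADII.get(element_key(a.element), 1.5) for a in atoms])
    fr = np.array([a.frac for a in atoms])
    bonds = []
    d = fr[:, None, :] - fr[None, :, :]
    d -= np.round(d)
    cart = d @ structure.cell.orth.T
    dist = np.linalg.norm(cart, axis=-1)
    cut = radii[:, None] + radii[None, :] + BOND_TOLERANCE
    ii, jj = np.where((dist < cut) & (dist > 1e-6))
    for i, j in zip(ii, jj):
        if i < j:
            bonds.append((int(i), int(j)))
    structure.bonds = bonds
    return bonds


# --------------------------------------------------------------------------
# Readers / writers (gemmi-backed)

def read_structure(path) -> CrystalStructure:
    """Read a PDB or mmCIF file.

    The element column is authoritative; files without it, without a unit
    cell, or carrying anisotropic displacement parameters are rejected.
    For alternate conformations the highest-occupancy copy is kept.
    """
    import gemmi

    st = gemmi.read_structure(str(path), merge_chain_parts=True)
    st.remove_alternative_conformations()
    cell = st.cell
    if cell.a <= 1.0 or cell.volume <= 1.001:
        raise ValueError(f"{path}: no usable unit cell (CRYST1/cell record required)")
    ucell = UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm or "P 1")
    if sg is None:
        raise ValueError(f"{path}: unknown space group {st.spacegroup_hm!r}")
    ops = []
    for op in sg.operations():
        R = np.array(op.rot, dtype=float) / op.DEN
        t = np.array(op.tran, dtype=float) / op.DEN
        ops.append((R, t))
    atoms = []
    model = st[0]
    for chain in model:
        for residue in chain:
            for at in residue:
                if at.element.name in ("X", ""):
                    raise ValueError(
                        f"{path}: atom {at.name} in {residue.name} has no element "
                        "(element column required; no guessing from the label)")
                if at.aniso.nonzero():
                    raise ValueError(
                        f"{path}: atom {at.name} carries anisotropic displacement "
                        "parameters; only isotropic B factors are supported")
                frac = cell.fractionalize(at.pos)
                atoms.append(Atom(
                    label=f"{chain.name}/{residue.name}{residue.seqid.num}/{at.name}",
                    element=at.element.name,
                    frac=np.array([frac.x, frac.y, frac.z]),
                    b_iso=at.b_iso,
                    occupancy=at.occ,
                ))
    out = CrystalStructure(cell=ucell, atoms=atoms, symmetry=ops,
                           spacegroup=sg.hm)
    build_bonds(out)
    return out


def write_pdb(structure: CrystalStructure, path) -> None:
    """Write the structure as a minimal single-chain PDB (fixture emission)."""
    import gemmi

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(structure.cell.a, structure.cell.b, structure.cell.c,
                             structure.cell.alpha, structure.cell.beta,
                             structure.cell.gamma)
    st.spacegroup_hm = structure.spacegroup
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res_by_key = {}
    for idx, a in enumerate(structure.atoms):
        parts = a.label.split("/")
        if len(parts) == 3:
            resname = "".join(ch for ch in parts[1] if ch.isalpha()) or "LIG"
            seq = int("".join(ch for ch in parts[1] if ch.isdigit()) or idx + 1)
            name = parts[2]
        else:
            resname, seq, name = "LIG", 1, a.label[:4]
        key = (resname, seq)
        if key not in res_by_key:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(seq, " ")
            res_by_key[key] = res
        res = res_by_key[key]
        at = gemmi.Atom()
        at.name = name
        at.element = gemmi.Element(element_key(a.element).capitalize())
        cart = structure.cell.orth @ a.frac
        at.pos = gemmi.Position(*cart)
        at.b_iso = a.b_iso
        at.occ = a.occupancy
        res.add_atom(at)
    for res in res_by_key.values():
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# --------------------------------------------------------------------------
# Symmetry expansion

def expand_to_p1(structure: CrystalStructure, merge_tol: float = 0.01
                 ) -> CrystalStructure:
    """Generate all symmetry images, merging special-position copies.

    Images within ``merge_tol`` angstrom of an already placed site are merged
    and the site multiplicity (number of operators landing on the site) is
    recorded.  Counting the merged site once is equivalent to the
    operator-sum convention of scaling the pseudoatom populations by
    1/multiplicity: there, the coincident images are summed multiplicity
    times at 1/multiplicity weight each.
    """
    cell = structure.cell
    new_atoms = []
    for atom in structure.atoms:
        placed = []       # (frac, count)
        for R, t in structure.symmetry:
            x = R @ atom.frac + t
            x -= np.floor(x)
            merged = False
            for k, (xf, cnt) in enumerate(placed):
                if np.linalg.norm(cell.min_image_cart(x - xf)) < merge_tol:
                    placed[k] = (xf, cnt + 1)
                    merged = True
                    break
            if not merged:
                placed.append((x, 1))
        for xf, cnt in placed:
            new_atoms.append(replace(
                atom,
                frac=xf.copy(),
                multiplicity=cnt,
            ))
    out = CrystalStructure(cell=cell, atoms=new_atoms,
                           symmetry=[(np.eye(3), np.zeros(3))],
                           spacegroup="P 1")
    build_bonds(out)
    return out


# --------------------------------------------------------------------------
# Preparation rules

def _bonded_heavy(structure: CrystalStructure, i: int):
    """Nearest bonded non-hydrogen neighbor of atom i (index), or None."""
    best, best_d = None, np.inf
    for j in structure.neighbors(i):
        if structure.atoms[j].is_hydrogen:
            continue
        d = np.linalg.norm(structure.cell.min_image_cart(
            structure.atoms[j].frac - structure.atoms[i].frac))
        if d < best_d:
            best, best_d = j, d
    return best


def _is_methyl_carbon(structure: CrystalStructure, i: int) -> bool:
    h = heavy = 0
    for j in structure.neighbors(i):
        if structure.atoms[j].is_hydrogen:
            h += 1
        else:
            heavy += 1
    return element_key(structure.atoms[i].element) == "C" and h == 3 and heavy == 1


def _is_water_oxygen(structure: CrystalStructure, i: int) -> bool:
    if element_key(structure.atoms[i].element) != "O":
        return False
    return all(structure.atoms[j].is_hydrogen for j in structure.neighbors(i))


def assign_hydrogen_b_factors(structure: CrystalStructure) -> CrystalStructure:
    """Riding-H B factors: 1.2x the nearest bonded heavy atom's B, or 1.5x for
    methyl-group and water hydrogens.  Idempotent."""
    for i, atom in enumerate(structure.atoms):
        if not atom.is_hydrogen:
            continue
        parent = _bonded_heavy(structure, i)
        if parent is None:
            raise ValueError(f"hydrogen {atom.label} has no bonded heavy atom")
        factor = 1.2
        if _is_methyl_carbon(structure, parent) or _is_water_oxygen(structure, parent):
            factor = 1.5
        atom.b_iso = factor * structure.atoms[parent].b_iso
    return structure


def extend_xh_bonds(structure: CrystalStructure,
                    target_lengths: dict | None = None) -> CrystalStructure:
    """Move each H outward along its X->H bond to the target (neutron) length.

    Heavy atoms never move.  Idempotent by construction (target reached).
    """
    targets = dict(NEUTRON_XH_LENGTHS)
    if target_lengths:
        targets.update({(element_key(a), element_key(b)): v
                        for (a, b), v in target_lengths.items()})
    cell = structure.cell
    for i, atom in enumerate(structure.atoms):
        if not atom.is_hydrogen:
            continue
        parent = _bonded_heavy(structure, i)
        if parent is None:
            raise ValueError(f"hydrogen {atom.label} has no bonded heavy atom")
        pel = element_key(structure.atoms[parent].element)
        key = (pel, "H")
        if key not in targets:
            raise KeyError(
                f"no target X-H length for pair {pel}-H (atom {atom.label}); "
                f"known pairs: {sorted(targets)}")
        vec = cell.min_image_cart(atom.frac - structure.atoms[parent].frac)
        d = np.linalg.norm(vec)
        if d < 1e-6:
            raise ValueError(f"degenerate X-H bond at {atom.label}")
        new_cart = (structure.cell.orth @ structure.atoms[parent].frac
                    ) + vec * (targets[key] / d)
        newf = cell.frac @ new_cart
        atom.frac = newf - np.floor(newf)
    return structure


def total_electrons(structure: CrystalStructure) -> float:
    """Occupancy-weighted electron count (Z sum) of the atom list."""
    return float(sum(a.occupancy * a.Z for a in structure.atoms))
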