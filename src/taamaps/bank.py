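"""Pseudoatom parameter bank: Hansen-Coppens multipole parameters per atom type.

A pseudoatom partitions the atomic charge density into a spherical core, a
kappa-scalable spherical valence shell and a kappa'-scalable multipolar
deformation expanded in density-normalized real spherical harmonics:

    rho(r) = rho_core(r) + P_val kappa^3 rho_val(kappa r)
             + sum_l kappa'^3 R_l(kappa' r) sum_m P_lm d_lm(r_hat)

Radial parts are sums of Slater primitives ``c * r^n * exp(-zeta r)`` stored
directly in a line-oriented text bank format (grammar below), so every entry
is self-contained and checkable by quadrature.

Bank file grammar (UTF-8, ``#`` starts a comment, blank lines ignored)::

    bank      := { entry }
    entry     := "TYPE" label element NL { field NL }
    field     := "SIG"    element { neighbor_element }
               | "PVAL"   float
               | "KAPPA"  float
               | "KPRIME" float
               | "PLM"    l m_token float        # m_token: 0 | 1+ | 1- | ...
               | "CORE"   n zeta coeff           # Slater primitive of rho_core
               | "VAL"    n zeta coeff           # Slater primitive of rho_val
               | "DEFRAD" l n zeta               # normalized R_l(r)
               | "FRAME"  ax1_elems ax2_elems chirality
                                                  # elems comma-separated, "*" = any

``CORE`` primitives must integrate (4 pi int rho r^2 dr) to the element's
core-electron count; ``VAL`` primitives to one electron (scaled by P_val).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ATOMIC_NUMBERS, CORE_ELECTRONS, element_key

logger = logging.getLogger(__name__)

L_MAX = 4


# --------------------------------------------------------------------------
# Slater primitives

def slater_integral(n: int, zeta: float) -> float:
    """``int_0^inf r^(n+2) exp(-zeta r) dr`` = (n+2)! / zeta^(n+3)."""
    return math.factorial(n + 2) / zeta ** (n + 3)


def density_norm(primitives) -> float:
    """Total electron count of a spherically averaged density: 4 pi int rho r^2 dr."""
    return 4.0 * math.pi * sum(c * slater_integral(n, z) for c, n, z in primitives)


def radial_norm(n: int, zeta: float) -> float:
    """Normalization of R_l(r) = N r^n exp(-zeta r) so that int R r^2 dr = 1."""
    return zeta ** (n + 3) / math.factorial(n + 2)


# --------------------------------------------------------------------------
# Data model

@dataclass(frozen=True)
class LocalFrameRule:
    """Axis definition for the nucleus-centered local frame.

    ``axis1_neighbors`` lists element patterns tried in order to pick the
    neighbor that defines the local z axis; ``axis2_neighbors`` picks a second
    neighbor fixing the xz half-plane.  ``"*"`` matches any element.
    ``chirality`` of -1 rotates the frame 180 degrees about z (determinant
    stays +1).
    """

    axis1_neighbors: tuple = ()
    axis2_neighbors: tuple = ()
    chirality: int = 1


@dataclass(frozen=True)
class MultipoleParams:
    """One pseudoatom type's Hansen-Coppens parameters."""

    type_label: str
    element: str
    Z: int
    P_val: float
    kappa: float
    kappa_prime: float
    # P_lm keyed by (l, m) with signed m: m > 0 cosine, m < 0 sine, m = 0 axial
    P_lm: dict = field(default_factory=dict)
    core_density: tuple = ()       # ((coeff, n, zeta), ...)
    valence_density: tuple = ()
    deformation_radial: dict = field(default_factory=dict)   # l -> (n, zeta)
    local_frame_rule: LocalFrameRule = field(default_factory=LocalFrameRule)
    signature: tuple | None = None   # (element, (sorted neighbor elements...))

    @property
    def P_core(self) -> float:
        return float(CORE_ELECTRONS[element_key(self.element)])

    @property
    def net_charge(self) -> float:
        return self.Z - self.P_core - self.P_val

    def validate(self) -> None:
        if self.kappa <= 0 or self.kappa_prime <= 0:
            raise ValueError(f"{self.type_label}: kappa and kappa' must be > 0")
        for prims, name in ((self.core_density, "CORE"), (self.valence_density, "VAL")):
            for c, n, z in prims:
                if z <= 0:
                    raise ValueError(f"{self.type_label}: {name} zeta must be > 0")
                if n < 0:
                    raise ValueError(f"{self.type_label}: {name} power n must be >= 0")
        ncore = density_norm(self.core_density)
        if abs(ncore - self.P_core) > 1e-6:
            raise ValueError(
                f"{self.type_label}: core density integrates to {ncore:.8f} e, "
                f"expected {self.P_core:.0f} (core electrons of {self.element})")
        nval = density_norm(self.valence_density)
        if abs(nval - 1.0) > 1e-6:
            raise ValueError(
                f"{self.type_label}: valence density integrates to {nval:.8f} e, "
                "expected 1 (normalized to one electron)")
        for (l, m) in self.P_lm:
            if not (0 <= l <= L_MAX and abs(m) <= l):
                raise ValueError(f"{self.type_label}: invalid multipole index (l={l}, m={m})")
            if l > 0 and l not in self.deformation_radial:
                raise ValueError(
                    f"{self.type_label}: populated l={l} has no DEFRAD radial function")
        for l, (n, z) in self.deformation_radial.items():
            if z <= 0:
                raise ValueError(f"{self.type_label}: DEFRAD zeta must be > 0")
            if n + 2 <= l:
                raise ValueError(
                    f"{self.type_label}: DEFRAD l={l} needs n + 2 > l for integrability")


@dataclass
class Bank:
    """Collection of pseudoatom types keyed by connectivity signature."""

    entries: list = field(default_factory=list)
    by_signature: dict = field(default_factory=dict)

    def add(self, entry: MultipoleParams) -> None:
        entry.validate()
        if entry.signature is not None:
            if entry.signature in self.by_signature:
                raise ValueError(f"duplicate connectivity signature {entry.signature}")
            self.by_signature[entry.signature] = entry
        self.entries.append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, signature) -> MultipoleParams | None:
        return self.by_signature.get(signature)


# --------------------------------------------------------------------------
# Bank file I/O

def _parse_m_token(tok: str) -> int:
    if tok.endswith("+"):
        return int(tok[:-1])
    if tok.endswith("-"):
        return -int(tok[:-1])
    return int(tok)


def _format_m(m: int) -> str:
    if m > 0:
        return f"{m}+"
    if m < 0:
        return f"{-m}-"
    return "0"


class BankParseError(ValueError):
    pass


def read_bank(path) -> Bank:
    """Parse a bank file.  Raises :class:`BankParseError` naming the offending line."""
    bank = Bank()
    cur: dict | None = None

    def finish():
        nonlocal cur
        if cur is None:
            return
        entry = MultipoleParams(
            type_label=cur["label"],
            element=cur["element"],
            Z=ATOMIC_NUMBERS[element_key(cur["element"])],
            P_val=cur.get("pval", 0.0),
            kappa=cur.get("kappa", 1.0),
            kappa_prime=cur.get("kprime", 1.0),
            P_lm=cur.get("plm", {}),
            core_density=tuple(cur.get("core", [])),
            valence_density=tuple(cur.get("val", [])),
            deformation_radial=cur.get("defrad", {}),
            local_frame_rule=cur.get("frame", LocalFrameRule()),
            signature=cur.get("sig"),
        )
        bank.add(entry)
        cur = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            kw = toks[0].upper()
            try:
                if kw == "TYPE":
                    finish()
                    cur = {"label": toks[1], "element": toks[2]}
                    continue
                if cur is None:
                    raise BankParseError("field outside of a TYPE block")
                if kw == "SIG":
                    cur["sig"] = (element_key(toks[1]),
                                  tuple(sorted(element_key(t) for t in toks[2:])))
                elif kw == "PVAL":
                    cur["pval"] = float(toks[1])
                elif kw == "KAPPA":
                    cur["kappa"] = float(toks[1])
                elif kw == "KPRIME":
                    cur["kprime"] = float(toks[1])
                elif kw == "PLM":
                    l = int(toks[1])
                    m = _parse_m_token(toks[2])
                    cur.setdefault("plm", {})[(l, m)] = float(toks[3])
                elif kw == "CORE":
                    cur.setdefault("core", []).append(
                        (float(toks[3]), int(toks[1]), float(toks[2])))
                elif kw == "VAL":
                    cur.setdefault("val", []).append(
                        (float(toks[3]), int(toks[1]), float(toks[2])))
                elif kw == "DEFRAD":
                    cur.setdefault("defrad", {})[int(toks[1])] = (int(toks[2]), float(toks[3]))
                elif kw == "FRAME":
                    ax1 = tuple(element_key(t) if t != "*" else "*"
                                for t in toks[1].split(","))
                    ax2 = tuple(element_key(t) if t != "*" else "*"
                                for t in toks[2].split(","))
                    chir = int(toks[3]) if len(toks) > 3 else 1
                    if chir not in (1, -1):
                        raise BankParseError("chirality must be +1 or -1")
                    cur["frame"] = LocalFrameRule(ax1, ax2, chir)
                else:
                    raise BankParseError(f"unknown keyword {kw!r}")
            except BankParseError as exc:
                raise BankParseError(f"{path}:{lineno}: {exc}") from None
            except (IndexError, ValueError) as exc:
                raise BankParseError(f"{path}:{lineno}: malformed {kw} line: {exc}") from None
    try:
        finish()
    except ValueError as exc:
        raise BankParseError(f"{path}: {exc}") from None
    if not bank.entries:
        logger.warning("bank file %s contains no entries", path)
    return bank


def write_bank(bank: Bank, path) -> None:
    """Write a bank; numeric fields use repr precision so round-trips are exact."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pseudoatom parameter bank\n")
        for e in bank.entries:
            fh.write(f"\nTYPE {e.type_label} {e.element}\n")
            if e.signature is not None:
                fh.write("SIG " + e.signature[0] + "".join(
                    f" {n}" for n in e.signature[1]) + "\n")
            fh.write(f"PVAL {e.P_val!r}\n")
            fh.write(f"KAPPA {e.kappa!r}\n")
            fh.write(f"KPRIME {e.kappa_prime!r}\n")
            for (l, m), p in sorted(e.P_lm.items()):
                fh.write(f"PLM {l} {_format_m(m)} {p!r}\n")
            for c, n, z in e.core_density:
                fh.write(f"CORE {n} {z!r} {c!r}\n")
            for c, n, z in e.valence_density:
                fh.write(f"VAL {n} {z!r} {c!r}\n")
            for l, (n, z) in sorted(e.deformation_radial.items()):
                fh.write(f"DEFRAD {l} {n} {z!r}\n")
            fr = e.local_frame_rule
            if fr.axis1_neighbors or fr.axis2_neighbors:
                fh.write("FRAME {} {} {:+d}\n".format(
                    ",".join(fr.axis1_neighbors) or "*",
                    ",".join(fr.axis2_neighbors) or "*",
                    fr.chirality))


# --------------------------------------------------------------------------
# Built-in spherical neutral densities (fallback pseudoatoms)
#
# Single-zeta Slater shells with Slater-rule effective exponents; density
# exponents are 2 Zeff / (n* a0) in 1/angstrom.  Each entry: core shells as
# (n_electrons, n_power, zeta), valence shell as (n_power, zeta).

_A0 = 0.52917721
_ELEMENT_SHELLS = {
    "H": {"core": [], "val": (0, 2 * 1.00 / _A0)},
    "C": {"core": [(2, 0, 2 * 5.70 / _A0)], "val": (2, 2 * (3.25 / 2) / _A0)},
    "N": {"core": [(2, 0, 2 * 6.70 / _A0)], "val": (2, 2 * (3.90 / 2) / _A0)},
    "O": {"core": [(2, 0, 2 * 7.70 / _A0)], "val": (2, 2 * (4.55 / 2) / _A0)},
    "P": {"core": [(2, 0, 2 * 14.70 / _A0), (8, 2, 2 * (10.85 / 2) / _A0)],
          "val": (4, 2 * (4.80 / 3) / _A0)},
    "S": {"core": [(2, 0, 2 * 15.70 / _A0), (8, 2, 2 * (11.85 / 2) / _A0)],
          "val": (4, 2 * (5.45 / 3) / _A0)},
    "CL": {"core": [(2, 0, 2 * 16.70 / _A0), (8, 2, 2 * (12.85 / 2) / _A0)],
           "val": (4, 2 * (6.10 / 3) / _A0)},
}


def _shell_primitive(n_electrons: float, n: int, zeta: float):
    coeff = n_electrons * zeta ** (n + 3) / (4.0 * math.pi * math.factorial(n + 2))
    return (coeff, n, zeta)


def element_densities(element: str):
    """(core_primitives, valence_primitives) for a neutral spherical atom.

    Core integrates to the core-electron count, valence to one electron.
    """
    key = element_key(element)
    if key not in _ELEMENT_SHELLS:
        raise KeyError(
            f"no built-in Slater density for element {element!r}; "
            f"available: {sorted(_ELEMENT_SHELLS)}")
    shells = _ELEMENT_SHELLS[key]
    core = tuple(_shell_primitive(ne, n, z) for ne, n, z in shells["core"])
    n_v, z_v = shells["val"]
    val = (_shell_primitive(1.0, n_v, z_v),)
    return core, val


def default_deformation_radial(element: str) -> dict:
    """Per-l Slater radial functions (n_l, zeta_l) used by the fixture bank."""
    key = element_key(element)
    _, (c, n_v, z_v) = (None, element_densities(element)[1][0])
    if key == "H":
        powers = {1: 1, 2: 2, 3: 2, 4: 3}
    else:
        powers = {1: 2, 2: 2, 3: 3, 4: 4}
    return {l: (powers[l], z_v) for l in range(1, L_MAX + 1)}


def fallback_params(element: str) -> MultipoleParams:
    """Spherical neutral pseudoatom (IAM-equivalent): no multipoles, kappa = 1."""
    key = element_key(element)
    Z = ATOMIC_NUMBERS[key]
    core, val = element_densities(element)
    return MultipoleParams(
        type_label=f"{key}_spherical",
        element=key,
        Z=Z,
        P_val=float(Z - CORE_ELECTRONS[key]),
        kappa=1.0,
        kappa_prime=1.0,
        core_density=core,
        valence_density=val,
        deformation_radial=default_deformation_radial(element),
    )


# --------------------------------------------------------------------------
# Atom-type assignment

def connectivity_signature(structure, index: int) -> tuple:
    """(element, sorted multiset of bonded-neighbor elements) for one atom."""
    atom = structure.atoms[index]
    neigh = []
    for i, j in structure.bonds:
        if i == index:
            neigh.append(element_key(structure.atoms[j].element))
        elif j == index:
            neigh.append(element_key(structure.atoms[i].element))
    return (element_key(atom.element), tuple(sorted(neigh)))


@dataclass
class Assignment:
    """Result of matching structure atoms against a bank."""

    params: list                 # MultipoleParams per atom (fallbacks included)
    unassigned: list             # indices that fell back to spherical neutral

    def __getitem__(self, i):
        return self.params[i]

    def total_charge(self, structure=None) -> float:
        return float(sum(p.net_charge for p in self.params))


def assign_atom_types(structure, bank: Bank) -> Assignment:
    """Map every atom to a bank entry by connectivity signature.

    Atoms whose signature has no bank entry are reported in ``unassigned`` and
    given spherical neutral fallback parameters (never silently dropped).
    """
    params, unassigned = [], []
    for i in range(len(structure.atoms)):
        sig = connectivity_signature(structure, i)
        entry = bank.lookup(sig)
        if entry is None:
            unassigned.append(i)
            entry = fallback_params(structure.atoms[i].element)
            logger.warning(
                "atom %s (%s, neighbors %s) has no bank entry; "
                "using spherical neutral fallback",
                structure.atoms[i].label, sig[0], ",".join(sig[1]) or "none")
        params.append(entry)
    return Assignment(params=params, unassigned=unassigned)


def normalize_charge(assignment: Assignment, target_total_charge: float) -> Assignment:
    """Uniformly scale P_val so the summed atomic charges hit the target.

    Keeps relative valence populations; solves
    ``sum_j (Z_j - P_core_j - s * P_val_j) = target``.
    """
    sum_zc = sum(p.Z - p.P_core for p in assignment.params)
    sum_pval = sum(p.P_val for p in assignment.params)
    needed = sum_zc - target_total_charge
    if abs(sum_pval) < 1e-12:
        if abs(needed) > 1e-9:
            raise ValueError("total P_val is zero; cannot redistribute charge")
        return assignment
    scale = needed / sum_pval
    new = [replace(p, P_val=p.P_val * scale) for p in assignment.params]
    return Assignment(params=new, unassigned=list(assignment.unassigned))


# --------------------------------------------------------------------------
# Local frames

def _pick_neighbor(patterns, candidates, used):
    """First candidate matching the ordered element patterns; None otherwise."""
    for pat in patterns:
        for idx, elem, dist in candidates:
            if idx in used:
                continue
            if pat == "*" or pat == elem:
                return idx
    return None


def resolve_local_frames(structure, assignment: Assignment) -> list:
    """Right-handed orthonormal local frame (columns = local x, y, z in the
    Cartesian crystal frame) for every atom, from its bonded neighbors.

    Neighbor candidates are ordered by (element, distance, label) so the result
    is independent of atom input order.  Atoms with no usable neighbors get the
    identity frame (only meaningful for spherical pseudoatoms).
    """
    cell = structure.cell
    frames = []
    neighbors_of = {i: [] for i in range(len(structure.atoms))}
    for i, j in structure.bonds:
        neighbors_of[i].append(j)
        neighbors_of[j].append(i)
    for i, atom in enumerate(structure.atoms):
        rule = assignment[i].local_frame_rule
        cands = []
        for j in neighbors_of[i]:
            vec = cell.min_image_cart(structure.atoms[j].frac - atom.frac)
            cands.append((j, element_key(structure.atoms[j].element),
                          float(np.linalg.norm(vec))))
        # distances quantized to 1e-6 A so ties break by label, not by
        # float rounding (keeps frames invariant under rigid translations)
        cands.sort(key=lambda t: (t[1], round(t[2], 6),
                                  structure.atoms[t[0]].label))
        used = set()
        n1 = _pick_neighbor(rule.axis1_neighbors or ("*",), cands, used)
        if n1 is None:
            frames.append(np.eye(3))
            continue
        used.add(n1)
        z = cell.min_image_cart(structure.atoms[n1].frac - atom.frac)
        z = z / np.linalg.norm(z)
        n2 = _pick_neighbor(rule.axis2_neighbors or ("*",), cands, used)
        if n2 is None:
            # any perpendicular completes the frame for axially symmetric types
            probe = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(probe, z)) > 0.9:
                probe = np.array([0.0, 1.0, 0.0])
            x = probe - np.dot(probe, z) * z
        else:
            v = cell.min_image_cart(structure.atoms[n2].frac - atom.frac)
            x = v - np.dot(v, z) * z
        nx = np.linalg.norm(x)
        if nx < 1e-8:
            probe = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(probe, z)) > 0.9:
                probe = np.array([0.0, 1.0, 0.0])
            x = probe - np.dot(probe, z) * z
            nx = np.linalg.norm(x)
        x = x / nx
        y = np.cross(z, x)
        if rule.chirality == -1:     # 180-degree rotation about z keeps det = +1
            x, y = -x, -y
        frames.append(np.column_stack([x, y, z]))
    return frames
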