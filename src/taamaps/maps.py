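"""Fourier synthesis of periodic density/potential maps and map I/O.

rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x), evaluated by FFT on a grid whose
voxel edge does not exceed the requested target in any cell direction.
F(000) is always excluded, so synthesized maps are zero-mean by construction;
experimental-style offsets are reintroduced only through :func:`scale_map`.

Units bookkeeping: a map synthesized from electron-radiation structure
factors (form factors in angstrom) carries raw units "A^-2" and is converted
to electrostatic-potential units e/A by :func:`to_e_per_angstrom`
(multiplication by 2 pi a0); X-ray maps are electron density in e/A^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .constants import E_PER_ANGSTROM_FACTOR
from .crystal import UnitCell
from .sf import StructureFactorSet


@dataclass
class DensityMap:
    """Periodic voxel grid over the unit cell.

    ``data[i, j, k]`` is the value at fractional coordinate
    (i/nx, j/ny, k/nz); the x index varies fastest in the memory contract.
    """

    data: np.ndarray
    cell: UnitCell
    units: str = "arbitrary"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("map data must be a 3-D array")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel(self) -> np.ndarray:
        """Approximate voxel edge lengths (cell edge / grid dim) per axis."""
        n = np.array(self.data.shape)
        return np.array([self.cell.a, self.cell.b, self.cell.c]) / n

    def sigma(self) -> float:
        return float(self.data.std())

    def interpolate_frac(self, frac_points) -> np.ndarray:
        """Periodic trilinear interpolation at fractional coordinates (..., 3)."""
        pts = np.atleast_2d(np.asarray(frac_points, dtype=float))
        n = np.array(self.data.shape)
        coords = (pts % 1.0) * n
        return ndimage.map_coordinates(self.data, coords.T, order=1,
                                       mode="grid-wrap")


def _grid_dims(cell: UnitCell, voxel_target: float, max_index) -> tuple:
    dims = []
    for edge, hmax in zip((cell.a, cell.b, cell.c), max_index):
        n = int(np.ceil(edge / voxel_target))
        if n % 2:
            n += 1
        if n < 2 * hmax + 2:
            raise ValueError(
                f"voxel target {voxel_target} A gives a {n}-point grid along a "
                f"{edge:.2f} A axis, below the Nyquist limit for index {hmax}; "
                "use a finer voxel target")
        dims.append(n)
    return tuple(dims)


def fourier_map(sf: StructureFactorSet, voxel_target: float = 0.3) -> DensityMap:
    """Inverse-Fourier synthesis of a structure-factor set.

    Accepts a Friedel-complete set or a hemisphere (``sf.hemisphere`` True),
    which is conjugate-completed on the fly.  The tiny imaginary residue of
    the FFT is asserted below 1e-8 of the map maximum and discarded.
    """
    cell = sf.reflections.cell
    hkl = sf.reflections.hkl
    F = sf.F
    max_index = np.abs(hkl).max(axis=0) if len(hkl) else (0, 0, 0)
    dims = _grid_dims(cell, voxel_target, max_index)
    A = np.zeros(dims, dtype=complex)
    idx = tuple((hkl % dims).T)
    A[idx] = F
    if sf.hemisphere:
        neg = tuple(((-hkl) % dims).T)
        A[neg] = np.conj(F)
    rho = np.fft.fftn(A) / cell.volume
    peak = np.abs(rho).max()
    if peak > 0 and np.abs(rho.imag).max() > 1e-8 * peak:
        raise ValueError("synthesized map has a non-negligible imaginary part; "
                         "input set is not Friedel-consistent")
    units = "A^-2" if sf.radiation == "electron" else "e/A^3"
    return DensityMap(
        data=rho.real, cell=cell, units=units,
        provenance={"model": sf.model, "radiation": sf.radiation,
                    "smearing": sf.smearing, "d_min": sf.reflections.d_min,
                    "voxel_target": voxel_target})


def to_e_per_angstrom(dmap: DensityMap) -> DensityMap:
    """Convert a raw electron-scattering potential map to e/A units.

    The Fourier coefficient of the Coulomb potential in e/A is
    (Z - f_x)/(pi g^2) per cell while the Mott-Bethe coefficient is
    (Z - f_x)/(2 pi^2 a0 g^2); the voxelwise conversion is the ratio
    2 pi a0.
    """
    if dmap.provenance.get("radiation") != "electron" or dmap.units not in (
            "A^-2",):
        raise ValueError("e/A conversion applies only to raw maps synthesized "
                         "from electron-radiation structure factors")
    out = replace(dmap, data=dmap.data * E_PER_ANGSTROM_FACTOR)
    out.units = "e/A"
    out.provenance = dict(dmap.provenance)
    return out


def scale_map(dmap: DensityMap, reference_sigma: float,
              zero_mean: bool = True) -> DensityMap:
    """Shift to zero mean and scale the voxel standard deviation to match a
    reference (typically the experimental map's sigma)."""
    if reference_sigma <= 0:
        raise ValueError("reference_sigma must be positive")
    sigma = dmap.data.std()
    if sigma == 0:
        raise ValueError("cannot scale a constant map")
    data = dmap.data - dmap.data.mean() if zero_mean else dmap.data.copy()
    data *= reference_sigma / sigma
    out = replace(dmap, data=data)
    out.units = "sigma-scaled"
    out.provenance = dict(dmap.provenance, reference_sigma=reference_sigma)
    return out


def resample_map(dmap: DensityMap, new_voxel: float) -> DensityMap:
    """Periodic trilinear resampling onto a coarser grid (voxel edge target)."""
    if new_voxel < min(dmap.voxel) - 1e-9:
        raise ValueError("resampling is meant for coarsening; new voxel must "
                         "not be finer than the current grid")
    dims = []
    for edge in (dmap.cell.a, dmap.cell.b, dmap.cell.c):
        n = max(2, int(np.ceil(edge / new_voxel)))
        if n % 2:
            n += 1
        dims.append(n)
    fr = np.stack(np.meshgrid(*[np.arange(n) / n for n in dims],
                              indexing="ij"), axis=-1).reshape(-1, 3)
    vals = dmap.interpolate_frac(fr).reshape(dims)
    out = replace(dmap, data=vals)
    out.provenance = dict(dmap.provenance, resampled_voxel=new_voxel)
    return out


# --------------------------------------------------------------------------
# Plane sections (deformation-map figures)

def plane_section(dmap: DensityMap, origin_frac, normal_cart,
                  extent: float = 6.0, spacing: float = 0.1):
    """Sample the map on a plane through ``origin_frac`` with the given
    Cartesian normal.  Returns (u, v, values) with u/v in angstrom along two
    in-plane axes; values by periodic trilinear interpolation."""
    normal = np.asarray(normal_cart, dtype=float)
    normal = normal / np.linalg.norm(normal)
    probe = np.array([1.0, 0.0, 0.0])
    if abs(probe @ normal) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = probe - (probe @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    ticks = np.arange(-extent / 2, extent / 2 + 1e-9, spacing)
    U, V = np.meshgrid(ticks, ticks, indexing="ij")
    origin_cart = dmap.cell.orth @ np.asarray(origin_frac, dtype=float)
    pts = (origin_cart[None, None, :] + U[..., None] * e1[None, None, :]
           + V[..., None] * e2[None, None, :])
    frac = pts.reshape(-1, 3) @ dmap.cell.frac.T
    vals = dmap.interpolate_frac(frac).reshape(U.shape)
    return ticks, ticks, vals


def plane_from_atoms(cell: UnitCell, frac_a, frac_b, frac_c):
    """(origin_frac, normal_cart) of the plane through three atom positions."""
    pa = cell.orth @ np.asarray(frac_a, float)
    pb = cell.orth @ np.asarray(frac_b, float)
    pc = cell.orth @ np.asarray(frac_c, float)
    normal = np.cross(pb - pa, pc - pa)
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise ValueError("the three positions are collinear")
    return np.asarray(frac_a, float), normal / nn


# --------------------------------------------------------------------------
# File I/O: MRC/CCP4 (mode 2) via gemmi, and Situs ASCII

def write_map(dmap: DensityMap, path, fmt: str = "mrc") -> None:
    if fmt == "mrc":
        import gemmi

        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(*dmap.data.shape)
        m.grid.unit_cell = gemmi.UnitCell(
            dmap.cell.a, dmap.cell.b, dmap.cell.c,
            dmap.cell.alpha, dmap.cell.beta, dmap.cell.gamma)
        m.grid.spacegroup = gemmi.find_spacegroup_by_name("P 1")
        arr = np.array(m.grid, copy=False)
        arr[:] = dmap.data.astype(np.float32)
        m.update_ccp4_header(2, True)
        m.write_ccp4_map(str(path))
    elif fmt == "situs":
        if not (abs(dmap.cell.alpha - 90) < 1e-6 and abs(dmap.cell.beta - 90) < 1e-6
                and abs(dmap.cell.gamma - 90) < 1e-6):
            raise ValueError("Situs ASCII export supports orthogonal cells only")
        vx = dmap.voxel
        if not np.allclose(vx, vx[0], atol=1e-6):
            raise ValueError("Situs export needs cubic voxels; "
                             "choose grid-compatible cell/voxel")
        nx, ny, nz = dmap.data.shape
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{vx[0]:.6f} 0.000000 0.000000 0.000000 {nx} {ny} {nz}\n\n")
            flat = np.transpose(dmap.data, (2, 1, 0)).ravel()   # x fastest
            for i in range(0, len(flat), 10):
                fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 10]) + "\n")
    else:
        raise ValueError(f"unknown map format {fmt!r}")


def read_map(path, fmt: str = "mrc") -> DensityMap:
    if fmt == "mrc":
        import gemmi

        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"))        # normalize axis order to X, Y, Z
        cell = m.grid.unit_cell
        data = np.array(m.grid, copy=True).astype(float)
        return DensityMap(
            data=data,
            cell=UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta,
                          cell.gamma),
            units="arbitrary", provenance={"source": str(path)})
    if fmt == "situs":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            voxel = float(header[0])
            nx, ny, nz = int(header[4]), int(header[5]), int(header[6])
            vals = []
            for line in fh:
                vals.extend(float(t) for t in line.split())
        data = np.array(vals).reshape(nz, ny, nx).transpose(2, 1, 0)
        cell = UnitCell(voxel * nx, voxel * ny, voxel * nz)
        return DensityMap(data=data, cell=cell, units="arbitrary",
                          provenance={"source": str(path)})
    raise ValueError(f"unknown map format {fmt!r}")
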