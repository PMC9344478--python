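# Methods

This note records the scientific and numerical choices behind `taamaps`: the
scattering models, the conventions that fix signs and units, what the
synthetic fixtures do and do not emulate, and the known limitations.

## Scattering models

**IAM.** Spherical neutral atoms. X-ray form factors use the International
Tables four-Gaussian-plus-constant fits (carried internally as five
Gaussians with b₅ = 0); electron form factors use the Peng five-Gaussian
parametrization directly. The electron IAM deliberately does *not* route
through Mott–Bethe: the published electron tables are the model definition.
Both coefficient sets are taken from gemmi's bundled copies of the published
tables; a CSV loader accepts user-supplied alternatives. Ionic IAM entries
are out of scope — IAM here is strictly neutral-atom.

**TAAM.** Hansen–Coppens pseudoatoms

ρ(**r**) = ρ_core(r) + P_val κ³ ρ_val(κr) + Σ_l κ′³ R_l(κ′r) Σ_m P_lm d_lm(r̂)

with all radial parts stored as Slater primitive sums c·rⁿ·e^(−ζr) in a
self-contained text bank. Core densities integrate to the element's
core-electron count (P_core is the core count), valence densities to one
electron, both enforced at parse time to 1e-6. Deformation radials
R_l(r) = N·r^(n_l)·e^(−ζ_l r) are normalized so ∫R_l r²dr = 1. The analytic
X-ray factor is

f(**h**) = f_core(g) + P_val f_val(g/κ) + Σ_l 4π i^l ⟨j_l⟩(g/κ′) Σ_m P_lm d_lm(ĥ_loc)

with ⟨j_l⟩ the Fourier–Bessel transform of R_l and ĥ_loc the unit scattering
vector expressed in the atom's local frame. The κ and κ′ scalings enter as
argument rescalings g/κ and g/κ′, i.e. density dilations. The i^l phases are
kept explicit (odd-l terms are imaginary), so Friedel symmetry
f(−**h**) = f*(**h**) holds for the real density.

**Normalization convention.** The literature varies in how the 4π and the
harmonic normalization are split. Here d_lm are *density-normalized* real
harmonics: d₀₀ = 1/4π and ∫|d_lm|dΩ = 2 for l ≥ 1, so a population P_lm
transfers |P_lm| electrons between the positive and negative lobes. The
normalization constants are computed once by adaptive quadrature (root-split
at the Legendre zeros) and cached; an independent lpmv-based quadrature in
the tests confirms them to 1e-8. The arbiter for the overall convention is
a brute-force 3-D numerical Fourier transform of the sampled pseudoatom
density, which the analytic factors must match to 1e-3 e — they agree to
~1e-6 e on the fixture types.

**Mott–Bethe.** f_e(g) = (Z − f_x(g))/(2π² a₀ g²) with a₀ = 0.52917721 Å.
This is the m₀e²/(8πε₀h²) prefactor (Planck h) reduced via a₀ = 4πε₀ħ²/m e²;
the bare-charge value f_e(g=1) = 0.09573 Å pins the constant. TAAM electron
factors are the exact composition mott_bethe(Z, f_x) — no Gaussian
refitting, valid at any resolution. The formula is applied per atom to the
*static* factor, then Debye–Waller and phase factors multiply the result:
the nucleus is smeared identically to its electron cloud (rigid pseudoatom).

## Slater Fourier–Bessel transforms

I(n,ζ,l;g) = ∫₀^∞ rⁿ e^(−ζr) j_l(2πgr) r²dr is evaluated in closed form from
∫ r^p e^(−ζr) e^(itr) dr = p!/(ζ−it)^(p+1) through the j_l recurrence,
descending the power together with l. For small arguments
(t·(n+l+3)/ζ < 1) the ascending series of j_l is used instead, because the
trigonometric closed form loses precision to cancellation there. The two
branches are verified against adaptive quadrature to ~1e-10 relative across
the parameter range used by the bank. Integrability requires n + 2 > l,
enforced as a domain error.

## Crystal model and preparation rules

Fractional coordinates are used internally everywhere; symmetry and phases
are exact in fractional space. Structures are read from PDB/mmCIF via gemmi
(element column authoritative, anisotropic ADPs rejected — the model here is
isotropic B), space-group operators come from gemmi's tables, and bonds are
detected by distance: d < r_cov,i + r_cov,j + 0.4 Å with a single covalent
radius table shared with the map-averaging statistics.

Preparation mirrors common practice for potential-map calculation from
deposited models: riding-hydrogen B factors are 1.2× the nearest bonded
heavy atom (1.5× for methyl and water H); X–H bonds are extended to
neutron-like lengths (C–H 1.09, N–H 1.02, O–H 0.97, S–H 1.34 Å, overridable
— these defaults are this package's choice of typical neutron values). Both
operations are idempotent.

P1 expansion applies every operator, wraps into the cell and merges images
within 0.01 Å, recording the site multiplicity. Counting a merged
special-position site once is arithmetically identical to the operator-sum
convention of scaling pseudoatom populations by 1/multiplicity. Local frames
are re-resolved from the expanded geometry (minimum-image neighbor vectors)
rather than rotated, which is equivalent for symmetry copies. Frame rules
pick the z axis toward the first neighbor matching an element pattern and
the xz plane toward a second; neighbor candidates are ordered by (element,
distance quantized to 1e-6 Å, label) so assignment and frames are invariant
under atom reordering and rigid translations. Chirality −1 rotates the frame
180° about z, keeping the determinant +1.

Atom typing matches first-shell connectivity signatures (element + sorted
neighbor elements). This deliberately collapses chemically distinct
environments with equal first shells (e.g. amide vs carboxylate oxygen) —
a documented simplification relative to full databank ontologies. Unmatched
atoms fall back, loudly, to spherical neutral pseudoatoms whose f(0) = Z to
1e-4. `normalize_charge` rescales all P_val uniformly to reach a target
total charge, preserving ratios.

## Reflections, structure factors, maps

Reflection sets are 100%-complete spheres d ≥ d_min, generated either
directly or by the cube-fill-then-truncate route; the two must agree exactly
and are regression-tested against each other. The Debye–Waller convention is
exp(−B s²) with s = 1/(2d), asserted in tests. Structure factors are direct
sums over the P1 atom list, chunked over reflections; TAAM caches the
spherical part per atom type.

Maps are synthesized by FFT on grids of the smallest even dimensions giving
voxel edges ≤ the target (0.3 Å default); indices beyond the grid Nyquist
limit raise an error instructing a finer grid. F(000) is always excluded, so
maps are zero-mean by construction; `scale_map` then matches a reference σ.
A map from electron-radiation factors (Å units) is converted to e Å⁻¹
potential by multiplying by 2π a₀ — the ratio between the Coulomb Fourier
coefficient (Z−f_x)/(πg²) and the Mott–Bethe coefficient — validated against
a hard-coded 1/(πg²) point-charge series in the tests. Parseval and the
σ = √(Σ|F|²)/V corollary hold to 1e-6 and are asserted. 2-D deformation
sections are trilinear plane extractions from a fine (0.1 Å) 3-D synthesis.
MRC/CCP4 mode-2 I/O goes through gemmi (non-XYZ axis orders are permuted on
read); Situs ASCII export covers orthogonal cells.

## Comparison statistics

CC is the Pearson correlation of mean-subtracted voxels (optionally under a
mask of voxels within 3 Å of any atom); CCr rank-transforms both maps first
(average ranks on ties) and equals Spearman correlation. Covalent-radius
averaging samples an axis-aligned cubic lattice centered on the atom at
0.1 Å spacing, keeping points *strictly* inside the element radius; the
strict inequality is fixed by the 2103-point count of a 0.8 Å carbon sphere
(≤ would give 2109). Note that a 0.15 Å radius visits 19 points, not 7,
because edge neighbors sit at 0.1·√2 ≈ 0.141 Å; 7 points corresponds to a
0.12 Å radius. Wilson plots bin ⟨|F|²⟩ in half-open 0.01 Å⁻² shells of 1/d²;
FSC uses Re(ΣF₁F₂*)/√(Σ|F₁|²Σ|F₂|²) in 0.1 Å⁻¹ shells of 1/d; R = Σ||F₁|−k|F₂||/Σ|F₁|
with k = 1 or the least-squares scale.

The apparent ΔB fit solves |F₁|/|F₂| = k·e^(−ΔB s²) by least squares on the
log ratio — per reflection (exact in the noiseless limit) or on Wilson bins
(default, mirroring slope analysis of the squared-amplitude relation; the
log-bin route is numerically stabler and identical in the noiseless limit).
The fit is exactly antisymmetric under swapping the inputs. Statistical
design of the noise test: the synthetic carrier set (~10⁴ reflections to
1.5 Å in a 20 Å cell) was sized a priori so the estimator's standard error
at 5% log-normal amplitude noise is ≈0.02 Å², making the 0.1 Å² recovery
bound a ≈4.5σ statement rather than a coin flip.

## Fixtures: what they emulate and what they do not

* **Gly–Asp zwitterion** (idealized internal-coordinate geometry, 25 Å P1
  cell, protein-like B factors): provides ammonium (+) and carboxylate (−)
  groups so both signs of the Mott–Bethe divergence are exercised, with
  every atom covered by the mini bank.
* **Water box**: rigid waters (O–H 0.97 Å, 104.5°), uniform-random placement
  with 2.5 Å O–O exclusion, B ~ U[10, 40] Å².
* **Sheet-like globule** (~580 atoms): parallel strands of 1.45 Å-spaced
  backbone-like atoms, 4.7 Å strand spacing, 5.7 Å layer stacking, 0.12 Å
  jitter. This pair-distance spectrum — not any tuning of the statistics —
  produces the protein-typical Wilson-plot shape (local minimum near 8 Å,
  local maximum near 4.7 Å). Random uniform atom clouds do not show it.
* **Mini bank**: physically plausible but invented parameters (Slater-rule
  exponents, modest charges and multipoles). Tests compare it only against
  internal oracles, never against published databank values.

Consequently, passing tests demonstrate the correctness of the machinery —
transforms, conventions, statistics — on idealized inputs. They do not
demonstrate agreement with experimental 3D ED maps of real proteins, which
additionally involves databank-quality parameters, solvent, dynamical
scattering and experimental noise, all out of scope here.

## Numerical choices and degenerate inputs

* Tie-breaks: frame-neighbor ordering quantizes distances to 1e-6 Å; rank
  ties average; empty FSC bins are reported missing rather than NaN.
* Maps with a non-negligible FFT imaginary residue (>1e-8 of max) raise —
  this catches Friedel-inconsistent input instead of silently discarding it.
* Constant maps are rejected by scaling/correlation; zero-variance inputs
  raise.
* `generate_hkl` estimates the reflection count up front and refuses runs
  that would exceed a configurable cap.
* Incomplete-data audit: deleting 3.17% of Friedel pairs drawn from the
  weakest amplitude quintile changes the synthesized map by <5% of σ;
  deletion uniform in |F| would remove ~√0.0317 ≈ 18% of the RMS by
  Parseval, so the weak-biased draw is the physically meaningful reading of
  experimental incompleteness.

## Known limitations

First-shell-only atom typing; neutral-atom IAM only; isotropic B only;
kinematical scattering (no dynamical/inelastic effects, no absorption or
anomalous corrections); no solvent model; Situs export restricted to
orthogonal cells; the mini bank is a fixture, not a substitute for a curated
databank.
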