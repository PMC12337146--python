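# Methods

This note documents the models implemented in `xspol`, the numerical
choices behind them, and what the test suite does and does not
establish.

## Physical model

### Onsager spherical-cavity model (`xspol.onsager`)

A molecule is a polarizable point dipole (intrinsic polarizability α,
Å³) at the centre of a spherical vacuum cavity of radius `a` (Å) in a
homogeneous dielectric with optical permittivity ε = n² (Maxwell
relation; an explicit ε takes precedence over n when both are given, and
a supplied pair must agree to 0.1%).  The implemented chain is

```
f_c  = 3ε/(2ε+1)                      cavity-field factor, ∈ [1, 1.5]
f_RF = 2(ε−1)/(a³(2ε+1))              reaction-field factor, Å⁻³
F_RF = 1/(1 − f_RF·α)                 self-consistent enhancement
α̃   = f_c·F_RF·α                     effective polarizability
α̅   = f_c·α̃                         energy-effective polarizability
α̅_B|A = α̅_B − α̅_A·V_B,m/V_A,m      excess polarizability
```

Each species' own reaction-field enhancement multiplies its own α in the
excess combination (the direct substitution of the energy expression
into the excess definition).  The regime f_RF·α ≥ 1 is a polarization
catastrophe and is rejected with an explicit error rather than returning
a negative enhancement.  Polarizabilities are CGS volume polarizabilities
in Å³ throughout; field amplitudes are an arbitrary linear scale because
only products and ratios appear.  Permanent-dipole (static) solvation
energetics are out of scope.

### Cavities and tessellation (`xspol.cavity`)

The molecular cavity is the union of atom-centred spheres with radii
`UFF_vdW × 1.1` by default (radii table shipped as CSV, overridable per
call).  Each sphere carries an icosphere mesh (icosahedron with `level`
4-fold subdivisions; 20·4^level triangles).  A tessera is a triangular
patch represented by its projected centroid; its area is the exact
spherical-triangle solid angle (van Oosterom–Strackee), so a closed
sphere sums to 4πr² to machine precision at every level.  Patches whose
representative point lies strictly inside another sphere are culled
(exposure test, no exact spherical-polygon clipping).  The residual seam
bias of this culling is bounded empirically: union areas agree with a
Monte-Carlo surface-exposure estimate to ~2% and union volumes with the
analytic sphere–sphere lens formula to <1% at levels ≥ 2.  The bias is
not monotone in the subdivision level (culling is all-or-nothing per
patch), which is why convergence claims are made for the BEM factors and
not for union volumes.

Volumes come from either (a) the divergence theorem,
V = ⅓ Σ aᵢ (rᵢ − p)·nᵢ with p the sphere-centroid origin to reduce
cancellation (exact for a single centred sphere), or (b) seeded
hit-or-miss Monte Carlo over the union's bounding box (default 10⁶
samples, minimum 10⁴ enforced, binomial standard error reported on
request).  Molar-volume ratios V_B,m/V_A,m are approximated by cavity
volume ratios computed with identical settings for both cavities.

### Boundary-element solver (`xspol.bem`)

Both continuum problems — the reaction field of interior sources and the
cavity (local) field of a uniform Maxwell field — reduce to one
dielectric jump condition for the total potential
φ = φ_source + (single layer σ):

```
ε ∂φ/∂n|out = ∂φ/∂n|in      on the cavity surface (vacuum inside).
```

Collocation at tessera centres with the standard single-layer jump
relations gives

```
[ 2π(ε+1)/(ε−1)·I − K·A ] σ = ∂φ_source/∂n ,
Kᵢⱼ = −(rᵢ−rⱼ)·nᵢ/|rᵢ−rⱼ|³ (i≠j),   A = diag(areas),
```

with the K diagonal fixed by the closed-surface Gauss sum rule
Σⱼ Kᵢⱼaⱼ = −2π.  The source term is the normal derivative of the bare
potential: a point charge or dipole inside the cavity for the reaction
problem, φ(s) = −E·s for the uniform-field (cavity-field) problem.  The
correctness contract is the set of analytic sphere limits, all
reproduced at icosphere level 3 to ≤1e-5 relative:

* total apparent charge of a centred charge q: −q(ε−1)/ε (Born) —
  exact at machine precision at any level because the constant mode is
  fixed exactly by the sum rule;
* reaction potential at the centre: −q(ε−1)/(εa);
* reaction-field factor of a centred dipole: 2(ε−1)/(a³(2ε+1));
* interior field under a uniform Maxwell field: (3ε/(2ε+1))·E, uniform
  across the cavity.

Errors in the dipole-mode quantities shrink ≈8× per subdivision level.
The solver is a dense direct solve (LAPACK); intended problem sizes are
≲10⁴ tesserae, so no iterative machinery or preconditioning is used.
ε = 1 short-circuits to zero induced charge.  The single-layer matrix S
(diagonal 1.0694·√(4π/aᵢ)) is assembled alongside K as a diagnostic; it
is symmetric positive definite on well-separated tessellations.

The molecular cavity-field factor `cavity_field_factor_vdw` is the mean
over interior probe points (atom centres by default, or a rejection-
sampled grid kept ≥30% of a radius away from the surface) of the
interior-field component along the applied direction.  This is a
*classical field average*; it coincides with the quantum response-based
factor (the α̅/α̃ ratio) in the sphere limit but not in general.  For
the water vdW cavity the classical average evaluates to ≈1.17 against
the response-based reference 1.1536 for the same cavity — the package
reports the classical value and makes no claim of reproducing the
response-based one.

### Excess polarizability and experimental extraction (`xspol.excess`)

The combination rule α̅_B|A = α̅_B − α̅_A·V_B,m/V_A,m is exact by
construction in the returned record.  Experimental counterparts follow
from standard dielectric theory of a dilute optical medium
(ε = n² = 1 + 4πNα̃ with N = N_A/V_m):

```
α̃_exp    = (n²−1)·V_m/(4π N_A)                   pure solvent
α̅_exp    = f_c·α̃_exp
α̅_B|A^exp = f_c·(n/2π)·(dn/dm_B)·M/N_A           from the refractive-
                                                  index increment
```

(the last from linearizing n² in the solute number density:
2n·δn = 4π·N_B·α̃_excess).  Validation against the reference water pair
(1.7871 / 2.0612 Å³ from n = 1.3223, V_m = 18.069 cm³/mol) agrees to
≤0.05%, and the full ssDNA experimental column (n = 1.332,
dn/dm = 0.168 cm³/g) row-wise to ≤1.1%.  The residuals reflect the use
of a single solvent-wide cavity factor f_c = 1.1536 where per-molecule
factors (≈1.151–1.166, obtained by back-solving the printed column)
would close the gap; f_c is overridable per call.  N_A = 6.02214×10²³,
conversions centralized in `xspol.constants`.  No frequency-dispersion
model: the single working wavelength (1312.8 nm) is carried as a label.

### Sequences and masses (`xspol.sequences`)

Oligonucleotide molar mass uses the 5′-OH, fully deprotonated polyanion
convention: Σ residue masses (dA 313.21, dC 289.18, dG 329.21, dT 304.2,
matching IUPAC-atomic-weight residue compositions to 0.01 g/mol) minus
61.96 (end group) minus 1.008·(n−1) (one proton per phosphodiester
linkage).  The reference mass table is reproduced to ±0.04 g/mol in 12
of 14 rows; the remaining two printed entries disagree with *any*
residue-additive formula at the ±0.05 level (the printed table violates
its own single-residue additivity by ~0.1 g/mol in those rows), so the
package keeps the chemically standard constants and documents the
scatter rather than refitting constants to the printed digits.

### Regressions and reports (`xspol.analysis`)

Unweighted OLS with intercept (scipy `linregress`; R², slope and
intercept standard errors).  The polarizability–mass regression over the
14 oligomers gives slope 0.1253 Å³/(g/mol), intercept 2.03 Å³, R² ≈ 1 —
polarizability is effectively additive over chemical units.  The
theory-vs-experiment regression puts the computed column on y and the
experimental on x; the flagged misprinted experimental entry (printed
2450.6 Å³ where its own inputs give ≈247.8) is excluded by default or
replaced by its recomputed value on request — both give slope ≈1.012
— and is never silently patched in the fixture, which stores printed
values verbatim.  Reports round to the reference precision (1 decimal
for Å³ tables, 4 for factors) and are byte-deterministic given fixtures
and config.

## Synthetic geometries

`synth_geometry` samples atoms uniformly in a cube of half-width
`spread` (element symbols cycling C/N/O/H) with a seeded generator; it
exists to exercise cavity construction and the BEM on irregular
sphere unions of controlled size and overlap.  It emulates nothing about
real molecular structure (no bonding, no realistic densities), so tests
built on it establish the *geometric and electrostatic* correctness of
the cavity/BEM layer, not chemical realism; chemical inputs enter the
package as tabulated polarizabilities and real geometries.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| vdW radius scale | 1.1 | — | common continuum-solvation default over UFF radii |
| tessellation level | 3 (1280/sphere) | — | sphere oracles to <0.1%; dense solve still ≲1 s |
| MC volume samples | 10⁶ | — | ~0.1% relative standard error on sphere-scale volumes |
| solvent ε (optical, water) | 1.7485 | — | water at 1312.8 nm |
| cavity factor f_c | 1.1536 | — | water vdW-cavity reference value; per-molecule override |
| basis scaling | 1.1751 | — | mean of the two benchmarked diffuse-function ratios |
| N_A | 6.02214×10²³ | mol⁻¹ | fixed |

## Known limitations

* Only vdW sphere-union cavities: no solvent-accessible or
  solvent-excluded surfaces.
* Exposure culling is binary per tessera; seam areas carry a small
  non-monotone bias (bounded by the Monte-Carlo and lens-formula
  oracles, <1% in volumes at level ≥ 2).
* The quantum response machinery (effective dipole operators, response
  functions, TD-DFT) is out of scope; computed polarizabilities enter as
  data.  Consequently the molecular (non-sphere) cavity-field factor is
  the classical field average described above.
* Single optical frequency; no dispersion.
* Onsager cavity radii are user inputs; the package fixes none for real
  species.
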