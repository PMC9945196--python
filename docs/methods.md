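# Methods

`tbfe` computes apparent trabecular-bone (Tb) moduli from calibrated CT
density volumes with a *continuum* voxel finite-element model: every voxel of
the volume of interest — bone and marrow alike — becomes one hexahedral
element whose elastoplastic properties are a function of its calibrated
density. No bone/marrow binarization is required, which is what makes the
measure usable at clinical CT resolutions where thin trabeculae are heavily
partial-volumed.

## Densitometric chain

CT numbers (HU) are mapped to BMD (g/cc) by a single global least-squares
line fitted to calibration-phantom rod samples. BMD converts voxelwise to
calcium-hydroxyapatite-equivalent density

    rho_CHA = (rho_BMD − D_water) / (D_CHA − D_water) · D_CHA,
    D_CHA = 3.18 g/cc, D_water = 1 g/cc,

and then to ash density `rho_ash = 0.0633 + 0.887 rho_CHA`. Both maps are
affine and strictly increasing, with exact analytic inverses (tested to
1e−10 round-trip). Negative CHA values (fat-rich marrow darker than water)
are preserved: the material map applies its own floor, and clipping twice
would mask calibration faults. Per-slice calibration is not supported; the
protocol provides no per-slice procedure.

## Constitutive model

Per-element parameters are power laws of ash density. Defaults follow the
Keyak-family relationships commonly used for bone FE:

| parameter | law | default |
|---|---|---|
| elastic modulus | E = a_E ρ^n_E | 14900 ρ^1.86 MPa |
| maximum (yield) stress | S_max = a_S ρ^n_S | 102 ρ^1.8 MPa |
| saturation stress | S_sat = a_sat ρ^n_sat | 43.2 ρ^1.81 MPa |
| Poisson ratio | — | 0.3 |
| Voce rate b | — | 10 |
| Swift slope R2 | — | 0 MPa |
| stiffness floor E_floor | — | 0.01 MPa |

All of these live in `DensityLawConfig` (configuration, not constants):
density–property laws for bone vary by site and calibration, so a package
hard-coding them would be wrong for most users. With the defaults
S_sat < S_max, i.e. R1 = S_sat − S_max < 0 and the post-yield limb *softens*
toward S_sat.

The uniaxial curve is bilinear-to-plastic: S = E ε below the elastic limit
ε_el and the mixed Swift–Voce law

    S(ε) = S_max + R1 (1 − e^{−b(ε−ε_el)}) + R2 (ε − ε_el)

above it. ε_el is not defined symbolically by the protocol; we take
ε_el = S_max / E, the strain where the elastic limb meets the plastic limb
(configurable override provided). The curve is continuous everywhere and C¹
except at ε_el.

The floor is implemented by clamping the density entering *all three* power
laws at the density where E equals E_floor, so E, S_max and ε_el stay
mutually consistent for marrow-valued and negative-density voxels. Note that
ordinary marrow (ρ_ash ≈ 0.063 from the ash intercept) already gets
E ≈ 88 MPa from the power law itself — the floor only guards the degenerate
tail. This small but nonzero marrow stiffness is intrinsic to the continuum
formulation and produces the "nominal stress leakage" behaviour.

### Plasticity formulation

Small-strain J2 (von Mises) plasticity, associative flow, isotropic
hardening, integrated by backward-Euler radial return. The flow stress
σ_y(α) as a function of accumulated equivalent plastic strain α is defined
*implicitly* so that a strain-driven uniaxial test reproduces the printed
curve in total strain exactly: σ_y solves σ = S(σ/E + α), using the
analytic continuation of the plastic limb for arguments slightly below ε_el
(softening can push them there). The radial return then reduces to one
scalar Newton solve per yielding Gauss point,

    q_tr − 3G Δγ = S((q_tr − 3G Δγ)/E + α_n + Δγ),

and the implicit hardening modulus H = S′/(1 − S′/E) enters the consistent
algorithmic tangent (Simo–Hughes form). The alternative reading — flow
stress as the plastic limb evaluated at ε_el + α directly — differs from the
printed curve by O(R1²b/E) in a uniaxial test (up to ~0.6% with the default
laws); the implicit definition removes that discrepancy, and the
single-element verification holds to ~2·10⁻⁵. Softening is admissible
whenever 3G + H > 0, which the default laws satisfy by a wide margin
(|S′| ≤ |R1| b ≪ E < 3G... strictly |S′|max ≈ 0.04 E).

## Discretization and solver

* **Mesh** — one 8-node cube element per voxel, shared nodes deduplicated;
  deterministic z-major numbering makes repeated runs bit-identical. Unique
  edge counts are recorded (they follow the closed forms Σ nᵢ Π(nⱼ+1)); no
  physics attaches to edges. Components not 26-connected to the bottom
  surface make the bottom-anchored system singular; they are detected up
  front and reported, with an opt-in `drop_floating` remediation.
* **Element** — trilinear shape functions, 2×2×2 Gauss (exact for the cube
  stiffness). Default strain-displacement operator is B-bar (mean
  dilatation) to avoid volumetric locking at ν = 0.3 with nearly
  incompressible plastic flow; full integration is selectable and the two are
  identical on the verification problems used here.
* **Boundary conditions** — platen-style: bottom nodes fixed in all
  directions; top nodes driven to (k/n_substeps)·0.1%·height at sub-step k
  (50 sub-steps default), along z for compression and along x or y for the
  two shear modes, with the orthogonal top-node movements restricted. A
  `validation` BC mode (compression only) releases the lateral constraints
  and pins rigid-body modes instead, so closed-form uniaxial states
  (modulus recovery, springs-in-series) are exactly attainable; it exists
  for verification, not for the imaging protocol.
* **Nonlinear iteration** — Newton–Raphson with the consistent tangent;
  convergence requires both an L2 force check (residual ≤ 0.5% of the
  reaction-force norm) and an L2 displacement check (correction ≤ 5% of the
  sub-step increment), mirroring the classical defaults of commercial codes
  (which do not document their norm choice; L2 is ours and both tolerances
  are configurable). The first sub-step starts from an exact elastic
  predictor — a zero initial guess concentrates all strain in the loaded
  element layer and can spuriously trigger softening plasticity there —
  and later sub-steps warm-start from the previous increment, so a purely
  elastic 50-sub-step run costs one linear solve.
* **Linear solves** — SuperLU factorization below 15k free DOFs,
  Jacobi-preconditioned conjugate gradients above (the bone/marrow stiffness
  contrast is only ~65, so Jacobi-CG converges in a few hundred iterations;
  a 48³ grid, 350k DOFs, solves in ~25 s within ~1.5 GB). Both paths give
  the same solution within solver tolerance (tested).
* **Geometric nonlinearity** — off by default: at 0.1% total strain
  geometric effects are O(10⁻³) relative, and the small-strain form is
  verifiable against closed forms. An updated-geometry option (per-sub-step
  recomputation of the isoparametric operators on the deformed mesh) is
  available behind `geometric_nonlinearity=True` for fidelity studies.

## Modulus extraction

After each sub-step the mean element von Mises stress over the top-surface
element layer is recorded against applied strain. The modulus is the slope of
the longest initial window of that curve whose least-squares r² stays ≥
0.999 (threshold configurable; the protocol says only "slope of the linear
section"). On a hard bilinear kink the 0.999 rule can admit one post-kink
point and bias the slope by up to ~1%; a 0.9999 threshold pins the window at
the kink. Shear "moduli" are reported exactly as the protocol constructs
them — mean top-surface von Mises over applied lateral strain — which is
*not* the classical engineering shear modulus and typically exceeds the
compressive modulus (a pure shear stress τ contributes √3 τ to von Mises).
Stress is plotted against applied strain (identical to measured top-surface
displacement under displacement control).

## Stress partition and loading maps

Per-voxel von Mises fields (element→voxel is 1:1) are compared between
trabecular and marrow regions with Welch's unpaired t-test. The trabecular
mask stand-in is a threshold (default 0.5) on the bone-volume-fraction map,
itself a clipped linear BMD ramp between marrow (1.0 g/cc) and compact bone
(1.8 g/cc) — documented stand-ins for validated segmentation/BVF methods
that are external to this package. Normalized stress τ = min(stress/P99, 1)
uses the linear-interpolation 99th percentile over the whole VOI
(configurable to bone-only); the loaded-bone fraction is
Σ_B τ·BVF / Σ_B BVF.

## Preprocessing

Bone segmentation is a deliberately simple stand-in (global threshold,
largest 26-connected component, hole fill) adequate for phantoms. The bone
axis is the principal axis of the peeled (40% in-plane) voxel cloud proximal
to the 8% site; rotation onto z and resampling to 150 µm are combined into a
*single* windowed-sinc (5-lobe Lanczos default, Hamming selectable)
interpolation pass, which measurably beats two passes in RMS on band-limited
data. The VOI is the 4%–6% percent-of-tibial-length slab from the most
distal occupied slice, peeled per axial slice by iterative 2D erosion until
the cross-sectional area drops by 30%; tibial length comes from
configuration (desk-scale data are not full-bone scans) and the phantom
supplies a known length.

## Synthetic phantom and scanner models

The phantom places parallel bone plates (normal to y, continuous along the
loading axis) at a centre-to-centre period of 650 µm and thickness 280 µm —
inside the young-adult distal-tibia ranges for Tb thickness (~237–306 µm)
and spacing (~366–401 µm) — with a seeded fraction of plates broken into
vertical rods, bone voxels at 0.6 g/cc CHA (BMD ≈ 1.41 g/cc) and water-like
marrow. Densities are emitted as BMD so every run exercises the full
calibration chain. Cohorts draw thickness (230–310 µm), period (600–710 µm),
bone CHA (0.5–0.7 g/cc) and rod fraction (0–0.3) uniformly per subject; the
cohort grid is 32³ (4.8 mm cube) and the single-phantom default 48³ (7.2 mm)
— sizes chosen as the smallest grids that hold several structural periods
while a full three-mode protocol and a 10-subject × 2-scanner cohort remain
single-CPU problems (minutes each).

A scanner is a Gaussian PSF (FWHM in µm) + resampling + seeded additive
Gaussian noise in the volume's units: HR = 300 µm FWHM, LR = 500 µm FWHM,
both at 150 µm output spacing and noise σ = 0.015 g/cc (≈ 20 HU through a
typical calibration slope). Blur conserves density mass — the property that
keeps continuum FE moduli comparable across resolutions — while corrupting
apparent microstructure. The "thickness proxy" used as the microstructure
contrast (4× mean Euclidean distance of bone voxels to background, on a
BVF ≥ 0.25 mask) is *deliberately* resolution-sensitive: a 0.5 (half-max)
threshold crosses a blurred edge at the true boundary, so the partial-volume
halo that inflates apparent thickness at coarse resolution is only visible
below half-max. Cohort runs use 10 sub-steps: the cohort's 0.1%-strain
solves remain elastic, where the extracted slope is independent of the ramp
discretization (verified to <0.1% between 50 and 100 sub-steps).

### What the phantom does not emulate

Anatomical tibia shape and cortex, beam hardening/scatter, projection-domain
reconstruction kernels, spatially varying PSF and noise texture, marrow
heterogeneity, and inter-scan repositioning. Passing the reproducibility
tests therefore demonstrates the *mechanism* (mass-preserving blur degrades
microstructure metrics but not continuum FE moduli) at realistic geometry
and contrast — not clinical performance on in vivo scans.

## Reproducibility statistics

Pearson r and ICC from the two-way ANOVA table (backed by
`pingouin.intraclass_corr`, cross-checked against explicit ANOVA sums in the
tests). Default form is ICC(A,1) — two-way mixed effects, absolute
agreement, single measurement — because scanners are fixed conditions and
absolute agreement is the stricter cross-scanner claim; all six standard
forms are selectable and reported with their McGraw–Wong identifiers.
Consistency ICC and Pearson are invariant under a common affine rescaling
and under offsetting a single arm; absolute agreement is degraded by an
inter-arm offset (both behaviours tested). Paired t-tests (one-sample t on
differences) compare loaded-fraction values between loading modes; the
degenerate zero-variance case is flagged explicitly.

## Numerical choices and degenerate inputs

* Radial-return scalar Newton: tolerance 1e−11 relative, 40 iteration cap,
  Δγ clamped non-negative; exponents clipped at ±500 so far-below-yield
  trial states stay finite.
* Percentile rule: NumPy linear-interpolation percentile (fixed; τ maps
  depend on it).
* Degenerate inputs raise typed errors: empty masks (`MeshError`),
  single-layer meshes (`BoundaryError`), unanchored components
  (`AnchoringError`), all-identical rating tables (`AnalysisError`), wrong
  units tags (`UnitError`).
* Modulus fallback: if no ≥2-point window reaches the r² threshold, the
  2-point secant is used with a logged warning.

## Problem sizes

Verification problems run at 1–27 elements; the stress-partition study at
48³ (110,592 elements, ~353k DOFs; ~3–4 min for the three load modes); the
reproducibility study at 10 subjects × 2 scanners × 32³ (~3 min). These are
the package's standard desk-scale study conditions.

## Known limitations

* Isotropic material only; no anisotropy, strain-rate dependence, damage, or
  cyclic loading. No failure-load (post-peak) search and no contact.
* The apparent modulus depends on the constrained-platen boundary
  conditions; values are comparable within the protocol, not material
  constants.
* Tb/marrow segmentation and BVF mapping are stand-ins; partition statistics
  on real scans should substitute validated methods behind the same
  interfaces.
* The updated-geometry option omits stress rotation terms (negligible at
  0.1% strain but untested beyond a few percent).
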