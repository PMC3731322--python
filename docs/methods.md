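# Methods

## Photon transport model

`nirsens` implements the standard weighted-photon ("survival weight")
Monte Carlo random walk for light in turbid media on a voxelized tissue
grid. Each photon starts at a scalp surface point with weight 1 and an
inward direction. A dimensionless scattering depth τ = −ln(u) is drawn per
scattering event; the photon is traced voxel face to voxel face with exact
segment intersections, and in each voxel of tissue t the remaining depth is
decremented by μ_s(t)·ℓ while the weight is multiplied by exp(−μ_a(t)·ℓ).
This "remaining optical depth" convention (rather than re-sampling the step
on every boundary crossing) is unbiased for heterogeneous scattering and is
essential for near-transparent CSF (μ_s = 0.01 mm⁻¹, ~100 mm free paths
crossing many voxels). New directions are sampled from the
Henyey–Greenstein phase function with the local anisotropy g; at a
tissue–air face the unpolarized Fresnel formula decides between internal
reflection (the face-normal direction component flips) and exit. A photon
terminates by exit, by exceeding the time cutoff (path length
> c/n · t_max, default 10 ns), or by Russian roulette once its weight
falls below 10⁻⁸ (survival probability 0.1, with the survivor's weight
gain debited from the absorbed tally so the per-run energy budget
exit + absorbed + in-flight = launched closes to better than 10⁻⁶
relative — asserted on every run).

**Fluence estimator.** Each voxel a segment crosses accrues w·ℓ with the
weight at segment entry (a path-length estimator). This has lower variance
on coarse grids than collision-based scoring and is the conventional
choice in voxel MC codes. The per-voxel accumulator divided by the number
of launched photons is the 2-point Green's function used downstream;
because partition *proportions* are ratios of sums of products of two such
grids, they are invariant to the normalization constant.

**Verification.** The transport kernel (numba-compiled) is checked against
closed forms rather than against itself: Beer–Lambert transmission on
forced straight paths; unit exit weight when μ_a = 0; empirical
E[cos θ] = g at 3σ for g ∈ {0, 0.01, 0.5, 0.9}; Fresnel normal-incidence
and total-internal-reflection values; source–detector reciprocity at 3σ;
and the diffusion limit — in a homogeneous gray-matter block the decay of
ln(r·φ) along the source axis matches the effective attenuation
coefficient μ_eff = √(3 μ_a (μ_a + μ_s(1−g))) within a few percent (the
1/r factor of the point-source solution must be divided out before
comparing slopes). A pure-Python single-photon propagator mirrors the
kernel's physics and serves as an independent execution route in tests.

## Optical properties

Defaults are adult-head coefficients averaged over the 690–830 nm NIRS
band (μ_a/μ_s in mm⁻¹): gray 0.0195/1.10, white 0.0169/1.35, CSF
0.0025/0.01, skull 0.011925/0.92, scalp 0.017275/0.72, with g = 0.01 and
n = 1 for every tissue. Note that g ≈ 0 means nearly isotropic scattering,
so these μ_s values act as reduced scattering coefficients; they are taken
as given and are fully configurable. With n = 1 no boundary reflections
occur; the Fresnel machinery is exercised only for user-supplied n > 1.

## Phantoms and what they do (not) emulate

The synthetic generator produces concentric-sphere and layered-slab
phantoms with default thicknesses scalp 6.9, skull 6.1, CSF 2, gray 4 mm
(white core), i.e. a 6.9 mm mean scalp and a 13 mm combined scalp+skull
overburden, at 1 mm isotropic voxels. The head-scale analyses use a 95 mm
outer radius, matching an adult head. Injection points are placed by
projecting a Fibonacci lattice (hexagonal-packing count
N = 8πr²/(√3·s²) for spacing s — about 5,200 points at s = 5 mm on a
95 mm sphere) radially onto the first non-air voxel; placement is exact
ray tracing and fully deterministic.

These phantoms reproduce mean layer thicknesses and bulk optics but not:
cortical folding, CSF distributed in depth (sulci and ventricles),
regional thickness variability, or anisotropic white matter. Passing
phantom tests therefore validates the *method* (transport physics,
sensitivity bookkeeping, regression machinery) and the broad magnitudes,
not location-specific values in a real head. Two consequences observed in
this package's own runs:

- Brain-fraction magnitudes are at the low edge of head-model values at
  short separations (~3.5% at 20 mm vs ~6% for a template head), because
  a uniform 13 mm overburden is less favorable than variable real anatomy
  where thin-overburden regions dominate the average.
- The fitted depth-decay coefficient is c ≈ 0.65–0.67 per mm rather than
  ~0.85. The deep-shell decay of template-head data is in fact comparable
  to the phantom's (per-location deep-shell ratios correspond to
  c ≈ 0.67–0.77), but in a folded head the *shallow* profile is flattened
  by cortex/CSF interdigitation and multi-location pooling, and the
  regression — dominated by the large shallow values — lands near 0.85.
  A smooth concentric phantom instead has one clear CSF shell at depth
  0–2 mm whose light piping inflates the first shell and steepens the
  apparent shallow decay. This is a geometry limitation of concentric
  phantoms, documented here deliberately rather than compensated for.

## Depth shells and the depth coordinate

The intracranial mask (CSF∪gray∪white) is eroded iteratively with a
6-connected structuring element, two iterations per shell by default;
shell k is the set difference of successive erosions, and scalp and skull
are kept as their own partitions (optionally plus the residual core so the
partition is exhaustive). On curved masks a 6-connected iteration advances
less than one voxel on average (~0.86 mm at 1 mm voxels), so shells are
~1.8 mm thick rather than the nominal 2 mm; on flat interfaces they are
exactly 2 mm. For this reason every shell's depth coordinate is *measured*
— the mean Euclidean-distance-transform depth of its voxels below the
inner skull surface (voxel centres sit half a voxel inside the interface,
hence a 0.5-voxel offset) — instead of assuming a nominal spacing. The
grid edge is treated as non-surface during erosion (border_value = 1), so
masks that touch the volume edge erode only from real tissue interfaces.

## Sensitivity analysis conventions

The continuous-wave 3-point map is the plain voxelwise product of the two
per-photon-normalized fluence grids; no adjoint directional correction.
Dynamic-range masking (zeroing voxels below 10^−k of the map's peak,
k ∈ {2,3,4,5}; 2 orders ≈ 40 dB) is applied to each map *before* partition
summation. SD separations are straight-line Euclidean distances; pair
enumeration around a target keeps unordered pairs with separation below a
cap (default 60 mm) and 3D midpoint within a radius (default 10 mm) of the
target. Separation curves use half-open 5 mm bins centred on multiples of
5 (the 30 mm bin collects 27.5–32.5 mm); the per-bin standard error is
over pairs, and aggregation across target locations replaces it with the
across-location standard error. Empty bins are omitted, never zero-filled;
a single-pair bin reports n = 1 with an undefined SE.

## Exponential depth regression

`fit_exponential` fits S(d) = a + b·c^d by bounded nonlinear least squares
(trust-region reflective via `scipy.optimize.curve_fit`; tolerances 1e-14
so noiseless inputs are recovered to machine precision). Starting values
come from a log-linear regression of log(S − min(S) + ε) on depth; bounds
are a ∈ [−0.1, 0.1], b ∈ (0, 1], c ∈ (0.5, 0.999). Fits are unweighted,
matching a pooled regression over locations; standard errors come from the
Jacobian covariance and 95% CIs use Student t with n − 3 degrees of
freedom. Non-convergence is returned as a flagged result with diagnostics,
never silently replaced. The rule-of-thumb summary is the arithmetic mean
of b and of c across the supplied fits; applied to the packaged reference
coefficient table over 20–40 mm separations it yields b̄ = 0.075,
c̄ = 0.85, i.e. S(d) ≈ 0.075·0.85^d — ~7.5% sensitivity at the inner
skull surface and ~3.3% at 5 mm depth. Internal computations are
proportions; reports multiply by 100 and round to two decimals.

## Problem sizes and reproducibility

Desk-scale defaults are 10⁶ photons per source (a minute-scale run per
injection point on one core; the template-head study this re-implements
used 10⁸) and 1–2 mm voxels. All randomness is driven by explicit integer
seeds: the compiled kernel seeds its own generator per run, pipeline
sources derive per-point seeds from the run seed, and repeated runs are
bit-identical. Every pipeline artifact carries a sidecar with the package
version, seed and configuration hash, and the run manifest lists SHA-256
checksums; fluence grids are cached by (phantom, point, MC settings) so
partial re-runs recompute only missing grids.

## Known limitations

- No time-resolved or frequency-domain outputs; no polarization; no
  refractive-index mismatch between interior tissues (n = 1 throughout by
  default).
- The detector aperture reads "3 mm diameter" as a 1.5 mm collection
  radius (configurable, since some codes use 3 mm radius).
- Concentric phantoms understate shallow-depth flattening of real heads
  (see above); absolute per-location values of a real template are out of
  scope.
- Erosion-shell thickness depends on the structuring element; results are
  reported against measured EDT depths to stay element-independent.
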