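# Methods

This note documents the models, numerical choices and known limitations of
`tsatract`, in the order the pipeline runs.

## Geometry and I/O conventions

Volumes live on a shared voxel grid: integer dims plus a 4×4 affine mapping
0-based voxel indices to world millimetres at voxel centres. All volumes in
one analysis must share the grid (dims equal, affines within 1e-4); a
registration hook exists but defaults to identity, since the method assumes
tractography has been run in a single common space. Orientation fields are
stored as 4D NIfTI with the vector as the trailing dimension (the FSL dyads
convention); the zero vector means "no orientation defined". Gradient
tables are FSL-style bvec/bval text; b = 0 columns are counted and dropped
— the stick regression is defined on the normalised signal s/s⁰, so b0
volumes contribute the reference, not regression rows. Only a single
nonzero shell is accepted. Cohorts are TSV with sex coded 1 = male,
2 = female.

## Phantom generator

The generator emulates the *outputs* of probabilistic tractography, not the
streamline process itself:

* **Visitation probability**: exp(−r²/2σ_t²) of the distance r to the
  nearest point of a smooth 3D curve (σ_t = `tube_sigma`, default 4 mm,
  chosen so the α = 0.07 threshold keeps a corridor ~9 mm in radius on a
  2 mm grid — a realistic single-bundle cross-section). Competing routes
  enter via a voxel-wise maximum at their stated relative amplitude.
  Directed maps get independent voxel-wise multiplicative log-normal jitter
  (sd 0.1) per seeding direction and participant, mimicking seed-direction
  asymmetry; the bidirectional minimum and population average are what
  suppress it downstream.
* **Orientation**: the unit tangent of the nearest curve wherever the base
  probability exceeds 1e-3, zero elsewhere.
* **DWI signal**: s = s⁰·(β·exp(−bδ(r·v̄)²) + c) with s⁰ fixed at 1000,
  b = 1500 s/mm², δ = 1e-3 mm²/s (typical deep white matter), β + c ≤ 1.
  Injected covariate effects add `age_slope·Age + sex_effect·Sex +
  interaction_effect·Age·Sex` to β inside a designated region; generation
  fails loudly if any participant's β leaves [0, 1]. Noise is additive
  Gaussian on the normalised signal by default — keeping the OLS fit's bias
  behaviour transparent — with a Rician option for realism; signals are
  clipped at zero.
* **Cohorts**: ages uniform on 18–80 and a female fraction of 86/130 by
  default, matching a typical ageing-cohort composition; `round(n·f)` rows
  get sex = 2 and order is shuffled deterministically.

What the phantom does **not** emulate: streamline-level propagation and its
distance bias, partial-volume and CSF contamination, multi-fibre voxels,
susceptibility distortion, and spatial normalisation error. Tests passing
on the phantom therefore validate the *post-processing chain* — geometry
extraction, regression, inference — under controlled truth, not robustness
to acquisition artefacts.

## Tract determination

Parameters and their defaults: threshold α = 0.07 (inclusive, ≥ α:
retention at equality is the literal reading of zeroing "below" the
threshold), ROI dilation 3 iterations of the 26-neighbour structuring
element, population-average smoothing 2 mm FWHM (one voxel; the minimal
regularisation at grid scale — the upstream value is not prescribed),
segment limit 4 mm, turning-angle limit π/3, kernel σ_a = 10 mm,
σ_r = 4 mm, support radius 8 mm.

Directed counts normalised by target-reaching streamlines can exceed 1 at
way-point voxels; they are clipped to 1. Every downstream operation on them
(minimum, mean, maximum) is order-preserving under clipping.

**Flood fill** uses 26-connectivity by default (configurable 6/18/26). The
choice matters: with face-only neighbours, the walk along an obliquely
oriented tube must alternate orthogonal lattice steps, and consecutive
polyline segments then turn by 90°, which the π/3 constraint forbids — the
polyline drifts off the core. Corner neighbours make single diagonal steps
available and the constrained walk tracks oblique and curved tubes.

**Constraint boundaries are inclusive** (tolerance 1e-9): on a 2 mm lattice
the canonical two-voxel catch-up step measures exactly 4.0 mm and the step
pair (0,1,1) → (1,1,0) turns by exactly 60°. Treating these as violations
locks the walk into off-core drift (observed up to 9 mm on arc phantoms);
treating the measure-zero boundary as admissible restores recovery to
within one voxel diagonal. When no candidate in a stratum satisfies both
constraints, the maximal-probability voxel is appended anyway and the
vertex index recorded as a flag for visual inspection. Ties in probability
break to the lowest linear voxel index, for reproducibility. The target is
"encountered" when a vertex's voxel is inside or 26-adjacent to the dilated
target ROI; running out of strata first rejects the tract — rejection is a
result, not an error.

The uncertainty kernel peaks at 1 (no density normalising constant), since
the tract probability is renormalised within each stratum anyway; Φ is
exactly zero beyond the 8 mm vertex neighbourhoods. Per-stratum
renormalisation divides by the stratum maximum of Φ⊙P_ab and leaves
all-zero strata at zero, so every nonempty stratum peaks at exactly 1.

## TSA estimation

The stick regressor exp(−bδ(r_i·v̄)²) depends on v̄ only through the squared
projection, so TSA is antipodally symmetric in the orientation, as it must
be. The regression is solved by the closed-form 2×2 normal equations,
vectorised over voxels; voxels with zero orientation, non-positive s⁰, or a
regressor constant across gradients (collinear with the intercept) are
flagged unfitted rather than raising. β is an unconstrained regression
coefficient: negative estimates are retained and flow into the statistics.

δ is accepted as a per-voxel map or a scalar (default 1e-3 mm²/s). For real
data a tensor-fit mean-diffusivity map is the documented choice; the
phantom supplies its known δ.

Map smoothing (default 1.5 mm FWHM, σ = FWHM/2√(2 ln 2)) is masked:
unfitted voxels contribute to neither the numerator nor the kernel
normalisation, so constants are preserved and no mass leaks across the
tract boundary. FWHM = 0 is the identity.

## Statistics

The voxel-wise model is TSA ~ 1 + Age + Sex + Age×Sex with sex used as
coded (1/2, uncentred) and the interaction the literal product; ν = n − 4.
Voxels unfitted in any participant are excluded listwise, keeping each
voxel's design balanced. Zero-variance voxels (all participants identical)
get t = 0 with a numerical guard at relative scale 1e-15. A rank-deficient
design (e.g. a single-sex cohort) raises an error naming the first column
collinear with its predecessors.

**Per-stratum summarisation** is two-tailed by design: the weighted
statistic t′ = t·P^λ is computed for every stratum voxel, and the positive
tail reports the unweighted t at argmax t′ while the negative tail reports
the t at argmin t′. A single signed-max rule cannot produce negative
clusters, which the method's signed sums require.

**Smoothness** is the standard random-field estimator: resels per node
√(v/4 ln 2) from the gradient variance v of the unit-normalised residual
field along the distance axis, FWHM = 1/mean(resels per node), averaged
over tracts (tracts with < 2 strata or zero gradient variance — the smooth
limit, FWHM = ∞ — are excluded from the average). Residuals are taken at
each stratum's core voxel (maximal tract probability). Distance is
measured in strata; millimetres are a display conversion only. The
estimator is calibrated within ~3% at FWHM 5–10 on fields of length 100.

**Critical height**: t* solves E[EC](u) = P(T > u) + R·ρ₁(u) = α with
resel count R = (Q−1)/FWHM and the 1D EC density ρ₁ of a t-field with
ν = n − 4 degrees of freedom (Gaussian-field formula available as
`field_model="gaussian"` for compatibility with software that treats
large-sample t's as Gaussian; at ν = 126 the two differ by < 1%). The
equation is inverted by bracketed root finding; as R → 0 the threshold
falls back to the point-wise one-sided quantile. Monte-Carlo validation
(5000 smooth t-fields) agrees within 3%.

**Clusters** are maximal runs of consecutive strata with t_d > t* (positive
tail) or t_d < −t* (negative); runs shorter than 3 strata are discarded.
The cluster p-value uses the expected-extent exponential model: with E[N]
expected supra-threshold strata and E[C] expected clusters from the EC
density, a cluster's extent is approximately exponential with mean
E[N]/E[C], and the reported p is 1 − exp(−E[C]·P(S ≥ extent)) — the
chance that a null field of this smoothness contains at least one cluster
this large. The approximation is validated against simulation (within ~40%
at moderate thresholds, and conservative in the regime the chain uses);
its extent-monotonicity, not its exactness, is what the inference relies
on, and the full chain's familywise false-positive rate is verified
directly.

**FDR** across all clusters of all tracts uses the two-stage non-negative
(BKY) step-up via statsmodels (`fdr_tsbky`); adjusted p-values are floored
at the raw p. Signed sums add the per-stratum t values inside surviving
clusters, separately by sign.

## Calibration experiments

`tsatract.validation` fixes one phantom tract (32³ grid, 2 mm, straight
tube, 10-participant population average, ~2800 support voxels, 25 strata)
and resamples cohorts through the complete chain. Study conditions chosen
once: 24 participants, 32 gradient directions, noise sd 0.02, β = 0.45,
c = 0.2. Under the null, the chain's familywise rate over 500 cohorts is
well below the nominal 5% — the minimum-extent rule and the FDR stage make
the combination conservative. For power, an age slope of 2.6e-3 per year
on the middle third of the strata yields a mean within-region age t of
~4.3 at n = 24, and the surviving positive cluster covers the injected
range in ≥ 98% of replicates. These problem sizes keep one replicate at
~0.2 s; they are deliberately smaller than a real cohort study, and rates
measured here transfer to other designs only qualitatively.

## Known limitations

* The polyline is a single path: branching tracts are represented by their
  dominant route or rejected; multi-path extraction is out of scope.
* Per-stratum max-t′ summarisation takes a maximum over correlated voxels,
  so the summarised null field is not exactly a unit t-field; the chain's
  actual false-positive rate is therefore verified empirically rather than
  assumed from the threshold's nominal level (it comes out conservative).
* Cluster p-values use a large-threshold approximation; below |t*| ≈ 2 the
  exponential extent model degrades.
* The design matrix is fixed to intercept + Age + Sex + Age×Sex; the GLM
  code is written per-voxel-vectorised and could host other designs, but no
  interface is exposed for them.
* Real-data preprocessing (eddy correction, brain extraction, crossing-
  fibre modelling, streamline propagation, spatial normalisation) is
  upstream of this package and assumed done; all volumes must already share
  one space.
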