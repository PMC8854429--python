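# tsatract

Tract-specific statistics for diffusion-weighted MRI: estimate the single
most probable white-matter trajectory between two grey-matter regions from
probabilistic-tractography visitation maps, measure a per-participant
anisotropy fraction specific to that trajectory, and test covariate effects
along it with one-dimensional random-field cluster inference.

## Who this is for

Voxel-wise anisotropy measures (FA and relatives) cannot say whether the
white matter *connecting two particular regions* differs between people:
most white-matter voxels host a mixture of crossing projection, association
and commissural fibres. `tsatract` addresses this by (1) reducing the
population's streamline visitation evidence for an ROI pair to one "core"
trajectory — or rejecting the pair when the evidence is ambiguous — and
(2) quantifying, per participant and voxel, the fraction of the diffusion
signal oriented along that tract.

## The method

**Core trajectory.** Directed visitation counts (seed → target and
target → seed) are normalised by the number of target-reaching streamlines,
the voxel-wise minimum over directions is averaged over participants,
smoothed, and rescaled to give P_ab ∈ [0, 1]. P_ab is thresholded at
α = 0.07 (ROIs dilated by 3 voxels to stay attached), flood-filled into
integer distance strata d from the seed, and a polyline L_ab is grown
through the per-stratum maximal-probability voxel subject to a 4 mm
segment-length and a π/3 turning-angle constraint. Reaching the target
accepts the tract; exhausting the strata rejects it. Around L_ab an
anisotropic Gaussian uncertainty field

Φ_ab(i) = max_v exp( −d_a²/2σ_a² − d_r²/2σ_r² ),  σ_a = 10 mm, σ_r = 4 mm

is evaluated within 8 mm of each vertex (d_a, d_r: components of i − v
along and across the local orientation ω_v), and the final tract
probability P_ab-tract = Φ_ab ⊙ P_ab is renormalised to a maximum of 1
within each distance stratum.

**Tract-specific anisotropy (TSA).** For each participant and tract voxel
j with mean streamline orientation v̄_j, ordinary least squares of

s_j / s⁰_j = β_j · exp( −b δ (R v̄_j)² ) + c_j

over the M gradient directions R (single shell, b in s/mm², diffusivity δ
in mm²/s) yields the TSA value β_j — the single-stick signal fraction
along the tract — and an isotropic intercept c_j. Maps are smoothed at
1.5 mm FWHM within the fitted mask.

**Statistics along the tract.** Voxel-wise OLS of
TSA = β₀ + β₁·Age + β₂·Sex + β₃·Age×Sex + ε (sex coded 1 = male,
2 = female) gives t-maps that are summarised per stratum through
t′(j) = t(j)·P_ab-tract(j)^λ (λ = 1): each tail reports the unweighted t of
the voxel with extremal t′. The per-distance series is treated as a 1D
random field: residual smoothness is estimated as an FWHM in stratum
units, the critical height t* solves the expected-Euler-characteristic
equation at α = 0.05, supra-threshold runs of ≥ 3 strata become clusters
with expected-extent p-values, and cluster p-values across all tracts are
corrected by two-stage non-negative FDR at q = 0.05. Significant t-values
are summed per tract by sign.

A seeded phantom generator produces every input with known ground truth —
Gaussian-tube visitation fields (optionally with competing routes),
tangent orientation fields, single-shell DWI signals from the forward
model above with optional injected age/sex/interaction effects, and
reproducible cohorts — so the whole chain is testable without data
downloads.

## Worked example

```bash
python examples/02_core_trajectory.py
```

prints, for a 10-participant straight-tube phantom on a 32³ grid:

```
status: accepted; vertices: 15; constraint flags: []
distance strata: 25
uncertainty field peak: 1.000 (closed form: 1 at a vertex)
max vertex deviation from ground truth: 0.11 mm (one voxel diagonal is 3.46 mm)
with alpha = 0.999: rejected
```

The tract is accepted and the recovered polyline sits on the true tube
centre; raising the threshold above the probability ridge disconnects the
corridor and the pair is rejected rather than forced. Continuing with
`examples/04_group_statistics.py`, a cohort with an age effect injected on
strata 9–16 yields:

```
residual smoothness: 2.12 strata FWHM; critical height t* = 3.30 (nu = 20)
  age      positive strata 9-16 peak t = +7.79 p = 0.0000 (survives FDR)
signed significant-t sums for the age contrast: +47.1 / 0.0
```

— the surviving cluster covers exactly the injected range, and no spurious
sex or interaction clusters appear. `examples/01_phantom_generation.py`
and `examples/03_tract_specific_anisotropy.py` demonstrate the generator
and the per-participant fit (exact recovery without noise; mean |error|
≈ 0.008 at 2% signal noise).

The same pipeline is scriptable from a shell:

```bash
tsatract run --out-dir out --seed 1          # phantom -> tract -> tsa -> stats
tsatract tract --out-dir out --alpha 0.07    # rerun one stage with overrides
```

with per-stage subcommands (`phantom`, `tract`, `tsa`, `stats`), a YAML
config file (`--config`), and a manifest recording every parameter, seed
and output hash.

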