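# Methods

This note documents the models, defaults, and design choices behind
`prfcohort`, and what the synthetic cohort does and does not emulate.

## The synthetic cohort

The generator produces, per participant (default n = 20) and visual area
(V1, V2), a table of cortical surface locations ("vertices") carrying
visual-field preference, anatomy, and ground-truth neural tuning. There
is no 3D mesh: a participant's cortex is a vertex table with area
weights, because every downstream analysis consumes only per-vertex
scalars.

**Eccentricity.** Vertex eccentricities are drawn from a truncated
exponential density a·e^(−bx) on [0.25, 7.2] deg (cortical
magnification). The default decay b = 0.26/deg is chosen so that the
coverage fraction e^(−0.25·b) − e^(−7.2·b) — the delineated band's share
of the full area under the curve — equals 78.3%, the published scale for
retinotopically delineated V1. Polar angles are uniform; hemisphere
labels follow the visual hemifield. The mathematical angle convention is
used (0° = right horizontal meridian, counterclockwise positive).

**Thickness (mm).** Per-vertex thickness is Gaussian with marginal mean
2.25 and SD 0.40 (spanning roughly 1–4 mm), composed of: a participant
offset (SD 0.06), a participant-specific polar harmonic A·cos(θ − φ)
with A ~ N(0, 0.12) (giving positions distinct, spatially structured
thickness), a +0.30 mm sulcus→gyrus increment, a +0.30 mm
parafovea→perifovea increment (boundary 2.0 deg), and a residual whose
SD is derived so the marginal SD always equals the configured value. The
structure terms are mean-centered, and values are clipped at 0.5 mm.
With the binary increments present the marginal is strictly a mixture;
it is numerically close to Gaussian, and the distributional unit test
zeroes the structure terms.

**Surface area (mm²).** Participant totals are lognormal with mean
2,770 (V1) / 2,270 (V2) and CV 0.105, reproducing the ~1.5× min–max
span printed for 20 participants; V1 and V2 share a Gaussian copula with
correlation 0.6. Vertex areas are random positive weights normalized so
they sum exactly to the participant total.

**Tuning width (deg).** Ground truth per vertex:

σ = σ₀·(1 − c·ΔS) + σ₁·(1 − c·ΔS)·e^η · e + β_t·(t − t̄) + β_S·(S − S̄) + ε

with σ₀ = 0.19, σ₁ = 0.15/deg, thickness effect β_t = +0.30 deg/mm,
area effect β_S = −1e-4 deg/mm², area–magnification coupling c = 0.45
(ΔS = relative area deviation; larger areas get shallower slopes *and*
lower intercepts), a shared participant "magnification" noise
η ~ N(0, 0.03) applied to the slope, vertex noise ε with SD 0.08, and a
floor at 0.05 deg. At the eccentricity distribution's defaults this
yields σ ≈ 0.6 ± 0.33 deg marginally, matching the published
0.6 ± 0.35 deg scale.

**Observers.** Discrimination thresholds follow the analogous model at
the 13 standard positions (eccentricities 0, 4.7, 6.7 deg × polar angles
45…315°): α = α₀·(1 − c·ΔS) + α₁·(1 − c·ΔS)·e^η·e + 0.30·(T_pos − t̄)
− 1.5e-4·(S − S̄), times 5% lognormal noise, floored at 0.02 deg, where
T_pos is the participant's mean thickness over the vertices mapped to
that position. α₀ = 0.08 deg and α₁ = 0.05 deg/deg put thresholds near
0.3 deg at 4.7° eccentricity.

**Effect-size calibration.** The planted coefficients were chosen so the
realized correlations in the 120-cell fixed-eccentricity table land in
the 0.4–0.8 band — the published signs, at or somewhat above the
published magnitudes (0.25–0.47). Planting exactly the published
magnitudes would make recovery of the weakest associations a coin flip
at this sample size once staircase measurement noise is added; the
package's purpose is verifiable recovery of the planted structure, so
reliability was preferred over magnitude fidelity. This is the main
sense in which passing tests do not certify real-data behaviour: real
effect sizes are smaller, and the generator's noise is white and
Gaussian where real anatomy and BOLD noise are spatially correlated.

## pRF simulation and fitting

**Stimulus.** 64 bar apertures: 8 motion directions × 8 traverse steps,
bar width 1.8 deg (a quarter of the maximal eccentricity), offsets tiling
[−7.2, 7.2] deg contiguously, rendered on a 0.1 deg/pixel grid of
half-width 8 deg, one aperture per 2 s sample. The pixel lattice and the
offsets are symmetric by construction, so rotating the frame set by 180°
reproduces it exactly. Opposite directions reuse the same strips in
reverse traversal order, as physically appropriate.

**Forward model.** Neural drive per frame is the pRF-weighted stimulus
overlap Σ_px aperture·exp(−((x−x₀)² + (y−y₀)²)/2σ²) — the unit-height
Gaussian convention of canonical pRF implementations, in which the
amplitude parameter carries arbitrary (grid-resolution dependent) BOLD
units. The drive is convolved with a double-gamma HRF (peak 5 s,
undershoot 15 s, ratio 1/6, sampled at TR = 2 s over 32 s, unit peak)
and scaled: y = baseline + amplitude·(drive ⊛ h). Simulated noise is
additive white Gaussian; "SNR" in the recovery studies means
amplitude/noise_sd under this convention. The drive normalization is a
pure reparametrization of the free amplitude, so fitted σ is unaffected
by it; only the meaning of a given noise level changes.

**Fitting.** Stage 1 evaluates every lattice point x₀, y₀ ∈ [−8, 8] step
0.5 deg × 20 log-spaced σ ∈ [0.1, 5] deg, with amplitude and baseline
solved in closed form per point (the per-σ drives for all positions are
obtained at once by Gaussian-blurring the aperture frames). Stage 2
refines (x₀, y₀, log σ) by Nelder–Mead on the exact windowed objective
(Gaussian evaluated within ±6σ), tolerance 1e-6 relative RSS. The fit
compares prediction and data in convolved space; an explicit Tikhonov
deconvolution utility (Toeplitz least squares) is provided but is not on
the default path, since inverting the HRF amplifies noise. All-constant
series are flagged degenerate with variance explained 0. Recovery at the
study conditions: noiseless max relative σ error < 1% over 200 random
pRFs (eccentricity ≤ 6.5 deg, σ log-uniform on [0.2, 2] deg); at
SNR 1 the median relative σ error is well under 10%.

## Psychophysics

The 2AFC observer is Weibull: P(correct) = γ + (1 − γ − λ)·
(1 − exp(−(δ/α)^β)) with γ = 0.5, slope β = 3.5, lapse λ = 0.02. The
"2-up-1-down" task naming is interpreted as the standard transformed
rule targeting the 70.7% point: two consecutive correct responses divide
the offset by the current step factor, any error multiplies by it.
Steps are multiplicative, starting at factor 2.0 and annealing ×0.75 per
early reversal to a floor of 1.10; the track stops at 16 reversals and
the threshold is the geometric mean of the last 8 reversal offsets;
simulations start at 4× the true α. The floor and stop count were set so
the estimator is approximately unbiased (≈ −2.6%) for the fixed point
where P(correct) = √0.5 ≈ 70.7%, and so that averaging more reversals
monotonically reduces the threshold SE. Each of the 13 positions is
measured with 3 independent tracks combined by geometric mean (the
single-track SD is ~18% of threshold; real protocols measure each
position repeatedly).

**Cortical projection.** Each vertex receives the threshold of the
nearest measured position under the Euclidean metric in the log-polar
embedding (log(1+e)·cos θ, log(1+e)·sin θ), which respects cortical
magnification and is continuous across the polar-angle wrap; vertices
below 0.5 deg eccentricity are matched to the central position and
flagged so downstream binning can collapse them to one data point.

## Statistics

Spearman correlations use average ranks for ties. Permutation p-values
are two-sided on |ρ| with the add-one estimator (1 + #{|ρ_perm| ≥
|ρ_obs|})/(1 + n_perm), n_perm = 10,000 by default; all n! relabellings
are enumerated when n! ≤ 40,320. Familywise error is controlled
single-step by the max-|ρ| permutation distribution, applying one
relabelling to all family members per draw (members with unequal n get
independent permutations, conservatively maxed per draw); a family is
one analysis panel's set of correlations. |ρ| comparisons carry a 1e-12
tolerance so exact ties under rank permutations count as exceedances.

The intra-/inter-individual decomposition is exactly group-mean
subtraction: removing participant means isolates the within-subject
component, removing position means isolates the between-subject
component; correlations are then computed on the residuals. No mixed
models are used.

The fixed-eccentricity analysis averages width and thickness over the
vertices within ±0.5 deg of the target eccentricity (default 4.7 deg),
assigned to the nearest of the six ring positions by polar angle,
yielding the 20 × 6 = 120-cell table. Data grids use equal-width
eccentricity bins (10 by default) crossed with either participants or
0.1 mm thickness bins; per-row linear fits value ~ eccentricity use
unweighted least squares on populated cell means (≥ 3 bins), and their
slopes, intercepts, and goodness of fit are correlated against surface
area (or bin thickness), the goodness-of-fit member serving as the
negative control. Rows/cells with insufficient data are skipped with a
warning; the spec-level ambiguity of how many thickness bins the
published grids used is exposed via `thickness_bin_width` and the
eccentricity bin count.

## Pipeline

`run_pipeline` executes simulate → pRF-fit → psychophysics → analyze →
report. The master seed spawns independent sub-seeds per stage;
re-running a config reproduces every table bit-identically. The pRF
stage refits a per-participant subsample (default 12 vertices at
noise_sd = amplitude) to populate the fitted columns and the
recovered-vs-true table; the correlation analyses run on the generator's
width column by default (`value_col`), since fitting every vertex of
every cohort is redundant once the fitter's recovery is separately
established. Outputs are TSV (UTF-8, '.' decimal) and JSON with a
config hash and the package version.

## Problem sizes in the recovery studies

The acceptance studies use 200 voxels for pRF recovery, 500 staircases
per observer at three α levels, 50,000 samples for the decay-rate round
trip, 2,000/1,000 simulations for type-I/FWE calibration, 100 cohorts
(20 participants × 2,000 V1 vertices) for the fixed-eccentricity sign
recovery, and 50 cohorts for the eccentricity-resolved recovery; these
sizes put Monte-Carlo error comfortably below each decision band.

## Known limitations

- No image- or mesh-level processing: thickness, folding class, and area
  are generated fields, not measurements; gyral labels are random rather
  than curvature-derived.
- The HRF is canonical and shared across participants; real HRFs vary.
- The pRF model is the isotropic 2D Gaussian; no surround suppression or
  compressive nonlinearity.
- Staircase geometry (stimulus rendering, eye movements) is abstracted
  into the Weibull observer.
- The spatial/temporal forced-choice distinction is provenance only.
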