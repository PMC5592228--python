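# Methods

## The model

Tissue is described as a binary spin bath: a free water pool *f* and a
restricted macromolecular pool *r*, coupled by magnetization exchange.  Each
pool carries longitudinal magnetization; the restricted pool's equilibrium
magnetization relative to the free pool is the pool size ratio *F*, the
proxy for macromolecular content.  Exchange rates obey detailed balance,
`kf = F · kr`.

Off-resonance irradiation at offset Δ saturates both pools:

- restricted pool: `Wr(Δ) = π ω₁² g(Δ; T2r)`, with `g` the absorption
  lineshape of the restricted pool (Gaussian by default, super-Lorentzian
  available);
- free pool (direct saturation): `Wf(Δ) = ω₁² T2f / (1 + (2πΔ T2f)²)`.

The pulsed saturation train is reduced to its continuous-wave power
equivalent (CWPE): a constant ω₁ with the same mean-square B1 per TR.  For
the default protocol — Gaussian pulses truncated at ±3σ, flip 540°,
duration 12 ms, TR 300 ms — the flip-angle and power integrals are
closed-form error functions, so the conversion is exact for the assumed
envelope.  The protocol is an interleaved 16-section 2-D FLASH; one
saturation module plays per section acquisition, so 16 pulses are deposited
per TR and the mean-square power is 16× the single-pulse value.  This
multislice reading matters: a single 540° pulse per 300 ms produces a
caudate MTR of ~7.5%, far below the 30–60% range measured in gray matter,
while the 16-module reading yields ~51%.

Under CW irradiation the coupled Bloch equations have the steady state

    Mf(Δ) = [R1f (R1r + kr + Wr) + kr R1r F]
            / [(R1f + kf + Wf)(R1r + kr + Wr) − kf kr]

with `R1f = 1/T1f` and `R1r` fixed at 1 s⁻¹ (unidentifiable from MT data;
standard convention).  The FLASH excitation weighting is constant across
offsets and absorbed into an effective free-pool spin density SDf, so the
unsaturated signal is `SDf` and the saturated signals `SDf · Mf(Δ)`.  An
independent oracle integrates the same ODEs to steady state (BDF, derivative
norm < 1e-10) and agrees with the closed form to better than 1e-5 relative.

## Voxelwise inversion

Each voxel's M0-normalized spectrum is fit over the free parameters
{F, kr, T2r} (optionally T2f) inside physiological bounds
(F ∈ [0.001, 0.5], kr ∈ [1, 100] s⁻¹, T2r ∈ [2, 50] µs,
T2f ∈ [10, 300] ms); T1f and (by default) T2f come from separately supplied
relaxometry maps, and SDf is read off the M0 amplitude.  The optimizer is a
Levenberg–Marquardt damped least-squares with Marquardt diagonal scaling and
Nielsen's gain-ratio damping update; candidate steps are clipped to the
bounds and only cost-decreasing steps are accepted, so the recorded cost
trace is nonincreasing by construction.  The optimization runs in
log-parameter space: the F–kr trade-off is multiplicative, and log
coordinates straighten the cost valley (in linear coordinates the same
solver needs ~2× the iterations and occasionally stalls).  Initialization is
a deterministic 3×3×3 grid over (F, kr, T2r) at the 20/50/80% points of the
bounds; a flat spectrum falls back to mid-bounds.  Convergence: relative
cost change < 1e-10, scaled gradient < 1e-10, or 200 iterations.

Noiseless spectra are recovered to ≪0.5% in all free parameters.  With a
single saturation power — the study design — F and kr are only weakly
separable: the linearized Cramér–Rao bound at (F=0.12, kr=20 s⁻¹, T2r=10 µs,
SNR 100) allows ~200% relative SD for F and ~900% for kr.  The bounded
log-space estimator achieves a ~25% median relative error for F at SNR 100
(scipy's trust-region solver, used as an independent cross-check, lands on
the same minima).  Recovery RMSE falls monotonically with SNR.  ROI medians
over ~150 voxels are far tighter, which is why the subject-level analysis
works; but exchange-rate features remain the noisiest part of the feature
vector, and single-voxel exchange rates from one-power data should not be
over-interpreted.

## Synthetic cohorts and phantoms

The generator emulates a three-group cross-sectional study (10 controls, 10
premanifest carriers, 10 manifest patients by default):

- Demographics: controls age 48 ± 13; premanifest age 40.6 ± 9.1, CAG
  42.5 ± 2.4; manifest age 54.2 ± 12.7, CAG 43.7 ± 2.8.  The disease burden
  score is `DBS = age × (CAG − 35.5)`; controls carry neither CAG expansion
  nor DBS.
- Caudate ground truth (means): pool ratio 0.10 / 0.11 / 0.14 and T2r
  11 / 10.5 / 9.5 µs for control / premanifest / manifest; kr 20 s⁻¹ in all
  groups (so kf tracks F); T2f 60 / 62 / 66 ms; T1f 1.20 / 1.25 / 1.30 s;
  SDf 1.00 / 0.98 / 0.92.  Between-subject SDs are set at the few-percent
  level typical of ROI-median qMT parameters across healthy subjects
  (F 5%, kr 5%, T2r 2.4%, T2f 2.5%, SDf 1.5%).
- Transition structure: the premanifest group is DBS-coupled — each
  parameter's subject-level mean slides monotonically along the
  control→manifest axis at 1/300 progress units per DBS unit around the
  group reference (DBS 284), saturating at both endpoints.  Controls and
  manifest patients sit on plateaus.  This encodes the premise that
  macromolecular load in the caudate tracks cumulative disease burden, with
  manifest disease as a distinct state: low-burden carriers look
  control-like, high-burden carriers approach the manifest profile, and the
  group as a whole forms the transition continuum.
- Left/right hemisphere parameters are drawn with correlation 0.8;
  truncated-normal sampling enforces physiological bounds.
- Phantoms: 32×32×16 grids with two ellipsoidal caudate masks (~150 voxels
  each) over a uniform background tissue; Rician magnitude noise with SNR
  100 at M0 (typical of 3 T FLASH at 2×2×4 mm); T1/T2f maps are emitted
  noiseless, standing in for separate relaxometry experiments.

What the generator does **not** emulate: anatomy beyond two ellipsoids,
partial-volume mixing at ROI borders, B0/B1 inhomogeneity, motion, scanner
drift, or segmentation/registration error in the masks.  Tests passing on
these phantoms therefore validate the estimation and classification chain
under the stated statistical conditions, not robustness to those real-data
effects.

## Feature extraction and standardization

Per subject, the classifier features are the ROI summaries of (T2f, SDf,
kf, kr, T2r) over the left and right caudate — ten features in a fixed
canonical order.  The summary statistic is the median over converged
in-mask voxels (mean available).  Features are z-scored column-wise before
clustering and PCA; units span microseconds to arbitrary signal units, and
unscaled Euclidean or eigen analysis would be dominated by a single
feature.  The standardization record allows an exact inverse transform.

## Clustering and projection

Stratification uses Gustafson–Kessel (GK) fuzzy clustering: alternating
updates of centers, fuzzy covariances, determinant-normalized norm matrices
`A_i = (det S_i)^(1/p) S_i⁻¹`, and memberships, iterated until the maximum
membership change is < 1e-6, best of 16 random restarts by final objective.
Two conditioning choices matter at n = 30 subjects in p = 10 dimensions:

- **Covariance shrinkage** (`cov_blend`, default 0.5): each fuzzy
  covariance is shrunk toward the global data covariance, as in
  regularized discriminant analysis, before inversion.  The textbook GK
  constraint fixes every cluster's volume to ρ = 1 in its own metric, so a
  compact group gains nothing from cohering — in a controlled experiment a
  27σ-separated 10-point blob was fragmented by pure GK at c = 6 while
  spherical c-means kept it whole.  Shrinkage anchors cluster volume at
  the data scale while preserving anisotropy, and leaves the adaptive-norm
  advantage on elongated, rotated clusters intact.  `cov_blend=0` recovers
  the pure algorithm; `norm="identity"` recovers fuzzy c-means exactly.
- **Eigenvalue floor and ridge**: eigenvalues are floored at max/10⁵ and a
  1e-9 ridge added, guarding the inversion against the near-singular fuzzy
  covariances that small samples produce.

The pipeline default fuzzifier is m = 3 (the estimator's own default is the
textbook m = 2).  With c = 6 clusters forced onto 30 subjects, m = 2
provably yields a balanced partition that splits each group across ~2
clusters; above a data-dependent fuzzifier threshold, redundant centers
merge and surplus clusters empty out — which is the regime the reported
clinical structure (a distinct high-burden cluster, controls with low-burden
carriers, empty clusters) lives in.  The objective descends monotonically
for the exact updates (pure GK and identity norm); with shrinkage the
covariance step is no longer the exact minimizer and the objective may
drift upward at roundoff scale (observed ≤ 2e-5 relative), which the tests
bound explicitly.

Ties in hard assignment go to the lowest cluster index.  Clusters are
ranked by mean member DBS with controls entering at a sentinel of 0
(flagged in the report); empty clusters are reported, never pruned.
Clustering runs in the full 10-dimensional standardized space; the
two-component PCA (sample covariance, sign convention: dominant loading
positive) is the presentation and factor-loading layer, not the cluster
input.

## Numerical and degenerate-input choices

- Super-Lorentzian lineshape: adaptive quadrature with the magic-angle
  point isolated; offsets below 1 kHz are rejected (on-resonance
  singularity).  Near resonance the super-Lorentzian exceeds the Gaussian
  (≈3× at 1 kHz for T2r = 10 µs); in the far tail both decay at the same
  Gaussian rate and the super-Lorentzian is smaller.
- Rician noise: `|x + n₁ + i n₂|` with per-channel SD = reference/SNR,
  reference = mean in-mask M0; `SNR = ∞` is the exact identity.
- Zero-distance membership convention: a point coinciding with a center
  takes membership 1 there (split evenly across coincident centers).
- Degenerate clustering (all subjects in one cluster) warns and still
  reports; an all-flat spectrum falls back to the mid-bounds start; empty
  ROIs and all-unconverged ROIs raise explicit missing-data errors.
- Zero-variance features are rejected by name during standardization,
  with a roundoff-aware threshold.

## Problem sizes

Default experiments are desk-scale: 30 subjects × (1+7) volumes on
32×32×16 grids, ~300 caudate voxels fitted per subject (~12 ms per voxel),
a full pipeline run in ~2 minutes on one core.  The physics oracle uses 100
random parameter sets × 7 offsets; recovery experiments use 100 noiseless
voxels and 200 noise replicates per SNR level.

## Known limitations

- The CWPE reduction ignores transient saturation dynamics within TR and
  any dipolar-order effects; the ODE oracle validates the steady-state
  algebra, not the pulsed-vs-CW approximation itself.
- Exchange-rate maps from single-power data are prior-dominated at realistic
  SNR (see the Cramér–Rao analysis above).
- The cluster structure at c = 6 on 30 subjects is sensitive to the
  restart seed and noise realization in the transition region; the
  reported partition should be read qualitatively, as a burden-ordered
  stratification, not as a stable subject-level diagnosis.
- Template-space ROI warping is out of scope; masks must be supplied (or
  simulated) in subject space on the acquisition grid.
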