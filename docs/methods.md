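# Methods

## Connectivity model

All metrics start from the per-voxel distribution of Pearson correlations.
For a masked gray-matter series (V voxels × T frames), voxel x's
correlation row r(x, ·) holds its correlation with every other masked
voxel (V − 1 values; the self-correlation is always excluded).
Zero-variance target voxels — possible in synthetic or heavily masked data
— are assigned correlation 0 with a warning; a zero-variance *seed* is an
error. Voxel order everywhere is the C-order raster linearization of the
mask grid (`numpy.flatnonzero` of the boolean mask), so voxel indices are
stable across runs and platforms.

Three single-condition summaries:

* **degree(τ)** — the count of correlations strictly above τ;
* **wGBC** — the mean of the full correlation row, positive and negative
  values alike (a `positive_only` flag restricts the average to positive
  correlations for sensitivity analyses);
* **ICD** — the positive correlations are binned into a 100-bin histogram
  on [0, 1] (bin width 0.01; bins are right-open except the last, so a
  value equal to a bin's left edge falls in that bin and 1.0 falls in the
  last bin), converted to the survival function S(τ_k) = (tail count from
  bin k)/n, and fitted with the stretched exponential
  S(τ) = exp(−(τ/α)^β). Fitting the survival function this way is the
  same as modeling the correlations as Weibull(α, β); α tracks the spread
  of the distribution and is the group-analysis statistic. Each point of
  the survival function is binary degree at that threshold divided by n,
  so the model describes how degree decays as the threshold grows —
  without ever picking one threshold.

Survival curves are normalized by the in-support count n (so S at the
first edge is 1); an alternative denominator (e.g. V − 1) can be passed
explicitly, since either convention appears in practice.

## The coupled metric

For paired conditions of one subject (identical mask and voxel order;
frame counts may differ), the edge-wise differences
D(x, y) = r₂(x, y) − r₁(x, y) ∈ [−2, 2] are summarized per seed voxel by
the same survival machinery on a 200-bin histogram over [0, 2] — double
the bins of the single-condition analysis so the bin width stays 0.01
over the doubled range. Three modes:

* `absolute` — histogram of |D|; exact zeros land in bin 0;
* `increase` — histogram of D restricted to D > 0;
* `decrease` — histogram of −D restricted to D < 0.

Exact zeros of D are excluded from the two half-distributions (they
carry no direction) and included in the absolute mode, so for any voxel
n_increase + n_decrease + n_zero = V − 1. Swapping the conditions negates
D, so the increase and decrease maps exchange exactly and the absolute
map is invariant — this is tested bit-for-bit.

Difference rows are computed streaming in seed chunks (256 seeds at a
time): two standardized V×T matrices are held, and each chunk's
correlation blocks are formed and consumed immediately, so the V×V
difference graph never materializes. Multi-run conditions are temporally
concatenated after per-run nuisance regression, before correlation.

## The survival-curve fit

`StretchedExponentialModel` fits S(τ) = exp(−(τ/α)^β) by nonlinear least
squares (scipy trust-region-reflective, both parameters bounded positive,
parameter step tolerance 1e-10, at most 200 iterations, analytic
Jacobian). Initialization uses the linearization
log(−log S) = β log τ − β log α on the interior points (0 < S < 1, τ > 0).
Bins with S = 0 are excluded from the initialization but included, as
zeros, in the nonlinear objective (`include_zero_tail=False` drops them);
the leading S = 1 plateau is kept by default (`exclude_plateau=True`
drops all but its first point). Fewer than three interior points —
e.g. all differences exactly zero — yields the degenerate sentinel
α = 0, β = 0, which per-voxel maps propagate and count.

Accuracy, measured by the test suite and the acceptance script: exact to
≤ 1e-6 on a noiseless curve; scale within 5 % and shape within 10 % on
20 000 sampled Weibull(0.15, 1.2) draws through the full
histogram → survival → fit path.

## Preprocessing

The nuisance design has 11 columns in fixed order: intercept, centered
linear and quadratic drift (centered polynomials of frame index, hence
orthogonal to the intercept), six rigid-body motion parameters, mean CSF
and mean white-matter signal. The global signal is deliberately not a
column; users who want it must append it themselves. Constant columns
(e.g. all-zero motion in synthetic data) are dropped with a warning
rather than failing; the residuals are exact least-squares residuals
(computed via QR), orthogonal to every retained column. CSF/WM means are
taken from the raw masked series (the convention when the ordering
versus drift removal is unspecified).

Temporal smoothing uses a unit-sum Gaussian kernel whose continuous
transfer function exp(−2π²σ²f²) equals 0.5 at the cutoff frequency
(default 0.12 Hz), with reflect padding; the mapping from a printed
cutoff to σ is therefore parameter-free. `temporal_transfer` evaluates
the realized discrete kernel's amplitude response and serves as the
oracle in tests. Spatial smoothing of maps interprets its width as FWHM
(6 mm default, the field convention), smooths mask-renormalized
(G∗(m·v))/(G∗m), and so leaves constants unchanged inside the mask.

Mean frame-to-frame displacement is the per-transition Euclidean norm of
the translation difference with rotations converted to arc length on a
50 mm-radius sphere and added in quadrature; `include_rotations=False`
reduces it to the translation-only convention, since the exact formula
varies between laboratories.

## Group statistics

* **Top Percent** (single group): per-voxel effect size mean/SD across
  subjects; zero-SD voxels are excluded with a warning; the top
  `percent` (default 15) is selected by nearest-rank percentile with
  ties at the cutoff included; face-connected (6-connectivity)
  components smaller than `cluster_min` (default 50) are removed.
  Note the statistic is scale-invariant per voxel (mean/SD), so it ranks
  regions by *consistency relative to spread*; in a synthetic cohort of
  exchangeable subjects the background noise floor is extremely
  consistent and Top Percent will not single out a planted effect however
  large its mean — the desk study below therefore uses the group t-test
  as its inferential stage and checks Top Percent's structural contract.
* **t-tests**: voxelwise two-sided, Welch for unpaired groups, paired
  optional; degenerate voxels (zero difference) report t = 0, p = 1.
  Edgewise tests run over the upper triangle of Fisher-z matrices with
  BH-FDR at q (default 0.05) and report per-node significant-edge counts
  (which sum to twice the edge count).
* **FDR**: Benjamini–Hochberg step-up (statsmodels).
* **Cluster correction**: instead of an external Monte-Carlo tool, a
  built-in permutation routine estimates the null distribution of the
  maximum supra-threshold cluster size by sign-flipping (paired) or label
  permutation (unpaired), seeded, 1000 permutations by default; its
  quantiles give cluster-extent thresholds.
* **Matrix connectivity**: atlas nodes are mean time courses over member
  voxels; node-by-node correlations are Fisher-transformed with |r|
  clipped at 1 − 1e-7 (logged), the matrix exactly symmetrized, diagonal
  NaN. The 278-node functional atlas used in practice is one instance;
  any labeled volume works.
* **Seed maps**: ROI mean course correlated with every masked voxel,
  atanh-transformed with the same clip.

## Synthetic data

Sessions are zero-mean Gaussian draws whose population correlation
matrix is specified exactly (eigenvalue square-root factorization;
matrices must be PSD up to 1e-8, and a delta that breaks PSD by less
than 1e-6 is projected to the nearest PSD matrix with a warning, larger
violations are errors). An optional AR(1) coefficient adds temporal
autocorrelation without changing the cross-sectional correlations
(x_t = φx_{t−1} + √(1−φ²)e_t). `noise_sd` adds independent measurement
noise, attenuating all correlations by 1/(1+noise_sd²); its default is 0
so the matrix is reproduced exactly in population. All randomness flows
from one seed through `numpy.random.SeedSequence` spawning (condition 1
before condition 2).

Block specs (equicorrelated blocks over a background correlation) cover
generic sessions. The paired scenarios need a hub holding hundreds of
moderately strong edges to otherwise weakly coupled voxels, which no
equicorrelated-block construction can make PSD; they are therefore built
from single-factor loadings (r_ij = λ_iλ_j), PSD by construction, with
the hub's edge targets hit exactly:

* `threshold_crossing` — one edge moves τ−0.01 → τ+0.01 (τ = 0.25,
  δ = 0.02): flips binary degree at τ by exactly 1 at both endpoints;
* `balanced_cancellation` — 200 of a hub's edges at 0.32 move by ±0.2 in
  equal numbers (hub loading 0.8): the hub's population mean edge change
  is exactly 0 and the mean |change| over perturbed edges exactly 0.2;
* `uniform_shift` — 100 hub edges rise by 0.2 from 0.2.

Defaults (V = 500, T = 300, the edge counts and δ above) are the study
conditions under which the scenario properties are asserted. The
generator does not emulate physiological noise spectra, scanner drift
fields beyond polynomials, or spatial autocorrelation of the noise —
passing tests demonstrate the metric's mathematical behavior under
controlled correlation structure, not performance on real scans.

## The desk study

`pipeline.run_desk_study` assembles everything: 14 subjects × 2
conditions on a 12×12×12 grid (1728 voxels), T = 150 frames. A planted
4×4×4 corner region's factor loading changes 0.2 → 0.7 against a
300-voxel partner network at loading 0.5, so planted edges change by
roughly 0.2–0.45. Subjects differ in temporal autocorrelation
(φ ~ U(0.2, 0.5) per subject), a minimal stand-in for between-subject
physiological heterogeneity, and every run is contaminated with linear
drift, motion-coupled signal and CSF/WM signal that the preprocessing
stage must remove. Per subject the pipeline runs nuisance regression,
temporal smoothing, coupled-ICD (absolute) and per-condition ICD; at the
group level, Top Percent (15 %, cluster 50) on the coupled-α maps and a
paired t-test of condition-2 versus condition-1 ICD α with BH-FDR, whose
rejections flag the planted region. Problem sizes were chosen so the
whole study runs in a few minutes on one CPU.

## Numerical conventions and edge cases

* Correlations are clipped to [−1, 1] after the matrix products; |r| is
  clipped to 1 − 1e-7 before any Fisher transform.
* Histogram bins are right-open except the last (closed), on a uniform
  grid; out-of-support values are dropped from counts and n.
* Grids are validated by shape plus affine agreement within 1e-4 mm
  before any cross-image operation; written maps encode out-of-mask
  voxels as zero, with the mask carried alongside.
* Degree uses a strict inequality (r > τ). The identity
  degree(τ_k) = n·S(τ_k) at bin edges is exact whenever no correlation
  ties a bin edge — almost surely for continuous data, which is how it
  is tested.

## Limitations

* Only two paired conditions are supported; unpaired designs should use
  the single-condition metrics.
* Slice-time/motion correction and registration are out of scope; inputs
  are assumed co-registered, with conditions on an identical voxel grid.
* β is fitted per voxel alongside α; both maps are emitted, but β is
  noisier and is not used in the group statistics.
* The Top Percent statistic is a consistency ranking; see the group
  statistics section for when it is and is not informative.
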