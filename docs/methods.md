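# Methods

This note documents the models, numerical choices and limitations behind
`colonylapse`. It is written for a reader who wants to know exactly what
each stage computes and why, and what passing the test suite does and does
not demonstrate about real data.

## Image quantification

**Smoothing.** Frames are denoised with Perona–Malik anisotropic
diffusion: 5 iterations of the flux-form update with step 0.25 and
exponential conduction g(d) = exp(−(d/κ)²). κ is the 90th percentile of
the nonzero neighbor-difference magnitudes of the input frame, held fixed
across iterations (deterministic; the nonzero restriction keeps the filter
active on sparse scenes where most gradients are exactly zero). Because
fluxes between pixel pairs are antisymmetric and borders are replicated,
the image sum is conserved up to clipping of negative values.

**Gridding.** Colony centers form a bilinear lattice between four
manually supplied corner anchors (top-left, top-right, bottom-left,
bottom-right in crop coordinates), so mild keystone/shear distortion is
handled without image rectification. One grid per plate is fitted at a
designated frame and reused for every frame of the series. The per-colony
window radius defaults to just under half the minimal center spacing.

**Segmentation (half-mode-max).** Within each colony window, the
background level is the mode of the integer-binned intensity histogram;
the threshold is background + (window max − background)/2. The mask is
the 8-connected component above threshold containing the window center,
or the nearest component if the center pixel is below threshold
(equidistant ties go to the larger component). A flat window yields an
empty mask, not an error.

**Measurement.** Colony intensity is the sum over mask pixels of
(pixel − background mode), clipped at zero. Subtracting the pedestal is
what makes the reported value the colony's own signal: without it a
colony of summed intensity I sitting on background b with mask area A
would be overestimated by A·b, which at low intensities exceeds any
useful accuracy bound.

**Spatial correction.** Two multiplicative stages on each plate matrix:
(1) border stage — the outermost two rows/columns (which overgrow from
extra nutrient access) are rescaled so their median equals the interior
median; (2) surface stage — a 9×9 moving median (edge-truncated) of the
border-adjusted matrix estimates the smooth plate surface S, and each
value is multiplied by median(S)/S. A final rescale restores the
original plate median exactly, so the correction never changes the
plate-level location, only the spatial pattern. The correction is
idempotent to within 1% on smooth fields. A 9-position moving median
cannot (by design) remove single-row artifacts; it targets plate-scale
gradients and edge effects.

## Growth curves and metrics

Curves are truncated to the first 40 hours (overgrowth and colony merging
corrupt later frames), then smoothed, then normalized; metrics are read
off the processed curves.

**Robust LOWESS.** Smoothing is a locally weighted linear regression over
a centered, edge-truncated window of 48 timepoints (4 h), tricube distance
kernel, followed by 3 bisquare reweighting passes. The robust scale is
*local*: for each point, 6× the median absolute residual within its own
window. Colony intensities span roughly four decades over a time course,
so a global residual scale — the textbook choice — treats the entire
high-intensity regime as outlying and collapses the fit there;
the local scale keeps outlier rejection (a 50σ spike is fully
down-weighted) while remaining valid under strongly heteroscedastic
noise. The fit is exact on linear data, and the whole operation is
vectorized across curves (closed-form 2×2 weighted least squares over
sliding windows) so a full screen smooths in about a minute.

**Normalizations.** Zero-normalization subtracts the first smoothed value
and clips negatives (imaging starts at pinning; a colony cannot have
negative growth). Colony fitness is the final zero-normalized value; at
the curve-level entry, each plate's final-intensity matrix is additionally
passed through the spatial correction above before CF is read off, when
grid positions are known. Endpoint normalization divides by the final
value, expressing progress as a fraction of final intensity; colonies
whose final intensity is below 1% of the plate median final (configurable)
are excluded as dead and reduce downstream replicate counts.

Time-constant multiplicative position effects cancel *exactly* in
endpoint normalization, which is why lagVstall needs no spatial
correction while colony fitness does.

**Reference and lagVstall.** The reference is the per-timepoint median of
all endpoint-normalized curves on a plate (computed in normalized space,
where the median is a meaningful typical trajectory independent of colony
size). The deviation profile is the pointwise difference from the
reference; lagVstall is its unweighted sum over the 5-minute samples. At
uniform spacing this differs from a time integral only by the constant Δt,
so the sum is used. Signed (not absolute) deviations are essential: a lag
strain sits below the reference everywhere (negative), while a stalled
strain — one that reaches its own plateau early — sits above it
(positive), because its fraction-of-final runs ahead of the population's.

## Differential statistics

Colonies of the same strain arrayed at multiple plate positions are pooled
as extra replicates (deterministically re-indexed by position). Strains
need at least 6 replicates in *both* conditions to be tested.

Per strain and metric, replicate values are compared between conditions
with a two-sided pooled-variance t-test on the raw metric values.
Robust Z-scores — (x − median)/MAD with unscaled MAD, computed within each
plate × condition population so that plate effects are absorbed — are
summarized per strain by the replicate median; their treated−untreated
difference (delta_z) sets the direction label. For colony fitness,
delta_z < 0 is "sensitive" (treatment cost fitness); for lagVstall,
delta_z > 0 is "sensitive" (the stall deepened under treatment) and
delta_z < 0 "resistant" (the stall weakened). Zero-variance degenerate
groups return p = 1 (equal means) or the flagged boundary p = 0.

**Storey q-values.** π₀(λ) = #{p > λ}/(m(1−λ)) is evaluated on
λ = 0, 0.01, …, 0.90, smoothed with a cubic polynomial, read off at
λ = 0.90, and clipped to (1/m, 1]. q-values are the step-up minima of
π₀·m·p/rank, monotone in p and bounded by 1; with π₀ fixed at 1 the
procedure reduces exactly to Benjamini–Hochberg (used as an oracle in the
tests). q-values are computed separately for the lagVstall and the
colony-fitness p-value families, since nominations are reported per
metric; the union and intersection of the two nominated sets are reported
alongside.

Percentile tail selection (e.g. the 5th/95th percentiles of untreated
lagVstall for enrichment) takes ceil(pct/100 · N) strains per tail with
ties broken by strain identifier, which makes tail membership
deterministic.

## Enrichment

Gene sets come from GMT files; terms are intersected with the screen
universe and emptied terms dropped (genes not present in the screen are
never counted). For overlap x between a nominated set of size N and a
term with M members in a universe of K genes, the p-value is the
hypergeometric upper tail P(X ≥ x) = 1 − F(x−1; K, M, N) and fold
enrichment is (x/N)/(M/K). Multiple testing across terms uses the same
Storey procedure. No minimum term size is imposed by default
(configurable).

## Synthetic screens

The simulator produces fully labeled experiments with the statistical
structure the pipeline assumes. Every colony follows a logistic in
*effective time*, I(t) = K/(1 + exp(−r(τ(t) − t_mid))) with
τ(t) = ∫ m(s) ds, where the rate multiplier m encodes the phenotype; τ is
piecewise linear and computed in closed form, so noiseless class curves
are analytic and pipeline outputs can be checked against exact
expectations.

Default study conditions: 1000 strains on a 32×48 plate (spare wells
cycle through strains again, creating the extra-replicate situation the
duplicate-pooling stage handles), 11 replicate plates per condition,
5-minute frames for 48 h, treatment immediately after frame 48 (4 h).
Classes and their defaults:

| class | share | parameters | untreated LVS | treated effect |
| --- | --- | --- | --- | --- |
| reference | 90% | K = 2×10⁵, r = 0.006/min, t_mid = 25 h | 0 | none |
| lag | 2.5% | r = 0.003, t_mid = 33.3 h | negative | none |
| stall | 2.5% | rate ×0.05 after 25 h | positive | none |
| uvr_sensitive | 2.5% | reference + 600 min pause | 0 | CF drops, LVS goes negative |
| uvr_resistant_stall | 2.5% | stall; rate fraction 0.05→0.15 under treatment | positive | stall weakens (LVS delta < 0, CF delta > 0) |

The reference saturates around 35 h, inside the 40-h analysis window —
necessary for lag strains (still rising at truncation) to sit below the
reference in normalized space. The stall fraction 0.05 leaves stalled
colonies essentially at their own plateau by 40 h, which is what makes
their normalized curves run *above* the reference (the diauxic-arrest
phenotype); with a substantially larger fraction the colony keeps growing
and the sign of lagVstall flips, which is a property of the metric worth
knowing when interpreting real screens.

Noise is per-timepoint multiplicative lognormal (σ = 0.05) plus a smooth
random low-order polynomial bias field per plate (peak amplitude 0.10),
emulating illumination and agar-thickness gradients. All randomness
derives from one seed; per-colony substreams are keyed by (condition,
plate replicate, row, col), so enlarging a layout does not reshuffle
existing colonies. Image rendering draws each colony as a radially
symmetric supergaussian blob exp(−(r/σ_b)⁸) — the near-sharp edge of a
real colony — normalized so the summed blob intensity equals the
programmed value exactly before background and Gaussian pixel noise are
added. A soft (Gaussian) profile would leave ~40% of the blob's intensity
below the half-max threshold and is not a realistic colony cross-section.

**What the simulator does not model:** colony merging and overgrowth,
lid condensation and reflections, pinning failures, agar drying,
time-varying spatial artifacts, and biological covariance between
neighbors. Passing the simulated-screen tests therefore demonstrates the
pipeline's statistical machinery (normalization, metric signs, error
control, determinism) under the stated noise model, not robustness to
every real-world imaging artifact.

## Problem sizes and calibration checks

The bundled end-to-end checks use the default 1000-strain, 11-replicate
screen (sign recovery of lag/stall classes; nomination recall ≥ 0.9 at
empirical FDR ≤ 0.10 against programmed responders), 10,000 simulated
null strains for t-test type-I calibration (0.05 ± 0.01), exhaustive
enumeration of every hypergeometric configuration with population ≤ 12
(agreement to 10⁻¹²), and a 16×24-colony, 50-frame rendered plate for the
image round trip (99th-percentile recovery error < 5% for colonies whose
peak exceeds 10× the pixel noise). Determinism is asserted at bit level
for identical seeds.

## Known limitations

* Replicates pooled from multiple positions on the same plate share that
  plate's residual spatial structure; the t-test treats them as
  independent, which can mildly understate variance for duplicated
  strains. Plate-level random-effect models are out of scope.
* The Storey π₀ smoother (cubic in λ) is one of several published
  variants; nomination counts can shift by a few strains under other
  smoothers when many p-values sit near the cutoff.
* The half-mode-max threshold assumes a unimodal background; strongly
  textured backgrounds would need a different background estimator.
* Growth curves are treated as continuous through the treatment frame;
  no re-zeroing is applied after treatment.
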