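# Methods

`replidyn` quantifies DNA replication dynamics and heterochromatin
epigenetics from multi-channel fluorescence images of nuclei that contain
mask-separable chromatin compartments — the motivating system is the female
*Microtus cabrerae* fibroblast, a tetraploid cell whose four giant X
chromosomes carry enlarged heterochromatic blocks, two of the facultative
type (X*, enriched for H3K27me3/macroH2A) and two of the constitutive type
(X, enriched for H3K9me3/HP1β). This note describes the measurement models,
the synthetic ground-truth generator used to validate them, the numerical
choices, and the known limitations.

## Measurement pipelines

### Mask-based PTM quantification (`image_quant`)

Per-compartment mean intensities of histone posttranslational modifications
(H3K9ac, H4K8ac, H3K27me3, H3K9me3) are measured over three regions built
from a mid-nuclear section: the nucleus (from DAPI), the heterochromatic
blocks (from a GFP-tagged block marker, macroH2A or HP1β), and the
"exclusion" region (nucleus AND NOT blocks). Mask construction is
median-filter → successive automatic thresholding → small-component
rejection:

* **Mid-nuclear section.** The Z plane maximising DAPI foreground area
  (Otsu-thresholded). A full 3D protocol would need the optical sectioning
  the source images do not reliably give for every mark.
* **Median filter.** Cubic `(2r+1)^d` window, `r = 1`, reflect padding.
  On thin synthetic stacks (5 planes) a 3D median erodes structures confined
  to the mid plane, so the canonical order here is: section first, then
  filter the 2D section. `median_filter` adapts its window to the input
  dimensionality, so both orders are available.
* **Successive thresholding.** An Otsu threshold is applied globally, then
  re-estimated within the current foreground for up to three further rounds
  (four steps total by default). A refinement is accepted only while the
  foreground is genuinely bimodal: the two classes induced by the candidate
  threshold must be separated by at least `s_min = 6` pooled within-class
  standard deviations. Calibration of that constant: an Otsu split of pure
  Gaussian noise scores ≈ 2.65 (half-normal means at ±0.80σ, within-class
  spread 0.60σ), a flat uniform plateau ≈ 3.5, while genuinely separated
  compartments (background/nucleus, nucleus/marker-bright block) score well
  above 8. The full threshold trace is recorded on every mask. Foreground
  polarity is bright-on-dark (above threshold).
* **Component rejection.** Connected components below 200 px (nuclei) or
  20 px (blocks) are dropped; if more components than expected survive for a
  block mask, components are ranked by mean marker intensity and a warning
  is raised.

Mean level is total intensity over the mask divided by pixel count, exactly.
Condition contrasts are reported as the ratio of population means
(sample/control) with a delta-method 95% CI for the ratio of two independent
means, plus a Welch t-test on the per-cell values. Transcription at the
blocks (EU pulse) is quantified as per-cell mean EU in each 3D block volume
with a paired t-test X vs X*.

### S-phase staging and durations (`replication_staging`)

PCNA replication foci form three successive spatial patterns: **early**
(many small foci through the nuclear interior, euchromatin), **mid**
(perinuclear/nucleolar rim foci plus the first large blob on the X* block),
**late** (large blobs on the X blocks). A frame is classified from the
max-projected PCNA image by a fixed rule on four features: the PCNA-positive
fraction of the nucleus (positive = above extra-nuclear background median +
5 robust sigmas), the fractions of X*- and X-block voxels that are
PCNA-positive, and a perinuclear score (fraction of PCNA-positive pixels in
the outer 15% radial shell of the nucleus-mask distance transform; the score
is pixel-weighted rather than per-focus because focus merging in dense early
patterns makes a per-component score unstable). Decision order: nonS if the
positive fraction < 0.5%; **late** if X overlap ≥ 20% (terminal pattern, so
it wins ties); **mid** if X* overlap ≥ 20% or perinuclear score ≥ 0.5;
**early** otherwise. All thresholds are configurable
(`StagingThresholds`); the defaults were fixed on the synthetic generator,
where the zero-noise confusion matrix is the identity and default-noise
accuracy is ≥ 95% per pattern.

Durations come from live-cell tracks at 20-min frame intervals by frame
counting: duration = (frames carrying the label or block flag) × interval.
Per cell, total S = early + mid + late exactly. With the S-phase entry phase
uniform on one frame interval — the asynchronous-culture situation — the
counting estimator is unbiased, which the generator tests verify. A track
contributes only if it shows ≥ 1 nonS frame before its first early frame and
after its last late frame (otherwise S entry/exit is censored), if its label
sequence obeys the grammar `nonS* early+ mid+ late+ nonS*`, and, for block
durations, if the flagged window starts and ends inside the track;
violations are excluded with a logged reason, never silently repaired. The
source protocol does not state its censoring rules; these are ours, explicit.

### Ratiometric fork-speed index (`fork_speed`)

Total nuclear PCNA is proportional to the number of active replisomes; total
EdU from a short pulse is proportional to replisomes × fork speed, so the
per-nucleus ratio EdU/PCNA indexes relative fork speed. Totals are
integrated over the whole nucleus mask after subtracting the per-image
background (median of non-nuclear pixels; configurable off). Ratios are
normalized to the median of the untreated early-S group and contrasts are
reported as median fold changes with Wilcoxon rank-sum tests; the median is
used throughout because the analysis is framed on box plots and the ratio
distributions are right-skewed. Normalized folds are invariant to any global
per-channel gain, and contamination of ≤ 10% of records with 10× outliers
moves the folds by < 5% on the default generator.

### DNA content and genome duplication rate (`dna_content`)

Integrated nuclear DAPI intensity is mapped to "G1 equivalents": a Gaussian
KDE (Silverman bandwidth, on log intensities, 512-point grid) locates the G1
and G2 modes — the most prominent mode pair with location ratio in
[1.7, 2.3] — and intensity is mapped linearly so G1 → 1.0, G2 → 2.0.
Replicates are normalized independently (absorbing gain differences) and
then pooled. The genome fraction replicated in each substage is read off the
staged, normalized population: boundary(substage) = q-quantile (default
q = 0.95) of the content of cells staged into it, then

    fraction(early) = (b_early − 1) × 100
    fraction(mid)   = (b_mid − b_early) × 100
    fraction(late)  = (2 − b_mid) × 100

summing to 100 exactly. The 0.95 quantile stands in for the "maximal"
content because the literal maximum is an extreme-value statistic with
unbounded upward bias under intensity noise; `q = 1.0` recovers the literal
maximum. Dividing fractions by the measured substage durations gives the
genome duplication rate in % per hour. An 18-bin pattern-frequency table
over [1, 2] provides the staging-independent control view.

**Known bias.** The q-quantile boundary undershoots the top of a substage
content band by (1 − q) × band width, and intensity noise lifts it back up;
fraction(mid) inherits the *difference* of the undershoots of its two
boundaries. When the early band is much wider than the mid band (the
hyperacetylated condition: 0.50 vs 0.24 G1 equivalents), the cancellation is
uneven and fraction(mid) carries an upward bias of ≈ 1.3 pp at zero noise
and ≈ 2.5–3 pp at the default noise, which the recovery tests make visible.
No choice of q removes both undershoot (q < 1) and extreme-value noise
amplification (q → 1) at once.

## The synthetic generator (`synthetic_data`)

The generator is first-class, tested code: it is the ground truth against
which every pipeline is validated, since no imaging data are deposited for
this system. Its defaults are the measured study conditions:

| parameter | untreated | HDACi-treated | HAT-targeted |
|---|---|---|---|
| substage durations early/mid/late (h) | 3.4 / 3.5 / 2.5 | 5.1 / 4.4 / 3.1 | 3.4 / 3.5 / 3.4 |
| X* / X block replication windows (h) | 1.9 / 1.8 | 2.7 / 2.2 | 1.9 / 3.2 |
| cumulative content boundaries | 0.37, 0.75 | 0.50, 0.74 | 0.37, 0.75 |
| relative fork speed early / mid+late | 1.0 / 1.4 | 0.9 / 0.84 | 1.0 / 1.4 |

The speed multipliers encode the three measured contrasts (mid+late vs early
in untreated cells 1.4×; treated vs untreated early 0.9×; treated vs
untreated mid+late 0.6× = 0.84/1.4). No substage durations were measured
under HAT targeting, where only the constitutive-block window (3.2 h, up
from 1.8 h) is reported; since that window must fit inside late S, the
targeted configuration extends late S to 3.4 h and keeps the other untreated
values — a modelling choice, not a measured quantity.

* **Tracks.** Each cell enters S at a uniform random phase offset within one
  frame interval and traverses nonS → early → mid → late → nonS; block flags
  rise for contiguous windows placed uniformly at random inside mid (X*) and
  late (X). Per-cell duration jitter is a unit-mean lognormal with
  configurable CV (default 0: per-cell variability of substage durations is
  not reported for this system, so none is asserted). A configurable
  fraction of tracks is truncated mid-S and flagged censored.
* **Populations.** Phases are drawn with configured proportions (defaults
  give S-substage occupancy proportional to the untreated substage
  durations, G1/G2 peaks of roughly equal weight). DNA content is 1.0 (G1),
  2.0 (G2) or uniform within the substage content band; integrated DAPI is
  `base × content` with multiplicative lognormal noise; EdU = speed ×
  PCNA × lognormal noise.
* **Images.** An ellipsoidal nucleus with four disjoint hard-boundary
  ellipsoidal blocks (two per type, on opposite diagonals), per-compartment
  PTM/EU/marker means, a per-pattern PCNA render (early: dispersed disks
  strictly outside blocks; mid: rim disks plus blobs filling the X* blocks;
  late: large blobs filling the X blocks), EdU = true speed × PCNA, and
  additive Gaussian voxel noise (σ = 5 on a 10/100 background/signal scale),
  clipped at zero.

**Noise model.** Totals carry multiplicative lognormal noise, voxels
additive Gaussian noise — standard fluorescence statistics; the source
states no noise model. Two CVs are separated: `intensity_cv = 0.2` for
EdU/PCNA/PTM totals (immunostaining-scale variability) and
`dapi_cv = 0.02` for integrated DAPI. The DAPI value is set by error
propagation through the DNA-content pipeline: the q = 0.95 substage boundary
of a content band of width *w* under content noise σ sits near
`top + t*σ` with `t*` solving `G(t) − t = (1−q)·w/σ` for
`G(z) = zΦ(z) + φ(z)`; keeping the noise lift below the estimator's own
granularity on the narrowest band (0.24 G1 equivalents) requires
σ ≲ 0.03 G1 equivalents, i.e. a DAPI CV of ≈ 2%. This is the regime of
well-exposed high-content DNA-content histograms with sharp G1/G2 peaks;
single-cell DAPI photometry with larger CV would need wider recovery
tolerances than the ones tested here.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: point-spread blur and optical sectioning cross-talk,
chromatin texture inside compartments (blocks are hard-edged and uniform),
photobleaching, cell movement and registration error across time-lapse
frames, segmentation failure modes from touching nuclei, and
staging-by-content correlation beyond the hard band assignment (a cell near
a substage boundary always shows that substage's pattern). Parameter
recovery on this generator validates the estimators' logic and their
noise behaviour, not robustness to optics.

## Statistics (`reporting_stats`)

"t test" is always Welch's unequal-variance t (group sizes and variances
differ throughout); the nonparametric two-group test is the Wilcoxon
rank-sum with midrank ties, exact for both n ≤ 10 without cross-group ties,
otherwise normal approximation with continuity correction; paired designs
use the one-sample t on differences; interval estimates are
mean ± t(0.975, n−1)·SE. Degenerate inputs resolve by convention and are
flagged: zero variance in both groups with equal means → p = 1; constant
nonzero paired differences → p = 0. No multiple-testing correction is
applied (none is applied in the source analyses); reports carry raw
p-values with the star convention *** p < 0.001. Monte-Carlo suites verify
each test's size at the nominal α.

## Problem sizes

Validation uses 500 tracks per condition for durations, 2,000-cell
populations for DNA content (three-population means in the recovery tests,
mirroring the pooled-replicate design), ~200 cells per group for the
ratiometric folds, and 10⁴ replicates for test-size calibration — the sizes
at which the recovery tolerances quoted above were established.

## Limitations

* The staging thresholds are generator-calibrated; on real images they would
  need re-tuning against a manually annotated set.
* The treated mid-S genome fraction carries the structural quantile bias
  described above (~+2.5 pp under default conditions).
* The classifier assumes one nucleus per field and given masks; instance
  segmentation of touching cells, mitosis detection and cell tracking are
  out of scope.
* Physical pixel size is stored as opaque metadata and never computed with
  (the source's printed XY pixel size is not physically interpretable).
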