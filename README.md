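# replidyn

Quantitative image analysis of DNA replication dynamics and heterochromatin
epigenetics in nuclei with giant sex-chromosome heterochromatin blocks.

Female *Microtus cabrerae* (Cabrera's vole) fibroblasts are tetraploid and
carry four giant X chromosomes whose enlarged heterochromatic blocks are
visible as discrete nuclear compartments: two blocks of the facultative type
(X*, H3K27me3/macroH2A-enriched) and two of the constitutive type (X,
H3K9me3/HP1β-enriched). This makes them a rare system where the replication
of individual chromatin classes can be timed by eye — and where the effect
of histone acetylation on replication can be measured compartment by
compartment. `replidyn` implements the four measurement pipelines such
experiments need, plus a fully seeded synthetic-data generator with
ground-truth bookkeeping so every estimator is testable without any imaging
download:

* **`image_quant`** — nuclear / block / exclusion masks from mid-nuclear
  sections (median filter, successive Otsu thresholding with recorded
  threshold trace), mean PTM levels per mask, ratios to control with 95%
  CIs, line profiles, paired EU-transcription quantification.
* **`replication_staging`** — classification of PCNA replication-foci
  patterns into nonS/early/mid/late and frame-counting estimation of total
  S-phase, substage, and block-replication durations from 20-min time-lapse
  tracks: `duration = (frames with label) x interval`, unbiased under
  uniform S-entry phase.
* **`fork_speed`** — per-nucleus ratio of total EdU (incorporated
  nucleotide) to total PCNA (active replisomes) as a relative fork-speed
  index; normalized median fold changes between stage groups and conditions
  with Wilcoxon tests.
* **`dna_content`** — G1/G2 peak fitting of integrated DAPI by kernel
  density estimation, linear normalization to G1 equivalents (G1 → 1,
  G2 → 2), percent of genome replicated per substage from quantile
  boundaries, genome duplication rate in %/h, and an 18-bin pattern-by-
  content frequency table.
* **`synthetic_data`** — generator of images, time-lapse tracks and
  population tables whose defaults are the measured study conditions
  (substage durations 3.4/3.5/2.5 h untreated vs 5.1/4.4/3.1 h under HDAC
  inhibition, block windows 1.9/1.8 → 2.7/2.2 h, content boundaries
  0.37/0.75 → 0.50/0.74, fork-speed multipliers 1.0/1.4/0.9/0.84).
* **`reporting_stats`** — Welch t, Wilcoxon rank-sum, paired t, 95% CIs,
  with explicit degenerate-input conventions and uniform JSON-able results.

## Worked example

Estimate S-phase and block-replication durations from simulated time-lapse
tracks of untreated vs HDAC-inhibitor-treated cells (200 cells each):

```python
from replidyn.synthetic_data import GroundTruthConfig, gen_timelapse_tracks
from replidyn.replication_staging import summarize_durations

u = gen_timelapse_tracks(GroundTruthConfig.untreated(seed=1), 200, seed=1)
t = gen_timelapse_tracks(GroundTruthConfig.treated(seed=2), 200, seed=2)
summary, tests = summarize_durations(u + t)
print(summary.to_string(index=False))
for q, r in tests.items():
    print(f"{q}: effect = {r.effect:+.2f} h, p = {r.p_value:.3g} {r.stars}")
```

```
condition quantity    mean_h     sd_h   n
untreated    early  3.406667 0.138429 200
  treated    early  5.106667 0.155882 200
untreated      mid  3.501667 0.167077 200
  treated      mid  4.413333 0.142718 200
untreated     late  2.498333 0.167077 200
  treated     late  3.081667 0.143722 200
untreated    total  9.406667 0.138429 200
  treated    total 12.601667 0.132398 200
untreated    Xstar  1.888333 0.157725 200
  treated    Xstar  2.706667 0.108592 200
untreated        X  1.783333 0.159389 200
  treated        X  2.205000 0.162605 200
total: effect = -3.20 h, p = 0 ***
early: effect = -1.70 h, p = 7.31e-305 ***
mid: effect = -0.91 h, p = 3.56e-195 ***
late: effect = -0.58 h, p = 4.65e-131 ***
Xstar: effect = -0.82 h, p = 2.79e-188 ***
X: effect = -0.42 h, p = 1.34e-88 ***
```

Frame counting recovers the configured ground truth: untreated S-phase
totals 9.4 h (3.4 + 3.5 + 2.5) versus 12.6 h under hyperacetylation, with
the facultative block window stretching from 1.9 to 2.7 h and the
constitutive block from 1.8 to 2.2 h; every contrast is flagged by the
Welch t-test. The SD column shows only frame-quantization scatter because
this run used zero per-cell duration jitter (the default; see
`docs/methods.md`).

The same generator-to-pipeline round trip works from the shell:

```sh
replidyn simulate --seed 3 --n-cells 200 --condition treated --out-dir sim/
replidyn durations sim/tracks.csv
replidyn dna-content sim/population.csv --q 0.95 --bins 18
replidyn fork-speed sim/population.csv --reference untreated:early
```

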