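# Methods

This note records the statistical conventions, simulator design and
numerical choices behind indikit, and what the shipped tests do and do not
establish.

## Scope and model

indikit is descriptive, not inferential in the modelling sense: it computes
threshold dichotomizations, quadrant compositions, fold changes and
rank-based two-sample tests on log2-scale expression values that are taken
as given. There is no normalization, batch correction, differential
expression or enrichment testing; values are assumed comparable across the
samples the user chooses to pool, and the unit string is a caption label
only.

### The uniform "strictly above" rule

Every dichotomization uses strict inequality: a sample counts as "high"
only when its value exceeds the threshold; values exactly on the threshold
fall to the low side. The same rule drives `percent_above`, the
Median^category > Median^All category flag, and both axes of the quadrant
gate. One consequence used as a self-check: with an even number of
pairwise-distinct values, the percent strictly above the global median is
exactly 50.

### Thresholds

`compute_thresholds` supports the mean, median and 75% quantile (q3) of a
gene over the complete table. Quantiles use linear interpolation between
order statistics (the numpy default), and the method is recorded in the
`ThresholdSet` for provenance. Thresholds are deliberately **never**
recomputed on a displayed subset: plots of selected indications keep the
cut-off anchored to the full cohort so percentages stay comparable.

### Quadrant convention

The four quadrants follow the flow-cytometry layout: Q2 is high/high
(upper right), Q1 upper left, Q3 lower left, Q4 lower right. Only the
high/high quadrant has an externally fixed meaning (the co-expressing
population a dual-targeting therapeutic needs); the labels of the other
three follow the clockwise-from-upper-left convention and are documented
here because tools differ. Boundary points go to the low side, consistent
with the strict rule above.

### Correlation

Spearman correlation (default) uses average ranks for ties; Pearson is
available. Two-sided p-values use the t-approximation with n−2 degrees of
freedom for n ≥ 10 and exact permutation enumeration for 3 ≤ n < 10 (all
n! pairings of one vector against the other; the permutation index arrays
are cached per n, the largest being 9! × 9 int8 ≈ 3 MB). Below 3 pairs the
coefficient and p-value are undefined (NaN) and figures render "r=NA".
Correlation is computed per displayed group, not pooled.

### Fold change and the Kruskal-Wallis test

Inputs are log2-scale, so the fold change between two levels is
FC = 2^(median(level) − median(reference)), reported linear-scale. Medians
(not means) keep FC consistent with the package's median-centric
thresholding and robust to outliers; swapping the reference inverts FC
exactly. The Kruskal-Wallis test (tie-corrected, chi-square approximation)
is used for all group comparisons, including the paired pre/post view:
the pairing there is validated and drawn as connector lines, but the
printed p-value is deliberately the unpaired KW test, keeping a single,
uniform test across the figure family rather than switching to a signed-rank
test for the paired case. No multiple-testing correction is applied
anywhere; all p-values are raw and meant for triage, not confirmatory
claims — a documented limitation.

### Clustering and quartile bins

Heatmap orderings use hierarchical clustering with Euclidean distance and
complete linkage (common heatmap defaults; both recorded in the result and
configurable). The input is condensed with `pdist` first, and identical
rows merge at distance zero, so they are always adjacent. Percentage
quartile bins are left-closed: Q1 [0,25), Q2 [25,50), Q3 [50,75),
Q4 [75,100] — 100% belongs to Q4.

## Harmonization

The canonical table is long-format with `patient_id`, `sample_id`,
`feature`, `value`, `unit` and free-form group columns. Records with a
missing value are dropped at harmonization with a logged count, because
every downstream statistic assumes complete values. Duplicate
(sample, feature) rows are an error rather than silently deduplicated —
stricter than some pipelines, but ambiguity here corrupts every percentage
downstream. The combined display column `intr` joins selected group columns
with `_`; values containing `_` are allowed since the column is never
re-parsed. Pathway scores are arithmetic means of log2 values (no
de-logging); gene-set members absent from the table are dropped with a
warning by default (`strict=True` errors), and a fully absent set always
errors.

## The cohort simulator

`simdata` generates the package's reference fixture and doubles as a
general multi-indication pre/post cohort simulator. Defaults:

- **16 solid-tumor indications**, each with 50 patients sampled pre- and
  post-treatment (100 samples per indication, 1600 total), and an exact
  database1/database2 split per indication (e.g. BLCA 52/48, BRCA 100/0,
  NSCLC 0/100). Database labels are a seeded permutation of an exact-count
  label vector, so the splits hold exactly, not just in expectation.
- **35 genes**: the anchors "Tumor target" and "Immune target" plus 33
  genes partitioned into four signatures (8 T-cell activation, 8 T-cell
  exhaustion, 8 T-cell infiltration, 9 NK-cell genes).
- **Values** are independent normal draws per (gene, indication, treatment)
  on the log2 TPM scale. Baseline means are 2.5–3.0 with sd 0.8–1.0,
  typical mid-range bulk log2 TPM dispersion.

The configured means encode the fixture's qualitative ground truth, which
the tests recover through the statistics rather than assert on raw draws:
"Tumor target" is high (6.0–6.5) in CRC, SCLC, PRAD, UTEN, NET and STAD and
low (2.5) elsewhere, so exactly those six indications flag as of interest;
its STAD post-treatment mean (5.0) sits below the pre-treatment mean (6.5);
and STAD database2 samples carry a −1.5 log2 batch offset on "Tumor
target". That last effect needs an explicit `database2_shift` field in the
gene configuration, since database assignment is otherwise independent of
the values; the shift is the simulator's model of a systematic
source-database batch effect.

Determinism: one global seed; each indication draws from a substream keyed
by CRC32 of its abbreviation, so adding or removing an indication never
changes another's draws, and the same seed reproduces the table
byte-for-byte.

What the simulator does **not** emulate: gene–gene correlation is off by
default (an optional shared latent factor per gene set can induce it),
there is no library-size or count-level noise model (values are normal on
the log2 scale, not log-transformed negative binomial counts), no missing
values, and no confounding between treatment arms beyond the configured
mean shifts. Passing tests therefore demonstrate correctness of the
statistics and the plumbing on well-behaved data, not robustness to the
heteroskedasticity, zero-inflation or batch structure of real RNA-seq
cohorts — real inputs should be inspected with the same figures before
trusting the triage.

## Figures

Figures are built in two phases: the stats result is computed first, a
`FigureSpec` collects the group order, threshold lines and every annotation
string (formatted from the stats object's fields), and rendering consumes
the spec. Tests assert on the spec, never on pixels. Formatting is
centralized: percentages to 0 decimals on box/scatter annotations, 1
decimal in heatmap cells; p-values switch to scientific notation below
0.001; undefined correlations render "r=NA". Scatter panels are highlighted
when the selected-quadrant percent is strictly greater than the highlight
value (default 40%), while composite-heatmap cells are marked at-or-above
their threshold (default 20%). Jitter uses a fixed per-figure seed derived
from the figure's kind and title, and SVG output omits timestamps, so
re-rendering a spec is byte-identical.

## Problem sizes in tests and the acceptance script

The shipped suites run on the default cohort (56,000 records, seconds to
simulate and analyze) plus small constructed tables: 200 random tables of
≤ 12 samples for the brute-force quadrant oracle, 100 random instances for
the hand-computed Kruskal-Wallis rank formula, 2,000 null simulations at 3
groups × 20 samples for the KW calibration check, and 1,120
(gene × indication × arm) cells for parameter recovery (observed arm means
within 4·sd/√50 of configured means in ≥ 99% of cells; the two STAD
"Tumor target" cells are expected to miss because of the deliberate
database2 shift). `scripts/acceptance.py` regenerates the cohort at the
caller's seed and reports the matched pre/post pair count recovered per
indication by the strict pairing validator.
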