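# Methods

## The QC model

A run is a probe × sample matrix of read counts X with N samples, a set of
positive-control probes (spike-ins at known input) and M negative-control
probes (non-human sequences).  The library size of sample *i* is the column
sum over **all** probes, controls included; both control filters are
fractions of that total, so removing controls before QC would bias exactly
the samples the method is meant to catch.  QC always runs on the full
matrix; control removal is offered only for the visualisation exports.

Two filters produce per-sample flags on the scale PASS < ALERT < FAIL;
the overall flag is the maximum of the two.

**Positive controls.**  `pos_pct` = 100 × (reads on spike-ins) / library.
Good-quality samples keep this in the 0–5% range; a sample whose RNA failed
to hybridise pushes reads into the spike-ins.  Flags: FAIL if
`pos_pct > pos_fail_pct` (default 40), ALERT if `pos_pct > pos_alert_pct`
(default 10).

**Negative controls.**  With cpm(X_{i,j}) = X_{i,j}/library_i × 10⁶,

    CPM_i = mean over the M negative probes of cpm(X_{i,j})
    Δ_i   = CPM_i − mean over the N samples of CPM

Δ sums to zero by construction (asserted to 1e-6 relative in the tests).
A sample with |Δ_i| > k·SD(Δ) (k = `sd_multiplier`, default 2) carries
sample-specific background and is flagged ALERT.  SD uses the N−1
denominator; with N < 3 a standard deviation of deviances is meaningless,
so the band is skipped with a warning and `deviance_filter_applied` is
recorded as false.  The band is deliberately scale-free, which means it is
blind to a run in which *every* sample is contaminated — all deviances then
sit inside ±k·SD.  The second rule covers that case: FAIL whenever the
negative-control read percentage exceeds `neg_fail_pct` (default 10) of the
library.

Decisions that the published description leaves open, resolved here:

- **Outlier severity.**  A deviance outlier is ALERT, not FAIL.  The
  flag-combination rule requires both filters to be able to emit ALERT, and
  explicit "fails" language is reserved for the fraction rules; a band
  outlier in an otherwise low-background sample is suspicious, not fatal.
- **Band sidedness.**  Two-sided by default (|Δ| vs k·SD).  Only *elevated*
  background indicates contamination, so a one-sided mode (Δ > k·SD) is
  available via `--one-sided-band` / `one_sided_band=True`.
- **Boundary semantics.**  Strict inequality everywhere ("exceeds"):
  a sample at exactly 40.0% is ALERT.  This also makes the degenerate
  SD = 0 band safe — no sample can be strictly outside a zero-width band
  when all Δ = 0.

## Input formats

The primary format is a delimited table (CSV/TSV, or .xlsx via openpyxl):
probe ids in the first column, sample ids in the header.  An
"instrument-export" dialect additionally skips any metadata rows above the
counts block: rows are discarded until the first row whose first cell
equals a sentinel (default `"Sample Name"`), which becomes the header.
This dialect is a documented stand-in for vendor exports whose exact layout
is proprietary; it is not a claim about any vendor's format.  Counts must
be non-negative integers (values within 1e-9 of an integer are accepted and
rounded — spreadsheet round-trips produce these); NaN, negative,
non-numeric and duplicate-id inputs are rejected at parse time with the
offending probe/sample named, so no NaN handling exists downstream.
Control probes are detected by case-insensitive id prefix (defaults `POS`
and `ANT`, the common panel convention) or by explicit id lists, which take
precedence.

## Normalization

- `cpm` (default), `log2cpm` = log2(cpm + 1).
- `vst` — "vst (NB closed form)": assuming NB counts with variance
  μ + αμ², the stabilizer is g(x) = (2/√α)·asinh(√(αx)) (g = 2√x at α = 0),
  strictly increasing with g(0) = 0.  The common dispersion α is estimated
  by a per-gene method of moments on counts rescaled to the median library
  size — α_g = max(0, (s² − m)/m²) for genes with m > 0 and s² > 0 — and
  the median over genes is used.  The transform is applied to the same
  depth-rescaled counts, so sequencing depth is normalised out and
  per-sample rank order is preserved.  The name is deliberately qualified:
  numerical agreement with any other package's vst is not a goal.
- For visualisation, control probes are removed *before* normalization by
  default (in a failed run the spike-ins would dominate the leading
  principal components); the QC filters always see the full matrix.

## Downstream exports

PCA treats samples as observations over the `top_k_genes` (default 500)
most variable genes, centered per gene but not scaled (unit-scaling a
targeted panel would equalise informative and flat genes).  Scores come
from a full SVD with a deterministic sign convention: the
largest-magnitude loading of each component is made positive.  Heatmap
exports z-score each gene row (sample SD, N−1; constant rows are zeroed and
reported), then cluster rows and columns with scipy hierarchical clustering
(euclidean or correlation distance; average, complete or ward linkage —
defaults euclidean/average, common practice for expression matrices).  Leaf
orders, linkage merge lists and z-values are the tested surface; PNG
rendering is an optional CLI artifact.  Flagged samples can be excluded
(`fail` or `fail+alert`); annotation labels join by sample id, with
unmatched samples labelled `"unannotated"` and reported rather than
dropped.

## Synthetic runs

The generator emulates the study conditions: ~2 M reads per sample with
lognormal jitter (σ = 0.25 on the log scale), 200 panel genes with a shared
lognormal expression profile and negative-binomial sampling at dispersion
α = 0.3, 4 + 4 control probes.  Control reads are allocated as *exact*
budgets — round(fraction × library), split multinomially within each
control set — while gene counts are stochastic.  This separates flag ground
truth (exact, computable from the configured fractions) from expression
realism (NB-dispersed, for the VST and PCA tests).  Scenario presets:
`clean_run` (spike-in fractions 1–4%, the good-quality range),
`single_pos_failure` (one sample at 50%), `single_neg_contamination` (one
sample at 15% background), `alert_only` (one sample at 15% spike-ins) and
`complete_run_failure` (all samples at 18–22% background).

Two generator choices matter for determinism of the truth flags.  First,
baseline negative fractions vary over a narrow linspace (0.4–0.6%) instead
of being identical: with identical fractions the deviances would be pure
integer-rounding noise and the scale-free band would flag an essentially
random sample.  For a linspace of n ≥ 8 points max|Δ|/SD ≈ 1.53 < 2, so no
baseline sample can breach the band; the same argument makes the
`complete_run_failure` property (all samples fail the fraction rule, none
the band) hold deterministically.  Second, every preset fraction sits at
least 2 percentage points away from a decision threshold, so rounding
(≤ 1 read) cannot flip a flag.  What the generator does **not** emulate:
probe hybridisation chemistry, FFPE degradation profiles, batch structure,
real panel gene content, or correlated contamination across probes —
passing tests demonstrate the decision logic and numerics, not performance
on any particular real panel.

## Problem sizes and tolerances

The test suite and the acceptance script run on synthetic runs of 8–16
samples × 208 probes, 1,000 random deviance vectors, 60 random 10 × 6
matrices checked against a pure-Python recomputation from the definitions,
and NB simulations of 500 genes × 40 samples (stabilization, means 10–10⁴)
and 200 genes × 50 samples (dispersion recovery, true α = 0.5) — sizes at
which the Monte-Carlo checks are stable across seeds while the whole suite
runs in seconds.  Deviance conservation is asserted at 1e-6 relative, CPM
column sums at 1e-6 relative, exact equality for flags and orderings.

## Known limitations

- The deviance band assumes the run is mostly clean; with many strong
  outliers the SD inflates and sensitivity drops (the fraction rule is the
  backstop only above 10%).
- The common-dispersion VST underfits genes whose dispersion deviates
  strongly from the panel median.
- The instrument-export dialect covers the "metadata rows above a counts
  block" family of layouts, not workbooks with multiple sheets of run
  metadata.
- With N < 3 only the fraction rules apply; two-sample runs get no
  background-outlier detection at all.
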