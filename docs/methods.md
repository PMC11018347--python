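# Methods

This note documents the statistical procedures glycoprox implements, the
assumptions behind the synthetic-data generators, and the design choices
made where the underlying experimental convention was genuinely open.

## Differential-enrichment calling

The unit of analysis is the MaxQuant protein group: a set of accessions
indistinguishable by their identified peptides, reported as one row and
never exploded into per-accession rows (which would double-count in overlap
statistics). Rows flagged by MaxQuant as contaminant, reverse-database, or
only-identified-by-site are removed before any statistics.

Intensities are LFQ values with 0 meaning "not quantified". Every intensity
is transformed as log2(I + 1); the pseudocount maps missing values to 0 on
the log scale instead of −∞. The fold change is the **difference of
per-construct means of the transformed values**, not the log of the ratio of
raw means — the convention of log-transform-then-average workflows
(Perseus-style), and the reading under which the pseudocount is actually
operative. Zero-intensity replicates are **included** as transformed value
0 rather than dropped: detection consistency is handled by a separate
replicate-presence filter, and dropping zeros would bias the fold change
upward for sporadically detected proteins.

The test is the two-sided unpaired Student's (equal-variance) two-sample
t-test on the transformed replicate values, n = 3 per construct by default.
One shared kernel (`glycoprox.stats.two_sample_t`) serves both proteomics
and behavior comparisons. Degenerate variance is resolved by limit
behaviour instead of NaN: both groups constant and equal → t = 0, p = 1;
both constant and unequal → t = ±∞, p = 0, with a `degenerate` flag.
(The all-detected vs all-missing case lands here deliberately: identical
replicate triples are infinitely incompatible under a pooled-variance
model, and the detection filter, not the p-value, is the guard against
over-calling such proteins.)

Calling policies:

* **hek**: peptide count ≥ 2 and log2 FC > 1. No detection filter and no
  p-value branch (cell-culture screens of this design used the fold-change
  rule alone).
* **brain**: peptide count ≥ 2, detection in ≥ 2 CD replicates, and
  (log2 FC > 1 **or** p < 0.05). The p-value branch requires positive
  log2 FC by default (`require_positive_fc_for_pvalue_call`): enrichment
  calling must not fire on significant depletion. The detection filter
  applies to CD replicates only; DM detection is unconstrained — the
  control may legitimately be all-missing.

No multiple-testing correction is applied by default (raw p < 0.05 is the
operative rule); a Benjamini–Hochberg option (`use_bh`) exists for users who
want FDR control. Thresholds, alpha, and the peptide/detection minima are
all policy fields.

## Transcriptome normalizing factors

factor(gene, region) = mean expression over neuron-typed cells in the
region's clusters ÷ mean over all neuron-typed cells. The average is
**cell-weighted** (pooling all neurons) rather than a mean of cluster means;
a `weighting="cluster"` switch provides the alternative. Only neurons enter
either average; when a matrix carries no cell typing, all cells are treated
as neurons with a logged warning.

The factor is a ratio of per-gene means, so any per-cell scaling that is
uniform across genes (library-size normalization) cancels exactly; per-gene
scalings do **not** cancel, so the matrix should carry library-size-
normalized (or raw, if sequencing depth is balanced) counts, not per-gene
standardized values. Genes with zero whole-brain mean get an undefined
factor (NaN) and are reported with a reason rather than dropped silently.

The normalized O-GlcNAc level is raw log2 FC ÷ factor. Dividing a log-scale
quantity by a linear abundance ratio is dimensionally awkward but is
implemented exactly as stated by the source convention; no re-derivation is
attempted, and negative log2 FC values are normalized like any others.
Protein groups mapping to multiple genes use the first gene symbol, with the
ambiguity flagged in the output's `reason` column; joins are by case-folded
symbol.

## Cross-region summaries

Overlaps are exact set algebra on normalized identifier sets (case-folded,
whitespace-stripped); the inclusion–exclusion identity is asserted on every
result. Percentages are reported against the first list's size, matching
the "X% of our candidates were previously reported" convention. No fuzzy
accession mapping is attempted — cross-namespace identifier tables are the
user's responsibility, and an all-pairs-zero overlap triggers a namespace
warning. Category fractions use the called list of the region as
denominator (not the whole proteome). The level–mRNA correlation is
Spearman by default (monotone association without a linearity assumption on
heterogeneous scales), Pearson via a flag; midranks handle ties; at least
three complete pairs are required.

## Behavior

PI^odor = [n(Air) − n(odor)] / [n(Air) + n(odor)] × 100% and
PI = [n(CS−) − n(CS+)] / [n(CS−) + n(CS+)] × 100%. Each learning score is
the mean of two reciprocal trials (MCH-shocked and OCT-shocked, ~100 flies
each, so ~200 flies per reported point), which cancels innate odor bias.
PI values are carried as exact integer rationals (`fractions.Fraction`) and
rendered at four decimals, so reciprocal means are bit-reproducible in
output files. Flies choosing neither arm are not modeled; input counts are
final. Group comparisons use the shared t-test kernel; acuity gating
(excluding genotypes with altered odor avoidance) is left to the user, who
gets the comparison p-value.

## Imaging

Z-stacks are reduced by per-pixel maximum projection, then the relative
fluorescence is mean(ROI pixels) ÷ mean(reference pixels) on the projected
image (projection-then-mean, not slice-wise). Masks are supplied, not
computed — ROI drawing is a manual step in this workflow, and segmentation
is out of scope. No background subtraction by default; a constant-offset
option exists.

## Synthetic-data generators

The generators produce inputs with the statistical structure the analysis
assumes, paired with ground truth; they are first-class, tested code.

**LFQ tables.** Log2 intensities are Gaussian per protein and replicate
(log-normal raw intensities): baseline_i ~ N(25, 2²) on the log2 scale
(raw LFQ ≈ 3×10⁷, the scale of typical MaxQuant output), replicate noise
N(0, 0.5²), and a planted mean shift of `effect_log2fc` (default 2) added
to CD samples of a random `substrate_fraction` (default 10%) of proteins.
No per-protein LFQ variance is published for this design, so the default
replicate sd of 0.5 is an assumption, not a calibration. Missingness is
Bernoulli zeroing, MCAR by default at rate 0.02 — low, reflecting the high
detection consistency of proteins that survive a streptavidin-enrichment
workflow whose downstream filter expects detection in ≥ 2 of 3 replicates;
at log2 baselines near 25 a single missing CD replicate flips the sign of a
protein's fold change, so high MCAR rates would make detection noise, not
abundance, the dominant caller. An intensity-dependent MNAR mode
(sigmoid in log2 intensity, same overall rate) is available. Contaminant
rows (default 5%) carry exactly one of the three MaxQuant filter flags.
Peptide counts default to 1 + Poisson(8), giving the mostly-multi-peptide
identifications typical of enriched pulldowns. What this generator does
*not* emulate: correlated noise between replicates, shared peptides between
groups, intensity-dependent variance, or ratio compression — so passing
recovery tests demonstrates correctness of the calling rules under the
stated noise model, not performance on real spectra.

**Single-cell matrices.** Counts are gamma-Poisson (negative-binomial) with
per-gene per-cluster means and a global dispersion φ (variance m + φm²);
dispersion exactly 0 is a degenerate deterministic mode (every cell equals
its cluster mean) used for exact identities in tests. Cluster labels map
to regions one-to-one. The generator does not emulate dropout inflation
beyond NB, batch structure, or cell-type mixtures within clusters.

**Behavior counts.** n(CS−) ~ Binomial(n_flies, p_correct),
n(CS+) = n_flies − n(CS−), odors alternating MCH/OCT so consecutive trials
form reciprocal pairs; expected PI is (2·p_correct − 1)×100%.

All generators are deterministic given the config seed (sub-streams split
with `numpy.random.SeedSequence`), and determinism is asserted byte-wise on
written files.

## Numerical choices

* Result files are written at full float64 precision (`%.17g`), so
  read∘write is the identity and rewriting is byte-stable; intensity
  strings are parsed with numpy's correctly rounded converter.
* Flag cells other than `"+"`/empty raise a format error under the default
  strict mode, or warn and parse as unset under lenient mode.
* Undefined quantities (p-values with < 2 replicates, factors with zero
  whole-brain mean, missing heatmap cells) are NaN with a recorded reason,
  never silently 0.

## Problem sizes used in checks

The shipped verification runs use 2 000 proteins × 3+3 replicates for
calling recovery (sensitivity ≥ 0.9 at planted effect 2; null false-positive
rate 5% ± 2%), 10 000 cells × 25 genes for factor recovery (within 5% of the
configured ratio 2.0), 100 random fixtures for t-test exactness (1e-10),
and 1 000 simulated trials for the learning PI (→ 50 at p_correct = 0.75).
These sizes give Monte-Carlo error comfortably inside each stated tolerance
while keeping the full run under a few seconds.

## Known limitations

* Region-specific candidate counts from real brain dissections cannot be
  reproduced without the deposited raw MS data; the pipeline's correctness
  is therefore demonstrated on simulation plus exact identities.
* The published HEK293T overlap counts (336/178/48/158) require the study's
  supplementary candidate lists, which are not redistributed; the check is
  wired up in `tests/test_acceptance.py` and activates when the lists are
  placed under `data/external/`.
* Whether the atlas expression values should be raw counts, library-size
  normalized, or log-transformed before averaging is not fixed by the
  source convention; the default expects library-size-normalized counts
  without log transform, and this is an assumption.
* The equal-variance t-test with n = 3 is exact only under Gaussian log2
  noise; with missingness the null distribution is a mixture and the
  realized false-positive rate can drift slightly from nominal (the
  simulation checks bound this drift under the default rates).
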