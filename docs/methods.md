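# Methods

## Variant-level classification of XCI status

The unit of observation is a heterozygous X-linked variant site with
replicate-level allelic read counts per cell type.  Sites pass four
filters, applied in order and tallied: genic assignment, biallelicity
(exactly one reference and one alternative allele), call quality ≥ 100,
indel length ≤ 50 bp, and expression of ≥ 5 reads in every sample.
Replicate counts are then summed per cell type; a (variant, cell type)
pair is testable only with ≥ 20 pooled reads.

The pooled allelic ratio is folded into the Xi-expression estimate
`p̂_Xi = min(ratio, 1 − ratio)`.  The min form is branch-free and
identical to the two-branch definition (the tie `No.Ref = No.Alt` gives
0.5 either way); a property test exercises the equivalence on random
counts.  The test statistic is the pooled minor-allele count against an
upper-tail exact binomial: testing at the group level on pooled counts is
the only definition consistent with group-level pooling, and is the one
implemented.

Three test families are evaluated, each Benjamini–Hochberg-corrected per
cell type across its own candidate variants (the family structure mirrors
the sequential "identify candidates, then test" procedure; the families
are: escape candidates = all fully testable variants; reactivation
candidates = those monoallelic in iPSCs, ratio < 0.025 or > 0.975;
late-silencing candidates = those with `p̂_Xi` < 0.025 in both NPCs and
neurons).  Significance is adjusted *P* < 0.01.  A variant can satisfy
several predicates at boundary ratios; precedence is
escape → reactivated → late-silenced, because escape's "all cell types"
condition logically supersedes the others.  Everything else testable is
inactive; anything missing a testable cell type is untestable.

**Replicate-consistency curation.**  The known failure mode of pooled
tests is a biallelic call whose minor-allele reads come from a single
replicate.  A call is flagged when, in a cell type driving it, ≥ 90% of
pooled minor-allele reads originate from one replicate, or all replicates
but one are strictly monoallelic.  Flagged calls are retained but marked;
an option demotes them to inactive.  Driving cell types: the significant
NPC/neuron tests for reactivated, iPSC for late-silenced, all three for
escape.

## Gene-level collapse and pooling

A gene's category is the majority category among its biallelic variants;
ties are broken by counting SNPs only (more reliable than indels), then by
the best variant's total coverage.  The gene-level biallelic-expression
estimate pools the chosen variants' (minor-count, total) observations by
fixed-effect inverse-variance weighting of logit proportions.  Each
observation is taken from the cell type driving the category (the larger
p̂ of NPC/neuron for reactivated, iPSC for late-silenced, the maximum-p̂
cell type for escape): the alternative of treating each cell type as a
separate "study" would overweight multi-cell-type variants.

Continuity correction: the logit is undefined at x = 0 or x = n, so
x′ = x + 0.5, n′ = n + 1 is applied to every observation
(Haldane–Anscombe), with variance 1/x′ + 1/(n′ − x′); a `zero-only`
option restricts the correction to boundary counts.  Fixed-effect (not
random-effects) pooling is the default since variants of one gene measure
one underlying proportion; the 99% interval is the normal approximation on
the logit scale, back-transformed.

## Gene-set statistics

All resampling tests fit a normal to a without-replacement resampled
background (default 1000 iterations) and report its tail CDF at the
observed value, plus the (r+1)/(n+1) empirical quantile alongside — the
normal fit can misbehave in far tails, and both are cheap.  Overlap
enrichment reports observed / background-mean; its background mean has
the closed-form hypergeometric expectation |q|·|r|/|U|, used as an oracle
in tests.  The TSS clustering statistic is the mean pairwise distance
between transcription start sites, computed in O(k log k) via the
sorted-order identity, with a lower-tail p.  The universe is always an
explicit input; a helper derives the "expressed" universe (> 10
normalized reads in every sample) from a count matrix.

Chromatin-state comparison takes gene × state percentage profiles as
input (rows validated to sum to 100 ± 1), reports per-state
log(mean-query / mean-inactive) with a one-sided rank-sum p and BH across
the 15 states.  A zero inactive-set mean yields a +∞ sentinel with a
warning.

The sex-bias test bins genes by the number of tissues with female-biased
expression (default edges 0, 1–5, 6–15, > 15; the published figure does
not enumerate its bins, so the edges are configurable) and applies
Fisher's exact test to the 2 × bins table: exact for 2×2 (optionally via
`collapse_at`), otherwise a seeded Monte-Carlo conditional test that
samples tables with fixed margins and counts those no more probable than
the observed one — no installed Python library provides the exact
network algorithm for r×c tables, and the Monte-Carlo version is the
standard substitute.

## Single-cell biallelic scores

Per covered site, r = max(ref, alt)/(ref + alt) UMIs and s = −ln(r):
0 for monoallelic sites, ln 2 ≈ 0.69 for balanced biallelic expression.
The sign convention follows the printed anchor values (monoallelic = 0,
balanced = 0.69).  When a gene has several traceable variants in a cell,
UMIs are summed per gene before computing r (maximum-information choice;
per-site scoring is an option).  The per-cell biallelic sum runs over
non-PAR X-linked genes — pseudoautosomal genes escape XCI as a block and
would inflate it.  Any covered site is scored (min 1 UMI) since a
stricter cut silently biases scores toward 0.  Category scores sum s over
reactivated genes (reactivation score) and full escapees (escapee score).
Pseudotime is an input column; binned summaries use equal-width bins
(default 50) with empty bins reported missing.

The pseudo-bulk variant-detection filter retains intragenic heterozygous
variants with per-allele base quality ≥ 20 and pooled reads above a
library-size-scaled threshold: 50 reads per 5×10⁸ total reads in
single-cell mode, 2 per 5×10⁸ in single-nucleus mode.

**Folded-binomial bias.**  At finite depth the expected score of a
balanced site sits below ln 2: with n UMIs at allele fraction ½,
E[max(X, n−X)/n] ≈ ½ + √(2/(πn))·½, so E[s] ≈ ln 2 − 2√(2/(πn)) — about
15% low at 50 UMIs and within 5% only beyond ~500 UMIs.  The recovery
test therefore checks convergence at 1000 UMIs/site; score sums at
typical UMI depths are systematically conservative, which matters for
absolute comparisons but not for monotone trends along pseudotime.

## Transcriptional deviation

Per cluster, control means are arithmetic means over control cells
(clusters without controls are excluded with a warning).  For each DE
gene the cell's fold change over the control mean is
(expr + ε)/(ctrl + ε) for upregulated genes and its reciprocal for
downregulated ones; the deviation is the mean over the cluster's DE
genes, so a control-like cell scores 1.  ε (default 10⁻⁹) guards zero
control means, which the reciprocal otherwise breaks on.  Fold changes
are computed on the linear expression scale (expm1 of log-normalized
data upstream); the scale is configurable since either convention is
defensible.  The bundled rank-sum DE helper (two-sided Wilcoxon, BH,
log2 fold of group means, default |log2FC| > 2 for deviation signatures,
0.25 for broader lists) exists to make the module self-testable on
synthetic data; real analyses may supply their own DE table.

## Synthetic data

The generator emulates the *processed* form of the study inputs, not
reads: no alignment, mapping bias or allele-specific mapping artefacts
are modeled, so passing tests demonstrate the statistics are implemented
correctly, not that upstream biases are handled.

* **Bulk counts** — per gene, 1–3 variants; haplotype phase (reference on
  active X) drawn once per gene, mirroring physical haplotypes, and
  shared with the single-cell simulator.  Per variant and replicate,
  total reads are negative-binomial (default mean 120, dispersion 10 —
  the empirical depth distribution is not published, so this is a
  modeling choice producing ~480× group depth at 4 replicates and
  occasional low-coverage dropouts that exercise the ≥5/≥20-read
  filters); reference reads are Binomial(total, 1 − p_Xi) on the
  active-X haplotype.
* **Truth profiles** — category fractions default to 20% reactivated,
  20% escape, 10% late-silenced, 50% inactive; silenced states draw
  p_Xi ~ U(0, 0.005), biallelic states U(0.15, 0.45) (escape
  U(0.2, 0.45)), consistent with the classification bands.  Reactivated
  genes reactivate in both later cell types (half), neurons only or NPCs
  only (a quarter each).
* **Annotation** — TSSs uniform on a 150 Mb chromosome; a configurable
  fraction of a designated set is packed into a 10 kb window for the
  clustering test; optional genes in a 2.7 Mb terminal pseudoautosomal
  interval carry the PAR flag.
* **Single-cell UMIs** — pseudotime uniform on [0, 1]; each gene's
  p_Xi(t) ramps piecewise-linearly from its iPSC value (t ≤ 0.2) to its
  neuron value (t ≥ 0.8), the simplest monotone reactivation model.
  Site totals are Poisson(UMI depth × detection rate), alleles binomial
  at the phase-adjusted fraction.
* **Expression for deviation** — log-normal expression with planted
  directional folds; per-condition exponents on the fold give graded
  het/hom effects; σ = 0 yields noiseless matrices where control
  deviation is exactly 1.

All randomness flows through one seeded generator with fixed sub-streams
per output (profile, phase, bulk, annotation, sc, expression), so the
same (config, seed) reproduces any output byte-identically and
regenerating one output never perturbs another.

## Problem sizes and numerical choices

The default test cohort is 200 genes × 3 cell types × 4 replicates
(seed 7), where the classifier recovers every category with sensitivity
and specificity 1.0; calibration suites use 1000 null variants at
p_Xi = 0.025 (≤ 2% reactivated calls observed), 500 null repetitions of
the distance test (empirical p uniform by KS), and 100 seeds of the
graded deviation recovery.  Exact binomial tails are validated against
log-gamma pmf summation to 10⁻¹² for all n ≤ 500.  p-values of 0 can
occur only through the normal-CDF approximation, never the exact tests;
BH is statsmodels' `fdr_bh` throughout.

## Known limitations

Variants overlapping multiple genes are assigned to each with a warning
rather than resolved by annotation; cross-cell-line consensus is a plain
set intersection; XIST-positive/negative partitioning of cells is a
detection-threshold decision left to the caller (default: any expression
counts as positive); and the deviation statistic inherits Jensen
inflation ≈ exp(σ²/2) in control cells under multiplicative noise, which
the graded-recovery tests tolerate by comparing conditions rather than
absolute values.
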