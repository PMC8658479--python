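# Methods

## The integrative statistic

The pipeline targets two-group bulk RNA-seq contrasts with very few
replicates (3–6 per group), where neither a parametric t reference nor
a per-gene permutation null is trustworthy: the t distribution's
normality assumption is shaky at n = 3–6, and a per-gene permutation
null has resolution no finer than 1/C(n<sub>a</sub>+n<sub>b</sub>, n<sub>a</sub>)
(1/20 for 3v3), which can never support p < 0.05.

Two effect measures are computed per gene on the normalized log2
surface: the pooled-variance Student t (sensitive to mean shifts,
variance-standardized) and the log2-median-ratio (lmr; a robust,
unstandardized effect size — the difference of group medians on the
log2 scale, i.e. the log2 ratio of linear-scale medians). Their joint
use is the point: t can be large for a tiny but consistent shift, lmr
requires the shift to be biologically sizeable, and the final call
demands evidence from both.

### The empirical null

Group labels are randomly re-assigned across the pooled samples with
group sizes preserved (permutation without replacement; bootstrap
resampling would break the exchangeability rationale). Both statistics
are recomputed for every gene in every resample, and the values are
**pooled across genes and resamples** into a single null vector per
statistic. Pooling is what buys resolution: N = n_genes ×
n_resamples null values support p-values down to 1/(N+1). The cost is
an exchangeability-across-genes assumption — for t it is mild (t is
variance-standardized), for lmr it means high-variance genes dominate
the null tails, making lmr p-values conservative for quiet genes and
liberal for noisy ones (marginally across genes they remain
calibrated; we measure component calibration in the tests).

When the number of distinct label assignments does not exceed the
requested resample count, exhaustive enumeration replaces random
sampling: all C(n<sub>a</sub>+n<sub>b</sub>, n<sub>a</sub>) splits are used except the observed
assignment and, for equal group sizes, its mirror image (which
reproduces the observed statistics with flipped sign and would leak
signal into the null). A 3v3 design thus has 18 effective resamples, a
5v5 design 250, a 6v6 design 922 — all below the default 1000, so the
default configuration is fully deterministic for these designs.

Empirical p-values are two-tailed with add-one smoothing,
p = (#{|null| ≥ |obs|} + 1)/(N + 1), so p is never 0 and its minimum
is exactly 1/(N+1).

### Combination and selection

The two component p-values are combined with Stouffer's method on
*signed* normal quantiles, z<sub>i</sub> = sign<sub>i</sub>·Φ⁻¹(1 − p<sub>i</sub>/2),
Z = (z<sub>t</sub> + z<sub>lmr</sub>)/√2, overall p = 2(1 − Φ(|Z|)). Signing is
essential: a gene whose mean shifts up while its median shifts down
carries discordant evidence that should cancel, not reinforce.

A gene is called differentially expressed when

1. its overall p (by default BH-adjusted across genes; the raw overall
   p can be selected instead) is below α = 0.05, and
2. its |lmr| exceeds the fold-change cutoff (|Q<sub>2.5</sub>| + |Q<sub>97.5</sub>|)/2
   computed from the pooled lmr null with linear-interpolation
   percentiles. The mean of *magnitudes* is used: for a near-symmetric
   null the literal signed mean is ≈ 0 and would exclude nothing.

Degenerate genes are resolved deterministically: zero pooled variance
with equal means gives t = 0; zero pooled variance with unequal means
gives a capped sentinel (largest finite |t| in the same computation
plus one, signed) so that ranking is preserved without infinities
entering the pooled null.

### Known limitation: correlated components

t and lmr measure the same location shift, so their signed z's
correlate strongly under the null (ρ ≈ 0.8 at 5v5 on NB data with
dispersion 0.1). Stouffer's √2 scaling assumes independence, so
Var(Z) ≈ 1 + ρ ≈ 1.8 instead of 1, and the overall p is
anticonservative: the measured null fraction with overall p < 0.05 is
≈ 0.15, close to the analytic 2Φ̄(1.96/√1.8) ≈ 0.14, and this
inflation propagates into BH-adjusted calls (observed false-discovery
proportion ≈ 0.17 at a nominal 0.05 level in the recovery setting
below). Both numbers are recomputed by `scripts/acceptance.py` at every
run. The second selection criterion (the lmr cutoff) removes a large
share of these marginal false positives — in every null run we have
measured, adding the cutoff strictly shrinks the called set — but it
does not restore nominal error control. Users who need calibrated
error rates should treat the overall p as a ranking score, or replace
the √2 with a correlation-adjusted scale (a deliberate extension, not
implemented here to keep the method as defined).

## Normalization

Stages are fixed in order and recorded in the matrix provenance:
cpm → (optional low-expression filter) → log2(x + 1) → quantile
normalization. Running stages out of order is an error.

* **cpm**: counts / library size × 10⁶; plain scaling, no TMM/RLE
  factors — quantile normalization supersedes per-sample scale factors
  anyway.
* **pseudocount 1** keeps zeros at log2(0 + 1) = 0 and is configurable.
* **Quantile normalization** maps each sample onto the mean
  order-statistic reference; ties within a sample receive the mean
  reference value over the tied rank span (the standard convention).
  With ties present, a column's post-normalization multiset differs
  from a tie-free column's — exact sorted-column equality holds only
  for tie-free data.
* **Low-expression filter** (default on, fully configurable): keep
  genes with cpm ≥ 1 in at least half the samples (rounded up). The
  filter runs on linear cpm, before log2.

## The synthetic-data generator

`simulate_experiment` draws gene-by-sample counts
NB(mean = w<sub>g</sub>/Σw · L<sub>s</sub>, var = mean + φ·mean²) with baseline log2
intensities uniform on (3, 10), dispersion φ = 0.1 (typical bulk
RNA-seq), library sizes uniform on (0.5, 2) million reads, and a
chosen fraction of genes carrying a ± log2 effect on the second group
label in lexicographic order (half positive, half negative; ceiling
positive for odd counts). One seeded generator stream in a fixed draw
order makes output bit-identical across runs.

It emulates: small-n two-group designs, NB overdispersion, library-size
variation, planted effect sizes. It does **not** emulate: batch
effects, covariates, paired designs, gene–gene correlation, count
outliers, or single-cell dropout. Passing calibration and recovery
checks on this generator therefore demonstrates correctness of the
machinery under idealized exchangeable noise, not performance on real
tissue data.

Default measurement sizes (chosen to make the full suite and the
acceptance script a desk-scale run): 2000 genes, 5 or 6 replicates per
group, 1000 requested resamples (auto-exhaustive for these designs),
5 seeds per summary statistic.

## Enrichment

* **ORA**: exact hypergeometric upper tail P(X ≥ k) per set, computed
  against a universe that defaults to the genes surviving the
  expression filter. The reporting filter is p < 0.05 **and** hit
  count strictly greater than 3 — a set hit by exactly 3 query genes
  never passes, however extreme its p. BH adjustment is reported
  alongside. An EASE-style conservative variant (tail computed on
  k − 1) is available behind a flag, off by default.
* **GSEA**: weighted-KS running sum on a ranked list; hits add
  |score|^w (w = 1) normalized over the set, misses subtract
  1/(N − N<sub>H</sub>); ES is the maximum signed deviation; positive wins
  exact magnitude ties. The null permutes gene labels — ES of
  uniformly drawn same-size sets (the appropriate null for preranked
  input; a phenotype-permutation null would require the sample-level
  matrix). perm_p is two-sided on |ES| with add-one smoothing; NES
  divides ES by the mean |null ES| of matching sign; sets are
  restricted to [3, 800] members after intersection with the ranked
  universe. Default 10,000 permutations (2000 in the bundled demo to
  keep it fast).
* **Ranking for GSEA** from a DEG result: sign(lmr)·(−log10 overall p),
  ties broken by lmr then symbol — the method itself does not
  prescribe a ranking metric; this one uses both the direction and the
  strength of the integrative evidence.

## Design choices that were genuinely open

* Quantile normalization applied to log2-cpm (not linear cpm): the
  stage order follows the transform-then-normalize reading.
* Pooled (cross-gene) nulls rather than per-gene nulls: rationale
  above; the per-gene alternative cannot reach the stated α with 3–6
  replicates.
* BH adjustment of the overall p is the default call criterion, with
  `adjust="none"` available; both values appear in every output table.
* Exact, case-sensitive symbol matching everywhere, with an explicit
  case-insensitive escape hatch in list subsetting.
* Venn comparison limited to 2–3 lists (tabular region counts);
  larger comparisons belong in a pairwise matrix.

## Numerical notes

* Percentiles use linear interpolation between order statistics.
* Empirical p-value counting uses a sorted-|null| binary search; ties
  between |observed| and |null| count toward the tail.
* Stouffer's overall p is floored at the smallest positive double to
  keep downstream log10 transforms finite.
* All tables print 8 significant digits; reruns of the same config are
  byte-identical.
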