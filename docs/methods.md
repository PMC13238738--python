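# Methods

## The model

`chromcall` quantifies chromatin profiling signal (ChIP-seq, CUT&RUN,
CUT&Tag, ATAC-seq) in predefined fixed-width genomic windows — by default
promoter windows of width W = 2000 bp spanning TSS ± 1 kb — rather than
calling data-dependent peaks. Working on a fixed region set makes
region-matched comparisons across marks, samples and conditions direct.

**Fragments and counting.** Paired-end mates are combined into one
fragment spanning both mapped coordinates; single-end reads are their own
fragments. Each fragment is reduced to its central position (midpoint,
floor convention for even lengths), so quantification is insensitive to
fragment-length differences between libraries. The observed statistic for
region *i* is the number of fragment midpoints inside it, y_i, under
half-open coordinates. Unmapped, secondary, supplementary and
duplicate-flagged records are skipped; in paired mode only proper pairs
contribute, each emitted once on its leftmost mate. Improper pairs are
not salvaged as single-end fragments (their count is logged).

**Global background.** Counts are modelled as Negative Binomial, the
standard overdispersed count model for sequencing data, with variance
mu + mu^2/theta. The genome is partitioned into non-overlapping tiles of
the region width W (trailing partial tiles dropped; any tile touching the
blacklist wholly removed), and two global parameters are fitted per
experiment on all retained tiles, zero-count tiles included:

* lambda_g — the mean count per tile (the genome-wide background rate);
* theta — the dispersion, by method of moments: theta = mu^2/(s^2 - mu)
  with the unbiased sample variance. When s^2 <= mu, or when the
  estimate exceeds 1e6, the model is taken to the Poisson limit
  (theta = infinity). Method of moments is closed-form and stable on
  millions of tiles; replicate-based or per-region dispersion estimation
  is deliberately out of scope.

Target regions are not excluded from the background tiles. On data with
strong, widespread enrichment this inflates the variance estimate and
hence makes the test somewhat conservative; it follows the one-tile-set
design and avoids coupling the background to the region definitions.

**Local modulation.** A matched control corrects region-level background
variation (accessibility, copy number, mappability):

    m_i = max(1, y_i(ctrl) / lambda_g(ctrl)),   lambda_t_i = m_i * lambda_g.

The lower bound of one stops low control coverage from deflating the
expected background (which would manufacture enrichment). Without a
control, m_i = 1 and inference is against the global background alone.
Modulation is computed for blacklisted regions too, but those rows carry
NA statistics.

**Test and scores.** Each region gets a one-sided upper-tail p-value
p_i = P(Y >= y_i), Y ~ NB(mu = lambda_t_i, size = theta), evaluated as
the survival function at y_i - 1 (Poisson tail when theta is infinite).
Degenerate inputs: y = 0 gives p = 1; lambda_t = 0 with y > 0 gives
p = 0 and z = NA. Benjamini–Hochberg adjustment is applied per
experiment across all non-blacklisted regions. Two effect measures are
reported: the enrichment score s_i = log2((y_i + eps)/(lambda_t_i + eps))
with pseudo-count eps = 1 (conventional for log2 count ratios and making
s(0,0) = 0), and the standardised deviation
z_i = (y_i - lambda_t_i)/sqrt(lambda_t_i + lambda_t_i^2/theta). A region
is called present (1) when s_i > 1.5 AND padj_i < 0.25 — both strict
inequalities; blacklisted regions are NA. The defaults are tuned for
broad promoter-associated marks, where the permissive FDR bound trades a
few false calls for sensitivity; both thresholds are configurable.

**States and comparisons.** Calls for an active and a repressive mark
combine to four states per region — N (neither), A (active only), R
(repressive only), B (bivalent, both) — with NA propagating from either
call. Two-sample comparison over an identical region set (enforced, not
coerced) reports delta_score, delta_z and delta_expression with the
second sample as baseline (delta = A − B), plus transition labels
`"<state_B>-><state_A>"` that read chronologically for longitudinal
pairs. No formal two-sample significance test is attached to the deltas.
Gene expression is joined by region name only (the promoter BED carries
gene identifiers); coordinate joins are avoided as a source of
TSS-annotation mismatches.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `width` (W) | 2000 bp | fixed width of every target region |
| `tile_width` | W | background tile width; equal to W so lambda_g is directly commensurable with region counts, no rescaling |
| `epsilon` | 1.0 | pseudo-count in the log2 enrichment score |
| `score_min` | 1.5 | presence threshold on the enrichment score (log2 units, strict) |
| `fdr_max` | 0.25 | presence threshold on the BH-adjusted p-value (strict) |
| `min_mapq` | 0 | optional MAPQ filter; quality filtering normally happens upstream |

## Numerical and degenerate-input policy

* Coordinates are 0-based half-open everywhere; a midpoint at an
  interval's `end` is outside it.
* Trailing partial tiles are dropped, not clipped: a per-tile mean over
  unequal widths would be biased.
* A region set whose entries are not exactly width W aborts loading;
  regions past a chromosome end or on unknown chromosomes are dropped
  with a warning (clipping would break the fixed-width invariant).
* theta estimates above 1e6 are clamped to the Poisson limit; at that
  size the NB and Poisson tails agree to < 1e-4 over the relevant range.
* A zero background rate is an error for a control (it divides the
  modulation) and a warning for a treatment.
* Deep in the upper tail a smaller theta yields a larger tail
  probability (more conservative); just above the mean the ordering can
  invert because overdispersion also concentrates mass at zero. The
  property tests assert the ordering only beyond mu + 3 sd.

## The synthetic-data generator

`SimulationSpec`/`simulate_dataset` write a complete toy dataset: a
genome of two 1 Mb chromosomes by default, 500 non-overlapping width-W
windows drawn from the W-grid with gene-like names, paired-end proper
pairs (MAPQ 60, fragment length Normal(200, 30) bp, no sequence content)
for an experiment and an optional control, a truth table, and an
optional expression table whose enriched promoters are shifted upward by
2·log2(fold). Background midpoints arrive per tile as Poisson with an
expected `background_rate` of 20 per window-width tile — a depth at
which promoter counts are informative but discrete effects still matter,
typical of a moderately sequenced ChIP experiment. Enriched windows
receive extra midpoints so their expectation is fold × background
(experiment only). Coverage-distortion intervals multiply the background
rate of **both** tracks — they emulate copy-number gain, which a matched
input control shares, and are exactly what the modulation factor is
meant to absorb. An optional gamma mixing of the per-tile rate (mean
one, shape `gamma_theta`) produces genuinely NB tile counts so
dispersion recovery is testable; plain mode gives Poisson. All
randomness flows from one recorded seed.

What the generator does **not** emulate: mappability structure, GC bias,
fragment-length dependence on chromatin state, read-level errors,
duplicate structure, or peak shape within a window. Passing tests
therefore validate the statistical machinery under its own model
assumptions — calibration, recall, control rescue — not robustness to
every artefact of real libraries; the blacklist and MAPQ options exist
precisely because real data need them.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use 500 windows over a
2 Mb toy genome (≈1000 background tiles, ≈20k fragments per track),
1e5-tile draws for parameter recovery, and 1000 random triples for the
tail-test oracle. These sizes give sub-percent standard errors on the
recovered parameters and keep Monte-Carlo noise on the null calibration
rate near 0.008 while each check runs in seconds.

## Known limitations

* One global dispersion per experiment: regions with genuinely
  region-specific technical variance are not modelled.
* The discrete test statistic makes per-region p-values super-uniform at
  moderate counts (attainable null rates below the nominal level); BH on
  such p-values is conservative.
* Enrichment only: depletion is not tested.
* No replicate handling; replicates must be merged or analysed
  separately upstream.
* The modulation's lower bound of one means true signal loss in a
  high-control region is indistinguishable from background.
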