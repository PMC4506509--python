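# Methods

## AP-MS differential interaction scoring

### Model and procedure

One comparison involves three conditions of `n` replicate purifications each
(default `n = 3`): wild-type bait (WT), mutant bait (MUT), and an
empty-vector control (EV) that defines nonspecific background binding.  Each
MUT replicate is paired with the WT replicate processed at the same time;
pairing is part of the run design, not inferred.

Stages, in order:

1. **Cleaning.**  Contaminants (default: common keratins, user-overridable)
   are dropped; indistinguishable isoforms are collapsed by summing counts
   per run.  Summation (rather than max) is used because spectra matched to
   either isoform are evidence for the merged protein; collapsing never
   changes a group's total count.
2. **Zero imputation.**  The analysis universe is the set of proteins
   observed (count > 0) in at least one run of the WT/MUT/EV trio.  Per run,
   the noise floor is `Normal(mean(S), sd(S))` with `S` the lowest
   `ceil(0.2 m)` of the run's `m` nonzero counts (sample s.d., ddof = 1).
   Every zero — explicit or implicit — is replaced by an independent draw,
   truncated below at `max(0.01, mean − 3 sd)`.  Truncation by clipping was
   chosen over redraw-until-positive: it guarantees positivity with a bias
   that is explicit (a point mass of ≈ Φ(−3) ≈ 0.1% at the floor) rather
   than an opaque shift of the whole distribution.  The window is computed
   per run, over nonzero counts only: zeros are the values being imputed and
   cannot define the noise floor.
3. **Bait normalization.**  Counts in bait-containing runs are divided by
   the run's bait count, making purifications of different efficiency
   comparable; the bait's normalized count is exactly 1 everywhere.
4. **High-confidence filter.**  A protein qualifies through an arm (WT or
   MUT) when (a) its *raw* pre-imputation count is nonzero in every
   replicate of that arm — an imputed zero simulates background noise and is
   not an identification — and (b) its mean count exceeds the EV mean by
   strictly more than 5-fold.  The arm/EV ratio is computed on the imputed
   counts on the common raw spectral-count scale: EV purifications contain
   no bait, so a bait-normalized EV count is not defined, while raw-scale
   counts from the same instrument are directly comparable.  Ties at
   exactly 5.0 are excluded.
5. **Paired test.**  Per high-confidence protein, ratios
   `r_k = c'_MUT,k / c'_WT,k` over the pairs (bait-normalized, imputed
   counts; denominators are positive by construction).  Default is a
   two-tailed one-sample t-test of `mean(r)` against 1 (`df = n − 1`); a
   log2-scale option tests `mean(log2 r)` against 0 and is exactly
   symmetric under ratio inversion.  A zero-variance series at the null
   yields p = 1; off the null, p = 0.  The reported fold change is always
   the arithmetic mean of the raw ratios.
6. **Adjustment and labels.**  Benjamini–Hochberg within one comparison's
   high-confidence family (one family per mutant, matching one volcano
   panel per mutant).  `decreased` requires `p_adj < alpha` AND
   `mean ratio < fc_lower`; `increased` symmetrically.  The lower
   fold-change gate defaults to 1/1.5 — the symmetric counterpart of the
   1.5 upper gate — and is exposed in `ScoringConfig`.
7. **Display.**  Heatmap of log2 mean ratios per protein × variant with
   values below −4.5 capped for display; volcano rows carry
   `−log10 p_adj` and a significance flag.

### Defaults that matter

| parameter | default | why |
|---|---|---|
| `hci_ratio_threshold` | 5 (strict) | background-exclusion stringency |
| `noise_quantile` | 0.20 | fraction of low nonzero counts defining the noise floor |
| `n_required_replicates` | 3 | presence-in-all-replicates rule |
| `alpha` | 0.05 | FDR level after BH |
| `fc_upper`, `fc_lower` | 1.5, 1/1.5 | symmetric fold gates |
| `ratio_scale` | raw | literal ratio test against 1; log2 available |
| `display_cap` | −4.5 | heatmap floor only, never used in testing |

## ChIP occupancy aggregation

Aligned read intervals (BED, 0-based half-open) are converted to per-base
coverage and binned (bin value = mean per-base depth; boundary-spanning
reads contribute proportionally; mass is conserved exactly).  ChIP and input
tracks are scaled to reads-per-million and subtracted per bin; negatives are
clamped to 0 because occupancy cannot be negative.  RPM scaling before
subtraction is configurable off.

Profiles anchor at the TSS with 100 windows of 10 bp on each side.  The TSS
of a minus-strand gene is its highest coordinate and window order is
reversed so index 0 is always most-upstream in gene orientation; window
values are mean per-base signal over in-bounds bases, and the class profile
is the unweighted mean over genes.  Class comparison is the ratio of mean
profile signal (MUT/WT), reported as log2.  A zero wild-type mean makes the
ratio undefined and is flagged degenerate rather than propagated.

## The synthetic-data generator

### AP-MS

Counts are Poisson–lognormal: `count ~ Poisson(a_p · f_cat · L)` with `L`
lognormal with mean 1 and CV 0.10, `a_p` the protein's base abundance and
`f_cat` the scenario's per-category MUT fold (1 everywhere else; the bait is
never fold-affected).  EV runs contain only the 150 background proteins
(lognormal abundances, median 6).  Proteins with expected count below 5 drop
out with probability 0.3 per run, mimicking search-engine missingness at the
noise floor.  Two scenarios: the disease scenario (pol3-specific fold 0.25,
all else 1) and the null scenario (all folds 1).  Subunit base abundance 60
and bait abundance 200 were chosen for statistical power at `n = 3` — with
10–15% per-count noise the expected |t| for a fold-0.25 protein is ≈ 15 at
df 2 — since the per-protein abundances of any real experiment are not being
imitated, only their statistical regime.

### ChIP

A scaled-down genome: one 1 Mb chromosome carrying 15 type1 + 40 type2 + 10
type3 genes placed non-overlapping with ≥ 2 kb flanks, plus a dedicated
45 kb rDNA contig (mirroring alignment of reads directly to the ribosomal
repeat reference).  Each library holds exactly 150,000 50-bp reads — the
fixed-total model of a sequencer delivering a target depth — composed of
per-gene enriched reads (Poisson around the class depth × condition fold,
centres normal around the TSS with sd 120 bp) plus uniform background
filling the remainder; input is background only.

Depths (1500 reads/gene for the three classes, 8000 for rDNA) follow from a
power analysis of the estimator's two bias sources: (i) clamping the
subtracted track at zero puts a positive noise floor `ε ≈ 0.4 σ_bin` under
both profiles, pulling the ratio toward 1 by ≈ `2.2 ε / P` in log2 (P = peak
window mean), so P must sit well above the background bin noise; (ii) the
rDNA class has a single anchor, so its log2 ratio inherits the full Poisson
CV of its read count, requiring several thousand reads for a ≈ 0.02 s.d.
With these defaults the expected recovery error is ≈ 0.03–0.04 in log2 for
the gene classes and ≈ 0.02 for rDNA.  The resulting enriched-read fraction
is far higher than a genome-wide experiment's because the genome is
scaled-down ~3,000-fold while per-gene depths are realistic; background
statistics per locus, which drive the estimator, are preserved.

### What passing tests do and do not show

The generator reproduces replicate over-dispersion, background binding,
search-engine dropout, paired designs, input background and TSS-local
enrichment.  It does not model ratio-dependent ionization competition,
shared peptides, chromatin accessibility structure in the input, mappability
or PCR duplicates.  Passing recovery tests therefore demonstrates that the
statistical machinery is correct and calibrated under its stated
assumptions, not that those assumptions exhaust real data.

## Numerical choices and degenerate inputs

* Imputation, normalization and testing are fully deterministic given one
  seed; runs and proteins are processed in sorted order.
* BH adjustment delegates to `statsmodels` after validation; it is checked
  exactly against a brute-force step-up enumeration in the tests.
* t-tests use the exact t distribution (`scipy`); df = 2 cases additionally
  match the closed form `F(t) = ½(1 + t/√(2+t²))` to 1e-9.
* Missing bait in a run, < 2 nonzero counts in a run, dangling or
  many-to-one pairings, unknown condition tokens, out-of-bounds reads and
  malformed lines all fail fast with the offending entity named.
* Problem sizes in the test suite and acceptance script (200 or 50
  simulation seeds, 2,000 null proteins, a 1 Mb + 45 kb genome) keep a full
  run in the tens of seconds while leaving Monte-Carlo error well inside
  every asserted tolerance.

## Known limitations

* The raw-scale ratio t-test is anti-conservative in principle for strongly
  skewed ratio distributions at n = 3; at CV 0.10 the measured type-I error
  is within Monte-Carlo error of nominal (the acceptance suite checks this),
  and the log2-scale option removes the asymmetry.
* EV-arm comparability relies on imputed raw-scale counts rather than
  bait-normalized ones (no bait exists in EV); if EV purifications had
  grossly different loading, a total-count scaling would be needed.
* Input subtraction with clamping biases near-zero regions upward; the
  occupancy ratio is therefore slightly compressed toward 1 when peaks are
  weak relative to background noise.
* Single-anchor classes (rDNA) have no between-gene averaging; their
  comparisons carry the full within-locus sampling noise.
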