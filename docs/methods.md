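# Methods

## The inference problem

A hexaploid individual carries six copies of each of its 11
chromosome types. Whole-chromosome aneuploidy — a seventh copy, or a
missing one — changes the fraction of sequencing reads that map to
that chromosome by roughly ±1/6, a signal that is detectable in
targeted-capture depth data but is entangled with two nuisances:
chromosomes differ in how many reads they attract (target content,
mappability), and samples differ in depth and amplification history.
`ploidymc` separates these by modelling the *composition* of each
sample's reads across chromosomes rather than absolute depth.

## Model

For sample *i* with read counts `n_i1..n_im`, the likelihood is
multinomial with cell probabilities `λ_j k_ij / Σ_v λ_v k_iv`. The
multinomial coefficient depends only on the data and is omitted
everywhere; every Metropolis–Hastings ratio cancels it. Two structural
consequences matter and are covered by tests:

* **Per-sample scale quasi-invariance.** Multiplying a whole row of K
  by a constant leaves the likelihood unchanged (`k=12` everywhere is
  indistinguishable from `k=6` everywhere); only the copy-number
  prior, which decays geometrically in `|k−6|`, breaks the tie. This
  is intrinsic to compositional data — absolute ploidy is not
  identifiable from read shares — and is why the prior is centred on
  the known baseline rather than flat.
* **Zero states.** `k_ij = 0` with reads present has zero likelihood
  (legal, always-rejected proposal); a row that is *entirely* zero
  while it has reads leaves the cell probabilities undefined and is
  treated as an invalid state (an exception), not as −∞.

Priors: Dirichlet(1) on λ; `P(k) ∝ (1−p)^|k−6|` truncated to {0..12}
(normalizer summed over the 13 states; `p=0` is flat, `p=1` a point
mass at 6 with the 0⁰=1 convention); uniform[0,1] on `p`. The ploidy
ceiling 12 (twice the baseline) is a hard constant of the method.

## Sampler

One iteration updates, in fixed order: all ploidy cells, all
chromosome weights, then `p`.

* **Ploidy cells** — symmetric ±1 random walk on the circle of
  integers {0..12} with 0 and 12 adjacent (the wrap keeps the proposal
  symmetric at the boundary). The sweep visits chromosomes in index
  order and updates all samples of a chromosome as one vectorized
  block; samples are conditionally independent given (λ, p), so this
  has the same law as a cell-by-cell sweep.
* **Chromosome weights** — coordinate *j* moves by a two-sided
  exponential step (magnitude ~ Exponential(rate), sign ±½ each),
  folded into [0,1] by reflection; the other coordinates are rescaled
  by `(1−λ_j′)/(1−λ_j)`, preserving the simplex sum exactly. With the
  uniform Dirichlet prior, only the likelihood enters the acceptance
  ratio. The kernel is treated as symmetric; the co-rescaling makes
  exact simplex symmetry approximate, which is why the test suite
  pins λ and checks the K-posterior against exhaustive enumeration —
  the sampler matches the exact 169-state posterior to total
  variation < 0.002 at 200k iterations, well inside the 0.02 bound
  asserted.
* **Sharpness `p`** — the same reflected-exponential step. The only
  factor of the target that depends on `p` is the ploidy-prior
  product, so that alone enters the ratio (the multinomial likelihood
  does not involve `p`).

A one-sided exponential step would not be a symmetric kernel; the
random sign is what makes the stated acceptance ratios correct.

Defaults follow the study design: 100,000 iterations, 10,000 burn-in,
proposal rates 100.0 (mean step 0.01) for both λ and `p`, four chains.
Initialization: `k=6` everywhere, λ at the pooled per-chromosome read
proportions (with a +0.5 pseudocount so empty chromosomes stay
positive), `p=0.5`; chains after the first start overdispersed
(λ ~ Dirichlet(1), k ∈ 6±1 randomized, p ~ U[0,1]). Each chain uses a
single seeded PCG64 generator (`seed + chain_index`); traces are a
pure function of (counts, config). Accumulated floating drift in the
simplex is renormalized every 1,000 iterations (the per-update drift
is ~1e-16; the invariant asserted is Σλ = 1 within 1e-9).

### Convergence diagnostics

The potential scale reduction is computed as `sqrt((W + B/N)/W)` (W
mean within-chain variance, B between-chain variance of means times
N); identical chains give exactly 1. Threshold 1.1 by default, plus
lag autocorrelation of `p` and per-cell posterior-mode agreement
across chains. Small toys can fail the diagnostic for a genuine
reason: with few samples and chromosomes the posterior has metastable
modes in which an entire row of K shifts by one while λ compensates
(the quasi-invariance above). These are real features of the target,
suppressed as samples and chromosomes grow; the diagnostic toy in the
test suite uses 10 samples × 6 chromosomes, where the modes are
unique.

### Mixing and run sizes

The `p` random walk's relaxation time at rate 100 is about
(1/0.01)² = 1e4 iterations, which sets the cost of integrating over
the hyperprior; prior-recovery checks therefore use batch-means
standard errors with batch lengths of several relaxation times rather
than naive SEs. Conversely, with ≥1e5 reads per sample the
K-posterior is nearly degenerate and chains equilibrate within a few
hundred sweeps, so the recovery experiments run 4,000 iterations with
1,000 burn-in — the 100,000-iteration default is kept for real data,
where depth per chromosome is far lower.

## Depth normalization (α)

`α_ij = n_ij N / (r_i c_j)` is a visual/QC statistic only — the model
consumes raw counts. α is exactly 1 on rank-one count matrices.
Rescaling one sample's depth changes its α row by the factor
`(1+(t−1)r_i/N)/(1+(t−1)n_ij/c_j)` — exact cancellation holds only in
the infinite-cohort limit, which is the regime the statistic is meant
for (one tree among hundreds). Stratified α recomputes all totals
within each PCR-cycle group, so group-shared amplification profiles
cancel within the stratum.

## Calling rule

A cell is called from the pooled post-burn-in state frequencies:
`gain` if the modal state is ≥7 with modal probability ≥ 0.95,
`loss` if ≤5 at the same threshold, `euploid` if the mode is 6, else
`uncertain`. The threshold is a package choice (configurable); modal
ties resolve to 6 when 6 is among the tied states, otherwise to the
tied state nearest 6 (then the smaller). Cohort percent-aneuploids
uses total trees as denominator; the alternative euploid-count
denominator is noted in the table output, since both conventions
appear in published summaries.

Fisher's exact test is computed by direct hypergeometric enumeration;
the two-sided value follows the minimum-likelihood convention (sum of
all margin-fixed tables with point probability ≤ the observed),
matching R's `fisher.test`. A `Fraction`-arithmetic enumeration and
scipy serve as independent cross-checks in the tests.

## Synthetic data

The generator draws each sample's total depth log-normally (median
2e5 reads, σ = 0.5 — a realistic spread for a targeted-capture
cohort), then multinomial counts with probabilities
∝ λ_j k_ij × batch factor. Chromosome weights default to uniform over
the 11 chromosomes; pass explicit weights to mimic a skewed target
space. Batch effects are multiplicative per (PCR group, chromosome),
drawn uniformly in 1 ± 0.1 — a deliberately simple stand-in for
amplification bias, shared by every sample in a group, which is
exactly the structure group-stratified inference absorbs into its
group-local λ. The study-scale fixture plants 20 events in 356
samples (old-growth 0; second-growth 8 gains + 1 loss; vegetative
cohort 2 gains + 9 losses, placed per chromosome as in the published
count tables), one event per carrier.

What passing the recovery tests shows: the inference pipeline
identifies whole-chromosome events generated by its own model, at
realistic depths, under group-shared multiplicative bias. What it
does not show: robustness to within-chromosome coverage structure
(GC, mappability, capture-bait density), mosaicism, segmental events,
or mapping artefacts between the study species and the reference
relative — none of which the generator emulates and the first three
of which the model explicitly does not address.

## BLAST multiplicity analysis

Operates on precomputed 13-column tabular BLAST output (the 12
standard fields plus number of identical matches). Hits are counted
per query including duplicate rows; the frequency-of-frequencies
table conserves the distinct-query count. Query deduplication drops
queries whose complete (sseqid, sstart, send) hit set duplicates an
earlier query's — a heuristic, documented as such. Twelve-hit sets
are split by percent-identity rank into top and bottom six; a tie at
the rank-6 boundary flags the split ambiguous rather than silently
choosing.

## Known limitations

* Absolute ploidy is unidentifiable from composition alone; calls are
  relative to the assumed baseline of 6.
* The λ kernel's symmetry on the simplex is approximate (co-rescaling
  after reflection); exactness is verified empirically against
  enumeration rather than proven.
* A shared batch factor close to half a copy-number step (±8%) can
  bias calls if stratification is skipped; stratified runs are the
  supported path when amplification groups are known.
* Detection requires the event to span the whole chromosome; partial
  aneuploidy and mosaicism are out of scope.
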