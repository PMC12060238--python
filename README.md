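# ploidymc

Detection of whole-chromosome aneuploidy from sequencing depth in
polyploid genomes, built for the awkward case where the genome is
large, repetitive, and poorly curated: coast redwood (*Sequoia
sempervirens*), a hexaploid (2n = 6x = 66) conifer whose reads are
counted against the 11 chromosomes of its diploid relative, giant
sequoia (*Sequoiadendron giganteum*).

The package is aimed at population-genomic studies of nonmodel
polyploids: it consumes per-chromosome mapped-read counts (e.g.
`samtools idxstats` output after deduplication and MQ filtering) and
returns, for every sample and chromosome, a posterior distribution
over chromosome copy number — so a tree carrying seven copies of
chromosome 10 instead of six is called with an explicit probability,
not a depth-ratio heuristic.

## Model

Read counts `n_ij` of sample *i* across chromosomes *j = 1..m* are
multinomial with cell probabilities

```
P_ij = λ_j · k_ij / Σ_v λ_v · k_iv
```

* `λ = (λ_1..λ_m)` — a simplex of chromosome weights (the effective
  mapping-target share of each chromosome), prior Dirichlet(**1**);
* `k_ij ∈ {0..12}` — the copy number of chromosome *j* in sample *i*,
  with a reflected, truncated geometric prior centred on the hexaploid
  baseline, `P(k) ∝ (1−p)^|k−6|`;
* `p ∈ [0,1]` — the prior's sharpness, hyperprior uniform[0, 1].

Inference is by Metropolis–Hastings MCMC (default 100,000 iterations,
10,000 burn-in): a ±1 random walk on the 13-cycle of copy-number
states for every cell, a reflected symmetric-exponential step with
simplex co-rescaling for each `λ_j`, and the same reflected step for
`p`. Multi-chain potential-scale-reduction and autocorrelation
diagnostics are built in.

Around the sampler sit the supporting analyses of a cohort study: the
doubly standardized depth statistic `α_ij = n_ij·N/(r_i·c_j)` for
visual QC (optionally stratified by PCR-cycle group), cohort gain/loss
tables with Fisher's exact tests (minimum-likelihood two-sided
convention), a generative simulator with planted aneuploidies for
validation, and a BLAST hits-per-query multiplicity analysis that
checks a reference assembly's ploidy from the copy count of its coding
sequences.

## Worked example

Simulate a 12-tree cohort with a chromosome-10 gain in tree 3 and a
chromosome-4 loss in tree 8, then infer:

```sh
ploidymc simulate --n-samples 12 --seed 7 --depth-median 50000 \
    --planted 3:chr10:7 --planted 8:chr4:5 --outdir sim
ploidymc infer --counts sim/counts.tsv --iterations 2500 --burn-in 500 \
    --n-chains 1 --seed 1 --outdir mcmc
```

`mcmc/calls.tsv` then contains one row per (sample, chromosome); the
two planted cells are the only non-euploid calls:

```
sample_id  chromosome  mode  mode_prob  call
S0003      chr10       7     1.0        gain
S0008      chr4        5     1.0        loss
```

`mode` is the posterior-modal copy number and `mode_prob` its
posterior probability; a gain/loss is only called when `mode_prob`
exceeds the threshold (default 0.95), otherwise the cell is reported
`euploid` or `uncertain`. Cohort tables and the exact tests follow
with `ploidymc summarize --calls mcmc/calls.tsv --metadata
sim/metadata.tsv --outdir tables`.

The same operations are available as a library
(`ploidymc.run_chains`, `ploidymc.summarize_posterior`, ...); see
`docs/methods.md` for the model's assumptions and numerical choices.

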