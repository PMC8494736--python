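# Methods

`gimap` detects pairs of genes whose somatic mutations co-occur more or
less often than expected in a tumor cohort, given how often each gene is
mutated and how heavily each tumor is mutated. This note describes the
statistical machinery, the choices made where the design was open, and
what the synthetic cohorts used for validation do and do not establish.

## The mutation matrix

All tests operate on a binary gene x sample matrix: entry (g, s) is 1 if
sample s carries at least one retained somatic SNV or small indel in
gene g. Construction from a variant table proceeds in a fixed order:

1. **Parsing.** Tab-separated MAF-like tables in two dialects (MAF-style
   `Variant_Classification` vocabulary, or ANNOVAR-style consequence
   labels) plus a configurable `SYNTHETIC` dialect. Malformed rows are
   counted in a `FilterReport`, never silently dropped.
2. **Hypermutator removal.** A sample is a hypermutator when its total
   variant count — including silent SNVs, hence counted *before* the
   functional filter — strictly exceeds
   `floor(rate x coverage x coding_length / 1e6)` = floor(10/Mb x 0.95 x
   23,698,355 bp) = **225**. The coding length is the non-redundant
   coding footprint of a reviewed protein-coding gene set, taken as a
   constant; counting is restricted to a configurable gene universe
   (default: all genes in the input) because the original gene set is
   not distributable. Sample blocklists (e.g. relapse or single-end
   libraries) are an explicit option, not inferred.
3. **Functional filter.** Only consequence classes with a likely protein
   effect are kept; each dialect has a fixed keep-list and a known
   drop-list, and anything else is reported as `unknown_consequence`.
4. **Overlapping-gene resolution.** Variants annotated to several
   overlapping genes are assigned by a ranked vote (Gencode v19 status,
   v19/v27 protein-coding type, exonic alteration counts, no dash in
   the symbol), with an alphabetical fallback on a full tie (logged).
5. **Matrix construction.** Multiple hits collapse to one entry;
   zero-mutation samples are removed, then genes mutated in fewer than
   2 samples, in one pass (a gene is not re-checked after the sample
   pass, but samples orphaned by the gene pass are dropped so the
   matrix invariant — every sample has a mutated gene — holds). Genes
   and samples are kept in alphabetical order so that every downstream
   result is deterministic.

## Permutation test

For each unordered pair the statistic is the co-occurrence count
`co_obs` (samples mutated in both genes). The null is the uniform
distribution over binary matrices with the observed row and column sums,
which conditions on both gene-level frequencies and sample-level loads.
P-values use the add-one estimator

    p_co = (1 + #{i : co_i >= co_obs}) / (1 + N)
    p_me = (1 + #{i : co_i <= co_obs}) / (1 + N)

so p is never 0 and lies in [1/(1+N), 1]; the two tails overlap at the
observed count, so p_co + p_me > 1 always.

Sampling uses a curveball Markov chain (random trades of the non-shared
column indices of two rows), which preserves margins exactly and has the
uniform distribution as its stationary law. Mixing parameters: burn-in
5x the number of 1-entries, thinning 1x between saved states; a test
checks visit frequencies against exhaustive enumeration on a small
instance, and Monte-Carlo tails against exact enumeration up to 5 x 8.
In pan-cancer mode each cancer type's sub-matrix runs its own chain
(block permutation) and counts are pooled, so the null respects
per-type frequency differences. N defaults to 1e4 at desk scale
(1e6 is the production-scale setting; every N is configurable).

## Empirical FDR and q-values

Permutation P-values are discrete and biased toward 1, so standard FDR
procedures do not apply. Instead `n_pseudo` (default 100) additional
permuted matrices are scored against the same ensemble as pseudo
observations, giving a null P-value multiset S_null per direction. For
an observed P*:

    FDR(P*) = V(P*) / R(P*),
    V(P*)  = prop(S_null <= P*) x #observed,   R(P*) = #{observed <= P*}

and q(P*) is the minimum FDR over all observed P >= P* (suffix minimum),
capped at 1. Ties count inclusively on both sides.

One subtlety: the pseudo-observed matrices are *extra* draws from the
chain, not members of the scored ensemble. Scoring an ensemble member
against itself floors its own P-value at 2/(1+N) while the observed
matrix can reach 1/(1+N); at desk-scale N that asymmetry empties the
null's extreme tail and manufactures q = 0 discoveries. With the extra
draws, observed and pseudo-observed are exchangeable under the null.

**Selection:** a pair is significant at q < 0.2 and p < 0.1 (strict),
and for the co-occurrence direction additionally co_obs >= 3.

## WeSME-style weighted-sampling test

The weighted test replaces matrix permutation by per-gene resampling:
each gene's mutated-sample set is redrawn (size preserved) without
replacement with per-sample probability proportional to mutation load,
within each cancer type; genes are resampled independently. This keeps
gene margins exact and sample loads correct in expectation. Sampling is
implemented by the exponential-race construction (keys E_s ~ Exp(w_s),
keep the k smallest), which is distribution-identical to sequential
draws with weight renormalization — verified against exact sequential
inclusion probabilities computed by enumeration — with a
rejection-sampling shortcut for small margins and a streaming top-k heap
for large ones.

Resampling is adaptive: every tested pair starts at 100 draws and
escalates to 1,000 and then 10,000 only while its interim P-value is
below 10 / current_draws (the cap of 10,000 is fixed; the 100 → 1,000 →
10,000 ladder and the factor 10 are this package's declared rule).

**FDR.** 300 fixed-margin permutations of the matrix are scored as null
contexts. Because fixed-margin permutation preserves every margin and
every load, a pair's weighted-resampling null distribution is identical
in every context, so one resample pool per pair serves the observed
matrix and all 300 permutations. Each context escalates a pair
according to its *own* interim P-value; pools grow to the union of all
contexts' demands, and every context is then read out at exactly the
depth the adaptive rule assigns it. (Escalating only where the observed
matrix demands it would starve the null's low-P tail of non-escalated
pairs and systematically understate the FDR — the observed low P-values
are selected for, the null ones are not.) Null P-values are stratified
by the rate-bin pair of the two genes — a gene is "high" when mutated
in >= 2% of samples (boundary inclusive) — and FDR/q are computed per
direction within each stratum.

**Pan-cancer mode** pools counts across types while resampling within
each type (a gene absent from a type contributes margin 0), and applies
the pre-test count filters: the ME test requires >= 3 mutually
exclusive samples, the co test >= 1 co-occurring sample. Rate bins use
pooled rates. With a single cancer type the pan test reduces exactly to
the per-type test.

**Replicates.** The full WeSME analysis is repeated 10 times with
distinct seeds; high-confidence candidates are those significant in at
least 9 of 10 runs. The permutation test is run once and passes through.

## Mutation load association (MLA)

A gene whose mutation probability rises with a sample's total load tends
to fake exclusivity with genes that lack that association. MLA is the
Wald statistic of a logistic regression of the gene's indicator on the
sample load (untransformed; the gene's own contribution to load is
included by default, with a leave-one-out switch for sensitivity).
Degenerate fits (constant indicator or load, separation, non-
convergence) carry a status code instead of a score. Suspect rules,
strict inequalities at threshold 3: an ME pair with |MLA_a - MLA_b| > 3
and max > 3; a co pair with both MLAs > 3.

## Synthetic cohorts

The generator emulates the statistical structure the tests assume, with
a truth table for recovery scoring:

- **Gene frequencies**: truncated power law (density ~ f^-1.75 on
  [1/n, 0.3]). Most genes are rare with a short tail of frequent
  drivers; with 200 background genes this yields a mean of ~4-5 mutated
  genes per sample, matching the low burden of pediatric tumors. The
  exponent, bounds, and law are configurable.
- **Sample loads**: log-normal multiplier (sigma 0.6, mean 1) per
  sample, times optional subtype multipliers.
- **Hypermutators**: a sampled fraction receives multiplier 25 applied
  to a baseline floored at 1 (hypermutation is its own regime, not a
  scaling of a possibly-low baseline), which puts their variant counts
  reliably above the 225 threshold.
- **Variant file**: one functional variant per mutated cell with a
  consequence drawn from the dialect keep-list, plus per-sample silent
  variants (Poisson, mean 12 x load multiplier) that exercise the
  count-before-filter hypermutator logic. Re-running the emitted file
  through the I/O stage reproduces the matrix exactly.
- **Planted pairs**: co-occurring pairs are drawn jointly from the 2x2
  table with margins (pa, pb) and joint mass lift x pa x pb (margins
  preserved in expectation; infeasible lifts fail fast with the maximal
  feasible value); ME pairs clear one of the two mutations (uniformly)
  in each double-mutant with probability = exclusivity, shrinking
  margins slightly (reported, not re-balanced). Planted genes use
  fixed, load-independent probabilities so that the planted margins and
  effect sizes are exact; background genes carry the load structure.
- **Subtypes**: per-type partitions with load multipliers and
  subtype-private genes reproduce the confounder where cross-subtype
  exclusivity is a load/subtype artifact.

What passing on these cohorts does *not* show: real cohorts have many
thousands of genes (here: hundreds), genuine pathway structure,
copy-number and structural events (absent), and mutation probabilities
that need not factor into gene x sample terms. The generative model is
chosen so that, conditional on margins, the fixed-margin null is exact
for background genes; real data offer no such guarantee, which is
precisely why the empirical FDR and the MLA diagnostics exist.

## Numerical and design notes

- All randomness flows from one `numpy` Generator per run (seeds
  recorded in outputs); the curveball and resampling kernels re-seed
  numba's RNG from it, so every fit is reproducible bit-for-bit.
- Null co-count distributions are stored as per-pair histograms
  (O(pairs x distinct counts) memory), never as matrices; the pseudo
  observation reservoir stores dense matrices only.
- Monte-Carlo-vs-enumeration tests allow 3 binomial standard errors
  plus the deterministic 2/N bias bound of the add-one estimator.
- Degenerate inputs: matrices whose margins force a unique fill-in are
  their own (only) permutation; two-gene matrices have fixed co-counts
  and unit P-values in both directions; genes mutated in all samples
  give p_co = 1 under resampling.
- Down-sampling experiments re-apply the singleton-gene filter to each
  subsample before testing, and reuse the >= 9/10 rule across the
  replicates of a size.
- Desk-scale defaults (N = 1e4 permutations, 300-sample cohorts with
  ~200 genes, 10 replicate runs) keep a full validation run in minutes
  on one core; production values (N = 1e6) are configuration changes,
  not code changes.
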