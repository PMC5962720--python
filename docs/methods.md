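# Methods

This note documents the models and procedures implemented in `repshannon`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic data do and do not show.

## Data model

A clonotype is the unique combination (TRBV gene, CDR3 amino-acid sequence,
TRBJ gene); a `ClonotypeTable` maps clonotypes to positive integer
abundances (sequences). Everything rank-based in the package uses one
canonical order — count descending, ties broken by lexicographic
(V, CDR3, J) — so that filtering, ranking and written output are
deterministic byte for byte. Counts must be integers because rarefaction
and the overlap statistics are hypergeometric at heart. Tables are read and
written as AIRR-Rearrangement-style TSV (`v_call`, `junction_aa`, `j_call`,
`duplicate_count`), the community standard for repertoire tables; any other
header set is supported via a dialect mapping. Productivity filtering is
assumed to have been done by the upstream annotator; the CDR3 validator
rejects non-amino-acid characters (including stop `*`).

## Sequencing-error correction

Within each TRBV-TRBJ cluster, clonotypes observed exactly once
(singletons) are candidate artifacts. A singleton is merged into a
non-singleton clonotype of the same cluster iff the CDR3 peptides are at
Levenshtein distance 1 **and** at least one of the target's distinct CDR3
nucleotide variants is at distance 1 from the singleton's nucleotide
sequence. Design choices where the procedure is underdetermined:

- **Multiple eligible targets**: the highest-count candidate wins (it is
  the maximum-likelihood source of a single-base PCR/sequencing error);
  remaining ties break lexicographically by CDR3 peptide.
- **Single pass**: eligibility and tie-breaking use the *original*
  non-singleton counts; merges are not cascaded or re-evaluated, making
  the result independent of processing order.
- Non-singletons carry the full set of distinct nucleotide variants; the
  nucleotide test passes if *any* variant is at distance 1.

Total sequence count is always conserved; richness never increases.
Distances are computed with `edlib`; an independent dynamic-programming
oracle lives in the test suite only.

## Diversity

For a frequency vector p, Renyi entropy of order a ≥ 0 is
H_a = ln(Σ p_i^a)/(1−a), with H_0 = ln S (richness S), H_1 the Shannon
entropy −Σ p_i ln p_i, and H_∞ = −ln max p_i (dominance). Natural
logarithms are used throughout, so the Hill diversity exp(H_a) is an
effective number of clonotypes. The default profile grid
{0, 0.25, 0.5, 0.75, 1, 2, 4, 8, 16, 32, 64, ∞} is dense where profiles
bend (a ≤ 1) and doubles until stabilization; it is configurable. Large
orders are evaluated through a log-sum-exp so that p_i^a cannot underflow.
Pielou evenness is J = H_1/ln S, defined for S ≥ 2.

**Steepest-descent slope.** To compare rank-abundance curves, counts are
ranked descending, runs of tied counts are collapsed to one point at the
plateau's midpoint rank, and the steepest (most negative) chord slope of
log10(count) versus log10(rank) is taken over pairs of points at least
0.25 decades of rank apart. The minimum span suppresses count-quantization
jitter, which otherwise biases pointwise central differences ~25% steep on
an exact power law; the final plateau is excluded as a chord endpoint
because the finite richness right-censors it. On integer-rounded power-law
curves count(r) = round(1000·r^(−s)) the estimator returns −0.51 / −1.03 /
−2.10 for s = 0.5 / 1 / 2. Perfectly even tables return 0.

## Shannon filtering

The effective clonotype number N = round(exp(H_1)) (half-away-from-zero;
clipped to [1, S]) is used as a hard cutoff: the N most abundant clonotypes
under the canonical sort are kept, the remainder discarded as scarce
uninformative clonotypes (SUC). The entropy is computed once, on the input
table (after error correction and any rarefaction), and not recomputed
after filtering. Boundary ties are resolved by the deterministic sort
rather than by keeping all tied clonotypes, so the kept richness equals N
exactly and results are reproducible; the choice is recorded in the CLI
summary output. A `--min-count` convenience flag provides the
"drop singletons" baseline.

## Rarefaction, similarity, overlap

Rarefaction to depth D draws D sequences without replacement from the
count vector — a multivariate hypergeometric sample (vectorized, seeded
`numpy` generator). Requesting D at or beyond the table total returns the
table unchanged with a warning: the full dataset is the only possible
subsample, which is exactly how depth grids that exceed the dataset size
behave in the experiments. A naive expand-shuffle-truncate oracle and the
closed-form expected richness Σ_i [1 − C(T−n_i, D)/C(T, D)] back the
implementation in tests.

Morisita-Horn similarity, Pearson correlation, k-way sharing
decomposition (each union clonotype labeled by the number of replicates
containing it), per-replicate sharing-enrichment curves down the abundance
ranking, and cumulative richness-coverage curves are implemented on
count vectors aligned over union key sets.

## Repertoire simulator

Simulated repertoires make the sampling question answerable exactly,
because the full population is known. A repertoire is a finite ranked
Zipf-Mandelbrot population of R = 2·10⁶ clonotype labels with type
probabilities π_r ∝ (r+q)^(−s); the evenness conditions are indexed by
A ∈ {2, 3, 4, 5, 10, 20, 100} (A=2 most skewed, A=100 near-uniform). For
each A the exponent s_A is root-found (Brent, bracket [0, 3]) so that the
expected number of distinct clonotypes in a 6·10⁵-sequence dataset,
E[S_obs] = Σ_r [1 − (1−π_r)^D] evaluated stably via log1p/expm1, equals
the published richness anchor N_A for that condition within 0.5%. The
offset q stays 0 — one anchor supports one free parameter — and the
calibrated top-type probability is checked against the cap B = 0.2
(π_1 ranges from 0.078 at A=2 down to 2·10⁻⁴ at A=100). Calibrated
exponents run from s₂ ≈ 1.024 to s₁₀₀ ≈ 0.461.

Dataset construction follows the published pipeline shape: the full token
total M_A (1.31·10⁸ down to 1.11·10⁷ sequences, taken as fixed inputs) is
distributed over ranks by one exact multinomial draw; ranks are assigned
to library labels by a uniform random permutation; the repertoire is then
rarefied without replacement to exactly 6·10⁵ sequences. Drawing 6·10⁵
tokens directly from π is distributionally identical to the two-stage
construction (verified by chi-square in the tests), which is also why the
calibration can use the closed form above.

The clonotype library is a uniform combinatorial labeler, not a V(D)J
recombination model: V and J uniform over the bundled murine TRBV/TRBJ
lists, CDR3 peptides starting with C and ending with F with lengths 8-20
(mode 14, triangular weights), one consistent in-frame nucleotide encoding
per label, uniqueness enforced by re-drawing collisions. Identities never
enter any abundance statistic — only the count vector does — so the
simulator also supports skipping label generation entirely.

## Experiments

All experiments subsample a reference dataset at depths
D ∈ {500, 10³, 5·10³, 5·10⁴, 5·10⁵, 10⁶} (configurable), 100 iterations by
default, and summarize ensembles by median and 95% percentile interval
(2.5th-97.5th; the interval method is a package choice). Iterations are
independent draws; within a draw, sampling is strictly without
replacement. Triples in the sharing experiment are 3 independent
subsamples per iteration. Randomness flows from one integer seed through a
spawned `SeedSequence` tree with one stream per (depth, iteration), so
results are bit-reproducible and a shorter run is a prefix of a longer one
at the same seed.

The coverage experiment draws a pool of n_iter subsamples per depth and
accumulates union richness over random orderings of the pool; the k = 1
point equals single-subsample richness coverage.

Problem sizes in the shipped test suite are scaled to what the properties
need: ensemble checks on the simulated A=3 dataset run 25 iterations at
four depths, while the acceptance script runs the full 100 iterations.

## What the synthetic data do and do not show

The simulator realizes skew via a one-parameter ranked power law
calibrated to a single richness anchor per condition. It reproduces the
interplay of depth, richness and overlap that drives the sampling
conclusions, but it does not model V(D)J generation probabilities,
PCR amplification bias, sequencing error (except in the dedicated
error-correction fixtures, where errors are spiked single-nucleotide
substitutions), or UMI-based deduplication. Quantities tied to the actual
mouse sequencing runs (the aliquot entropy values themselves, the
experimental replicate-overlap counts) require the archived raw data plus
upstream annotation and are accepted as *inputs*, not recomputed. Because
only richness anchors the calibration, second-order features of the
abundance head are not pinned: at the shallowest subsampling depth (500
sequences from 6·10⁵) the simulated A=3 repertoire yields ≈99.1% private
clonotypes across triples where ≈99.7% was reported for the original
realization — the remaining statistics of the sharing table agree within a
few percent.

## Known limitations

- The error-correction pass is single-pass by design; pathological chains
  of 1-edit singletons are not cascaded.
- `ClonotypeTable` keeps data in memory (pandas); repertoires of ~10⁷
  clonotypes will work but are not optimized.
- The simulator's label generator is intentionally not a biological
  recombination model; do not use simulated CDR3 sequences for
  sequence-level analyses.
- Percentile intervals at small iteration counts are noisy; medians of
  the three sharing categories need not sum to exactly 100 even though
  each triple's percentages do.
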