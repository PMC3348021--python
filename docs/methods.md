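# Methods

## The problem and the model

A bicluster of a gene-expression matrix M (n genes × m conditions) is a
submatrix (I′, J′) whose genes behave coherently across the selected
conditions. This package searches for *trajectory-coherent* biclusters:
groups of genes whose expression rises and falls in the same way across a
subset of conditions, regardless of absolute level or scale. Coherence is
rank-based, so any strictly increasing per-gene transform of the data
(log-scaling, normalization) leaves every score in this package unchanged.

### Trinary behavior encoding

The matrix is first recoded into a behavior matrix M′ with one column per
unordered condition pair (k, q), k < q, in lexicographic order —
m(m−1)/2 columns. Entry (i, l) is +1 if gene i rises from condition k to
q, −1 if it falls, 0 if the two stored values are exactly equal. Equality
is exact by design: the encoding is a strict trichotomy, and expression
values on a continuous scale essentially never tie, so an epsilon would
only introduce a hidden parameter. Rows of M′ are gene trajectory
patterns; the search state (a *configuration*) is a gene subset I′ plus a
subset K of pair-columns. Encoding a bicluster takes all |J′|(|J′|−1)/2
pairs internal to J′; decoding (below) maps K back to conditions.

### The ASR objective

Bicluster quality is the Average Spearman's Rho:

    ASR(I′, J′) = 2 · max{ Σ_{i<j∈I′} ρ_ij / (|I′|(|I′|−1)),
                           Σ_{k<l∈J′} ρ_kl / (|J′|(|J′|−1)) }

i.e. the larger of the mean pairwise Spearman correlation among gene rows
(restricted to J′) and among condition columns (restricted to I′), in
[−1, 1]. The factor 2 against the ordered-pair divisor makes each term a
plain mean over unordered pairs. Spearman correlations use average ranks
on ties; a zero-rank-variance vector (all values tied) correlates 0 with
everything — the convention keeps ASR defined on flat rows and columns
without manufacturing spurious ±1s. ASR is computed on the original
expression values of the selection, never on the trinary recoding. During
the search a configuration is scored on the union of its pair endpoints;
scoring requires at least a 2 × 2 selection (smaller is an error, not 0).

The Mean Squared Residue (mean of squared residues
a_ij − a_iJ − a_Ij + a_IJ; 0 for additive blocks) is also provided — it
drives the node-deletion seed generator, not the search. Unlike ASR it is
scale-sensitive, so users feeding raw (non-logged) intensities to the
`cc` initializer should expect it to favor low-variance blocks.

## The search

### Pattern and move operators

The *bicluster pattern* P of a configuration holds, per pair-column, the
dominating trinary value over I′ and its frequency (dominance). Ties in
the dominance count are broken by the fixed priority 1 ≻ −1 ≻ 0 —
preferring a trend over "no change" matches the trajectory motivation, and
any fixed rule keeps moves deterministic. Gene quality is the fraction of
pair-columns where the gene's trits agree with P; column quality is the
dominance frequency itself.

`mv_g` (genes only): every gene with quality < α is dropped; genes outside
the configuration with quality ≥ α are admitted best-first (ties by
index), at most `max_add_genes` per move (default 5). The small default
batch is deliberate: each move must survive the strict-ASR acceptance test
below, and small batches let that test vet admissions individually — with
unbounded admission a single move can flood the bicluster with background
genes that merely mimic the pattern, and the all-or-nothing acceptance
cannot unbundle them.

`mv_c` (columns only) works at condition granularity, reflecting that
conditions, not individual pair-columns, are the biological unit being
selected. Pair-columns with dominance < β are dropped. A selected
condition whose pair-columns in K have *mean* dominance < β is judged bad
and expelled with all its columns. Candidate conditions outside the
selection qualify when their mean pair dominance against the surviving
conditions reaches β; up to one candidate per expelled condition is
admitted (configurable), contributing only its pair-columns that
individually reach β. The column-level guarantee is preserved: after the
move, every retained and added column has dominance ≥ β with respect to
the pre-move pattern. A purely column-granular swap was tried first and
discarded: removing part of a condition's pairs never changes the
condition set ASR sees, so no such move can ever be accepted by a
strict-improvement rule, and the operator goes dead.

### Descent and acceptance

One descent iteration computes P, proposes both operators, evaluates each
candidate's ASR on its endpoint condition set, and takes the better
candidate if it *strictly* improves the current ASR (`move_order='best'`,
the default; fixed first-improvement orders 'gc'/'cg' are available).
Strict improvement guarantees termination; plateau moves are rejected.
The descent stops when ASR reaches `asr_threshold`, at a local optimum, or
after Y = `max_descent_iters` iterations.

### Iterated local search

The outer loop keeps the best configuration seen, compared by the ASR of
its *decoded* bicluster. After each descent it perturbs the best
bicluster — uniformly replacing ⌈10%⌉ of its genes and ⌈10%⌉ of its
conditions with outsiders (ceiling, so at least one of each always moves)
— re-encodes, and descends again. The run stops after Z =
`max_stagnant_perturbations` consecutive cycles without improving the best
decoded ASR. Ties keep the incumbent, so the best ASR trajectory is
non-decreasing and the whole run is a pure function of (matrix, seed
bicluster, parameters including the RNG seed).

### Decoding

A configuration decodes to a bicluster by taking the union of K's pair
endpoints and then discarding weakly combined conditions: each round
removes every condition paired (within K) with fewer than 50% (the
`decode_coverage` default) of the other selected conditions, iterating to
a fixpoint. All below-threshold conditions drop simultaneously per round;
this batch rule is order-independent and guarantees the coverage property
holds in the output (single-pass and one-at-a-time variants do not).
Decoding applies only to the final result; during the search, ASR sees the
unfiltered endpoint set.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| α (`alpha`) | 0.8 | gene quality threshold (fraction of concordant pair-columns) |
| β (`beta`) | 0.8 | column/condition dominance threshold |
| `asr_threshold` | 0.7 | descent early-stop quality |
| Y (`max_descent_iters`) | 100 | iterations per descent |
| Z (`max_stagnant_perturbations`) | 50 | stagnant cycles before stopping |
| `perturb_fraction` | 0.10 | fraction of genes/conditions replaced per perturbation |
| `decode_coverage` | 0.50 | minimum pairing fraction for a condition to survive decoding |
| `max_add_genes` | 5 | gene admissions per move |
| `max_add_columns` | None | condition admissions per move (None = one per expulsion) |

α, β and `asr_threshold` are data-dependent: dense, strongly structured
matrices support 0.8/0.8/0.7, while noisier data is better served by
looser settings (e.g. 0.5/0.7/0.5). All thresholds are fractions in
(0, 1]; ASR thresholds live in [−1, 1].

## Initial biclusters

The search improves a seed; three generators are built in, plus file
input. `cc` is MSR node deletion in its simplest form: starting from the
full matrix, repeatedly delete the single row or column with the largest
mean squared residue contribution (ties: lowest index, a tied row before a
tied column) until MSR ≤ δ. Multiple-node deletion, node addition and
masking from the full published pipeline are deliberately omitted — the
seed only needs reasonable quality. `opsm` greedily grows a condition
ordering (trying each remaining condition at each insertion point,
maximizing the count of strictly increasing supporting rows, ties by
condition index then position) to a requested width; it is a width-1-beam
simplification of order-preserving-submatrix mining. `random` samples
uniformly. All are deterministic given the seed.

## Synthetic benchmark

The generator implants trend-coherent blocks in an i.i.d. N(0, 1)
background (optionally a per-row permuted background that preserves
marginals). Member cells follow a shared condition trend t_j — evenly
spaced distinct levels in shuffled order, scaled to unit variance — put
through a per-gene transform: `shift` adds a N(0, 1) offset per gene,
`scale` multiplies by a log-normal positive factor, `monotone` applies an
arbitrary strictly increasing per-gene map of the trend ranks. Gaussian
noise of s.d. `noise_sd` is added and rows/columns are shuffled. Distinct
trend levels matter: they give the implanted genes a definite up/down
direction on every member condition pair, which is the structure the
trinary encoding represents; near-tied levels would leave pairs with no
recoverable pattern. The default `noise_sd = 0.38` was calibrated so the
mean member-pair Spearman correlation of a shift block is ≈ 0.90
(measured 0.898 over 30 generator seeds).

What the generator does *not* emulate: correlated background genes,
heavy-tailed or batch-structured noise, overlapping modules sharing genes,
and background genes are only trend-correlated by chance. Passing the
recovery benchmark therefore shows the search machinery works under clean
module structure with realistic noise, not that it handles the full
messiness of microarray or single-cell data.

Recovery is scored by Jaccard indices (cells, genes, conditions) under a
greedy best-pairing of found to implanted blocks by descending cell
Jaccard — at benchmark scale (a handful of blocks) greedy matching agrees
with optimal assignment. One caveat of cell-level scores on this
benchmark: background genes that mimic the implanted trajectory by chance
are genuine members from the method's (rank-correlation) viewpoint but
count against the Jaccard, which bounds attainable scores slightly below
1 at realistic noise.

## Numerical and degenerate-input choices

- Spearman denominators use a single square root of the product of rank
  sums of squares, so rank-identical vectors score exactly ±1; results are
  clipped to [−1, 1] against last-ulp drift.
- All internal indices are 0-based; files and logs carry identifiers only.
- Matrices need n ≥ 2 and m ≥ 3 (otherwise the pair encoding degenerates);
  scored biclusters need at least 2 × 2; a configuration needs a non-empty
  gene set and pair-column set.
- Moves that would leave fewer than 2 genes (mv_g) or fewer than 2
  conditions / no columns (mv_c) are rejected as explicit no-ops rather
  than silently truncated.
- Decoding that leaves fewer than 2 conditions is an error the caller may
  catch to discard the candidate (the outer search does exactly that).
- Missing values are rejected unless row-mean imputation is requested
  explicitly; no normalization or log transform is ever applied.

## Known limitations

- One run returns one bicluster; multiple biclusters come from multiple
  seeds (the estimator's `n_init`), with no masking or diversity pressure,
  so different seeds may converge to the same optimum.
- ASR's `max{row term, column term}` can favor thin, few-condition
  biclusters whose columns correlate trivially; the decode coverage rule
  and condition-granular column moves mitigate but do not eliminate this.
- The greedy OPSM-style seed is a heuristic: it can miss the optimal
  order-preserving submatrix (its supports are exact only at width 2).
- Quality/dominance thresholds compare fractions over few columns when
  biclusters are small, so α and β behave coarsely there.
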