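# pdnsbic — pattern-driven neighborhood search biclustering

`pdnsbic` finds **biclusters** in gene-expression matrices: groups of genes
whose expression rises and falls the same way across a subset of conditions.
It targets analysts of bulk or single-cell expression data who want
trajectory-coherent modules rather than constant-value blocks, and in
particular anyone who already has rough biclusters (from node-deletion,
order-preserving-submatrix or other tools) and wants them refined.

## Method

The data matrix M (n genes × m conditions) is recoded into a trinary
*behavior matrix* M′ with one column per unordered condition pair (k, q):

    M′[i, (k,q)] =  1  if M[i,k] < M[i,q]
                    0  if M[i,k] = M[i,q]
                   −1  if M[i,k] > M[i,q]

so each row is a gene's up/down/no-change trajectory across all combined
conditions. A candidate bicluster is encoded as a gene set I′ plus a set K
of pair-columns, and scored with the **Average Spearman's Rho**

    ASR(I′, J′) = 2 · max{ Σ_{i<j∈I′} ρ_ij / (|I′|(|I′|−1)),
                           Σ_{k<l∈J′} ρ_kl / (|J′|(|J′|−1)) }  ∈ [−1, 1],

the larger of the mean pairwise Spearman correlation among gene rows and
among condition columns. Iterated local search then alternates:

- **descent** — per iteration, compute the bicluster *pattern* (the
  dominating trit per pair-column), drop genes whose concordance with the
  pattern falls below α and admit better outside genes (`mv_g`), or swap
  badly-dominated conditions for better ones at threshold β (`mv_c`);
  a move is accepted only if ASR strictly increases;
- **perturbation** — randomly replace 10% of the best bicluster's genes
  and conditions and descend again, stopping after Z stagnant cycles.

The final configuration is decoded back to conditions, keeping only
conditions combined with at least 50% of the other selected ones. Scores
are rank-based, so results are invariant under any monotone transform of
the expression values.

## Worked example

A typical use: polish a rough bicluster. Here the rough guess covers 60%
of a trend-coherent module implanted in a 200 × 20 synthetic matrix
(member-pair Spearman ≈ 0.9):

```python
import numpy as np
from pdnsbic import (ImplantSpec, PDNSBiclustering, SyntheticSpec,
                     generate, match_score, overlap_seed, asr)

spec = SyntheticSpec(n_genes=200, n_conditions=20,
                     biclusters=(ImplantSpec(25, 7),), seed=11)
matrix, truth = generate(spec)

# a rough bicluster, e.g. from another tool: 60% of the true cells
rough = overlap_seed(truth[0], matrix, keep_genes=20, keep_conditions=5,
                     rng=np.random.default_rng(0))
print(f"rough seed:  {rough.n_genes} genes x {rough.n_conditions} conditions, "
      f"ASR = {float(asr(matrix, rough)):.3f}, "
      f"cell Jaccard vs truth = {match_score([rough], truth).cell_jaccard:.3f}")

est = PDNSBiclustering(alpha=0.7, beta=0.7, asr_threshold=0.9,
                       init=[(rough.genes, rough.conditions)], random_state=0)
est.fit(matrix.values)
best = est.get_best_bicluster()
print(f"after PDNS:  {best.n_genes} genes x {best.n_conditions} conditions, "
      f"ASR = {best.asr:.3f}, "
      f"cell Jaccard vs truth = {match_score([best], truth).cell_jaccard:.3f}")
```

which prints:

```
rough seed:  25 genes x 7 conditions, ASR = 0.348, cell Jaccard vs truth = 0.400
after PDNS:  26 genes x 7 conditions, ASR = 0.905, cell Jaccard vs truth = 0.889
```

The search raised the bicluster's internal coherence (ASR 0.35 → 0.91) and,
because the implanted module is what generates that coherence, recovered
almost exactly the true gene and condition memberships (Jaccard 0.40 →
0.89). `PDNSBiclustering` is a scikit-learn estimator: after `fit`,
`rows_` and `columns_` hold boolean membership arrays and
`biclusters_found_` the scored biclusters, best first.

The same workflow is available from the shell:

```sh
pdnsbic synth --seed 1 --out-matrix m.tsv --out-truth truth.json
pdnsbic init --matrix m.tsv --method opsm --out seed.json
pdnsbic run  --matrix m.tsv --init seed.json --seed 0 --out found.json
pdnsbic eval --matrix m.tsv --found found.json --truth truth.json
pdnsbic score --matrix m.tsv --bicluster found.json
pdnsbic preprocess --matrix m.tsv --out behavior.tsv
```

All randomized commands take `--seed` (default 0) and are byte-reproducible.

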