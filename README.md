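# dnet — differential co-expression network analysis of perturbation time courses

`dnet` asks a simple question of longitudinal expression data: **which gene–gene
co-expression relationships exist only because of a perturbation?** Given a
paired design — the same system sampled over time with and without a treatment
(a vaccine dose, a therapeutic antibody, any stimulus) — it builds one
co-expression network per condition and subtracts them. The edges that survive
form the *differential network* (DN): co-expression rewired in by the
treatment. The DN is then decomposed into communities of densely
interconnected genes, each community is characterized by *when* it activates,
communities are placed in temporal order, their hub genes are identified, and
each is tested for pathway over-representation.

The package is aimed at systems-biology analysts working with single-subject
or few-replicate time series (e.g. hourly saliva sampling around a vaccination,
or a short in-vitro drug course with duplicate runs), where per-timepoint
differential expression is underpowered and network rewiring is the more
informative readout.

## Method

For each gene with treated series $T_i$ and untreated series $U_i$ over $N$
shared timepoints:

1. **QC** — drop duplicate rows; drop genes missing at more than $1/8$ of
   timepoints; impute remaining blanks to 0; floor all values at 1; drop
   zero-variance series.
2. **Responsive-gene selection** — score each gene by the time-averaged
   relative difference
   $\Delta_{TU} = \frac{1}{N}\sum_{i=1}^{N}\frac{T_i - U_i}{T_i + U_i} \in [-1, 1]$
   and keep genes in the bottom or top quartile of the $\Delta_{TU}$
   distribution.
3. **Networks** — connect gene pairs whose Pearson correlation reaches the
   99.5% quantile of the all-pairs correlation distribution (one-sided:
   strong positive co-expression), once per condition; with duplicated
   experiments, intersect the replicate networks.
4. **Differential network** — keep treated edges absent from the untreated
   network; drop isolated nodes.
5. **Communities** — Louvain modularity maximization (weighted, seeded);
   prune communities of fewer than five genes; label C0, C1, … by size.
6. **Temporal signatures** — per gene, subtract the time-0 value, normalize
   to unit Euclidean norm, take the treated-minus-untreated difference, and
   renormalize, giving heatmap rows in $[-1,1]$ (positive = up-regulation);
   rows are ordered by complete-linkage (farthest-point) clustering. A
   community's *peak time* is the timepoint maximizing the absolute
   community-mean signal; sorting peaks yields the activation ordering.
7. **Hubs** — top-five degree-centrality genes per community, centralities
   computed on the community's induced subgraph, ties kept.
8. **Enrichment** — one-sided hypergeometric over-representation of each
   community (≥ 8 genes) against a user-supplied GMT gene-set collection,
   Benjamini–Hochberg FDR per community.

A synthetic-data module generates paired matrices with planted co-expression
modules (correlated *only* under treatment, each with a punctuated activation
time), condition-shared background correlation that must cancel in the DN,
missing values and constant genes — plus the ground truth needed to score
every stage.

## Worked example

```python
from dnet import PipelineConfig, SimulationConfig, run_pipeline, score_recovery

result = run_pipeline(PipelineConfig(
    outdir="dnet_example_out", simulation=SimulationConfig(seed=1), seed=1,
))
print(result.partition.sizes)
print(score_recovery(result.partition, result.truth))
for label, peak, sign, mag in result.ordering.entries[:4]:
    print(label, f"t{peak}", sign, round(mag, 3))
```

prints (seed 1, default conditions: 2,000 genes × 24 timepoints, five planted
30-gene modules):

```
{'C0': 30, 'C1': 30, 'C2': 30, 'C3': 30, 'C4': 29, 'C5': 18, 'C6': 8, 'C7': 8,
 'C8': 7, 'C9': 6, 'C10': 5, 'C11': 5}
1.0
C4 t2 up 0.56
C10 t3 down 0.681
C2 t7 up 0.588
C1 t12 up 0.584
```

Communities C4, C2, C1, C0, C3 are the five planted modules (adjusted Rand
index 1.0 against the ground truth) and they peak exactly at the planted
activation times t2, t7, t12, t17, t22; the remaining small communities are
background structure. The `examples/` directory walks through each capability
separately — simulation, gene selection, DN construction, communities and
hubs, temporal ordering, enrichment — and `dnet --help` exposes the same
stages as a command line (`simulate`, `preprocess`, `select`, `network`,
`intersect`, `dn`, `communities`, `hubs`, `temporal`, `enrich`, `run-all`).

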