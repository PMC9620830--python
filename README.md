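# listagg

Rank aggregation of gene lists: simulation, consensus methods, evaluation,
and automated method selection.

## The problem

A common output of a genomic screen is a list of genes implicated in some
process — sometimes with a meaningful internal order (*ranked*), sometimes
as a bare set (*unranked*, e.g. an annotated pathway or a reported hit
list). Combining the lists from several studies of the same question into
one consensus ranking is a rank-aggregation problem with awkward, very
real features: a human-genome-scale universe (~20 000 entities), lists
that cover only a small part of it, sources of wildly different quality,
and a mix of ranked and unranked evidence that most aggregation methods
cannot consume directly.

`listagg` is a toolkit for working in exactly this regime, aimed at
bioinformaticians running gene-list meta-analyses and at methodologists
benchmarking aggregation algorithms. It provides:

- **A stochastic simulator** of realistic gene-list collections. Entity
  *k* has significance μ_k (positive for the 1000 signal entities, 5% of
  a 20 000-entity universe; zero otherwise). List *i* observes
  Z_ki ~ N(μ_k, σ_i²) with ln σ_i ~ N(ln M, D²) — *M* is the mean noise
  scale, *D* the heterogeneity of quality across sources. Lists are
  truncated to a log-normally drawn length N_i = min(⌊C_i⌋ + L, U) with
  ln C_i ~ N(ln m_c, D_c²), after removing X = ⌊γ(20000 − N_i)⌋
  never-assayed entities uniformly at random, and labelled RANKED or
  UNRANKED. Four scenario presets (`MixLarge`, `MixSmall`, `RankLarge`,
  `RankSmall`) emulate many/few-source collections with and without
  unranked lists; a Mix dataset and its Rank counterpart share identical
  ranked lists at the same seed.
- **Aggregation methods**: Borda statistics over normalized ranks
  (rMEAN / rMED / rGEO), Stuart's exact order-statistic probability, RRA's
  Bonferroni-minimum Beta p-value, Markov-chain aggregation (MC3),
  iterative empirical-Bayes reweighting (BIRRA), meta-analysis by
  information content (MAIC) with per-list weights, vote counting, and
  RepeatChoice tie refinement. "Mix" variants (rMixMEAN, rMixMED,
  rMixGEO, MixStuart) admit unranked lists by assigning every member the
  effective rank n/2 — half the list length; plain variants drop unranked
  lists, as they are used in practice.
- **An evaluation harness** measuring accuracy@k (overlap of a result's
  top-k with the truth ranking's top-k) and recall@k against set-valued
  truth, replicated over seeds with 95% confidence intervals.
- **A selector** implementing a decision flowchart over three observable
  dataset properties — unranked lists present, number of sources, and
  quality heterogeneity, the latter inferred from the coefficient of
  variation of MAIC's fitted list weights.

## Worked example

```python
import listagg as la

cfg = la.preset("MixLarge", M=3.0, D=3.0, gamma=0.0, seed=1)
sim = la.generate_dataset(cfg)
print(f"{len(sim.dataset)} lists over {len(sim.dataset.universe)} entities; "
      f"{len(sim.truth_set)} signal entities")
for name in ("MAIC", "rMixGEO", "VC", "rGEO"):
    res = la.run_method(name, sim.dataset)
    acc = la.accuracy_at_k(res, sim.truth_ranking, 1000)
    print(f"{name:8s} accuracy@1000 = {acc:.3f}")
score, label = la.infer_heterogeneity(sim.dataset)
print(f"heterogeneity score = {score:.2f} ({label})")
rec = la.select_method(sim.dataset)
print("recommended:", ", ".join(rec.methods))
```

prints

```
32 lists over 20000 entities; 1000 signal entities
MAIC     accuracy@1000 = 0.729
rMixGEO  accuracy@1000 = 0.620
VC       accuracy@1000 = 0.587
rGEO     accuracy@1000 = 0.345
heterogeneity score = 0.49 (low)
recommended: MAIC, rMixGEO
```

This is a large mixed collection (11 ranked + 21 unranked lists) at the
classic noise level M = 3 with strong quality heterogeneity D = 3. MAIC
recovers 72.9% of the 1000 true signal entities in its top 1000 —
noticeably ahead of the equal-weight consensus rMixGEO (62.0%) and vote
counting (58.7%), because its per-list weights down-weight the noisy
sources. rGEO, which discards the 21 unranked lists, drops to 34.5%:
unranked evidence carries substantial information. The selector scores
this dataset's weight dispersion at 0.49, just below the default 0.5
high-heterogeneity threshold, and recommends MAIC first either way.

The same workflow is available from the shell:

```bash
listagg simulate --scenario MixLarge --m 3 --d 3 --seed 1 --out sim/
listagg aggregate --method MAIC --in sim/dataset.tsv --universe sim/universe.txt --out ranking.tsv
listagg select --in sim/dataset.tsv --universe sim/universe.txt --run-best
listagg evaluate --scenario MixSmall --m 3 --d 1 --methods MAIC,rMixGEO --reps 20 --out eval
```

Datasets travel as line-oriented TSV, one list per line:
`name<TAB>category<TAB>RANKED|UNRANKED<TAB>entity1<TAB>entity2...`.

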