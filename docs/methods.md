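# Methods

This note records the models and procedures `listagg` implements, the
defaults and why they were chosen, the numerical conventions, and what
the synthetic benchmark does and does not establish.

## Generative model for synthetic collections

A collection is simulated over a universe of `n_entities` entities
(default 20 000, human-genome scale), of which `n_signal` (default 1000,
i.e. the top 5%) are *signal*: entity k at signal rank k has significance
μ_k > 0, all other entities μ = 0. The truth ranking is the signal
entities by decreasing μ_k; the truth set is the same 1000 entities
unordered.

Each source list i draws:

1. a noise scale σ_i with ln σ_i ~ Normal(ln M, D²). M is the mean noise
   scale; D the *heterogeneity of quality* — at D = 0 every list has the
   same reliability, at D = 3 the collection mixes near-noiseless and
   purely random sources.
2. scores Z_ki ~ Normal(μ_k, σ_i²) for every entity, ranked decreasingly
   (exact ties, a measure-zero event, break by entity id);
3. a reporting length N_i = min(⌊C_i⌋ + L, U) with
   ln C_i ~ Normal(ln m_c, D_c²). The log-scale draw makes length
   perturbations proportionally larger for short lists, matching how a
   50-gene difference matters for a 100-gene list but not a 19 000-gene
   one;
4. removal of X = ⌊γ(n_entities − N_i)⌋ entities uniformly at random
   (entities the study never assayed — these can include top-ranked
   entities), then truncation to the top N_i survivors (bottom-ranked
   genes not reported);
5. a RANKED or UNRANKED label. Unranked lists keep their membership but
   discard order.

### Parameter defaults and rationale

| parameter | default | meaning |
|---|---|---|
| `n_entities` | 20 000 | universe (human genome scale) |
| `n_signal` | 1000 | signal entities (top 5%) |
| `M` | 3 | mean noise scale; M = 3 is the classic benchmark case |
| `D` | 1 | sd of ln σ across lists; grid {0.1, 1, 3} spans low→high heterogeneity |
| `m_c`, `D_c` | 300, 1 | median cutting point and its log-sd: typical reported lists of a few hundred genes with heavy length spread |
| `L`, `U` | 50, 20 000 | hard length bounds |
| `gamma` | 0 | absent-entity rate; 0.3 exercises the removal path |
| `mu_profile`, `mu_max` | linear, 3 | μ_k = μ_max·(1 − (k−1)/n_signal): strictly decreasing so top signal entities are genuinely easier than marginal ones; at M = 3 the top of the list has signal-to-noise ≈ 1. Exponential and step profiles are pluggable alternatives. |

Two conventions deserve explicit statement:

- **D is the standard deviation of ln σ**, not its variance. The
  `d_is_variance` flag flips this; the choice only rescales the D axis,
  never the qualitative behaviour.
- **Which entity ids carry signal is a seeded random draw.** If signal
  ids were lexicographically first, the deterministic entity-id tie-break
  used in final rankings would silently favour signal entities and
  inflate measured accuracy.

Randomness uses numpy's PCG64 with one `SeedSequence((seed, stream))`
per list (stream = list index, stream 0 reserved for the signal
shuffle), so datasets are bit-reproducible across platforms and a Rank
scenario regenerates byte-identical ranked lists from the same seed as
its Mix counterpart (ranked lists occupy the first streams).

Scenario presets fix the list composition: MixLarge = 11 ranked + 21
unranked sources, MixSmall = 4 + 2, RankLarge/RankSmall = the ranked
subsets. Each list receives its own category.

## Rank representation

All rank-consuming methods share one convention: the *normalized rank*
of an entity in a list is its effective rank divided by the universe
size, in (0, 1]; entities absent from a list are imputed at 1.0, the
worst possible value. A RANKED list of length n contributes ranks 1..n;
an UNRANKED list contributes the half-length rank n/2 (kept fractional
for odd n) for every member — the "Mix" adaptation that lets Borda and
Stuart consume unranked lists. Normalizing by universe size rather than
list length keeps partial lists over a fixed universe comparable.

## Aggregation methods

- **Borda (rMEAN/rMED/rGEO and Mix variants)** — arithmetic mean, median
  or geometric mean of each entity's normalized-rank row; ascending.
- **Stuart / MixStuart** — the exact joint probability that n
  independent uniform order statistics fall below the entity's sorted
  ranks, via the alternating recursion V_k = Σ_j (−1)^(j−1) V_{k−j}
  r_(n−k+1)^j / j!, score n!·V_n. Computed densely in float64; the
  smallest scores that arise (≈ (1/20000)^32 · 32!) stay far above the
  underflow threshold, and scores are used only for ordering.
- **RRA** — ρ = min_k P(Beta(k, n−k+1) ≤ r_(k)) with Bonferroni
  correction min(1, n·ρ); `scipy.stats.beta` supplies the CDFs.
- **MC3** — random walk over the entities of the ranked lists: from i,
  pick a list containing i uniformly, a candidate j uniformly within it,
  and move iff the list prefers j; mixed with uniform teleportation
  (default 0.05). The stationary distribution is found by power
  iteration (tolerance 1e−10, cap 1e5 sweeps) using per-list suffix
  sums, O(total list length) per sweep, so genome-scale chains stay
  cheap; a dense transition-matrix builder exists purely as a test
  oracle. Entities in no ranked list are appended after the chain's
  support in id order.
- **BIRRA** — iterative empirical Bayes: take the top 5% of the current
  aggregate as provisional positives; per list, bin normalized ranks
  (50 equal-width bins) and score each bin by the add-one-smoothed log
  likelihood ratio of positives to negatives, monotonized non-increasing
  from the best bin by a suffix cumulative maximum *over occupied bins
  only* — empty bins receive no gene, and their smoothing-only odds
  would otherwise leak into real bins and flatten the per-list signal;
  an entity's score is its bin log-odds summed over lists. Iterate to a
  ranking fixed point (cap 20).
- **MAIC** — iterative information-content weighting. Entity score
  s(g) = Σ over source categories of max{w_l · f_l(position of g in l)}
  within the category (the max stops near-duplicate sources from double
  counting); list weight w_l = √(mean s over members); f_l for ranked
  lists is an isotonic non-increasing fit (PAV via
  `scipy.optimize.isotonic_regression`) of current member scores against
  list position, normalized to mean 1, and f ≡ 1 for unranked lists.
  Weights are rescaled by their maximum each iteration (a pure gauge
  choice — orderings, not weight magnitudes, are the contract);
  convergence when the largest weight change is below 1e−4, cap 100
  iterations, non-convergence returned flagged rather than raised. These
  update equations are a reconstruction validated by behaviour —
  symmetry, duplicate-list invariance, and recovery of the true 1/σ_i
  ordering on simulated data — not by line-by-line equality with any
  other implementation.
- **VC** (vote counting) — number of lists containing the entity.
- **RepeatChoice** — reads each list as a ranking-with-ties (unranked
  members as one tie block above the absent block), seeds the order from
  the first list and refines residual tie blocks with each subsequent
  list; inherently list-order dependent.

**Tie handling.** Every final ranking is a deterministic total order:
stable sort on the method's score with the entity id as the last key.
Methods whose scores are inherently coarse — vote counts, BIRRA's binned
odds, MAIC's category-max sums — insert the mean normalized rank as a
secondary key first. Without it, piecewise-constant scores would leave
blocks at the top-1000 boundary ordered arbitrarily by id, and even a
noiseless collection would not be scored perfectly; with it, the
noiseless limit is exact for every method. `tie_note` on each result
records the keys used.

BiGbottom, BiGNA, BARD and BARC (Bayesian Gibbs-sampling aggregators)
are recognized by the registry and the selector but intentionally not
implemented; requesting them raises a dedicated error naming
alternatives.

## Evaluation

accuracy@k = |top-k(result) ∩ top-k(truth ranking)| / k; recall@k =
|top-k(result) ∩ truth set| / |truth set|. The two coincide when the
truth set equals the truth ranking's top-k. Results shorter than k keep
denominator k (recorded convention). Replicated experiments regenerate
the dataset with seed = base_seed + r so all methods see identical
inputs per replicate; a method failing on a replicate is recorded as
missing, never silently dropped. The 95% interval is the normal
approximation mean ± 1.96·sd/√n over replicate values — with coverage
rates in [0, 1] and ≥ 20 replicates this is adequate and matches the
usual line-plus-shading presentation. Benchmark properties in the test
suite use 20 replicates (the library exposes `n_reps`; published-scale
runs typically use 100): at 20 replicates the CI half-widths on
accuracy@1000 are ≈ 0.005–0.05, small against the method gaps being
tested.

## Method selection

The selector maps three observable properties to a recommendation:

| unranked present | size | heterogeneity | recommend |
|---|---|---|---|
| yes | any | high | MAIC |
| yes | any | low | MAIC, rMixGEO |
| no | large | high | BIRRA |
| no | large | low | rGEO, BiGbottom, MAIC, rMEAN, MC3 |
| no | small | high | BiGbottom (unavailable here; MAIC/BIRRA match it at a top-1000 cutoff) |
| no | small | low | rGEO, MC3, BiGbottom |

"Large" means ≥ `large_threshold` lists (default 10: it separates
4–6-source collections from 11+-source ones). Heterogeneity is inferred
by running MAIC and taking the coefficient of variation of its final
list weights — scale-free, hence independent of the weight gauge; the
default high threshold of 0.5 sits between the scores observed on
simulated D = 0.1 collections (≈ 0.04) and D = 3 collections (≈ 0.5–0.55),
and `calibrate_het_threshold` re-places it for a specific collection
shape as the midpoint of matched low/high-heterogeneity simulated score
means. The Mix rows do not split by size: the same two methods lead both
mixed-collection sizes.

## What the benchmark does and does not show

The simulator reproduces the features that drive method differences on
real collections — genome-scale universes, log-normal list lengths,
heterogeneous source quality, unranked evidence, never-assayed genes —
but not others: no correlation structure among signal genes beyond the
shared μ profile, no study-specific biases (platform effects, citation
lag), and entity ids carry no biology. Passing the benchmark therefore
shows a method handles noise, truncation, heterogeneity and mixed rank
information correctly; it does not certify performance on any particular
real dataset.

The noiseless-limit check (every method scores accuracy@1000 = 1.0 at
M = 10⁻⁹, D = 0, γ = 0) is run with lists long enough to cover the
signal (m_c = 2000, D_c = 0): truncated lists cannot reveal entities no
source reports, so with default lengths the bound is set by coverage,
not by method correctness, and the check would be uninformative.

## Degenerate inputs and numerical notes

- Empty lists, duplicate entities within a list, duplicate list names
  and entities outside the universe are hard errors at construction.
- BIRRA reduces its bin count with a warning when the universe is
  smaller than the bin grid; it requires ≥ 2 ranked lists, MC3 ≥ 1
  ranked list, Mix-less Borda/Stuart/RRA ≥ 1 ranked list.
- Stuart's alternating recursion loses relative precision near score 1,
  harmless for ordering; scores are clipped to [0, 1].
- MC3's power iteration is exactly mass-preserving per sweep; the
  teleportation floor guarantees a unique stationary distribution.
- `sample_cut_length` guards exp-overflow at extreme D_c by capping
  ln C at 700 (min-clipping against U makes the cap inactive in any
  realistic setting).

## Known limitations

- MAIC and BIRRA internals are reconstructions (see above); their
  absolute scores are not comparable to other implementations even
  where orderings agree.
- The selector's heterogeneity threshold is calibrated on this
  simulator; collections whose quality variation has a very different
  shape (e.g. bimodal with many tied duplicates) may need
  `calibrate_het_threshold` or a manual label.
- Recall-based evaluation of real collections is supported by the API
  (`recall_at_k`, truth-set files) but no real datasets ship with the
  package.
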