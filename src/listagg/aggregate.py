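"""Rank aggregation methods for collections of ranked and unranked lists.

All methods consume a :class:`~listagg.core.Dataset` and return an
:class:`~listagg.core.AggregationResult`. Methods fall into two families:

* ranked-only methods (``rMEAN``/``rMED``/``rGEO``, ``Stuart``, ``RRA``,
  ``MC3``, ``BIRRA``) silently drop UNRANKED lists, emulating how these
  algorithms are used in practice when unranked sources are available;
* unranked-capable methods (``VC``, ``RepeatChoice``, ``MAIC``) and the
  "Mix" adaptations (``rMixMEAN``/``rMixMED``/``rMixGEO``, ``MixStuart``)
  which admit an unranked list by assigning all its members the same
  effective rank, half the list length.

The shared rank representation is a dense matrix of normalized ranks:
``effective_rank / |universe|`` in ``(0, 1]``, with entities absent from a
list imputed at 1.0 (the worst possible rank). This single convention
makes partial lists over a common universe comparable across methods.

Final rankings break exact score ties deterministically: methods whose
scores are coarse (vote counts, binned odds, category-max weights) use the
mean normalized rank as a secondary key, and every method uses the entity
id as the last key.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import isotonic_regression

from .core import AggregationResult, Dataset, GeneList, effective_ranks

__all__ = [
    "RankMatrix",
    "build_rank_matrix",
    "borda",
    "vote_counting",
    "repeat_choice",
    "rra",
    "stuart",
    "mc3",
    "birra",
    "maic",
    "run_method",
    "available_methods",
    "AggregationError",
    "ConvergenceError",
    "UnknownMethodError",
    "UnavailableMethodError",
]


class AggregationError(ValueError):
    """Input unusable for the requested method."""


class ConvergenceError(RuntimeError):
    """Iterative scheme failed to converge within its iteration cap."""


class UnknownMethodError(KeyError):
    """Method name not in the registry."""


class UnavailableMethodError(NotImplementedError):
    """Method recognized by the registry but not provided by this package."""


@dataclass(frozen=True)
class RankMatrix:
    """Dense normalized-rank matrix: entities x lists, values in (0, 1].

    ``values[i, j]`` is the effective rank of entity *i* in list *j*
    divided by the universe size; entities absent from a list hold the
    imputed worst rank 1.0 (flagged in ``imputed``).
    """

    entities: np.ndarray  # sorted entity ids, shape (G,)
    list_names: tuple[str, ...]
    values: np.ndarray  # shape (G, n_lists)
    imputed: np.ndarray  # bool, shape (G, n_lists)

    @property
    def n_lists(self) -> int:
        return len(self.list_names)


def _usable_lists(dataset: Dataset, include_unranked: bool) -> tuple[GeneList, ...]:
    if include_unranked:
        return dataset.lists
    return dataset.ranked_lists()


def build_rank_matrix(dataset: Dataset, include_unranked: bool = True) -> RankMatrix:
    """Assemble the normalized-rank matrix of a dataset.

    RANKED columns carry positions ``1..n`` divided by the universe size;
    UNRANKED columns (when included) carry ``n/2`` divided by the universe
    size for every member; absent entities are imputed at 1.0.
    """
    lists = _usable_lists(dataset, include_unranked)
    entities = np.array(sorted(dataset.universe))
    index = {e: i for i, e in enumerate(entities)}
    g = len(entities)
    values = np.ones((g, len(lists)))
    imputed = np.ones((g, len(lists)), dtype=bool)
    for j, gl in enumerate(lists):
        for e, r in effective_ranks(gl).items():
            i = index[e]
            values[i, j] = r / g
            imputed[i, j] = False
    return RankMatrix(
        entities=entities,
        list_names=tuple(gl.name for gl in lists),
        values=values,
        imputed=imputed,
    )


def _mean_rank_key(dataset: Dataset, entities: np.ndarray, include_unranked: bool) -> np.ndarray:
    """Mean normalized rank per entity, used as a deterministic tie-break key."""
    lists = _usable_lists(dataset, include_unranked)
    if not lists:
        return np.ones(len(entities))
    mat = build_rank_matrix(
        Dataset(lists=lists, universe=frozenset(entities.tolist())),
        include_unranked=include_unranked,
    )
    return mat.values.mean(axis=1)


def _rank_entities(
    entities: np.ndarray,
    scores: np.ndarray,
    higher_is_better: bool,
    secondary: np.ndarray | None = None,
) -> tuple[str, ...]:
    """Total order: primary score, optional secondary key, entity id last."""
    primary = -scores if higher_is_better else scores
    keys = [entities]
    if secondary is not None:
        keys.append(secondary)
    keys.append(primary)
    order = np.lexsort(tuple(keys))
    return tuple(entities[order].tolist())


def _result(
    dataset: Dataset,
    method: str,
    entities: np.ndarray,
    scores: np.ndarray,
    higher_is_better: bool,
    used_unranked: bool,
    secondary: np.ndarray | None = None,
    tie_note: str | None = None,
    **kwargs,
) -> AggregationResult:
    if tie_note is None:
        tie_note = (
            "ties broken by mean normalized rank, then entity id"
            if secondary is not None
            else "ties broken by entity id"
        )
    return AggregationResult(
        ranking=_rank_entities(entities, scores, higher_is_better, secondary),
        scores=dict(zip(entities.tolist(), scores.tolist())),
        method=method,
        higher_is_better=higher_is_better,
        tie_note=tie_note,
        used_unranked=used_unranked,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Borda family


_BORDA_STATS = ("MEAN", "MED", "GEO")


def borda(dataset: Dataset, stat: str = "GEO", mix: bool = False) -> AggregationResult:
    """Borda consensus by a row statistic of the normalized-rank matrix.

    ``stat`` selects the arithmetic mean (MEAN), median (MED) or geometric
    mean (GEO) of each entity's normalized ranks; lower is better. With
    ``mix=True`` unranked lists enter via the half-length rank rule
    (methods rMixMEAN/rMixMED/rMixGEO); otherwise they are dropped.
    """
    stat = stat.upper()
    if stat not in _BORDA_STATS:
        raise ValueError(f"stat must be one of {_BORDA_STATS}, got {stat!r}")
    if not _usable_lists(dataset, mix):
        raise AggregationError(
            f"borda(mix={mix}) has no usable lists: dataset holds "
            f"{len(dataset)} lists, {len(dataset.ranked_lists())} ranked"
        )
    mat = build_rank_matrix(dataset, include_unranked=mix)
    if stat == "MEAN":
        scores = mat.values.mean(axis=1)
    elif stat == "MED":
        scores = np.median(mat.values, axis=1)
    else:
        scores = np.exp(np.log(mat.values).mean(axis=1))
    name = f"rMix{stat}" if mix else f"r{stat}"
    return _result(
        dataset, name, mat.entities, scores, higher_is_better=False,
        used_unranked=mix and dataset.has_unranked,
    )


# ---------------------------------------------------------------------------
# Vote counting and RepeatChoice


def vote_counting(dataset: Dataset) -> AggregationResult:
    """Score each entity by the number of lists (ranked or unranked) containing it."""
    if len(dataset) == 0:
        raise AggregationError("vote_counting needs at least one list")
    entities = np.array(sorted(dataset.universe))
    index = {e: i for i, e in enumerate(entities)}
    counts = np.zeros(len(entities))
    for gl in dataset.lists:
        for e in gl.entities:
            counts[index[e]] += 1
    secondary = _mean_rank_key(dataset, entities, include_unranked=False)
    return _result(
        dataset, "VC", entities, counts, higher_is_better=True,
        used_unranked=dataset.has_unranked, secondary=secondary,
        tie_note="ties broken by mean normalized rank over ranked lists, then entity id",
    )


def repeat_choice(dataset: Dataset) -> AggregationResult:
    """Sequential tie refinement starting from the first list.

    Each list is read as a ranking-with-ties over the universe: a RANKED
    list contributes its order followed by one block of absent entities;
    an UNRANKED list contributes one tie block of members above the
    absent block. The first list seeds the order; each subsequent list
    splits every residual tie block by its own ranking; leftover ties are
    broken by entity id.
    """
    if len(dataset) == 0:
        raise AggregationError("repeat_choice needs at least one list")
    universe = sorted(dataset.universe)

    def key_fn(gl: GeneList) -> dict[str, float]:
        if gl.is_ranked:
            return {e: float(i) for i, e in enumerate(gl.entities)}
        return {e: 0.0 for e in gl.entities}

    blocks: list[list[str]] = [list(universe)]
    for gl in dataset.lists:
        keys = key_fn(gl)
        absent = float(len(gl)) + 1.0
        new_blocks: list[list[str]] = []
        for block in blocks:
            if len(block) == 1:
                new_blocks.append(block)
                continue
            groups: dict[float, list[str]] = {}
            for e in block:
                groups.setdefault(keys.get(e, absent), []).append(e)
            for k in sorted(groups):
                new_blocks.append(groups[k])
        blocks = new_blocks
    ranking: list[str] = []
    for block in blocks:
        ranking.extend(sorted(block))
    entities = np.array(ranking)
    # position in the final order doubles as the (lower-is-better) score
    scores = np.arange(1, len(ranking) + 1, dtype=float)
    return AggregationResult(
        ranking=tuple(ranking),
        scores=dict(zip(ranking, scores.tolist())),
        method="RepeatChoice",
        higher_is_better=False,
        tie_note="residual ties broken by entity id",
        used_unranked=dataset.has_unranked,
    )


# ---------------------------------------------------------------------------
# Order-statistic methods: RRA and Stuart


def _sorted_rank_rows(dataset: Dataset, mix: bool, method: str) -> tuple[RankMatrix, np.ndarray]:
    if not _usable_lists(dataset, mix):
        raise AggregationError(f"{method}(mix={mix}) has no usable lists")
    mat = build_rank_matrix(dataset, include_unranked=mix)
    return mat, np.sort(mat.values, axis=1)


def rra(dataset: Dataset, mix: bool = False) -> AggregationResult:
    """Robust rank aggregation via minimum Beta order-statistic p-values.

    For each entity with sorted normalized ranks ``r_(1) <= ... <= r_(n)``
    over the *n* usable lists (absent = 1.0), the k-th order statistic of
    n independent uniforms has a Beta(k, n-k+1) law; the score is the
    Bonferroni-corrected minimum over k of ``P(Beta(k, n-k+1) <= r_(k))``.
    Lower is better.
    """
    mat, sorted_r = _sorted_rank_rows(dataset, mix, "rra")
    n = mat.n_lists
    k = np.arange(1, n + 1)
    p = stats.beta.cdf(sorted_r, k[None, :], (n - k + 1)[None, :])
    rho = p.min(axis=1)
    scores = np.minimum(1.0, n * rho)
    name = "MixRRA" if mix else "RRA"
    return _result(
        dataset, name, mat.entities, scores, higher_is_better=False,
        used_unranked=mix and dataset.has_unranked,
    )


def stuart_scores(sorted_r: np.ndarray) -> np.ndarray:
    """Joint upper-tail order-statistic probability, row-wise.

    For each row of sorted normalized ranks ``r_(1) <= ... <= r_(n)``,
    returns ``P(U_(1) <= r_(1), ..., U_(n) <= r_(n))`` for n independent
    uniforms, via the recursion
    ``V_0 = 1, V_k = sum_{j=1..k} (-1)^(j-1) V_{k-j} r_(n-k+1)^j / j!``
    and probability ``n! * V_n``.
    """
    sorted_r = np.atleast_2d(np.asarray(sorted_r, dtype=float))
    g, n = sorted_r.shape
    v = np.zeros((g, n + 1))
    v[:, 0] = 1.0
    for k in range(1, n + 1):
        rk = sorted_r[:, n - k]  # r_(n-k+1), 1-based
        acc = np.zeros(g)
        term = np.ones(g)
        for j in range(1, k + 1):
            term = term * rk / j  # rk**j / j!
            acc += (1.0 if j % 2 else -1.0) * v[:, k - j] * term
        v[:, k] = acc
    return np.clip(math.factorial(n) * v[:, n], 0.0, 1.0)


def stuart(dataset: Dataset, mix: bool = False) -> AggregationResult:
    """Stuart consensus: exact joint probability of the observed rank vector.

    Scores each entity by the probability that n independent uniform order
    statistics all fall below its sorted normalized ranks; lower is
    better. ``mix=True`` admits unranked lists via the half-length rule
    (MixStuart).
    """
    mat, sorted_r = _sorted_rank_rows(dataset, mix, "stuart")
    scores = stuart_scores(sorted_r)
    name = "MixStuart" if mix else "Stuart"
    return _result(
        dataset, name, mat.entities, scores, higher_is_better=False,
        used_unranked=mix and dataset.has_unranked,
    )


# ---------------------------------------------------------------------------
# MC3: Markov-chain aggregation


def mc3(
    dataset: Dataset,
    teleport: float = 0.05,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> AggregationResult:
    """Markov-chain aggregation over the entities of the ranked lists.

    From entity *i*, pick one ranked list containing *i* uniformly, then a
    candidate *j* uniformly from that list; move to *j* iff the list ranks
    *j* above *i*, else stay. The chain is mixed with uniform
    teleportation at rate ``teleport`` and its stationary distribution
    (power iteration to ``tol`` in the max norm) scores the entities;
    higher is better. Entities in no ranked list are appended after the
    chain's support in entity-id order with score 0.
    """
    ranked = dataset.ranked_lists()
    if not ranked:
        raise AggregationError("mc3 needs at least one RANKED list")
    if not (0.0 < teleport < 1.0):
        raise ValueError("teleport must be in (0, 1)")
    support = sorted({e for gl in ranked for e in gl.entities})
    index = {e: i for i, e in enumerate(support)}
    n_states = len(support)
    members = [np.array([index[e] for e in gl.entities]) for gl in ranked]
    deg = np.zeros(n_states)
    for m in members:
        deg[m] += 1.0
    pi = np.full(n_states, 1.0 / n_states)
    base = teleport / n_states
    for iteration in range(1, max_iter + 1):
        w = pi / deg
        nxt = np.zeros(n_states)
        for m in members:
            n_l = len(m)
            wm = w[m]
            # mass moving up: into position p flows (1/N) * sum of w over
            # members ranked strictly below p
            below = np.concatenate(([0.0], np.cumsum(wm[::-1])[:-1]))[::-1]
            stay = wm * (n_l - np.arange(n_l)) / n_l
            nxt[m] += below / n_l + stay
        nxt = (1.0 - teleport) * nxt + base
        if np.max(np.abs(nxt - pi)) < tol:
            pi = nxt
            break
        pi = nxt
    else:
        raise ConvergenceError(
            f"mc3 power iteration did not reach tol={tol} within {max_iter} iterations"
        )
    support_arr = np.array(support)
    order = np.lexsort((support_arr, -pi))
    head = support_arr[order]
    tail = np.array(sorted(dataset.universe - set(support)))
    ranking = tuple(head.tolist()) + tuple(tail.tolist())
    scores = dict(zip(support_arr.tolist(), pi.tolist()))
    scores.update({e: 0.0 for e in tail.tolist()})
    return AggregationResult(
        ranking=ranking,
        scores=scores,
        method="MC3",
        higher_is_better=True,
        tie_note="ties broken by entity id; off-support entities appended by id",
        used_unranked=False,
        extras={"iterations": iteration, "teleport": teleport},
    )


def mc3_transition_matrix(dataset: Dataset, teleport: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Dense transition matrix of the MC3 chain (oracle-sized instances only).

    Returns ``(P, states)`` with ``P[i, j]`` the probability of moving
    from ``states[i]`` to ``states[j]``. Intended for cross-checking the
    iterative solver against a direct eigen-solution on small problems.
    """
    ranked = dataset.ranked_lists()
    support = sorted({e for gl in ranked for e in gl.entities})
    index = {e: i for i, e in enumerate(support)}
    n = len(support)
    p = np.zeros((n, n))
    deg = np.zeros(n)
    for gl in ranked:
        for e in gl.entities:
            deg[index[e]] += 1.0
    for gl in ranked:
        n_l = len(gl)
        idx = [index[e] for e in gl.entities]
        for pos_i, i in enumerate(idx):
            for pos_j, j in enumerate(idx):
                if pos_j < pos_i:
                    p[i, j] += 1.0 / (deg[i] * n_l)
                else:
                    p[i, i] += 1.0 / (deg[i] * n_l)
    p = (1.0 - teleport) * p + teleport / n
    return p, np.array(support)


# ---------------------------------------------------------------------------
# BIRRA: Bayesian iterative reweighting with binned rank odds


def birra(
    dataset: Dataset,
    prior_pi: float = 0.05,
    n_bins: int = 50,
    max_iter: int = 20,
) -> AggregationResult:
    """Iterative empirical-Bayes aggregation over binned normalized ranks.

    Starting from the mean normalized rank, each iteration (1) calls the
    top ``prior_pi`` fraction of the current aggregate "positive", (2)
    computes, per list and per rank bin, the add-one-smoothed log
    likelihood ratio of positives to negatives, monotonized to be
    non-increasing from the best bin, and (3) re-scores every entity by
    the sum of its bin log-odds across lists. Stops when the ranking is a
    fixed point or after ``max_iter`` sweeps. Higher scores are better.
    """
    ranked = dataset.ranked_lists()
    if len(ranked) < 2:
        raise AggregationError(f"birra needs >= 2 RANKED lists, found {len(ranked)}")
    if not (0.0 < prior_pi < 1.0):
        raise ValueError("prior_pi must be in (0, 1)")
    mat = build_rank_matrix(dataset, include_unranked=False)
    g, n_lists = mat.values.shape
    if g < n_bins:
        warnings.warn(
            f"universe of {g} entities is smaller than n_bins={n_bins}; "
            f"reducing to {g} bins",
            stacklevel=2,
        )
        n_bins = g
    bins = np.clip(np.ceil(mat.values * n_bins).astype(int) - 1, 0, n_bins - 1)
    mean_rank = mat.values.mean(axis=1)
    n_pos = max(1, int(round(prior_pi * g)))
    order = np.lexsort((mat.entities, mean_rank))
    scores = -mean_rank  # initial aggregate, higher better
    prev_order = order
    odds_range = np.zeros(n_lists)
    for _ in range(max_iter):
        positive = np.zeros(g, dtype=bool)
        positive[prev_order[:n_pos]] = True
        scores = np.zeros(g)
        for j in range(n_lists):
            pos_counts = np.bincount(bins[positive, j], minlength=n_bins)
            neg_counts = np.bincount(bins[~positive, j], minlength=n_bins)
            log_odds = np.log(
                (pos_counts + 1.0) / (n_pos + n_bins)
            ) - np.log((neg_counts + 1.0) / (g - n_pos + n_bins))
            # non-increasing from the best bin: suffix cumulative maximum
            # over occupied bins only (empty bins receive no gene, and
            # their smoothing-only odds must not leak into real bins)
            occ = (pos_counts + neg_counts) > 0
            mono = np.maximum.accumulate(log_odds[occ][::-1])[::-1]
            log_odds[occ] = mono
            odds_range[j] = mono[0] - mono[-1]
            scores += log_odds[bins[:, j]]
        order = np.lexsort((mat.entities, mean_rank, -scores))
        if np.array_equal(order, prev_order):
            break
        prev_order = order
    return _result(
        dataset, "BIRRA", mat.entities, scores, higher_is_better=True,
        used_unranked=False, secondary=mean_rank,
        extras={"list_log_odds_range": dict(zip(mat.list_names, odds_range.tolist()))},
    )


# ---------------------------------------------------------------------------
# MAIC: iterative information-content weighting


def maic(
    dataset: Dataset,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> AggregationResult:
    """Meta-analysis by information content: iterative list weighting.

    Each list *l* carries a weight ``w_l`` and, if RANKED, a monotone
    non-increasing positional weighting ``f_l`` (an isotonic fit of the
    current entity scores against list position, normalized to mean 1;
    UNRANKED lists use ``f_l = 1``). An entity's score is the sum over
    source categories of the best weighted support within the category,

        s(g) = sum_c max{ w_l * f_l(rank of g in l) : l in c, g in l },

    so duplicated sources in one category cannot double count. Weights
    update as ``w_l = sqrt(mean of s over members of l)`` and are rescaled
    by their maximum (the gauge); iteration stops when the largest weight
    change falls below ``tol``. Higher scores are better; score ties are
    broken by mean normalized rank. Accepts ranked and unranked lists.
    """
    if len(dataset) == 0:
        raise AggregationError("maic needs at least one list")
    entities = np.array(sorted(dataset.universe))
    index = {e: i for i, e in enumerate(entities)}
    g = len(entities)
    lists = dataset.lists
    members = [np.array([index[e] for e in gl.entities]) for gl in lists]
    is_ranked = [gl.is_ranked for gl in lists]
    categories: dict[str, list[int]] = {}
    for li, gl in enumerate(lists):
        categories.setdefault(gl.category, []).append(li)
    n_lists = len(lists)
    w = np.ones(n_lists)
    f: list[np.ndarray | None] = [
        np.ones(len(m)) if r else None for m, r in zip(members, is_ranked)
    ]

    def compute_scores() -> np.ndarray:
        s = np.zeros(g)
        for cat_lists in categories.values():
            if len(cat_lists) == 1:
                li = cat_lists[0]
                contrib = w[li] * (f[li] if is_ranked[li] else 1.0)
                np.add.at(s, members[li], contrib)
            else:
                cat_s = np.zeros(g)
                for li in cat_lists:
                    contrib = w[li] * (f[li] if is_ranked[li] else 1.0)
                    np.maximum.at(cat_s, members[li], contrib)
                s += cat_s
        return s

    converged = False
    scores = compute_scores()
    for _ in range(max_iter):
        # refit positional weightings to the current scores
        for li in range(n_lists):
            if not is_ranked[li]:
                continue
            y = scores[members[li]]
            fit = np.asarray(isotonic_regression(y, increasing=False).x)
            m = fit.mean()
            f[li] = fit / m if m > 0 else np.ones(len(fit))
        new_w = np.array([math.sqrt(max(scores[m].mean(), 0.0)) for m in members])
        top = new_w.max()
        if top > 0:
            new_w = new_w / top
        delta = np.max(np.abs(new_w - w))
        w = new_w
        scores = compute_scores()
        if delta < tol:
            converged = True
            break
    secondary = _mean_rank_key(dataset, entities, include_unranked=True)
    return _result(
        dataset, "MAIC", entities, scores, higher_is_better=True,
        used_unranked=dataset.has_unranked, secondary=secondary,
        list_weights=dict(zip((gl.name for gl in lists), w.tolist())),
        converged=converged,
        extras={"category_count": len(categories)},
    )


# ---------------------------------------------------------------------------
# Registry


_REGISTRY: dict[str, tuple] = {
    "rMEAN": (borda, {"stat": "MEAN", "mix": False}),
    "rMED": (borda, {"stat": "MED", "mix": False}),
    "rGEO": (borda, {"stat": "GEO", "mix": False}),
    "rMixMEAN": (borda, {"stat": "MEAN", "mix": True}),
    "rMixMED": (borda, {"stat": "MED", "mix": True}),
    "rMixGEO": (borda, {"stat": "GEO", "mix": True}),
    "Stuart": (stuart, {"mix": False}),
    "MixStuart": (stuart, {"mix": True}),
    "RRA": (rra, {"mix": False}),
    "VC": (vote_counting, {}),
    "RepeatChoice": (repeat_choice, {}),
    "MC3": (mc3, {}),
    "BIRRA": (birra, {}),
    "MAIC": (maic, {}),
}

# Methods the selector may name but this package does not provide:
# Bayesian Gibbs-sampling aggregators whose update equations are published
# only with their original implementations.
_UNAVAILABLE = ("BiGbottom", "BiGNA", "BARD", "BARC")


def available_methods() -> tuple[str, ...]:
    """Names accepted by :func:`run_method`."""
    return tuple(_REGISTRY)


def run_method(name: str, dataset: Dataset, **params) -> AggregationResult:
    """Dispatch an aggregation method by its registry name.

    Extra keyword arguments are forwarded to the method (overriding the
    registry defaults). Recognized-but-unavailable Bayesian methods raise
    :class:`UnavailableMethodError`; unknown names raise
    :class:`UnknownMethodError` listing the registry.
    """
    if name in _UNAVAILABLE:
        raise UnavailableMethodError(
            f"{name} is a Bayesian Gibbs-sampling aggregator not provided by "
            f"this package; use its original implementation. Nearest available "
            f"alternatives: MAIC, BIRRA."
        )
    try:
        fn, defaults = _REGISTRY[name]
    except KeyError:
        raise UnknownMethodError(
            f"unknown method {name!r}; available: {', '.join(_REGISTRY)}"
        ) from None
    kwargs = {**defaults, **params}
    return fn(dataset, **kwargs)
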