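"""Performance measurement: coverage at top-k cutoffs over replicated runs.

Two coverage measures are provided. ``accuracy_at_k`` compares the top-k
of a result against the top-k of a known truth *ranking* (the simulated
setting, where the truth order is known); ``recall_at_k`` compares the
top-k against an unordered truth *set* (the real-data setting). Both lie
in [0, 1] and coincide when the truth set is exactly the truth ranking's
top-k. ``replicate_experiment`` repeats simulation + aggregation +
measurement over seeds and reports per-cutoff means with normal-
approximation 95% confidence intervals.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import run_method
from .core import AggregationResult
from .simulate import SimulationConfig, generate_dataset

DEFAULT_CUTOFFS = (1, 10, 50, 100, 500, 1000)

#: normal quantile for a two-sided 95% interval
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class EvaluationCurve:
    """Per-cutoff metric means with replicate confidence intervals."""

    cutoffs: tuple[int, ...]
    values: tuple[float, ...]
    ci_half_width: tuple[float, ...]
    n_replicates: int
    replicates: pd.DataFrame  # columns: rep, cutoff, value (NaN = failed rep)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.cutoffs):
            raise ValueError("values and cutoffs must align")
        for v in self.values:
            if not (math.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"metric value outside [0,1]: {v}")

    def at(self, k: int) -> tuple[float, float]:
        """(mean, ci half-width) at cutoff ``k``."""
        i = self.cutoffs.index(k)
        return self.values[i], self.ci_half_width[i]


def accuracy_at_k(
    result: AggregationResult, truth_ranking: Sequence[str], k: int
) -> float:
    """Overlap of the result's top-k with the truth ranking's top-k, over k.

    If the truth ranking holds fewer than ``k`` entries, its whole order
    is used; if the result is shorter than ``k``, the available head is
    compared but the denominator stays ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    top_true = set(truth_ranking[:k])
    top_res = set(result.top(k))
    return len(top_true & top_res) / k


def recall_at_k(result: AggregationResult, truth_set: Iterable[str], k: int) -> float:
    """Fraction of the truth set recovered in the result's top-k."""
    truth = set(truth_set)
    if not truth:
        raise ValueError("truth_set must be non-empty")
    return len(truth & set(result.top(k))) / len(truth)


def replicate_experiment(
    cfg: SimulationConfig,
    methods: Sequence[str],
    n_reps: int = 20,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    base_seed: int = 0,
    method_params: dict[str, dict] | None = None,
) -> dict[str, EvaluationCurve]:
    """Replicate simulation + aggregation and measure accuracy per cutoff.

    Replicate *r* regenerates the dataset with ``seed = base_seed + r``
    and runs every method on it, so methods are compared on identical
    inputs. A method failing on one replicate is recorded as missing
    (NaN) for that replicate, not dropped silently. The 95% CI is the
    normal approximation ``mean +/- 1.96 * sd / sqrt(n)`` over replicate
    values.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    cutoffs = tuple(int(k) for k in cutoffs)
    method_params = method_params or {}
    rows: dict[str, list[dict]] = {m: [] for m in methods}
    for r in range(n_reps):
        sim = generate_dataset(dataclasses.replace(cfg, seed=base_seed + r))
        for m in methods:
            try:
                res = run_method(m, sim.dataset, **method_params.get(m, {}))
                vals = {k: accuracy_at_k(res, sim.truth_ranking, k) for k in cutoffs}
            except Exception as exc:  # recorded, not dropped
                vals = {k: float("nan") for k in cutoffs}
                rows[m].append(
                    {"rep": r, "cutoff": cutoffs[0], "value": float("nan"),
                     "error": f"{type(exc).__name__}: {exc}"}
                )
                continue
            for k in cutoffs:
                rows[m].append({"rep": r, "cutoff": k, "value": vals[k], "error": ""})
    out: dict[str, EvaluationCurve] = {}
    for m in methods:
        df = pd.DataFrame(rows[m], columns=["rep", "cutoff", "value", "error"])
        means, halves = [], []
        for k in cutoffs:
            vals = df.loc[df["cutoff"] == k, "value"].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                means.append(float("nan"))
                halves.append(float("nan"))
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            means.append(min(1.0, max(0.0, mean)))
            halves.append(_Z95 * sd / math.sqrt(len(vals)))
        out[m] = EvaluationCurve(
            cutoffs=cutoffs,
            values=tuple(means),
            ci_half_width=tuple(halves),
            n_replicates=n_reps,
            replicates=df,
        )
    return out


def curves_to_frame(curves: dict[str, EvaluationCurve]) -> pd.DataFrame:
    """Summary table: one row per (method, cutoff) with mean and CI."""
    rows = []
    for m, c in curves.items():
        for k, v, h in zip(c.cutoffs, c.values, c.ci_half_width):
            rows.append(
                {"method": m, "cutoff": k, "mean": v, "ci_half_width": h,
                 "n_replicates": c.n_replicates}
            )
    return pd.DataFrame(rows)


def plot_curves(curves: dict[str, EvaluationCurve], ax=None, title: str | None = None):
    """Line-plus-shading plot of accuracy curves (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for m, c in curves.items():
        x = np.array(c.cutoffs)
        y = np.array(c.values)
        h = np.array(c.ci_half_width)
        ax.plot(x, y, marker="o", label=m)
        ax.fill_between(x, np.clip(y - h, 0, 1), np.clip(y + h, 0, 1), alpha=0.2)
    ax.set_xscale("log")
    ax.set_xlabel("cutoff k")
    ax.set_ylabel("accuracy@k")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return ax
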