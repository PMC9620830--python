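"""Stochastic generator of realistic ranked/unranked gene-list collections.

The generative model emulates collections of genomic screen results at
human-genome scale. A universe of ``n_entities`` entities (default 20 000)
contains ``n_signal`` signal entities (default 1000, i.e. the top 5%) with
positive significance ``mu_k``; all other entities have ``mu_k = 0``. Each
source list *i* observes a noisy score for every entity,

    Z_ki ~ Normal(mu_k, sigma_i^2),      ln(sigma_i) ~ Normal(ln M, D^2)

so *M* sets the mean noise scale and *D* the heterogeneity of quality
across sources (how much lists differ in reliability). Entities are ranked
by decreasing ``Z_ki``; a per-list reporting length

    N_i = min(floor(C_i) + L, U),        ln(C_i) ~ Normal(ln m_c, D_c^2)

is drawn on a log scale (a 100-entity difference matters near the top of a
list, not near the bottom). A fraction ``gamma`` of never-assayed entities,
``X = floor(gamma * (n_entities - N_i))``, is first removed uniformly at
random; the list is then truncated to its top ``N_i`` remaining entities
and labelled RANKED or UNRANKED.

Four scenario presets mirror the structure of real collections: Mix/Rank
(with/without unranked sources) crossed with Large/Small (many/few
sources). A Mix preset and its Rank counterpart generated from the same
seed share byte-identical ranked lists, isolating the effect of adding
unranked sources.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Dataset, GeneList, ListKind, write_dataset

SCENARIOS = ("MixLarge", "MixSmall", "RankLarge", "RankSmall")

# Ranked/unranked source counts per scenario, mirroring the composition of
# real collections: Large = a virus-scale collection (11 ranked + 21
# unranked), Small = a bacterial-infection-scale collection (4 ranked + 2
# unranked). Rank scenarios keep exactly the ranked lists of the matching
# Mix scenario.
_SCENARIO_COUNTS: dict[str, tuple[int, int]] = {
    "MixLarge": (11, 21),
    "MixSmall": (4, 2),
    "RankLarge": (11, 0),
    "RankSmall": (4, 0),
}

_MU_STREAM = 0  # sub-stream index reserved for the signal-entity shuffle


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model.

    Parameters
    ----------
    n_entities, n_signal
        Universe size and number of signal entities (positive ``mu_k``).
    M, D
        Mean noise scale and heterogeneity of quality: ``ln sigma_i ~
        Normal(ln M, D^2)`` (``D`` is the standard deviation of the log
        noise scale; set ``d_is_variance`` to treat it as the variance).
    m_c, D_c
        Mean and log-scale spread of the cutting point ``C_i``.
    L, U
        Hard bounds on list length; ``N_i = min(floor(C_i) + L, U)``.
    gamma
        Absent-entity rate: fraction of the ``n_entities - N_i``
        non-reported slots removed uniformly at random before truncation,
        emulating entities a study never assayed.
    mu_profile, mu_max
        Shape of the significance curve over signal entities. ``"linear"``
        decays from ``mu_max`` to ``mu_max/n_signal``; ``"exponential"``
        decays as ``mu_max * exp(-3(k-1)/n_signal)``; ``"step"`` gives all
        signal entities ``mu_max``.
    list_specs
        One ``(category, kind)`` pair per list to generate.
    seed
        Master seed; every random stream derives from it.
    """

    n_entities: int = 20_000
    n_signal: int = 1000
    M: float = 3.0
    D: float = 1.0
    m_c: float = 300.0
    D_c: float = 1.0
    L: int = 50
    U: int = 20_000
    gamma: float = 0.0
    mu_profile: str = "linear"
    mu_max: float = 3.0
    d_is_variance: bool = False
    list_specs: tuple[tuple[str, ListKind], ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.L <= self.U <= self.n_entities):
            raise ValueError(f"need 1 <= L <= U <= n_entities, got L={self.L} U={self.U}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0,1], got {self.gamma}")
        if self.n_signal > self.n_entities:
            raise ValueError("n_signal cannot exceed n_entities")
        if self.M <= 0 or self.m_c <= 0:
            raise ValueError("M and m_c must be positive")
        if self.D < 0 or self.D_c < 0:
            raise ValueError("D and D_c must be non-negative")
        object.__setattr__(
            self,
            "list_specs",
            tuple((c, ListKind(k)) for c, k in self.list_specs),
        )

    @property
    def log_sigma_sd(self) -> float:
        return math.sqrt(self.D) if self.d_is_variance else self.D

    def entity_ids(self) -> np.ndarray:
        width = max(5, len(str(self.n_entities)))
        return np.array([f"E{i:0{width}d}" for i in range(1, self.n_entities + 1)])


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated dataset together with its ground truth and latents."""

    dataset: Dataset
    truth_ranking: tuple[str, ...]
    truth_set: frozenset[str]
    per_list_sigma: dict[str, float]
    per_list_cut: dict[str, int]
    config: SimulationConfig


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # One independent, platform-stable PCG64 stream per (seed, stream).
    return np.random.default_rng(np.random.SeedSequence((int(cfg.seed), int(stream))))


def assign_entity_means(cfg: SimulationConfig) -> dict[str, float]:
    """Assign the significance curve ``mu_k`` over the universe.

    Exactly ``n_signal`` entities get strictly decreasing positive means;
    all others get 0. Which entity ids carry signal is a seeded random
    draw (not the lexicographically first ids), so deterministic
    entity-id tie-breaking downstream cannot favour signal entities.
    Deterministic given the config.
    """
    ids, mu = _entity_means_arrays(cfg)
    return dict(zip(ids.tolist(), mu.tolist()))


def _entity_means_arrays(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    ids = cfg.entity_ids()
    k = np.arange(1, cfg.n_signal + 1, dtype=float)
    if cfg.mu_profile == "linear":
        profile = cfg.mu_max * (1.0 - (k - 1.0) / cfg.n_signal)
    elif cfg.mu_profile == "exponential":
        profile = cfg.mu_max * np.exp(-3.0 * (k - 1.0) / cfg.n_signal)
    elif cfg.mu_profile == "step":
        # constant signal strength; ties in mu are broken by an
        # infinitesimal decay so the truth ranking stays a total order
        profile = cfg.mu_max * (1.0 - 1e-9 * (k - 1.0))
    else:
        raise ValueError(f"unknown mu_profile {cfg.mu_profile!r}")
    signal_idx = _rng(cfg, _MU_STREAM).choice(cfg.n_entities, size=cfg.n_signal, replace=False)
    mu = np.zeros(cfg.n_entities)
    mu[signal_idx] = profile
    return ids, mu


def sample_sigma(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    """Draw one per-list noise scale: ``ln sigma ~ Normal(ln M, sd)``."""
    return float(np.exp(rng.normal(math.log(cfg.M), cfg.log_sigma_sd)))


def sample_cut_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    """Draw one reporting length ``N_i = min(floor(C_i) + L, U)``."""
    log_c = rng.normal(math.log(cfg.m_c), cfg.D_c)
    c = math.exp(min(log_c, 700.0))  # guard exp overflow at extreme D_c
    return int(min(math.floor(c) + cfg.L, cfg.U))


def removal_count(cfg: SimulationConfig, n_i: int) -> int:
    """Number of entities removed at random before truncation:
    ``X = floor(gamma * (n_entities - N_i))``."""
    return int(math.floor(cfg.gamma * (cfg.n_entities - n_i)))


def generate_list(
    cfg: SimulationConfig,
    mu: np.ndarray,
    category: str,
    kind: ListKind,
    rng: np.random.Generator,
    name: str,
    ids: np.ndarray | None = None,
) -> tuple[GeneList, float, int]:
    """Generate one source list; returns ``(list, sigma_i, N_i)``.

    Steps: draw ``sigma_i``; draw ``Z_ki`` for every entity; rank by
    decreasing ``Z``; draw ``N_i``; remove ``X = floor(gamma *
    (n_entities - N_i))`` entities uniformly at random; truncate to the
    top ``N_i`` survivors; label with ``kind``.
    """
    if ids is None:
        ids = cfg.entity_ids()
    sigma = sample_sigma(cfg, rng)
    z = rng.normal(loc=mu, scale=sigma)
    # decreasing Z; exact ties (measure zero) broken by entity id
    order = np.lexsort((ids, -z))
    n_i = sample_cut_length(cfg, rng)
    x = removal_count(cfg, n_i)
    if x > 0:
        removed = rng.choice(cfg.n_entities, size=x, replace=False)
        keep = np.ones(cfg.n_entities, dtype=bool)
        keep[removed] = False
        order = order[keep[order]]
    top = ids[order[:n_i]]
    entities = tuple(top.tolist())
    return GeneList(name=name, category=category, kind=kind, entities=entities), sigma, n_i


def generate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate the full dataset described by ``cfg``.

    Each list uses its own random stream keyed by ``(seed, index)``, so a
    Rank scenario regenerates byte-identical ranked lists from the same
    seed as its Mix counterpart (whose ranked lists come first).
    """
    if not cfg.list_specs:
        raise ValueError("config has no list_specs; nothing to generate")
    ids, mu = _entity_means_arrays(cfg)
    lists: list[GeneList] = []
    sigmas: dict[str, float] = {}
    cuts: dict[str, int] = {}
    for i, (category, kind) in enumerate(cfg.list_specs):
        name = f"list{i + 1:02d}"
        gl, sigma, n_i = generate_list(
            cfg, mu, category, kind, _rng(cfg, i + 1), name, ids=ids
        )
        lists.append(gl)
        sigmas[name] = sigma
        cuts[name] = n_i
    signal = mu > 0
    order = np.lexsort((ids[signal], -mu[signal]))
    truth_ranking = tuple(ids[signal][order].tolist())
    dataset = Dataset.from_lists(lists, universe=ids.tolist())
    return SimulatedDataset(
        dataset=dataset,
        truth_ranking=truth_ranking,
        truth_set=frozenset(truth_ranking),
        per_list_sigma=sigmas,
        per_list_cut=cuts,
        config=cfg,
    )


def preset(
    scenario: str,
    M: float = 3.0,
    D: float = 1.0,
    gamma: float = 0.0,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Config for one of the four scenario types.

    ``MixLarge``/``RankLarge`` emulate a many-source collection (11 ranked
    + 21 unranked / the same 11 ranked); ``MixSmall``/``RankSmall`` a
    few-source collection (4 ranked + 2 unranked / the same 4 ranked).
    Ranked lists come first in ``list_specs`` so Mix and Rank datasets
    from one seed share identical ranked lists. Extra keyword overrides
    are forwarded to :class:`SimulationConfig`.
    """
    try:
        n_ranked, n_unranked = _SCENARIO_COUNTS[scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}") from None
    specs = [(f"src{i + 1:02d}", ListKind.RANKED) for i in range(n_ranked)]
    specs += [
        (f"src{n_ranked + j + 1:02d}", ListKind.UNRANKED) for j in range(n_unranked)
    ]
    return SimulationConfig(
        M=M, D=D, gamma=gamma, seed=seed, list_specs=tuple(specs), **overrides
    )


def write_simulated(sim: SimulatedDataset, out_dir: str | Path) -> None:
    """Write a simulated dataset plus truth files and a latent sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(sim.dataset, out / "dataset.tsv", universe_path=out / "universe.txt")
    truth_rank = Dataset.from_lists(
        [GeneList("truth", "truth", ListKind.RANKED, sim.truth_ranking)]
    )
    write_dataset(truth_rank, out / "truth_ranking.tsv")
    truth_set = Dataset.from_lists(
        [GeneList("truth", "truth", ListKind.UNRANKED, tuple(sorted(sim.truth_set)))]
    )
    write_dataset(truth_set, out / "truth_set.tsv")
    sidecar = {
        "sigma": sim.per_list_sigma,
        "cut": sim.per_list_cut,
        "config": {
            k: (list(map(list, v)) if k == "list_specs" else v)
            for k, v in dataclasses.asdict(sim.config).items()
        },
    }
    (out / "latents.json").write_text(json.dumps(sidecar, indent=2, default=str))
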