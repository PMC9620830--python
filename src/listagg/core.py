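"""Domain types and the gene-list exchange format.

A *gene list* is the unit of evidence: one experimental source reporting a
set of entities (genes, proteins, transcripts ...), either with internal
order information (``RANKED``) or as a bare set (``UNRANKED``). A *dataset*
is a collection of such lists over a common entity universe, the input to
every aggregation method in :mod:`listagg.aggregate`.

The on-disk exchange format is line-oriented TSV, one list per line::

    name<TAB>category<TAB>RANKED|UNRANKED<TAB>entity1<TAB>entity2<TAB>...

Lines starting with ``#`` are comments. An optional companion universe file
holds one entity id per line; without it the universe is the union of the
lists. Truth inputs reuse the same format: a truth ranking is a single
RANKED record, a truth set a single UNRANKED record.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path


class ListKind(str, enum.Enum):
    """Whether a source provides internal order information."""

    RANKED = "RANKED"
    UNRANKED = "UNRANKED"


class FormatError(ValueError):
    """Raised for malformed exchange-format input or invalid list data."""


@dataclass(frozen=True)
class GeneList:
    """One experimental source: an ordered or unordered collection of entities.

    Parameters
    ----------
    name
        Unique identifier of the source within a dataset.
    category
        Source category label. Methods that weight lists (MAIC) take the
        best-supporting list per category so that near-duplicate sources do
        not double count.
    kind
        ``ListKind.RANKED`` if the order of ``entities`` is meaningful,
        ``ListKind.UNRANKED`` if any permutation denotes the same list.
    entities
        Non-empty, duplicate-free sequence of entity ids.
    """

    name: str
    category: str
    kind: ListKind
    entities: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ListKind(self.kind))
        object.__setattr__(self, "entities", tuple(self.entities))
        if len(self.entities) == 0:
            raise FormatError(f"list {self.name!r} is empty")
        if len(set(self.entities)) != len(self.entities):
            seen: set[str] = set()
            dup = next(e for e in self.entities if e in seen or seen.add(e))
            raise FormatError(f"list {self.name!r} contains duplicate entity {dup!r}")

    def __len__(self) -> int:
        return len(self.entities)

    @property
    def is_ranked(self) -> bool:
        return self.kind is ListKind.RANKED


@dataclass(frozen=True)
class Dataset:
    """A collection of gene lists over a shared entity universe."""

    lists: tuple[GeneList, ...]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lists", tuple(self.lists))
        object.__setattr__(self, "universe", frozenset(self.universe))
        names = [gl.name for gl in self.lists]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))
            raise FormatError(f"duplicate list name {dup!r} in dataset")
        for gl in self.lists:
            missing = set(gl.entities) - self.universe
            if missing:
                raise FormatError(
                    f"list {gl.name!r} contains entities outside the universe: "
                    f"{sorted(missing)[:5]}"
                )

    @classmethod
    def from_lists(
        cls, lists: Iterable[GeneList], universe: Iterable[str] | None = None
    ) -> "Dataset":
        """Build a dataset; the universe defaults to the union of the lists."""
        lists = tuple(lists)
        if universe is None:
            universe = frozenset(e for gl in lists for e in gl.entities)
        return cls(lists=lists, universe=frozenset(universe))

    def __len__(self) -> int:
        return len(self.lists)

    @property
    def has_unranked(self) -> bool:
        return any(not gl.is_ranked for gl in self.lists)

    def ranked_lists(self) -> tuple[GeneList, ...]:
        return tuple(gl for gl in self.lists if gl.is_ranked)


@dataclass(frozen=True)
class AggregationResult:
    """A consensus ranking with per-entity scores.

    ``ranking`` is a total order over (a subset of) the universe, best
    first. ``higher_is_better`` declares the score polarity so the ranking
    can be checked for consistency with ``scores``. ``list_weights`` is
    populated by methods that estimate per-list quality (MAIC).
    """

    ranking: tuple[str, ...]
    scores: Mapping[str, float]
    method: str
    higher_is_better: bool
    tie_note: str
    list_weights: Mapping[str, float] | None = None
    used_unranked: bool = False
    converged: bool = True
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranking", tuple(self.ranking))
        if len(set(self.ranking)) != len(self.ranking):
            raise ValueError("ranking contains duplicate entities")
        sign = -1.0 if self.higher_is_better else 1.0
        prev = None
        for e in self.ranking:
            cur = sign * float(self.scores[e])
            if prev is not None and cur < prev:
                raise ValueError(
                    f"ranking of {self.method} inconsistent with score polarity"
                )
            prev = cur

    def top(self, k: int) -> tuple[str, ...]:
        return self.ranking[:k]


def effective_ranks(gene_list: GeneList) -> dict[str, float]:
    """Per-entity rank of a list, encoding the unranked half-length rule.

    A RANKED list of length *n* yields integer ranks ``1..n`` in list
    order. An UNRANKED list assigns every member the same real-valued rank
    *n/2* — the midpoint convention used to adapt ranked-only methods to
    unranked input ("Mix" variants).
    """
    n = len(gene_list)
    if gene_list.is_ranked:
        return {e: float(i) for i, e in enumerate(gene_list.entities, start=1)}
    return {e: n / 2.0 for e in gene_list.entities}


def _format_list(gene_list: GeneList) -> str:
    # UNRANKED entities are written sorted so output is deterministic
    # regardless of in-memory order.
    ents = gene_list.entities if gene_list.is_ranked else tuple(sorted(gene_list.entities))
    return "\t".join((gene_list.name, gene_list.category, gene_list.kind.value) + ents)


def write_dataset(
    dataset: Dataset, path: str | Path, universe_path: str | Path | None = None
) -> None:
    """Write a dataset in the TSV exchange format.

    Lists are written in dataset order; UNRANKED entities in lexicographic
    order. When ``universe_path`` is given, the universe is written there
    (one id per line, sorted); otherwise entities outside every list are
    silently dropped on a read round-trip, so a universe file is required
    whenever the universe exceeds the union of the lists.
    """
    if len(dataset) == 0:
        raise FormatError("refusing to write an empty dataset (0 lists)")
    path = Path(path)
    with path.open("w") as fh:
        for gl in dataset.lists:
            fh.write(_format_list(gl) + "\n")
    if universe_path is not None:
        with Path(universe_path).open("w") as fh:
            for e in sorted(dataset.universe):
                fh.write(e + "\n")


def read_gene_list(line: str) -> GeneList:
    """Parse one exchange-format record."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise FormatError(f"record has {len(fields)} fields, need >= 4: {line[:80]!r}")
    name, category, kind_s = fields[:3]
    try:
        kind = ListKind(kind_s)
    except ValueError:
        raise FormatError(
            f"list {name!r}: kind must be RANKED or UNRANKED, got {kind_s!r}"
        ) from None
    return GeneList(name=name, category=category, kind=kind, entities=tuple(fields[3:]))


def read_dataset(
    path: str | Path,
    universe_path: str | Path | None = None,
    dialect: str = "tsv",
) -> Dataset:
    """Read a dataset from the TSV exchange format.

    ``dialect`` names the file format; only ``"tsv"`` is defined. The
    universe defaults to the union of the lists unless ``universe_path``
    supplies an explicit entity universe.
    """
    if dialect != "tsv":
        raise FormatError(f"unknown dialect {dialect!r}; known dialects: tsv")
    path = Path(path)
    lists: list[GeneList] = []
    with path.open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            lists.append(read_gene_list(line))
    universe: Iterable[str] | None = None
    if universe_path is not None:
        with Path(universe_path).open() as fh:
            universe = [ln.strip() for ln in fh if ln.strip()]
    return Dataset.from_lists(lists, universe=universe)


def read_truth(path: str | Path) -> tuple[Sequence[str], frozenset[str]]:
    """Read a truth file: returns ``(ranking_or_set_members, set)``.

    The file holds a single record. A RANKED record is a truth ranking
    (order meaningful); an UNRANKED record a truth set.
    """
    ds = read_dataset(path)
    if len(ds) != 1:
        raise FormatError(f"truth file must hold exactly one record, found {len(ds)}")
    gl = ds.lists[0]
    return gl.entities, frozenset(gl.entities)
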