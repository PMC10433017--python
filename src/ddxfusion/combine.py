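"""Fusion rules for top-10 ranked differential-diagnosis (DDx) lists.

Three rules are implemented for merging the ranked candidate lists that
different DDx generators produce for the same patient:

* ``combine_union`` — pool every candidate, dropping duplicates.  With L
  disjoint top-10 lists the result has 10·L entries.
* ``combine_weighted_1n`` — Borda-style reciprocal-rank fusion: a diagnosis
  at rank r in a list contributes weight 1/r; weights are summed across
  lists and the top-k (default 10) diagnoses by total weight form the
  output.
* ``combine_shared`` — keep only diagnoses present in *every* input list
  (a concordance filter; the result can be empty).

``count_shared`` is the concordance statistic itself: the number of
diagnoses an index list shares with all other lists under comparison.

Diagnosis identity is exact string equality of ids; no synonym or
ontology matching is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MAX_LIST_LENGTH",
    "RankedDDxList",
    "CombinedEntry",
    "CombinedList",
    "combine_union",
    "combine_weighted_1n",
    "combine_shared",
    "count_shared",
]

#: Ranked lists are truncated at this length (top-10 lists throughout).
MAX_LIST_LENGTH = 10


@dataclass(frozen=True)
class RankedDDxList:
    """One generator's ordered candidate diagnoses for one case.

    ``entries[i]`` is the diagnosis id at rank ``i + 1``; ranks are therefore
    consecutive from 1.  Ids must be unique within the list and the list may
    hold at most :data:`MAX_LIST_LENGTH` entries.
    """

    generator_id: str
    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise ValueError(f"list for generator {self.generator_id!r} is empty")
        if len(self.entries) > MAX_LIST_LENGTH:
            raise ValueError(
                f"list for generator {self.generator_id!r} has "
                f"{len(self.entries)} entries; at most {MAX_LIST_LENGTH} allowed"
            )
        if any(not d for d in self.entries):
            raise ValueError("diagnosis ids must be non-empty strings")
        if len(set(self.entries)) != len(self.entries):
            dupes = sorted({d for d in self.entries if self.entries.count(d) > 1})
            raise ValueError(
                f"duplicate diagnosis ids in list for generator "
                f"{self.generator_id!r}: {dupes}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, diagnosis_id: str) -> bool:
        return diagnosis_id in self.entries

    def rank_of(self, diagnosis_id: str) -> int:
        """1-based rank of ``diagnosis_id``; raises ``KeyError`` if absent."""
        try:
            return self.entries.index(diagnosis_id) + 1
        except ValueError:
            raise KeyError(diagnosis_id) from None

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.entries)


@dataclass(frozen=True)
class CombinedEntry:
    diagnosis_id: str
    weight: float | None
    provenance: frozenset[str]


@dataclass(frozen=True)
class CombinedList:
    """Output of a combination rule.

    ``method`` is one of ``union``, ``weighted_1n`` or ``shared``.  Entries
    are unique; for ``weighted_1n`` the weights are non-increasing in list
    order and for ``shared`` every entry carries the full input-generator
    set as provenance.
    """

    method: str
    entries: tuple[CombinedEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.method not in ("union", "weighted_1n", "shared"):
            raise ValueError(f"unknown combination method {self.method!r}")
        ids = [e.diagnosis_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("combined list contains duplicate diagnosis ids")
        if self.method == "weighted_1n":
            weights = [e.weight for e in self.entries]
            if any(w is None or w < 0 for w in weights):
                raise ValueError("weighted_1n entries must carry non-negative weights")
            if any(a < b for a, b in zip(weights, weights[1:])):
                raise ValueError("weighted_1n weights must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, diagnosis_id: str) -> bool:
        return any(e.diagnosis_id == diagnosis_id for e in self.entries)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(e.diagnosis_id for e in self.entries)

    @property
    def ordered_ids(self) -> tuple[str, ...]:
        return tuple(e.diagnosis_id for e in self.entries)


def _index_lists(lists: Sequence[RankedDDxList]) -> Sequence[RankedDDxList]:
    lists = tuple(lists)
    if not lists:
        raise ValueError("at least one ranked list is required")
    return lists


def _membership(
    lists: Sequence[RankedDDxList],
) -> tuple[dict[str, int], dict[str, int], dict[str, set[str]]]:
    """Best (minimum) rank, first containing-list index and provenance per id."""
    best_rank: dict[str, int] = {}
    first_list: dict[str, int] = {}
    provenance: dict[str, set[str]] = {}
    for li, lst in enumerate(lists):
        for rank, d in enumerate(lst.entries, start=1):
            if d not in best_rank or rank < best_rank[d]:
                best_rank[d] = rank
            first_list.setdefault(d, li)
            provenance.setdefault(d, set()).add(lst.generator_id)
    return best_rank, first_list, provenance


def combine_union(lists: Sequence[RankedDDxList]) -> CombinedList:
    """Pool all diagnoses across lists, excluding duplicates.

    Order is deterministic: ascending best rank attained in any input, ties
    broken by input-list priority (earlier lists win), then lexicographic
    id.  Ordering does not affect the inclusion-accuracy metric; it exists
    so output is reproducible and readable.
    """
    lists = _index_lists(lists)
    best_rank, first_list, provenance = _membership(lists)
    order = sorted(best_rank, key=lambda d: (best_rank[d], first_list[d], d))
    entries = tuple(
        CombinedEntry(d, None, frozenset(provenance[d])) for d in order
    )
    return CombinedList("union", entries)


def combine_weighted_1n(
    lists: Sequence[RankedDDxList], k: int = MAX_LIST_LENGTH
) -> CombinedList:
    """Reciprocal-rank (1/n) weighted fusion keeping the top ``k`` diagnoses.

    The weight of a diagnosis is the sum over input lists containing it of
    1/rank; diagnoses absent from a list simply gain no weight from it.
    Ties in total weight break by smaller best single-list rank, then
    input-list priority, then lexicographic id.  Weights are accumulated in
    exact rational arithmetic so that genuinely tied sums of reciprocal
    ranks (e.g. 1/3 + 1/6 vs 1/2) fall through to the tie-break rule
    instead of being ordered by floating-point rounding noise.
    """
    lists = _index_lists(lists)
    if k < 1:
        raise ValueError("k must be a positive integer")
    best_rank, first_list, provenance = _membership(lists)
    weight: dict[str, Fraction] = {}
    for lst in lists:
        for rank, d in enumerate(lst.entries, start=1):
            weight[d] = weight.get(d, Fraction(0)) + Fraction(1, rank)
    order = sorted(
        weight, key=lambda d: (-weight[d], best_rank[d], first_list[d], d)
    )[:k]
    entries = tuple(
        CombinedEntry(d, float(weight[d]), frozenset(provenance[d])) for d in order
    )
    return CombinedList("weighted_1n", entries)


def combine_shared(lists: Sequence[RankedDDxList]) -> CombinedList:
    """Keep only diagnoses shared by every input list.

    Requires at least two lists.  The output is ordered by rank in the
    first (index) list and may be empty when the lists are disjoint.
    """
    lists = _index_lists(lists)
    if len(lists) < 2:
        raise ValueError("combine_shared requires at least two lists")
    common = frozenset.intersection(*(lst.ids for lst in lists))
    all_generators = frozenset(lst.generator_id for lst in lists)
    entries = tuple(
        CombinedEntry(d, None, all_generators)
        for d in lists[0].entries
        if d in common
    )
    return CombinedList("shared", entries)


def count_shared(
    index_list: RankedDDxList, others: Iterable[RankedDDxList]
) -> int:
    """Number of diagnoses present in the index list and every other list.

    With one other list this is the pairwise shared-diagnosis count (0..10);
    with two it is the three-way count.  This is the concordance statistic
    used as the predictor of index-list accuracy.
    """
    others = tuple(others)
    if not others:
        raise ValueError("count_shared requires at least one other list")
    common = index_list.ids
    for lst in others:
        common = common & lst.ids
    return len(common)
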