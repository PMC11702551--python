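"""Consensus ranking of candidate compounds for an indication.

The similarity lists of an indication's associated drugs ("seeds") are
combined into a single total order: a candidate's consensus *count* is the
number of seed lists in which it appears within the similarity-list cutoff,
and ties are broken by mean rank within the cutoff, mean rank across the
full lists, mean signature distance, and finally compound id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidInputError
from .signatures import SimilarityLists

__all__ = [
    "IndicationMapping",
    "ConsensusEntry",
    "ConsensusList",
    "rank_candidates",
]


@dataclass
class IndicationMapping:
    """Drug–indication associations over a candidate drug library.

    ``associations`` is deduplicated and kept in a deterministic (sorted)
    order; every associated drug must belong to ``drug_library``, the
    candidate universe used for predictions.
    """

    associations: list[tuple[str, str]]
    drug_library: frozenset[str]

    def __init__(
        self,
        associations: Iterable[tuple[str, str]],
        drug_library: Iterable[str] | None = None,
    ):
        assoc = sorted({(str(d), str(i)) for d, i in associations})
        drugs_in_assoc = {d for d, _ in assoc}
        if drug_library is None:
            library = frozenset(drugs_in_assoc)
        else:
            library = frozenset(str(d) for d in drug_library)
            missing = drugs_in_assoc - library
            if missing:
                raise InvalidInputError(
                    f"associated drugs missing from drug library: {sorted(missing)[:5]}"
                )
        self.associations = assoc
        self.drug_library = library
        self._by_indication: dict[str, set[str]] = {}
        for d, i in assoc:
            self._by_indication.setdefault(i, set()).add(d)

    @property
    def n_associations(self) -> int:
        return len(self.associations)

    def indication_ids(self) -> list[str]:
        return sorted(self._by_indication)

    def drugs_for(self, indication_id: str) -> set[str]:
        try:
            return set(self._by_indication[indication_id])
        except KeyError:
            raise InvalidInputError(
                f"unknown indication id {indication_id!r}"
            ) from None

    def benchmarkable_indications(self, min_drugs: int = 2) -> list[str]:
        """Indications with at least ``min_drugs`` associated drugs, sorted."""
        return sorted(
            i for i, drugs in self._by_indication.items() if len(drugs) >= min_drugs
        )

    def restrict_to_indications(self, indication_ids: Iterable[str]) -> "IndicationMapping":
        """A mapping containing only the given indications (library unchanged)."""
        keep = set(indication_ids)
        unknown = keep - set(self._by_indication)
        if unknown:
            raise InvalidInputError(f"unknown indications: {sorted(unknown)[:5]}")
        return IndicationMapping(
            [(d, i) for d, i in self.associations if i in keep],
            drug_library=self.drug_library,
        )


@dataclass(frozen=True)
class ConsensusEntry:
    """One candidate's consensus statistics for a single indication.

    ``mean_cutoff_rank`` is ``inf`` when the candidate appears within the
    cutoff of no seed list (count 0) — the undefined case sorts last.
    """

    compound_id: str
    count: int
    mean_cutoff_rank: float
    mean_full_rank: float
    mean_distance: float
    final_rank: int


@dataclass
class ConsensusList:
    """Total order over the candidate set for one indication."""

    entries: list[ConsensusEntry]
    cutoff: int
    seed_drugs: frozenset[str]
    _rank: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._rank = {e.compound_id: e.final_rank for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def rank_of(self, compound_id: str) -> int:
        try:
            return self._rank[compound_id]
        except KeyError:
            raise InvalidInputError(
                f"compound {compound_id!r} is not among the ranked candidates"
            ) from None


def _consensus_stats(
    seed_idx: np.ndarray,
    cand_idx: np.ndarray,
    lists: SimilarityLists,
    cutoff: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-candidate (count, mean_cutoff_rank, mean_full_rank, mean_distance).

    A seed's own similarity list excludes the seed itself, so a candidate
    that is also a seed is averaged over the remaining seed lists only.
    """
    ranks = lists.ranks[np.ix_(seed_idx, cand_idx)].astype(np.float64)
    dists = lists.distances[np.ix_(seed_idx, cand_idx)]
    valid = seed_idx[:, None] != cand_idx[None, :]  # mask self-list cells

    n_lists = valid.sum(axis=0).astype(np.float64)
    within = valid & (ranks <= cutoff)
    count = within.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cutoff = np.where(
            count > 0,
            np.where(within, ranks, 0.0).sum(axis=0) / np.maximum(count, 1),
            np.inf,
        )
        mean_full = np.where(
            n_lists > 0,
            np.where(valid, ranks, 0.0).sum(axis=0) / np.maximum(n_lists, 1),
            np.inf,
        )
        mean_dist = np.where(
            n_lists > 0,
            np.where(valid, dists, 0.0).sum(axis=0) / np.maximum(n_lists, 1),
            np.inf,
        )
    return count, mean_cutoff, mean_full, mean_dist


def _consensus_order(
    seed_idx: np.ndarray,
    cand_idx: np.ndarray,
    lists: SimilarityLists,
    cutoff: int,
):
    """Sorted candidate positions plus the per-candidate statistics."""
    count, mean_cutoff, mean_full, mean_dist = _consensus_stats(
        seed_idx, cand_idx, lists, cutoff
    )
    ids = np.asarray([lists.compound_ids[j] for j in cand_idx], dtype=object)
    id_pos = np.empty(len(ids), dtype=np.intp)
    id_pos[np.argsort(ids)] = np.arange(len(ids))
    # lexsort: last key is primary
    order = np.lexsort((id_pos, mean_dist, mean_full, mean_cutoff, -count))
    return order, count, mean_cutoff, mean_full, mean_dist


def rank_candidates(
    assoc_drugs: Iterable[str],
    lists: SimilarityLists,
    cutoff: int,
    candidates: Iterable[str] | None = None,
    exclude_seeds: bool = False,
) -> ConsensusList:
    """Rank candidate compounds by consensus over seed similarity lists.

    Parameters
    ----------
    assoc_drugs : iterable of str
        The indication's associated drugs (seeds). Must be non-empty and
        present in ``lists``.
    lists : SimilarityLists
        All-against-all similarity lists over the compound library.
    cutoff : int
        Similarity-list cutoff: a seed list "contains" a candidate when the
        candidate's rank in that list is <= cutoff.
    candidates : iterable of str, optional
        Candidate universe; defaults to every compound in ``lists``.
    exclude_seeds : bool
        Drop the seed drugs themselves from the candidate set.

    Returns
    -------
    ConsensusList
        Every candidate, ordered by (count desc, mean rank within cutoff asc,
        mean full-list rank asc, mean distance asc, compound id asc), with
        1-based ``final_rank``.
    """
    seeds = sorted({str(d) for d in assoc_drugs})
    if not seeds:
        raise InsufficientDataError("no seed drugs for consensus ranking")
    if cutoff < 1:
        raise InvalidInputError(f"similarity-list cutoff must be >= 1, got {cutoff}")
    missing = [d for d in seeds if d not in lists]
    if missing:
        raise InvalidInputError(
            f"seed drugs absent from similarity lists: {missing[:5]}"
        )
    if candidates is None:
        cand = list(lists.compound_ids)
    else:
        cand = sorted({str(c) for c in candidates})
        missing_c = [c for c in cand if c not in lists]
        if missing_c:
            raise InvalidInputError(
                f"candidates absent from similarity lists: {missing_c[:5]}"
            )
    if exclude_seeds:
        seed_set = set(seeds)
        cand = [c for c in cand if c not in seed_set]
    if not cand:
        raise InsufficientDataError("candidate set is empty")

    seed_idx = np.asarray([lists.index(d) for d in seeds], dtype=np.intp)
    cand_idx = np.asarray([lists.index(c) for c in cand], dtype=np.intp)
    order, count, mean_cutoff, mean_full, mean_dist = _consensus_order(
        seed_idx, cand_idx, lists, cutoff
    )
    entries = [
        ConsensusEntry(
            compound_id=cand[j],
            count=int(count[j]),
            mean_cutoff_rank=float(mean_cutoff[j]),
            mean_full_rank=float(mean_full[j]),
            mean_distance=float(mean_dist[j]),
            final_rank=pos + 1,
        )
        for pos, j in enumerate(order)
    ]
    return ConsensusList(entries=entries, cutoff=cutoff, seed_drugs=frozenset(seeds))
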