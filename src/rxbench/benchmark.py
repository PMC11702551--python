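"""Benchmarking protocols and null controls.

Two protocols are implemented:

- the *original* protocol scores similarity-list quality directly:
  indication accuracy (IA) is the percentage of an indication's associated
  drugs whose similarity list contains another associated drug within a rank
  cutoff; averaging IA over indications gives AIA;

- the *leave-one-out* protocol scores the consensus predictions: each
  associated drug is withheld in turn, the remaining drugs seed a consensus
  ranking, and the withheld drug's final rank feeds the new indication
  accuracy (nIA, percentage recovered within a rank cutoff) and the
  normalized discounted cumulative gain (nNDCG, with DCG = 1/log2(rank+1)
  and ideal DCG = 1). Per-indication values are averaged (unweighted) into
  nAIA and aggregate nNDCG.

Null controls: an analytic control nAIA of 100·k/N for rank cutoff k over N
candidates, and an empirical control nNDCG from benchmarking column-permuted
(structureless) interaction matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .consensus import IndicationMapping, rank_candidates, _consensus_order
from .errors import InsufficientDataError, InvalidInputError
from .signatures import InteractionMatrix, SimilarityLists, build_similarity_lists

__all__ = [
    "IndicationResult",
    "BenchmarkSummary",
    "original_ia",
    "dcg",
    "loo_rank",
    "benchmark_mapping",
    "hypergeom_control_naia",
    "randomized_control_nndcg",
]

logger = logging.getLogger(__name__)

DEFAULT_RANK_CUTOFFS = (10, 25, 100)


def dcg(rank: int) -> float:
    """Discounted cumulative gain of a single hit at ``rank``: 1/log2(rank+1).

    The ideal DCG is 1 (a hit at rank 1), so this value is also the NDCG.
    """
    if rank < 1:
        raise InvalidInputError(f"rank must be >= 1, got {rank}")
    return 1.0 / math.log2(rank + 1)


def original_ia(
    indication_drugs: Iterable[str],
    lists: SimilarityLists,
    rank_cutoff: int,
) -> float:
    """Original-protocol indication accuracy, as a percentage.

    For each associated drug, test whether *any other* associated drug
    appears within ``rank_cutoff`` of its similarity list.
    """
    drugs = sorted({str(d) for d in indication_drugs})
    if len(drugs) < 2:
        raise InsufficientDataError(
            "indication accuracy needs at least two associated drugs"
        )
    if rank_cutoff < 1:
        raise InvalidInputError(f"rank cutoff must be >= 1, got {rank_cutoff}")
    idx = np.asarray([lists.index(d) for d in drugs], dtype=np.intp)
    sub = lists.ranks[np.ix_(idx, idx)]
    off_diag = ~np.eye(len(idx), dtype=bool)
    hits = ((sub <= rank_cutoff) & off_diag).any(axis=1).sum()
    return 100.0 * hits / len(drugs)


def loo_rank(
    indication_drugs: Iterable[str],
    withheld: str,
    lists: SimilarityLists,
    cutoff: int,
    candidates: Iterable[str] | None = None,
) -> int:
    """Final consensus rank of one withheld drug.

    Seeds are the indication's drugs minus the withheld drug; the withheld
    drug must remain in the candidate universe.
    """
    drugs = {str(d) for d in indication_drugs}
    withheld = str(withheld)
    if withheld not in drugs:
        raise InvalidInputError(
            f"withheld drug {withheld!r} is not associated with the indication"
        )
    if len(drugs) < 2:
        raise InsufficientDataError(
            "leave-one-out needs at least two associated drugs"
        )
    seeds = drugs - {withheld}
    consensus = rank_candidates(seeds, lists, cutoff, candidates=candidates)
    return consensus.rank_of(withheld)


@dataclass
class IndicationResult:
    """Leave-one-out results for one indication."""

    indication_id: str
    n_drugs: int
    ranks: dict[str, int]  # withheld drug -> final consensus rank
    nia: dict[int, float]  # rank cutoff -> percent recovered
    nndcg: dict[int, float]  # rank cutoff -> mean NDCG (0 beyond cutoff)
    nndcg_overall: float
    ia: dict[int, float]  # original-protocol IA per rank cutoff


@dataclass
class BenchmarkSummary:
    """Aggregate benchmark over all assessed indications (unweighted means)."""

    rank_cutoffs: tuple[int, ...]
    similarity_cutoff: int
    n_candidates: int
    naia: dict[int, float]
    nndcg: dict[int, float]
    nndcg_overall: float
    aia: dict[int, float]
    results: list[IndicationResult]
    skipped_indications: list[str] = field(default_factory=list)
    control_naia: dict[int, float] | None = None
    control_nndcg: dict[int, float] | None = None

    @property
    def n_indications(self) -> int:
        return len(self.results)


def _assess_indication(
    indication_id: str,
    drugs: Sequence[str],
    lists: SimilarityLists,
    cutoff: int,
    rank_cutoffs: Sequence[int],
    cand_idx: np.ndarray,
    cand_pos: Mapping[str, int],
) -> IndicationResult:
    drug_idx = {d: lists.index(d) for d in drugs}
    ranks: dict[str, int] = {}
    for withheld in drugs:
        seed_idx = np.asarray(
            [drug_idx[d] for d in drugs if d != withheld], dtype=np.intp
        )
        order, *_ = _consensus_order(seed_idx, cand_idx, lists, cutoff)
        # position of withheld candidate within the sorted order
        target = cand_pos[withheld]
        ranks[withheld] = int(np.nonzero(order == target)[0][0]) + 1

    rank_values = list(ranks.values())
    n = len(rank_values)
    nia = {
        k: 100.0 * sum(r <= k for r in rank_values) / n for k in rank_cutoffs
    }
    gains = [dcg(r) for r in rank_values]
    nndcg_overall = float(np.mean(gains))
    nndcg = {
        k: float(np.mean([g if r <= k else 0.0 for g, r in zip(gains, rank_values)]))
        for k in rank_cutoffs
    }
    ia = {k: original_ia(drugs, lists, k) for k in rank_cutoffs}
    return IndicationResult(
        indication_id=indication_id,
        n_drugs=len(drugs),
        ranks=ranks,
        nia=nia,
        nndcg=nndcg,
        nndcg_overall=nndcg_overall,
        ia=ia,
    )


def benchmark_mapping(
    mapping: IndicationMapping,
    lists: SimilarityLists,
    cutoff: int,
    rank_cutoffs: Sequence[int] = DEFAULT_RANK_CUTOFFS,
    candidates: Iterable[str] | None = None,
) -> BenchmarkSummary:
    """Run the leave-one-out benchmark over every benchmarkable indication.

    Indications with fewer than two drugs present in the similarity lists are
    skipped (and logged). The candidate universe defaults to the mapping's
    drug library, restricted to compounds present in the lists.

    Aggregates are unweighted means over indications of per-indication means
    over withheld drugs.
    """
    rank_cutoffs = tuple(int(k) for k in rank_cutoffs)
    if not rank_cutoffs or any(k < 1 for k in rank_cutoffs):
        raise InvalidInputError("rank cutoffs must be positive integers")
    if cutoff < 1:
        raise InvalidInputError(f"similarity-list cutoff must be >= 1, got {cutoff}")

    if candidates is None:
        cand = sorted(d for d in mapping.drug_library if d in lists)
        dropped = len(mapping.drug_library) - len(cand)
        if dropped:
            logger.info(
                "%d library drugs missing from similarity lists; excluded", dropped
            )
    else:
        cand = sorted({str(c) for c in candidates})
        missing = [c for c in cand if c not in lists]
        if missing:
            raise InvalidInputError(
                f"candidates absent from similarity lists: {missing[:5]}"
            )
    if not cand:
        raise InsufficientDataError("empty candidate universe")
    cand_idx = np.asarray([lists.index(c) for c in cand], dtype=np.intp)
    cand_pos = {c: i for i, c in enumerate(cand)}

    results: list[IndicationResult] = []
    skipped: list[str] = []
    for ind in mapping.indication_ids():
        drugs = sorted(d for d in mapping.drugs_for(ind) if d in lists and d in cand_pos)
        if len(drugs) < 2:
            skipped.append(ind)
            logger.debug("skipping indication %s: <2 assessable drugs", ind)
            continue
        results.append(
            _assess_indication(
                ind, drugs, lists, cutoff, rank_cutoffs, cand_idx, cand_pos
            )
        )
    if not results:
        raise InsufficientDataError(
            "no benchmarkable indication (each needs >= 2 drugs with signatures)"
        )

    naia = {k: float(np.mean([r.nia[k] for r in results])) for k in rank_cutoffs}
    nndcg = {k: float(np.mean([r.nndcg[k] for r in results])) for k in rank_cutoffs}
    aia = {k: float(np.mean([r.ia[k] for r in results])) for k in rank_cutoffs}
    return BenchmarkSummary(
        rank_cutoffs=rank_cutoffs,
        similarity_cutoff=int(cutoff),
        n_candidates=len(cand),
        naia=naia,
        nndcg=nndcg,
        nndcg_overall=float(np.mean([r.nndcg_overall for r in results])),
        aia=aia,
        results=results,
        skipped_indications=skipped,
    )


def hypergeom_control_naia(n_candidates: int, rank_cutoff: int) -> float:
    """Expected nAIA (percent) when a single withheld drug lands uniformly.

    Drawing one relevant item into a random total order over ``n_candidates``
    items places it in the top ``rank_cutoff`` with probability k/N — the
    hypergeometric expectation with one success state.
    """
    if n_candidates < 1:
        raise InvalidInputError("candidate count must be positive")
    if not (1 <= rank_cutoff <= n_candidates):
        raise InvalidInputError(
            f"rank cutoff {rank_cutoff} outside [1, {n_candidates}]"
        )
    return 100.0 * rank_cutoff / n_candidates


def _permute_columns(
    scores: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independently permute each column's values across compounds."""
    out = np.empty_like(scores)
    n = scores.shape[0]
    for j in range(scores.shape[1]):
        out[:, j] = scores[rng.permutation(n), j]
    return out


def randomized_control_nndcg(
    matrix: InteractionMatrix,
    mapping: IndicationMapping,
    cutoff: int,
    rank_cutoffs: Sequence[int] = DEFAULT_RANK_CUTOFFS,
    n_reps: int = 10,
    seed: int | None = None,
) -> dict[int | str, float]:
    """Mean control nNDCG over ``n_reps`` column-permuted matrices.

    Each replicate independently permutes every protein column across
    compounds (preserving per-protein score distributions while destroying
    compound structure), rebuilds the similarity lists, and reruns the
    benchmark. Returns mean nNDCG per rank cutoff plus the ``"overall"`` key.
    Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise InvalidInputError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)
    per_rep: list[BenchmarkSummary] = []
    for _ in range(n_reps):
        permuted = InteractionMatrix(
            list(matrix.compound_ids),
            list(matrix.protein_ids),
            _permute_columns(matrix.scores, rng),
        )
        lists = build_similarity_lists(permuted)
        per_rep.append(benchmark_mapping(mapping, lists, cutoff, rank_cutoffs))
    out: dict[int | str, float] = {
        k: float(np.mean([s.nndcg[k] for s in per_rep])) for k in per_rep[0].rank_cutoffs
    }
    out["overall"] = float(np.mean([s.nndcg_overall for s in per_rep]))
    return out
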