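"""Grouped mapping split, similarity-list-cutoff sweep, and scoring-type comparison."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .benchmark import DEFAULT_RANK_CUTOFFS, benchmark_mapping
from .consensus import IndicationMapping
from .errors import InsufficientDataError, InvalidInputError
from .signatures import Fingerprint, SimilarityLists, build_similarity_lists
from .sites import BindingSiteRecord, ScoringType, build_matrix

__all__ = [
    "SplitResult",
    "ScoringComparison",
    "split_mapping",
    "sweep_cutoffs",
    "find_optimum",
    "compare_scoring_types",
    "metric_columns",
]


@dataclass
class SplitResult:
    """Disjoint optimization/evaluation mappings over benchmarkable indications."""

    optimization: IndicationMapping
    evaluation: IndicationMapping


def split_mapping(
    mapping: IndicationMapping,
    optimization_fraction: float = 0.3,
    seed: int | None = None,
) -> SplitResult:
    """Randomly partition benchmarkable indications into two mappings.

    All of an indication's associations travel together; indications with a
    single drug are dropped. The optimization side receives
    round-half-up(fraction × n) indications. Deterministic for a fixed seed;
    both sides keep the full drug library as candidate universe.
    """
    if not (0.0 < optimization_fraction < 1.0):
        raise InvalidInputError(
            f"optimization fraction must be in (0, 1), got {optimization_fraction}"
        )
    indications = mapping.benchmarkable_indications()
    if len(indications) < 2:
        raise InsufficientDataError(
            "need at least two benchmarkable indications to split"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(indications, dtype=object)[rng.permutation(len(indications))])
    n_opt = int(math.floor(optimization_fraction * len(indications) + 0.5))
    n_opt = min(max(n_opt, 1), len(indications) - 1)  # both sides non-empty
    return SplitResult(
        optimization=mapping.restrict_to_indications(shuffled[:n_opt]),
        evaluation=mapping.restrict_to_indications(shuffled[n_opt:]),
    )


def metric_columns(rank_cutoffs: Sequence[int]) -> list[str]:
    """Column names produced by :func:`sweep_cutoffs` for given rank cutoffs."""
    cols = [f"naia_top{k}" for k in rank_cutoffs]
    cols += [f"nndcg_top{k}" for k in rank_cutoffs]
    cols.append("nndcg_overall")
    return cols


def sweep_cutoffs(
    mapping: IndicationMapping,
    lists: SimilarityLists,
    cutoffs: Iterable[int],
    rank_cutoffs: Sequence[int] = DEFAULT_RANK_CUTOFFS,
) -> pd.DataFrame:
    """Benchmark once per similarity-list cutoff.

    Returns a DataFrame with a ``cutoff`` column (strictly increasing) and
    one column per metric (``naia_top{k}``, ``nndcg_top{k}``,
    ``nndcg_overall``).
    """
    cutoffs = sorted({int(c) for c in cutoffs})
    if not cutoffs:
        raise InvalidInputError("no similarity-list cutoffs to sweep")
    if cutoffs[0] < 1:
        raise InvalidInputError("similarity-list cutoffs must be >= 1")
    rows = []
    for c in cutoffs:
        summary = benchmark_mapping(mapping, lists, c, rank_cutoffs)
        row: dict[str, float] = {"cutoff": c}
        for k in summary.rank_cutoffs:
            row[f"naia_top{k}"] = summary.naia[k]
            row[f"nndcg_top{k}"] = summary.nndcg[k]
        row["nndcg_overall"] = summary.nndcg_overall
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.astype({"cutoff": int})


def find_optimum(table: pd.DataFrame, metric: str) -> tuple[int, float]:
    """Cutoff at which a metric column is maximal (ties -> smallest cutoff)."""
    if table.empty:
        raise InvalidInputError("sweep table is empty")
    if metric not in table.columns or metric == "cutoff":
        raise InvalidInputError(
            f"unknown metric {metric!r}; available: "
            f"{[c for c in table.columns if c != 'cutoff']}"
        )
    ordered = table.sort_values("cutoff", kind="stable").reset_index(drop=True)
    pos = int(ordered[metric].to_numpy().argmax())  # argmax -> first maximum
    return int(ordered.loc[pos, "cutoff"]), float(ordered.loc[pos, metric])


@dataclass
class ScoringComparison:
    """Best (scoring type, cutoff, value) per metric, with full sweep tables."""

    best: dict[str, tuple[str, int, float]]
    tables: dict[str, pd.DataFrame]


def compare_scoring_types(
    fingerprints: Mapping[str, Fingerprint],
    site_library: Iterable[BindingSiteRecord],
    mapping: IndicationMapping,
    cutoffs: Iterable[int] = range(1, 101),
    rank_cutoffs: Sequence[int] = DEFAULT_RANK_CUTOFFS,
    protein_ids: Sequence[str] | None = None,
) -> ScoringComparison:
    """Sweep the similarity-list cutoff under each of the three scoring types.

    For every metric, reports the scoring type and cutoff achieving the
    maximum (ties resolved to the first type in C, CxP, dCxP order, then the
    smallest cutoff). The per-type sweep tables are retained.
    """
    site_library = list(site_library)
    cutoffs = list(cutoffs)
    tables: dict[str, pd.DataFrame] = {}
    for stype in ScoringType:
        matrix = build_matrix(fingerprints, site_library, stype, protein_ids)
        lists = build_similarity_lists(matrix)
        tables[stype.value] = sweep_cutoffs(mapping, lists, cutoffs, rank_cutoffs)
    best: dict[str, tuple[str, int, float]] = {}
    for metric in metric_columns(rank_cutoffs):
        champion: tuple[str, int, float] | None = None
        for stype in ScoringType:
            cutoff, value = find_optimum(tables[stype.value], metric)
            if champion is None or value > champion[2]:
                champion = (stype.value, cutoff, value)
        assert champion is not None
        best[metric] = champion
    return ScoringComparison(best=best, tables=tables)
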