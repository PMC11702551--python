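"""Per-indication explanatory features and dual-mapping comparison.

Correlates leave-one-out performance (nIA) with indication size, original
similarity-list accuracy (IA), and three intra-indication chemical-similarity
summaries, using Spearman correlation (metrics are not normally
distributed). Also compares two benchmarks head-to-head on matched
indications and shared drug–indication associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import IndicationResult, original_ia
from .consensus import IndicationMapping
from .errors import InsufficientDataError, InvalidInputError
from .signatures import Fingerprint, SimilarityLists, tanimoto

__all__ = [
    "IndicationFeatures",
    "MappingComparison",
    "spearman",
    "chem_similarity_features",
    "compute_indication_features",
    "correlate_performance",
    "compare_mappings",
]

CHEM_FEATURE_NAMES = ("chem_max_pair", "chem_avg_avg", "chem_avg_max")


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Requires two equal-length sequences of at least 3 non-constant values.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise InvalidInputError("inputs must be 1-D sequences of equal length")
    if x.size < 3:
        raise InsufficientDataError("Spearman correlation needs >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError(
            "Spearman correlation is undefined for constant input"
        )
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def chem_similarity_features(
    fingerprints: Sequence[Fingerprint],
) -> tuple[float, float, float]:
    """Three intra-indication chemical-similarity summaries.

    Over the pairwise Tanimoto coefficients of one indication's drugs:

    - ``chem_max_pair``: best similarity between any pair;
    - ``chem_avg_avg``: per drug, the mean similarity to the other drugs,
      averaged over drugs;
    - ``chem_avg_max``: per drug, the best similarity to any other drug,
      averaged over drugs.
    """
    fps = list(fingerprints)
    n = len(fps)
    if n < 2:
        raise InsufficientDataError(
            "chemical-similarity features need at least two drugs"
        )
    sim = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        sim[i, j] = sim[j, i] = tanimoto(fps[i], fps[j])
    off = sim[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    max_pair = float(off.max())
    avg_avg = float(off.mean(axis=1).mean())
    avg_max = float(off.max(axis=1).mean())
    return max_pair, avg_avg, avg_max


@dataclass
class IndicationFeatures:
    """Candidate explanatory features for one indication."""

    indication_id: str
    n_drugs: int
    ia: dict[int, float]
    chem_max_pair: float
    chem_avg_avg: float
    chem_avg_max: float


def compute_indication_features(
    mapping: IndicationMapping,
    lists: SimilarityLists,
    fingerprints: Mapping[str, Fingerprint],
    rank_cutoffs: Sequence[int] = (10, 25, 100),
) -> list[IndicationFeatures]:
    """Features for every benchmarkable indication whose drugs have data."""
    out = []
    for ind in mapping.benchmarkable_indications():
        drugs = sorted(
            d for d in mapping.drugs_for(ind) if d in lists and d in fingerprints
        )
        if len(drugs) < 2:
            continue
        max_pair, avg_avg, avg_max = chem_similarity_features(
            [fingerprints[d] for d in drugs]
        )
        out.append(
            IndicationFeatures(
                indication_id=ind,
                n_drugs=len(drugs),
                ia={k: original_ia(drugs, lists, k) for k in rank_cutoffs},
                chem_max_pair=max_pair,
                chem_avg_avg=avg_avg,
                chem_avg_max=avg_max,
            )
        )
    return out


def correlate_performance(
    results: Iterable[IndicationResult],
    features: Iterable[IndicationFeatures],
    min_drugs: int = 2,
) -> pd.DataFrame:
    """Spearman correlations of per-indication nIA against each feature.

    Rows are ``nia_top{k}`` for each rank cutoff present in the results;
    columns are ``n_drugs``, ``ia`` (same rank cutoff), and the three
    chemical-similarity features. Indications with fewer than ``min_drugs``
    drugs are removed before ranking.
    """
    by_ind = {f.indication_id: f for f in features}
    rows = [
        (r, by_ind[r.indication_id])
        for r in results
        if r.indication_id in by_ind and r.n_drugs >= min_drugs
    ]
    if len(rows) < 3:
        raise InsufficientDataError(
            f"only {len(rows)} indications after filtering; need >= 3"
        )
    def safe_spearman(x, y):
        # a constant column (e.g. IA saturated at 100%) has no defined
        # correlation; report NaN for that cell rather than failing the table
        try:
            return spearman(x, y)
        except InsufficientDataError:
            return float("nan")

    cutoffs = sorted(rows[0][0].nia)
    table = {}
    for k in cutoffs:
        nia = [r.nia[k] for r, _ in rows]
        table[f"nia_top{k}"] = {
            "n_drugs": safe_spearman(nia, [f.n_drugs for _, f in rows]),
            "ia": safe_spearman(nia, [f.ia[k] for _, f in rows]),
            "chem_max_pair": safe_spearman(nia, [f.chem_max_pair for _, f in rows]),
            "chem_avg_avg": safe_spearman(nia, [f.chem_avg_avg for _, f in rows]),
            "chem_avg_max": safe_spearman(nia, [f.chem_avg_max for _, f in rows]),
        }
    frame = pd.DataFrame(table).T
    frame.index.name = "metric"
    frame.attrs["n_indications"] = len(rows)
    return frame


@dataclass
class MappingComparison:
    """Head-to-head comparison of two benchmarks (A vs B).

    ``shared_ranks`` rows are (drug, indication_A, indication_B, rank_A,
    rank_B); a *better* rank is strictly smaller. ``mean_rank_delta`` is the
    mean of rank_A − rank_B: positive means B ranked shared drugs higher.
    """

    indication_deltas: pd.DataFrame  # per matched indication: nIA_A - nIA_B per cutoff
    shared_ranks: list[tuple[str, str, str, int, int]]
    better_a: int
    better_b: int
    equal: int
    mean_rank_delta: float
    topk_counts: dict[int, tuple[int, int]]  # cutoff -> (n within k in A, in B)


def compare_mappings(
    results_a: Iterable[IndicationResult],
    results_b: Iterable[IndicationResult],
    indication_match: Iterable[tuple[str, str]],
    rank_cutoffs: Sequence[int] = (10, 25, 100),
) -> MappingComparison:
    """Compare two benchmark runs on matched indications and shared drugs.

    ``indication_match`` pairs each indication id of A with its counterpart
    in B and must be one-to-one. Shared associations are the drugs withheld
    (and hence ranked) under both matched indications.
    """
    match = [(str(a), str(b)) for a, b in indication_match]
    a_ids = [a for a, _ in match]
    b_ids = [b for _, b in match]
    if len(set(a_ids)) != len(match) or len(set(b_ids)) != len(match):
        raise InvalidInputError("indication match table must be one-to-one")
    res_a = {r.indication_id: r for r in results_a}
    res_b = {r.indication_id: r for r in results_b}

    delta_rows = []
    shared: list[tuple[str, str, str, int, int]] = []
    for ind_a, ind_b in match:
        if ind_a not in res_a or ind_b not in res_b:
            continue
        ra, rb = res_a[ind_a], res_b[ind_b]
        row: dict[str, object] = {"indication_a": ind_a, "indication_b": ind_b}
        for k in rank_cutoffs:
            row[f"nia_top{k}_delta"] = ra.nia.get(k, np.nan) - rb.nia.get(k, np.nan)
        delta_rows.append(row)
        for drug in sorted(set(ra.ranks) & set(rb.ranks)):
            shared.append((drug, ind_a, ind_b, ra.ranks[drug], rb.ranks[drug]))

    better_a = sum(1 for *_, x, y in shared if x < y)
    better_b = sum(1 for *_, x, y in shared if y < x)
    equal = len(shared) - better_a - better_b
    mean_delta = (
        float(np.mean([x - y for *_, x, y in shared])) if shared else float("nan")
    )
    topk = {
        k: (
            sum(1 for *_, x, _y in shared if x <= k),
            sum(1 for *_, _x, y in shared if y <= k),
        )
        for k in rank_cutoffs
    }
    return MappingComparison(
        indication_deltas=pd.DataFrame(delta_rows),
        shared_ranks=shared,
        better_a=better_a,
        better_b=better_b,
        equal=equal,
        mean_rank_delta=mean_delta,
        topk_counts=topk,
    )
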