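"""Compound–protein interaction scoring from a binding-site library.

Each protein carries zero or more predicted binding sites; a site pairs a
predicted-ligand fingerprint with a site confidence score in [0, 1]. A
compound's *chemical* score against a protein is its best Tanimoto similarity
to any of that protein's site ligands. Three scoring types turn this into an
interaction score:

- ``C``    — the chemical score alone (compound-only);
- ``CxP``  — chemical score × site score of the chosen site;
- ``dCxP`` — percentile of the chemical score among all compounds' chemical
  scores for that protein, × site score of the chosen site.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidInputError
from .signatures import Fingerprint, InteractionMatrix, tanimoto

__all__ = [
    "BindingSiteRecord",
    "ScoringType",
    "best_ligand_similarity",
    "interaction_score",
    "build_matrix",
]


@dataclass(frozen=True)
class BindingSiteRecord:
    """One predicted binding site: protein, site id, ligand fingerprint, confidence."""

    protein_id: str
    site_id: str
    ligand_fp: Fingerprint
    site_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.site_score <= 1.0):
            raise InvalidInputError(
                f"site_score {self.site_score} outside [0, 1] "
                f"(protein {self.protein_id!r}, site {self.site_id!r})"
            )


class ScoringType(str, Enum):
    C = "C"
    CXP = "CxP"
    DCXP = "dCxP"

    @classmethod
    def from_string(cls, value: str) -> "ScoringType":
        for member in cls:
            if member.value == value:
                return member
        raise InvalidInputError(
            f"unknown scoring type {value!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


def best_ligand_similarity(
    compound_fp: Fingerprint, sites: Iterable[BindingSiteRecord]
) -> tuple[float, BindingSiteRecord]:
    """Best Tanimoto between a compound and one protein's site ligands.

    Ties on the chemical score are broken by higher site score, then by
    ascending site id, so the result is independent of site order.
    """
    sites = list(sites)
    if not sites:
        raise InsufficientDataError("protein has no predicted binding sites")
    proteins = {s.protein_id for s in sites}
    if len(proteins) > 1:
        raise InvalidInputError(
            f"sites belong to multiple proteins: {sorted(proteins)}"
        )
    best = max(
        sites,
        key=lambda s: (
            tanimoto(compound_fp, s.ligand_fp),
            s.site_score,
            _descending_id_key(s.site_id),
        ),
    )
    return tanimoto(compound_fp, best.ligand_fp), best


class _descending_id_key:
    """Inverts string ordering so max() picks the lexicographically smallest id."""

    __slots__ = ("value",)

    def __init__(self, value: str):
        self.value = value

    def __lt__(self, other: "_descending_id_key") -> bool:
        return self.value > other.value

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _descending_id_key) and self.value == other.value


def _weak_percentile(score: float, context: np.ndarray) -> float:
    """Fraction of context values <= score; the maximum maps to 1.0."""
    if context.size == 0:
        raise InvalidInputError("empty percentile context")
    return float(np.count_nonzero(context <= score) / context.size)


def interaction_score(
    compound_fp: Fingerprint,
    sites: Iterable[BindingSiteRecord],
    scoring_type: ScoringType | str,
    percentile_context: Sequence[float] | np.ndarray | None = None,
) -> float:
    """Score one compound against one protein under a scoring type.

    ``percentile_context`` is required for ``dCxP``: the chemical scores of
    every library compound against this protein, against which the weak
    percentile of this compound's chemical score is taken.
    """
    if isinstance(scoring_type, str):
        scoring_type = ScoringType.from_string(scoring_type)
    chem, chosen = best_ligand_similarity(compound_fp, sites)
    if scoring_type is ScoringType.C:
        return chem
    if scoring_type is ScoringType.CXP:
        return chem * chosen.site_score
    if percentile_context is None:
        raise InvalidInputError(
            "dCxP scoring requires a percentile context of chemical scores"
        )
    context = np.asarray(percentile_context, dtype=np.float64)
    return _weak_percentile(chem, context) * chosen.site_score


def build_matrix(
    fingerprints: Mapping[str, Fingerprint],
    site_library: Iterable[BindingSiteRecord],
    scoring_type: ScoringType | str = ScoringType.CXP,
    protein_ids: Sequence[str] | None = None,
) -> InteractionMatrix:
    """Assemble the full compound × protein interaction matrix.

    Compounds are the fingerprint keys (insertion order preserved); proteins
    default to the sorted ids present in the site library, but an explicit
    ``protein_ids`` sequence may add proteins without sites — those columns
    are zero for every compound. For ``dCxP`` the percentile context is the
    per-protein distribution of chemical scores across all compounds.
    """
    if isinstance(scoring_type, str):
        scoring_type = ScoringType.from_string(scoring_type)
    compounds = list(fingerprints)
    if not compounds:
        raise InsufficientDataError("no compound fingerprints supplied")
    by_protein: dict[str, list[BindingSiteRecord]] = {}
    for rec in site_library:
        by_protein.setdefault(rec.protein_id, []).append(rec)
    if protein_ids is None:
        proteins = sorted(by_protein)
    else:
        proteins = [str(p) for p in protein_ids]
        extra = set(by_protein) - set(proteins)
        if extra:
            raise InvalidInputError(
                f"site library references proteins not in protein_ids: {sorted(extra)}"
            )
    if not proteins:
        raise InsufficientDataError("no proteins in site library")

    n_c, n_p = len(compounds), len(proteins)
    chem = np.zeros((n_c, n_p))
    site_score = np.zeros((n_c, n_p))
    for j, pid in enumerate(proteins):
        sites = by_protein.get(pid)
        if not sites:
            continue  # protein with no sites: scores stay 0
        for i, cid in enumerate(compounds):
            c, chosen = best_ligand_similarity(fingerprints[cid], sites)
            chem[i, j] = c
            site_score[i, j] = chosen.site_score

    if scoring_type is ScoringType.C:
        scores = chem
    elif scoring_type is ScoringType.CXP:
        scores = chem * site_score
    else:  # dCxP: weak percentile per protein column, across compounds
        pct = np.zeros_like(chem)
        for j, pid in enumerate(proteins):
            if pid not in by_protein:
                continue
            col = chem[:, j]
            pct[:, j] = (col[None, :] <= col[:, None]).mean(axis=1)
        scores = pct * site_score

    return InteractionMatrix(compounds, proteins, scores)
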