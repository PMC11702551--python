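"""Interaction signatures, signature distance, and similarity lists.

A compound's *interaction signature* is its row in an :class:`InteractionMatrix`:
one real-valued score per protein. Compound–compound similarity is the root
mean squared distance (RMSD) between signatures, and each compound's
*similarity list* ranks every other compound by ascending distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "InteractionMatrix",
    "Fingerprint",
    "SimilarityLists",
    "rmsd_distance",
    "build_similarity_lists",
    "tanimoto",
]


@dataclass
class InteractionMatrix:
    """Dense compound × protein score table.

    Parameters
    ----------
    compound_ids : sequence of str
        Unique row identifiers.
    protein_ids : sequence of str
        Unique column identifiers.
    scores : array-like of shape (n_compounds, n_proteins)
        Real-valued interaction scores, nominally in [0, 1]. Out-of-range
        values trigger a warning (not an error) so that alternative scoring
        schemes can still be loaded.
    """

    compound_ids: list[str]
    protein_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise InvalidInputError("duplicate compound ids in matrix")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise InvalidInputError("duplicate protein ids in matrix")
        expected = (len(self.compound_ids), len(self.protein_ids))
        if self.scores.shape != expected:
            raise InvalidInputError(
                f"score table shape {self.scores.shape} does not match "
                f"{expected[0]} compounds x {expected[1]} proteins"
            )
        if not np.all(np.isfinite(self.scores)):
            raise InvalidInputError("interaction scores must all be finite")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            warnings.warn(
                "interaction scores outside [0, 1]; proceeding unmodified",
                stacklevel=2,
            )
        self._index = {c: i for i, c in enumerate(self.compound_ids)}

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def index(self, compound_id: str) -> int:
        try:
            return self._index[compound_id]
        except KeyError:
            raise InvalidInputError(f"unknown compound id {compound_id!r}") from None

    def signature(self, compound_id: str) -> np.ndarray:
        """Return the interaction signature (row) of one compound."""
        return self.scores[self.index(compound_id)]


@dataclass(frozen=True)
class Fingerprint:
    """Sparse bit-vector fingerprint: the set of set-bit positions.

    Defaults to a 2048-bit space, the conventional ECFP4 width.
    """

    bits: frozenset[int]
    bit_space: int = 2048

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", frozenset(int(b) for b in self.bits))
        if self.bit_space <= 0:
            raise InvalidInputError("bit_space must be positive")
        for b in self.bits:
            if not (0 <= b < self.bit_space):
                raise InvalidInputError(
                    f"bit position {b} outside [0, {self.bit_space})"
                )

    def __len__(self) -> int:
        return len(self.bits)


def rmsd_distance(sig_a, sig_b) -> float:
    """Root mean squared distance between two interaction signatures.

    Symmetric, nonnegative, and zero exactly when the vectors are identical.

    Raises
    ------
    InvalidInputError
        If the vectors are empty, of unequal length, or non-finite.
    """
    a = np.asarray(sig_a, dtype=np.float64)
    b = np.asarray(sig_b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1:
        raise InvalidInputError("signatures must be 1-D vectors")
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("signatures must be non-empty")
    if a.size != b.size:
        raise InvalidInputError(
            f"signature length mismatch: {a.size} vs {b.size}"
        )
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("signatures must be finite")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class SimilarityLists:
    """All-against-all similarity lists over one compound library.

    Stored as dense matrices for fast benchmarking:

    - ``distances[i, j]``: RMSD between compounds i and j (diagonal 0);
    - ``ranks[i, j]``: 1-based rank of compound j within compound i's list
      (``ranks[i, i] == 0`` is a sentinel — a compound never appears in its
      own list);
    - ``order[i]``: the indices of the other compounds in list order.

    Exact distance ties are broken by ascending compound id, so every list is
    a deterministic permutation of all other compounds with ranks 1..N-1.
    """

    compound_ids: list[str]
    distances: np.ndarray
    ranks: np.ndarray
    order: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {c: i for i, c in enumerate(self.compound_ids)}

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def index(self, compound_id: str) -> int:
        try:
            return self._index[compound_id]
        except KeyError:
            raise InvalidInputError(f"unknown compound id {compound_id!r}") from None

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._index

    def rank_of(self, owner: str, other: str) -> int:
        """1-based rank of ``other`` in ``owner``'s similarity list."""
        i, j = self.index(owner), self.index(other)
        if i == j:
            raise InvalidInputError("a compound does not appear in its own list")
        return int(self.ranks[i, j])

    def list_for(self, compound_id: str) -> list[tuple[str, float, int]]:
        """The full similarity list of one compound.

        Returns
        -------
        list of (other_compound_id, distance, rank) in list order.
        """
        i = self.index(compound_id)
        return [
            (self.compound_ids[j], float(self.distances[i, j]), r)
            for r, j in enumerate(self.order[i], start=1)
        ]


def build_similarity_lists(matrix: InteractionMatrix) -> SimilarityLists:
    """Build every compound's similarity list from an interaction matrix.

    Distances are pairwise signature RMSDs; within each list compounds are
    sorted by ascending distance, with exact ties broken by ascending
    compound id. Requires at least two compounds.
    """
    n = matrix.n_compounds
    if n < 2:
        raise InsufficientDataError(
            "similarity lists need a library of at least 2 compounds"
        )
    # RMSD = Euclidean distance / sqrt(n_proteins)
    dist = squareform(pdist(matrix.scores, metric="euclidean"))
    dist /= np.sqrt(matrix.n_proteins)

    # id_pos[j] = position of compound j in lexicographic id order (tiebreak)
    id_pos = np.empty(n, dtype=np.intp)
    id_pos[np.argsort(np.asarray(matrix.compound_ids, dtype=object))] = np.arange(n)

    order = np.empty((n, n - 1), dtype=np.intp)
    ranks = np.zeros((n, n), dtype=np.intp)
    all_idx = np.arange(n)
    for i in range(n):
        others = all_idx[all_idx != i]
        srt = others[np.lexsort((id_pos[others], dist[i, others]))]
        order[i] = srt
        ranks[i, srt] = np.arange(1, n)
    return SimilarityLists(
        compound_ids=list(matrix.compound_ids),
        distances=dist,
        ranks=ranks,
        order=order,
    )


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto (Jaccard) coefficient of two fingerprints.

    |intersection| / |union|, in [0, 1]. Two all-zero fingerprints compare
    as 0 (the 0/0 case is defined away). Requires matching bit spaces.
    """
    if fp_a.bit_space != fp_b.bit_space:
        raise InvalidInputError(
            f"fingerprint bit spaces differ: {fp_a.bit_space} vs {fp_b.bit_space}"
        )
    union = len(fp_a.bits | fp_b.bits)
    if union == 0:
        return 0.0
    return len(fp_a.bits & fp_b.bits) / union
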