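"""Synthetic interaction matrices, mappings, fingerprints, and site libraries.

Plants recoverable structure: each indication gets an archetype signature,
its drugs are noisy copies of it, and their fingerprints share a common bit
block. Everything is deterministic for a fixed seed, so benchmarks and
oracle tests run without any external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import IndicationMapping
from .errors import InvalidInputError
from .signatures import Fingerprint, InteractionMatrix
from .sites import BindingSiteRecord

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the planted-cluster generator.

    ``noise_sd`` is the standard deviation of the Gaussian noise added to
    each drug's copy of its indication archetype (signatures are clipped to
    [0, 1] afterwards — for noise scales small relative to the background
    bounds the clipping bias is negligible). With ``structured=False`` every
    drug draws its own archetype, which removes all planted signal and makes
    benchmark results fall to the null-control level.
    """

    n_compounds: int = 50
    n_proteins: int = 20
    n_indications: int = 5
    drugs_per_indication: int | tuple[int, int] = 4
    noise_sd: float = 0.05
    background_low: float = 0.0
    background_high: float = 1.0
    bit_space: int = 2048
    bits_per_compound: int = 48
    shared_bits: int = 24
    sites_per_protein: int = 1
    structured: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_compounds, self.n_proteins, self.n_indications) < 1:
            raise InvalidInputError("counts must be positive")
        lo, hi = self.drugs_range
        if lo < 2:
            raise InvalidInputError("each indication needs at least 2 drugs")
        if lo > hi:
            raise InvalidInputError("drugs_per_indication range inverted")
        if self.n_indications * lo > self.n_compounds:
            raise InvalidInputError(
                "not enough compounds for the requested indication clusters"
            )
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be nonnegative")
        if not (0 <= self.background_low <= self.background_high <= 1):
            raise InvalidInputError("background bounds must satisfy 0 <= lo <= hi <= 1")
        if self.shared_bits > self.bits_per_compound:
            raise InvalidInputError("shared_bits cannot exceed bits_per_compound")
        if self.bits_per_compound > self.bit_space:
            raise InvalidInputError("bits_per_compound cannot exceed bit_space")

    @property
    def drugs_range(self) -> tuple[int, int]:
        d = self.drugs_per_indication
        return (d, d) if isinstance(d, int) else (int(d[0]), int(d[1]))


@dataclass
class SyntheticDataset:
    matrix: InteractionMatrix
    mapping: IndicationMapping
    fingerprints: dict[str, Fingerprint]
    site_library: list[BindingSiteRecord]
    archetypes: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def _random_bits(rng: np.random.Generator, n: int, bit_space: int) -> frozenset[int]:
    return frozenset(int(b) for b in rng.choice(bit_space, size=n, replace=False))


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset (matrix, mapping, fingerprints, sites).

    Compounds ``cpd0000..`` are assigned to disjoint indication clusters
    ``ind000..`` in order; leftover compounds are unassociated background.
    Returns bit-identical output for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    compounds = [f"cpd{i:04d}" for i in range(config.n_compounds)]
    proteins = [f"prt{j:04d}" for j in range(config.n_proteins)]

    lo, hi = config.drugs_range
    cluster_sizes = []
    remaining = config.n_compounds
    for k in range(config.n_indications):
        # leave room for the clusters still to come
        still_needed = (config.n_indications - k - 1) * lo
        cap = min(hi, remaining - still_needed)
        size = int(rng.integers(lo, cap + 1)) if cap > lo else lo
        cluster_sizes.append(size)
        remaining -= size

    span = config.background_high - config.background_low

    def background(size) -> np.ndarray:
        return config.background_low + span * rng.random(size)

    scores = background((config.n_compounds, config.n_proteins))
    associations: list[tuple[str, str]] = []
    archetypes: dict[str, np.ndarray] = {}
    fingerprints: dict[str, Fingerprint] = {}

    pos = 0
    for k, size in enumerate(cluster_sizes):
        ind = f"ind{k:03d}"
        archetype = background(config.n_proteins)
        archetypes[ind] = archetype
        shared = _random_bits(rng, config.shared_bits, config.bit_space)
        for i in range(pos, pos + size):
            sig = archetype + rng.normal(0.0, config.noise_sd, config.n_proteins) \
                if config.noise_sd > 0 else archetype.copy()
            if not config.structured:
                sig = background(config.n_proteins)
            scores[i] = np.clip(sig, 0.0, 1.0)
            associations.append((compounds[i], ind))
            own = _random_bits(
                rng, config.bits_per_compound - config.shared_bits, config.bit_space
            )
            fingerprints[compounds[i]] = Fingerprint(
                shared | own, bit_space=config.bit_space
            )
        pos += size

    for i in range(pos, config.n_compounds):
        fingerprints[compounds[i]] = Fingerprint(
            _random_bits(rng, config.bits_per_compound, config.bit_space),
            bit_space=config.bit_space,
        )

    # Site ligands are lightly perturbed copies of real compound fingerprints,
    # so chemical scores carry some of the planted structure.
    site_library: list[BindingSiteRecord] = []
    for j, pid in enumerate(proteins):
        for s in range(config.sites_per_protein):
            template = fingerprints[compounds[int(rng.integers(config.n_compounds))]]
            flip = _random_bits(rng, max(1, config.bits_per_compound // 8),
                                config.bit_space)
            site_library.append(
                BindingSiteRecord(
                    protein_id=pid,
                    site_id=f"{pid}_s{s}",
                    ligand_fp=Fingerprint(
                        frozenset(template.bits ^ flip), bit_space=config.bit_space
                    ),
                    site_score=float(rng.random()),
                )
            )

    matrix = InteractionMatrix(compounds, proteins, scores)
    mapping = IndicationMapping(associations, drug_library=compounds)
    return SyntheticDataset(
        matrix=matrix,
        mapping=mapping,
        fingerprints=fingerprints,
        site_library=site_library,
        archetypes=archetypes,
    )
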