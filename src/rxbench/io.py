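"""Readers and writers for the plain-text interchange formats.

All files are TSV with a header row. Fingerprints are serialized as
comma-separated set-bit positions alongside their bit space. Aggregate
results are written as JSON. Every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .benchmark import BenchmarkSummary
from .consensus import ConsensusList, IndicationMapping
from .errors import FormatError
from .signatures import Fingerprint, InteractionMatrix
from .sites import BindingSiteRecord

__all__ = [
    "MappingSummary",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "read_mapping",
    "write_mapping",
    "read_fingerprints",
    "write_fingerprints",
    "read_site_library",
    "write_site_library",
    "read_match_table",
    "write_benchmark_results",
    "write_consensus_list",
    "read_config",
    "smiles_to_ecfp4",
]


def _read_tsv_rows(path: str | Path) -> list[tuple[int, list[str]]]:
    """All rows of a TSV file as (1-based line number, cells), header included."""
    rows = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if row[0].startswith("#"):
                continue
            rows.append((lineno, row))
    if not rows:
        raise FormatError("file is empty", path=str(path))
    return rows


def read_interaction_matrix(path: str | Path) -> InteractionMatrix:
    """Parse a matrix TSV: header of protein ids, first column of compound ids."""
    rows = _read_tsv_rows(path)
    header_line, header = rows[0]
    if len(header) < 2:
        raise FormatError(
            "header must contain at least one protein column",
            path=str(path), line=header_line,
        )
    protein_ids = header[1:]
    if len(set(protein_ids)) != len(protein_ids):
        dup = sorted({p for p in protein_ids if protein_ids.count(p) > 1})
        raise FormatError(
            f"duplicate protein id(s): {dup}", path=str(path), line=header_line
        )
    compound_ids: list[str] = []
    seen: set[str] = set()
    data = np.empty((len(rows) - 1, len(protein_ids)))
    for r, (lineno, row) in enumerate(rows[1:]):
        if len(row) != len(header):
            raise FormatError(
                f"expected {len(header)} columns, found {len(row)}",
                path=str(path), line=lineno,
            )
        cid = row[0]
        if cid in seen:
            raise FormatError(
                f"duplicate compound id {cid!r}", path=str(path), line=lineno
            )
        seen.add(cid)
        compound_ids.append(cid)
        try:
            data[r] = [float(v) for v in row[1:]]
        except ValueError as exc:
            raise FormatError(
                f"non-numeric score: {exc}", path=str(path), line=lineno
            ) from None
    return InteractionMatrix(compound_ids, protein_ids, data)


def write_interaction_matrix(matrix: InteractionMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["compound_id", *matrix.protein_ids])
        for cid, row in zip(matrix.compound_ids, matrix.scores):
            writer.writerow([cid, *(repr(float(v)) for v in row)])


@dataclass
class MappingSummary:
    """Statistics reported when a drug–indication mapping is read."""

    n_drugs: int
    n_indications: int
    n_associations: int
    n_benchmarkable_indications: int
    n_dropped_drugs: int = 0
    n_dropped_associations: int = 0


def read_mapping(
    path: str | Path,
    drug_library: Iterable[str] | None = None,
) -> tuple[IndicationMapping, MappingSummary]:
    """Parse a mapping TSV of (drug_id, indication_id) rows.

    Extra columns are ignored; duplicate rows collapse to one association.
    With a ``drug_library`` filter, associations of absent drugs are dropped
    and counted in the summary (only compounds with interaction signatures
    can be benchmarked).
    """
    rows = _read_tsv_rows(path)
    _, header = rows[0]
    if len(header) < 2:
        raise FormatError(
            "mapping needs at least drug_id and indication_id columns",
            path=str(path), line=rows[0][0],
        )
    pairs: set[tuple[str, str]] = set()
    for lineno, row in rows[1:]:
        if len(row) < 2:
            raise FormatError(
                "row has fewer than 2 columns", path=str(path), line=lineno
            )
        pairs.add((row[0], row[1]))
    if not pairs:
        raise FormatError("mapping contains no associations", path=str(path))

    if drug_library is not None:
        library = frozenset(str(d) for d in drug_library)
        kept = {(d, i) for d, i in pairs if d in library}
        dropped_assoc = len(pairs) - len(kept)
        dropped_drugs = len({d for d, _ in pairs} - library)
        pairs = kept
        if not pairs:
            raise FormatError(
                "no associations remain after drug-library filtering", path=str(path)
            )
    else:
        library = frozenset(d for d, _ in pairs)
        dropped_assoc = dropped_drugs = 0

    mapping = IndicationMapping(sorted(pairs), drug_library=library)
    summary = MappingSummary(
        n_drugs=len({d for d, _ in mapping.associations}),
        n_indications=len(mapping.indication_ids()),
        n_associations=mapping.n_associations,
        n_benchmarkable_indications=len(mapping.benchmarkable_indications()),
        n_dropped_drugs=dropped_drugs,
        n_dropped_associations=dropped_assoc,
    )
    return mapping, summary


def write_mapping(mapping: IndicationMapping, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["drug_id", "indication_id"])
        writer.writerows(mapping.associations)


def _parse_bits(cell: str, path: str, lineno: int) -> frozenset[int]:
    cell = cell.strip()
    if not cell:
        return frozenset()
    try:
        return frozenset(int(b) for b in cell.split(","))
    except ValueError:
        raise FormatError(
            f"malformed bit list {cell[:40]!r}", path=path, line=lineno
        ) from None


def _format_bits(fp: Fingerprint) -> str:
    return ",".join(str(b) for b in sorted(fp.bits))


def read_fingerprints(path: str | Path) -> dict[str, Fingerprint]:
    """Parse a fingerprint TSV: compound_id, bit_space, comma-separated bits."""
    rows = _read_tsv_rows(path)
    fps: dict[str, Fingerprint] = {}
    for lineno, row in rows[1:]:
        if len(row) != 3:
            raise FormatError(
                f"expected 3 columns, found {len(row)}", path=str(path), line=lineno
            )
        cid, space, bits = row
        if cid in fps:
            raise FormatError(
                f"duplicate compound id {cid!r}", path=str(path), line=lineno
            )
        try:
            bit_space = int(space)
        except ValueError:
            raise FormatError(
                f"non-integer bit_space {space!r}", path=str(path), line=lineno
            ) from None
        fps[cid] = Fingerprint(_parse_bits(bits, str(path), lineno), bit_space)
    if not fps:
        raise FormatError("no fingerprints in file", path=str(path))
    return fps


def write_fingerprints(fps: Mapping[str, Fingerprint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["compound_id", "bit_space", "bits"])
        for cid in fps:
            writer.writerow([cid, fps[cid].bit_space, _format_bits(fps[cid])])


def read_site_library(path: str | Path) -> list[BindingSiteRecord]:
    """Parse a site-library TSV: protein_id, site_id, site_score, bit_space, ligand_bits."""
    rows = _read_tsv_rows(path)
    records: list[BindingSiteRecord] = []
    seen: set[tuple[str, str]] = set()
    for lineno, row in rows[1:]:
        if len(row) != 5:
            raise FormatError(
                f"expected 5 columns, found {len(row)}", path=str(path), line=lineno
            )
        pid, sid, score, space, bits = row
        if (pid, sid) in seen:
            raise FormatError(
                f"duplicate site ({pid!r}, {sid!r})", path=str(path), line=lineno
            )
        seen.add((pid, sid))
        try:
            records.append(
                BindingSiteRecord(
                    protein_id=pid,
                    site_id=sid,
                    site_score=float(score),
                    ligand_fp=Fingerprint(
                        _parse_bits(bits, str(path), lineno), int(space)
                    ),
                )
            )
        except ValueError as exc:
            raise FormatError(str(exc), path=str(path), line=lineno) from None
    if not records:
        raise FormatError("no binding sites in file", path=str(path))
    return records


def write_site_library(
    records: Sequence[BindingSiteRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["protein_id", "site_id", "site_score", "bit_space", "ligand_bits"])
        for r in records:
            writer.writerow(
                [r.protein_id, r.site_id, repr(float(r.site_score)),
                 r.ligand_fp.bit_space, _format_bits(r.ligand_fp)]
            )


def read_match_table(path: str | Path) -> list[tuple[str, str]]:
    """Parse a 2-column indication match table (indication_A, indication_B)."""
    rows = _read_tsv_rows(path)
    out = []
    for lineno, row in rows[1:]:
        if len(row) < 2:
            raise FormatError(
                "match table rows need 2 columns", path=str(path), line=lineno
            )
        out.append((row[0], row[1]))
    return out


def write_consensus_list(consensus: ConsensusList, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["final_rank", "compound_id", "count", "mean_cutoff_rank",
             "mean_full_rank", "mean_distance"]
        )
        for e in consensus:
            writer.writerow(
                [e.final_rank, e.compound_id, e.count,
                 "" if not np.isfinite(e.mean_cutoff_rank) else repr(e.mean_cutoff_rank),
                 repr(e.mean_full_rank), repr(e.mean_distance)]
            )


def write_benchmark_results(summary: BenchmarkSummary, out_dir: str | Path) -> None:
    """Write per-indication TSV, per-association TSV, and aggregate JSON.

    Produces ``indications.tsv`` (one row per assessed indication),
    ``associations.tsv`` (one row per withheld drug with its final rank),
    and ``summary.json`` (the aggregate metrics and controls).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ks = summary.rank_cutoffs

    rows = []
    for r in summary.results:
        row = {"indication_id": r.indication_id, "n_drugs": r.n_drugs}
        row.update({f"nia_top{k}": r.nia[k] for k in ks})
        row.update({f"nndcg_top{k}": r.nndcg[k] for k in ks})
        row["nndcg_overall"] = r.nndcg_overall
        row.update({f"ia_top{k}": r.ia[k] for k in ks})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "indications.tsv", sep="\t", index=False)

    with open(out / "associations.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["indication_id", "drug_id", "final_rank"])
        for r in summary.results:
            for drug in sorted(r.ranks):
                writer.writerow([r.indication_id, drug, r.ranks[drug]])

    payload = {
        "similarity_cutoff": summary.similarity_cutoff,
        "rank_cutoffs": list(ks),
        "n_candidates": summary.n_candidates,
        "n_indications": summary.n_indications,
        "skipped_indications": summary.skipped_indications,
        "naia": {str(k): summary.naia[k] for k in ks},
        "nndcg": {str(k): summary.nndcg[k] for k in ks},
        "nndcg_overall": summary.nndcg_overall,
        "aia": {str(k): summary.aia[k] for k in ks},
    }
    if summary.control_naia is not None:
        payload["control_naia"] = {str(k): v for k, v in summary.control_naia.items()}
    if summary.control_nndcg is not None:
        payload["control_nndcg"] = {str(k): v for k, v in summary.control_nndcg.items()}
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` configuration file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(
                    f"expected 'key = value', got {line!r}",
                    path=str(path), line=lineno,
                )
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def smiles_to_ecfp4(smiles: str, bit_space: int = 2048) -> Fingerprint:
    """Optional adapter: ECFP4 (Morgan radius-2) fingerprint from a SMILES.

    Requires rdkit; the core package never imports it.
    """
    from rdkit import Chem  # deferred: optional dependency
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormatError(f"unparseable SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=bit_space)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(frozenset(bv.GetOnBits()), bit_space=bit_space)
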