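"""Readers and writers for the plain-text formats used throughout.

Wild types arrive as FASTA, variants as TSV/CSV tables with either a
``mutations`` column (semicolon-separated ``D26E`` notation) or a
``mutant_sequence`` column, and functional-domain annotations as a TSV of
1-based inclusive intervals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .mutation import STANDARD_AA, MutantRecord, MutationError
from .sae import DomainAnnotation


def read_wildtypes(path: str | Path) -> dict[str, str]:
    """FASTA file → {record id: upper-case sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str).fillna("")


def read_variant_table(
    path: str | Path,
    wt_sequence: str,
    alphabet: str = STANDARD_AA,
) -> list[MutantRecord]:
    """Parse a variant table into validated records.

    Expected columns: ``id``, ``label`` and one of ``mutations`` (notation)
    or ``mutant_sequence``.
    """
    df = _read_table(path)
    cols = set(df.columns)
    if "id" not in cols or "label" not in cols:
        raise MutationError(f"variant table needs 'id' and 'label' columns, got {sorted(cols)}")
    records = []
    for row in df.itertuples(index=False):
        if "mutations" in cols and getattr(row, "mutations", ""):
            rec = MutantRecord.from_notation(
                row.id, wt_sequence, row.mutations, row.label, alphabet
            )
        elif "mutant_sequence" in cols and getattr(row, "mutant_sequence", ""):
            rec = MutantRecord.from_mutant_sequence(
                row.id, wt_sequence, row.mutant_sequence, row.label, alphabet
            )
        else:
            raise MutationError(
                f"record {row.id}: neither 'mutations' nor 'mutant_sequence' present"
            )
        records.append(rec)
    return records


def write_variant_table(
    records: Sequence[MutantRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "id": [r.record_id for r in records],
            "mutations": [";".join(m.notation for m in r.mutations) for r in records],
            "mutant_sequence": [r.mutant_sequence for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_domains(path: str | Path) -> dict[str, DomainAnnotation]:
    """Domain TSV (protein_id, start, end[, name]) → annotations per protein."""
    df = _read_table(path)
    out: dict[str, DomainAnnotation] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        intervals = [
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
        ]
        out[pid] = DomainAnnotation(pid, tuple(intervals))
    return out


def write_domains(annotations: Mapping[str, DomainAnnotation], path: str | Path) -> None:
    rows = [
        {"protein_id": ann.protein_id, "start": s, "end": e, "name": f"domain_{i+1}"}
        for ann in annotations.values()
        for i, (s, e) in enumerate(ann.intervals)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path, indent: Optional[int] = 2) -> None:
    Path(path).write_text(json.dumps(obj, indent=indent, sort_keys=True) + "\n")
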