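"""File formats the pipeline reads and writes.

Raw input is a SMILES file (one molecule per line, optional tab-separated
name, ``#`` comments ignored) or a delimited table with a header row:
``smiles`` plus optional ``count``, ``active`` (0/1) and ``target_class``
columns.  Between pipeline stages, the selected display set travels as a
delimited table ``canonical_smiles, frequency, scale [, annotations]``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .substructure import Kind, MoleculeInput, SubstructureRecord

__all__ = [
    "read_smiles_file",
    "read_table",
    "records_from_table",
    "write_selected_table",
    "read_selected_table",
]


def read_smiles_file(path: str | Path) -> list[MoleculeInput]:
    """Read `SMILES[\\tNAME]` lines; blank lines and ``#`` comments skipped."""
    out: list[MoleculeInput] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            smiles = fields[0].strip()
            name = fields[1].strip() if len(fields) > 1 and fields[1].strip() else None
            out.append(MoleculeInput(smiles, name=name))
    return out


def read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited table with a header; the delimiter is sniffed from
    the extension unless given (``.csv`` → comma, otherwise tab)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "smiles" not in df.columns and "canonical_smiles" not in df.columns:
        raise ValueError(f"{path}: table needs a 'smiles' column")
    return df


def records_from_table(df: pd.DataFrame, kind: Kind = Kind.SCAFFOLD,
                       ) -> list[SubstructureRecord]:
    """Build aggregated records from a pre-aggregated table.

    Expects unique SMILES rows with a ``count`` (default 1 each); optional
    ``activity_ratio`` in [0, 1] and ``target_class`` columns become record
    annotations (a class label is taken as fraction 1.0 for that record).
    """
    smiles_col = "canonical_smiles" if "canonical_smiles" in df.columns else "smiles"
    records = []
    for _, row in df.iterrows():
        freq = int(row["count"]) if "count" in df.columns and pd.notna(row.get("count")) else 1
        ratio = None
        if "activity_ratio" in df.columns and pd.notna(row.get("activity_ratio")):
            ratio = float(row["activity_ratio"])
            if not (0.0 <= ratio <= 1.0):
                raise ValueError(f"activity_ratio {ratio} outside [0, 1]")
        fractions: dict[str, float] = {}
        if "target_class" in df.columns and pd.notna(row.get("target_class")):
            label = str(row["target_class"]).strip()
            if label:
                fractions = {label: 1.0}
        records.append(SubstructureRecord(str(row[smiles_col]), kind, freq,
                                          ratio, fractions))
    return records


def write_selected_table(path: str | Path, records: list[SubstructureRecord],
                         scales: list[float]) -> None:
    """Write the display set (the exchange format between stages)."""
    rows = []
    for rec, scale in zip(records, scales):
        rows.append({
            "canonical_smiles": rec.canonical_smiles,
            "kind": rec.kind.value,
            "frequency": rec.frequency,
            "scale": round(scale, 6),
            "activity_ratio": rec.activity_ratio,
            "class_fractions": ";".join(f"{c}:{f:g}"
                                        for c, f in rec.class_fractions.items()),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_selected_table(path: str | Path) -> tuple[list[SubstructureRecord], list[float]]:
    df = pd.read_csv(path, sep="\t")
    records, scales = [], []
    for _, row in df.iterrows():
        fractions = {}
        if pd.notna(row.get("class_fractions")) and str(row["class_fractions"]):
            for part in str(row["class_fractions"]).split(";"):
                c, f = part.rsplit(":", 1)
                fractions[c] = float(f)
        ratio = float(row["activity_ratio"]) if pd.notna(row.get("activity_ratio")) else None
        records.append(SubstructureRecord(row["canonical_smiles"], Kind(row["kind"]),
                                          int(row["frequency"]), ratio, fractions))
        scales.append(float(row["scale"]))
    return records, scales
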