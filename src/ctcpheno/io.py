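"""Reading and writing of tabular pipeline artifacts.

Expression matrices travel as TSV/CSV with a header row of cell IDs and a
first column named ``gene``; cell metadata and clinical tables are CSV with
named headers.  All round-trips are identities on values and identifiers.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, PatientRecord, META_COLUMNS
from .errors import FormatError, ValidationError

PathLike = Union[str, Path]

CLINICAL_COLUMNS = ("patient_id", "treatment_line", "pfs_days", "pfs_event",
                    "os_days", "os_event")


def _sep_for(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_expression_matrix(path: PathLike, sep: Optional[str] = None,
                           meta_path: Optional[PathLike] = None,
                           ) -> ExpressionMatrix:
    """Read a genes-as-rows TPM table (first column = gene identifiers).

    Raises
    ------
    FormatError
        On duplicate gene or cell identifiers.
    ValidationError
        On negative, missing or non-numeric values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        body = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric expression value: {exc}") from exc
    meta = read_cell_metadata(meta_path) if meta_path is not None else None
    return ExpressionMatrix(body, meta)


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike,
                            sep: Optional[str] = None) -> None:
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = "gene"
    # %.17g guarantees binary round-trip of IEEE doubles
    out.to_csv(path, sep=_sep_for(path, sep), float_format="%.17g")


def read_cell_metadata(path: PathLike) -> pd.DataFrame:
    """Read per-cell metadata CSV (cell_id, patient_id, unique_reads, is_cluster)."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    if "cell_id" not in df.columns:
        raise FormatError("cell metadata requires a cell_id column")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell metadata lacks columns {missing}")
    df = df.set_index(df["cell_id"].astype(str)).drop(columns=["cell_id"])
    if df.index.has_duplicates:
        raise FormatError("duplicate cell_id in metadata")
    return df


def write_cell_metadata(matrix: ExpressionMatrix, path: PathLike) -> None:
    out = matrix.cell_meta.copy()
    out.insert(0, "cell_id", out.index)
    out.to_csv(Path(path), index=False)


def read_clinical_table(path: PathLike) -> List[PatientRecord]:
    """Read a clinical CSV into validated patient records.

    Required columns: ``patient_id``, ``treatment_line``, ``pfs_days``,
    ``pfs_event``, ``os_days``, ``os_event``.  Unknown columns are preserved
    in each record's ``extras``.  Times may be blank (censoring information
    absent), but a present time needs its event flag and must be positive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table lacks columns {missing}")
    if df["patient_id"].astype(str).duplicated().any():
        raise FormatError("duplicate patient_id in clinical table")
    extra_cols = [c for c in df.columns if c not in CLINICAL_COLUMNS]
    records: List[PatientRecord] = []
    for _, row in df.iterrows():
        def _opt_time(v):
            return None if pd.isna(v) else float(v)

        def _opt_flag(v):
            if pd.isna(v):
                return None
            if isinstance(v, str):
                return v.strip().lower() in {"true", "1", "yes", "t"}
            return bool(v)

        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                treatment_line=int(row["treatment_line"]),
                pfs_days=_opt_time(row["pfs_days"]),
                pfs_event=_opt_flag(row["pfs_event"]),
                os_days=_opt_time(row["os_days"]),
                os_event=_opt_flag(row["os_event"]),
                extras={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_clinical_table(records: List[PatientRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "treatment_line": r.treatment_line,
            "pfs_days": r.pfs_days,
            "pfs_event": r.pfs_event,
            "os_days": r.os_days,
            "os_event": r.os_event,
        }
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format="%.17g")


def write_table(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    """Write any report table as TSV."""
    df.to_csv(Path(path), sep="\t", index=index)
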