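"""Core data model: expression matrices, clinical records, annotations.

The in-memory containers are thin, validated wrappers around pandas objects.
``ExpressionMatrix`` holds a genes-as-rows, cells-as-columns TPM matrix plus
per-cell metadata (patient, uniquely mapped reads, cluster flag); gene lookup
is case-insensitive, and a panel gene absent from the matrix behaves as
all-zero expression (logged once) so that marker panels remain scorable on
partial matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError, ValidationError

logger = logging.getLogger(__name__)

META_COLUMNS = ("patient_id", "unique_reads", "is_cluster")


class ExpressionMatrix:
    """Gene x cell non-negative TPM matrix with per-cell metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per cell ID.
    cell_meta
        DataFrame indexed by cell ID with columns ``patient_id`` (str),
        ``unique_reads`` (non-negative int) and ``is_cluster`` (bool).
        If omitted, a minimal metadata frame is synthesised (single patient
        ``"P0"``, reads 1e6, no clusters) — convenient for unit fixtures.
    """

    def __init__(self, values: pd.DataFrame,
                 cell_meta: Optional[pd.DataFrame] = None):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate cell identifiers: {dups}")
        arr = values.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValidationError("expression values must be numeric")
            if np.isnan(arr).any():
                raise ValidationError("expression values contain missing entries")
            if not np.isfinite(arr).all():
                raise ValidationError("expression values must be finite")
            if (arr < 0).any():
                raise ValidationError("expression values must be non-negative")
        self.values = values.astype(float)
        if cell_meta is None:
            cell_meta = pd.DataFrame(
                {
                    "patient_id": "P0",
                    "unique_reads": 1_000_000,
                    "is_cluster": False,
                },
                index=values.columns,
            )
        missing = [c for c in META_COLUMNS if c not in cell_meta.columns]
        if missing:
            raise MetadataError(f"cell metadata lacks columns {missing}")
        if set(cell_meta.index) != set(values.columns):
            raise FormatError("cell metadata index does not match cell IDs")
        cell_meta = cell_meta.loc[values.columns]
        if cell_meta["patient_id"].isna().any():
            raise MetadataError("every cell needs a patient_id")
        reads = cell_meta["unique_reads"]
        if reads.isna().any() or (reads < 0).any():
            raise MetadataError("unique_reads must be present and non-negative")
        self.cell_meta = cell_meta.assign(
            patient_id=cell_meta["patient_id"].astype(str),
            unique_reads=reads.astype(np.int64),
            is_cluster=cell_meta["is_cluster"].astype(bool),
        )
        # case-insensitive gene lookup
        self._gene_lut: Dict[str, str] = {}
        for g in values.index:
            self._gene_lut.setdefault(str(g).upper(), g)
        self._warned_missing: set = set()

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_cells} cells)"

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.cell_meta.equals(other.cell_meta)
        )

    # -- access --------------------------------------------------------------
    def has_gene(self, gene: str) -> bool:
        return gene.upper() in self._gene_lut

    def gene(self, gene: str) -> pd.Series:
        """Expression of ``gene`` across cells; all-zero if absent (logged)."""
        key = gene.upper()
        if key in self._gene_lut:
            return self.values.loc[self._gene_lut[key]]
        if key not in self._warned_missing:
            logger.warning("gene %s absent from matrix; treated as zero", gene)
            self._warned_missing.add(key)
        return pd.Series(0.0, index=self.values.columns, name=gene)

    def panel_matrix(self, genes: Sequence[str]) -> pd.DataFrame:
        """Genes-as-rows submatrix over ``genes``, absent genes as zero rows."""
        return pd.DataFrame([self.gene(g).rename(g) for g in genes])

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(cell_ids)
        missing = [c for c in ids if c not in self.values.columns]
        if missing:
            raise FormatError(f"unknown cell IDs: {missing}")
        return ExpressionMatrix(self.values[ids], self.cell_meta.loc[ids])


@dataclass
class PatientRecord:
    """One patient's treatment line and survival endpoints.

    ``pfs_days``/``os_days`` are the progression-free and overall survival
    intervals in days from treatment start; the matching ``*_event`` flag is
    True when progression/death was observed and False when censored at last
    follow-up.  A missing time must come with a missing event flag.
    """

    patient_id: str
    treatment_line: int
    pfs_days: Optional[float] = None
    pfs_event: Optional[bool] = None
    os_days: Optional[float] = None
    os_event: Optional[bool] = None
    extras: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if int(self.treatment_line) < 1:
            raise ValidationError("treatment_line must be >= 1")
        self.treatment_line = int(self.treatment_line)
        for time_attr, event_attr in (("pfs_days", "pfs_event"),
                                      ("os_days", "os_event")):
            t = getattr(self, time_attr)
            e = getattr(self, event_attr)
            if t is not None:
                if not np.isfinite(t) or t <= 0:
                    raise ValidationError(f"{time_attr} must be > 0")
                if e is None:
                    raise ValidationError(
                        f"{event_attr} required when {time_attr} present")
                setattr(self, event_attr, bool(e))
            elif e is not None:
                raise ValidationError(
                    f"{event_attr} defined without {time_attr}")


EPITHELIAL_GROUPS = ("Low", "Middle", "High")
EMT_STEM_GROUPS = (
    "HighStem_LowEMT",
    "LowStem_MiddleEMT",
    "LowStem_LowEMT",
    "LowStem_HighEMT",
)


@dataclass
class CellAnnotation:
    """Per-cell phenotype: panel scores, group labels and category."""

    cell_id: str
    patient_id: str
    is_cluster: bool = False
    epithelial_score: float = 0.0
    stem_score: float = 0.0
    emt_score: float = 0.0
    epithelial_group: Optional[str] = None
    emt_stem_group: Optional[str] = None
    category: object = None  # 1..4 or "other" once assigned

    def __post_init__(self) -> None:
        for s in (self.epithelial_score, self.stem_score, self.emt_score):
            if s < 0:
                raise ValidationError("panel scores are sums of logs, >= 0")
        if (self.epithelial_group is not None
                and self.epithelial_group not in EPITHELIAL_GROUPS):
            raise ValidationError(
                f"unknown epithelial group {self.epithelial_group!r}")
        if (self.emt_stem_group is not None
                and self.emt_stem_group not in EMT_STEM_GROUPS):
            raise ValidationError(
                f"unknown EMT/stem group {self.emt_stem_group!r}")


@dataclass
class ContingencyTable:
    """r x c table of non-negative integer counts with labelled margins."""

    row_labels: Sequence[str]
    col_labels: Sequence[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        r, c = self.counts.shape
        if r != len(self.row_labels) or c != len(self.col_labels):
            raise FormatError("counts shape does not match labels")
        if r < 2 or c < 2:
            raise FormatError("contingency table needs at least 2x2")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


def annotations_to_frame(annotations: Sequence[CellAnnotation]) -> pd.DataFrame:
    """Tabular view of annotations (one row per cell)."""
    return pd.DataFrame(
        [
            {
                "cell_id": a.cell_id,
                "patient_id": a.patient_id,
                "is_cluster": a.is_cluster,
                "epithelial_score": a.epithelial_score,
                "stem_score": a.stem_score,
                "emt_score": a.emt_score,
                "epithelial_group": a.epithelial_group,
                "emt_stem_group": a.emt_stem_group,
                "category": a.category,
            }
            for a in annotations
        ]
    )
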