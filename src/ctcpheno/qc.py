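"""Candidate QC: read-depth filtering and contaminant elimination.

Single CTC candidates are collected marker-free (nucleated, CD45/CD50
immunofluorescence negative), so the sequenced wells still contain
leukocytes, endothelial cells and clusters with conjugated leukocytes.
These are eliminated from the TPM profiles: a cell expressing the leukocyte
marker PTPRC at or above the positivity threshold is a leukocyte (or, when
flagged as a multi-cell cluster, a mixed cluster — clusters conjugated to
leukocytes cannot be distinguished from leukocytes alone, so both are
excluded); a PTPRC-negative cell expressing the endothelial marker PECAM1
is endothelial.  Read-depth QC (strictly more than ``min_reads`` uniquely
mapped reads) is applied first and reported per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

import pandas as pd

from .core import ExpressionMatrix
from .errors import CardinalityError, MetadataError
from .utils import round_half_up

logger = logging.getLogger(__name__)

CONTAMINANT_CLASSES = ("none", "leukocyte", "endothelial", "mixed_cluster")


@dataclass
class QCResult:
    """Per-cell QC outcome; ``retained`` iff reads pass and no contaminant call."""

    cell_id: str
    unique_reads: int
    reads_pass: bool
    contaminant_class: str = "none"
    retained: bool = False

    def __post_init__(self) -> None:
        if self.contaminant_class not in CONTAMINANT_CLASSES:
            raise ValueError(
                f"unknown contaminant class {self.contaminant_class!r}")
        self.retained = bool(self.reads_pass
                             and self.contaminant_class == "none")


def filter_by_reads(cells: ExpressionMatrix,
                    min_reads: int = 100_000) -> List[QCResult]:
    """Flag cells by uniquely-mapped read count (pass iff reads > min_reads).

    No cells are dropped here; the result carries one entry per cell in
    matrix order.
    """
    if "unique_reads" not in cells.cell_meta.columns:
        raise MetadataError("unique_reads missing from cell metadata")
    results = []
    for cell_id, reads in cells.cell_meta["unique_reads"].items():
        results.append(QCResult(cell_id=str(cell_id), unique_reads=int(reads),
                                reads_pass=int(reads) > int(min_reads)))
    return results


def classify_contaminants(cells: ExpressionMatrix,
                          positivity_tpm: float = 1.0,
                          reads_results: Sequence[QCResult] | None = None,
                          ) -> List[QCResult]:
    """Call leukocyte / endothelial / mixed-cluster contaminants per cell.

    Precedence: PTPRC positivity dominates PECAM1 (leukocytes are the
    dominant contaminant of the enrichment protocol).  Cluster-flagged
    cells positive for PTPRC become ``mixed_cluster``.
    """
    by_cell: Dict[str, QCResult] = {}
    if reads_results is not None:
        by_cell = {r.cell_id: r for r in reads_results}
    ptprc = cells.gene("PTPRC")
    pecam1 = cells.gene("PECAM1")
    is_cluster = cells.cell_meta["is_cluster"]
    results = []
    for cell_id in cells.cell_ids:
        if ptprc[cell_id] >= positivity_tpm:
            klass = "mixed_cluster" if bool(is_cluster[cell_id]) else "leukocyte"
        elif pecam1[cell_id] >= positivity_tpm:
            klass = "endothelial"
        else:
            klass = "none"
        prior = by_cell.get(cell_id)
        reads = (prior.unique_reads if prior is not None
                 else int(cells.cell_meta.loc[cell_id, "unique_reads"]))
        reads_pass = prior.reads_pass if prior is not None else True
        results.append(QCResult(cell_id=cell_id, unique_reads=reads,
                                reads_pass=reads_pass,
                                contaminant_class=klass))
    return results


def run_qc(cells: ExpressionMatrix, min_reads: int = 100_000,
           positivity_tpm: float = 1.0) -> List[QCResult]:
    """Read-depth QC followed by contaminant classification."""
    reads = filter_by_reads(cells, min_reads=min_reads)
    return classify_contaminants(cells, positivity_tpm=positivity_tpm,
                                 reads_results=reads)


def qc_summary(results: Sequence[QCResult]) -> Dict[str, int]:
    """Candidate/retained/eliminated counts with integer retained percentage.

    ``retained_pct`` is rounded half-up to the nearest integer percent.
    """
    if not results:
        raise CardinalityError("qc_summary needs at least one QC result")
    candidates = len(results)
    retained = sum(r.retained for r in results)
    return {
        "candidates": candidates,
        "retained": retained,
        "eliminated": candidates - retained,
        "retained_pct": round_half_up(100.0 * retained / candidates),
    }


def qc_table(results: Sequence[QCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "unique_reads": r.unique_reads,
                "reads_pass": r.reads_pass,
                "contaminant_class": r.contaminant_class,
                "retained": r.retained,
            }
            for r in results
        ]
    )
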