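"""Reference fixtures reconstructed from published summary tables.

The underlying study reports only summary tables for its 27-patient mCRC
cohort (the per-cell sequencing data live in a raw-read archive and are not
needed here).  This module rebuilds *synthetic* per-cell / per-patient
fixtures that realize those printed summaries exactly:

* the 59-cell cross-classification of epithelial groups (High 8 / Middle 10 /
  Low 41) against EMT/stem groups (7 / 9 / 12 / 31), cell identities synthetic;
* a 27-patient detection fixture with 8 epithelial-positive, 20
  EMT-positive and 24 either-positive patients (pairwise overlaps are not
  published; the reconstruction uses the unique patient-set sizes implied by
  inclusion-exclusion, which is all the detection-rate statistics consume);
* a 110-candidate QC fixture: every candidate above 100,000 uniquely mapped
  reads, 109 above 400,000, and 51 candidates eliminated as leukocytes,
  endothelial cells or mixed clusters, leaving 59 retained.

Only the summary statistics of these fixtures are meaningful; per-cell
identities, expression values and patient assignments are synthetic.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd

from .core import (CellAnnotation, ContingencyTable, ExpressionMatrix,
                   PatientRecord)
from .crosstab import CROSSTAB_COLS, CROSSTAB_ROWS

#: published 3x4 cross-tab: rows High/Middle/Low epithelial, columns
#: HighStem_LowEMT / LowStem_MiddleEMT / LowStem_LowEMT / LowStem_HighEMT
REPORTED_CROSSTAB_COUNTS = (
    (7, 0, 1, 0),
    (0, 0, 7, 3),
    (0, 9, 4, 28),
)

#: published detection counts over 27 patients
REPORTED_DETECTION = {"epithelial": 8, "emt": 20, "epithelial_or_emt": 24}
REPORTED_COHORT_SIZE = 27


def reported_crosstab() -> ContingencyTable:
    """The published 59-cell contingency table."""
    return ContingencyTable(CROSSTAB_ROWS, CROSSTAB_COLS,
                            np.array(REPORTED_CROSSTAB_COUNTS))


def crosstab_annotations() -> List[CellAnnotation]:
    """Synthetic 59-cell annotation list realizing the published cross-tab."""
    annotations = []
    k = 0
    for i, row in enumerate(CROSSTAB_ROWS):
        for j, col in enumerate(CROSSTAB_COLS):
            for _ in range(REPORTED_CROSSTAB_COUNTS[i][j]):
                k += 1
                annotations.append(CellAnnotation(
                    cell_id=f"R{k:03d}", patient_id=f"P{(k - 1) % 24 + 1:03d}",
                    epithelial_group=row, emt_stem_group=col))
    return annotations


def detection_fixture() -> Tuple[List[CellAnnotation], List[PatientRecord]]:
    """Synthetic 27-patient fixture with the published positivity sets.

    Epithelial-positive patients are P001-P008 and EMT-positive are
    P005-P024, so that either-positive = P001-P024 (inclusion-exclusion
    forces an overlap of 4).  P025-P027 have no retained cells.
    """
    annotations: List[CellAnnotation] = []
    k = 0
    for i in range(1, REPORTED_COHORT_SIZE + 1):
        pid = f"P{i:03d}"
        if i <= REPORTED_DETECTION["epithelial"]:
            k += 1
            annotations.append(CellAnnotation(
                cell_id=f"D{k:03d}", patient_id=pid,
                epithelial_group="Middle", emt_stem_group="LowStem_LowEMT"))
        if 5 <= i <= 24:
            k += 1
            annotations.append(CellAnnotation(
                cell_id=f"D{k:03d}", patient_id=pid,
                epithelial_group="Low", emt_stem_group="LowStem_HighEMT"))
    clinical = [PatientRecord(patient_id=f"P{i:03d}", treatment_line=2)
                for i in range(1, REPORTED_COHORT_SIZE + 1)]
    return annotations, clinical


def qc_fixture() -> ExpressionMatrix:
    """Synthetic 110-candidate matrix matching the published QC arithmetic.

    40 leukocytes (PTPRC+), 5 endothelial (PECAM1+), 6 mixed clusters
    (PTPRC+, cluster flag) and 59 marker-negative CTCs; all candidates above
    100,000 uniquely mapped reads and exactly one at or below 400,000.
    """
    genes = ["PTPRC", "PECAM1", "EPCAM"]
    cols = {}
    meta_rows = []

    def add(cell_id, ptprc, pecam1, epcam, cluster, reads):
        cols[cell_id] = [ptprc, pecam1, epcam]
        meta_rows.append({"cell_id": cell_id, "patient_id": "Q0",
                          "unique_reads": reads, "is_cluster": cluster})

    k = 0
    for _ in range(40):
        k += 1
        add(f"Q{k:03d}", 500.0, 0.0, 0.0, False, 900_000)
    for _ in range(5):
        k += 1
        add(f"Q{k:03d}", 0.0, 300.0, 0.0, False, 900_000)
    for _ in range(6):
        k += 1
        add(f"Q{k:03d}", 200.0, 0.0, 40.0, True, 900_000)
    for i in range(59):
        k += 1
        reads = 150_000 if i == 0 else 900_000  # the single sub-400k cell
        add(f"Q{k:03d}", 0.0, 0.0, 50.0, False, reads)
    values = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    return ExpressionMatrix(values, meta)
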