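"""Cross-classification statistics: 3x4 contingency analysis, Fisher tests,
detection rates and within-patient heterogeneity.

The 12-way cross-classification of epithelial groups against EMT/stem groups
is tested for independence with the Pearson chi-square test and dissected
cell-by-cell with Haberman adjusted standardized residuals,

    r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - n_i./n) (1 - n_.j/n)),

approximately standard normal under independence, coded significant at
|r| >= 1.96 (p < 0.05) and |r| >= 2.58 (p < 0.01), signed (over- vs
under-represented).  Four (epithelial, EMT/stem) pairs are promoted to named
categories 1-4; everything else is "other".

Detection rates count a patient positive for a CTC type when at least one
retained cell carries it (epithelial CTC = Middle or High epithelial group;
EMT CTC = Middle or High EMT group), and rate comparisons use the exact
two-sided Fisher test computed by hypergeometric enumeration in exact
rational arithmetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import (CellAnnotation, ContingencyTable, EMT_STEM_GROUPS,
                   EPITHELIAL_GROUPS, PatientRecord)
from .errors import DegenerateTableError, JoinError, ValidationError
from .utils import round_half_up

logger = logging.getLogger(__name__)

#: row order of the published cross-tab (by epithelial level, high first)
CROSSTAB_ROWS = ("High", "Middle", "Low")
CROSSTAB_COLS = EMT_STEM_GROUPS

#: the four named categories as (epithelial_group, emt_stem_group) pairs
CATEGORY_MAP: Dict[Tuple[str, str], int] = {
    ("High", "HighStem_LowEMT"): 1,
    ("Low", "LowStem_MiddleEMT"): 2,
    ("Middle", "LowStem_LowEMT"): 3,
    ("Low", "LowStem_HighEMT"): 4,
}

SIGNIFICANCE_CODES = ("high_p01", "high_p05", "ns", "low_p05", "low_p01")

EPITHELIAL_POSITIVE_GROUPS = ("Middle", "High")
EMT_POSITIVE_GROUPS = ("LowStem_MiddleEMT", "LowStem_HighEMT")


def cross_tabulate(annotations: Sequence[CellAnnotation]) -> ContingencyTable:
    """3x4 cross-tab of epithelial group (rows) vs EMT/stem group (columns)."""
    counts = np.zeros((len(CROSSTAB_ROWS), len(CROSSTAB_COLS)), dtype=np.int64)
    row_of = {g: i for i, g in enumerate(CROSSTAB_ROWS)}
    col_of = {g: j for j, g in enumerate(CROSSTAB_COLS)}
    for a in annotations:
        if a.epithelial_group is None or a.emt_stem_group is None:
            raise ValidationError(
                f"cell {a.cell_id} lacks a group label")
        counts[row_of[a.epithelial_group], col_of[a.emt_stem_group]] += 1
    return ContingencyTable(CROSSTAB_ROWS, CROSSTAB_COLS, counts)


def _expected(table: ContingencyTable) -> np.ndarray:
    n = table.n
    if n == 0:
        raise DegenerateTableError("empty contingency table")
    rt = table.row_totals
    ct = table.col_totals
    if (rt == 0).any() or (ct == 0).any():
        raise DegenerateTableError("zero row or column margin")
    return np.outer(rt, ct) / n


def chi_square_test(table: ContingencyTable) -> Dict[str, float]:
    """Pearson chi-square test of independence on an r x c table."""
    expected = _expected(table)
    if (expected < 5).any():
        logger.warning(
            "%d of %d expected counts below 5; chi-square approximation "
            "may be poor", int((expected < 5).sum()), expected.size)
    statistic = float(((table.counts - expected) ** 2 / expected).sum())
    df = (len(table.row_labels) - 1) * (len(table.col_labels) - 1)
    return {"statistic": statistic, "df": df,
            "p": float(chi2.sf(statistic, df))}


@dataclass
class ResidualCell:
    row: str
    col: str
    observed: int
    expected: float
    adjusted_residual: float
    significance: str

    def __post_init__(self) -> None:
        if self.significance not in SIGNIFICANCE_CODES:
            raise ValueError(f"bad significance code {self.significance!r}")


def _code(residual: float, alpha_levels: Tuple[float, float]) -> str:
    # alpha_levels sorted loose->strict, cutpoints fixed at the two-sided
    # normal quantiles 1.96 / 2.58
    loose, strict = 1.959963984540054, 2.5758293035489004
    if residual >= strict:
        return "high_p01"
    if residual >= loose:
        return "high_p05"
    if residual <= -strict:
        return "low_p01"
    if residual <= -loose:
        return "low_p05"
    return "ns"


def adjusted_residuals(table: ContingencyTable,
                       alpha_levels: Tuple[float, float] = (0.05, 0.01),
                       ) -> List[ResidualCell]:
    """Haberman adjusted standardized residual for every table cell."""
    expected = _expected(table)
    n = table.n
    rt = table.row_totals / n
    ct = table.col_totals / n
    cells = []
    for i, rlab in enumerate(table.row_labels):
        for j, clab in enumerate(table.col_labels):
            denom = math.sqrt(expected[i, j] * (1 - rt[i]) * (1 - ct[j]))
            resid = (table.counts[i, j] - expected[i, j]) / denom
            cells.append(ResidualCell(
                row=rlab, col=clab, observed=int(table.counts[i, j]),
                expected=float(expected[i, j]),
                adjusted_residual=float(resid),
                significance=_code(float(resid), alpha_levels)))
    return cells


def count_significant(residuals: Sequence[ResidualCell], direction: str,
                      alpha: float = 0.05) -> int:
    """Number of cells significantly high (or low) at the given level."""
    if direction not in {"high", "low"}:
        raise ValueError("direction must be 'high' or 'low'")
    if alpha >= 0.05:
        codes = {f"{direction}_p05", f"{direction}_p01"}
    else:
        codes = {f"{direction}_p01"}
    return sum(r.significance in codes for r in residuals)


def residual_table(residuals: Sequence[ResidualCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "epithelial_group": r.row,
                "emt_stem_group": r.col,
                "observed": r.observed,
                "expected": r.expected,
                "adjusted_residual": r.adjusted_residual,
                "significance": r.significance,
            }
            for r in residuals
        ]
    )


def assign_categories(annotations: Sequence[CellAnnotation],
                      ) -> List[CellAnnotation]:
    """Set ``category`` (1-4 or "other") on every annotation, in place."""
    for a in annotations:
        a.category = CATEGORY_MAP.get(
            (a.epithelial_group, a.emt_stem_group), "other")
    return list(annotations)


@dataclass
class DetectionTable:
    """Per-CTC-type patient positivity over a fixed cohort."""

    cohort_size: int
    positive: Dict[str, int]

    def negative(self, ctc_type: str) -> int:
        return self.cohort_size - self.positive[ctc_type]

    def rate_pct(self, ctc_type: str) -> int:
        return round_half_up(100.0 * self.positive[ctc_type]
                             / self.cohort_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ctc_type": t,
                    "positive": self.positive[t],
                    "negative": self.negative(t),
                    "rate_pct": self.rate_pct(t),
                }
                for t in self.positive
            ]
        )


def ctc_type_counts(annotations: Sequence[CellAnnotation],
                    ) -> pd.DataFrame:
    """Per-patient counts of epithelial, EMT and either-type CTCs."""
    rows: Dict[str, Dict[str, int]] = {}
    for a in annotations:
        d = rows.setdefault(a.patient_id,
                            {"epithelial": 0, "emt": 0,
                             "epithelial_or_emt": 0})
        is_epi = a.epithelial_group in EPITHELIAL_POSITIVE_GROUPS
        is_emt = a.emt_stem_group in EMT_POSITIVE_GROUPS
        d["epithelial"] += int(is_epi)
        d["emt"] += int(is_emt)
        d["epithelial_or_emt"] += int(is_epi or is_emt)
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis(
        "patient_id").reset_index()
    return out


def patient_positivity(annotations: Sequence[CellAnnotation],
                       clinical: Sequence[PatientRecord]) -> DetectionTable:
    """Patient-level detection table for the three CTC types.

    A patient is positive for a type when one or more of their retained
    cells carries it; cohort patients with no retained cells are negative.
    """
    cohort = {r.patient_id for r in clinical}
    unknown = {a.patient_id for a in annotations} - cohort
    if unknown:
        raise JoinError(f"annotations reference unknown patients {sorted(unknown)}")
    counts = ctc_type_counts(annotations)
    positive = {"epithelial": 0, "emt": 0, "epithelial_or_emt": 0}
    for _, row in counts.iterrows():
        for t in positive:
            positive[t] += int(row[t] >= 1)
    return DetectionTable(cohort_size=len(cohort), positive=positive)


def _hypergeom_pmf_exact(k: int, a_margin: int, b_margin: int,
                         col_margin: int) -> Fraction:
    """P(first row of a 2x2 with fixed margins has k in column one)."""
    n = a_margin + b_margin
    return (Fraction(math.comb(a_margin, k))
            * Fraction(math.comb(b_margin, col_margin - k))
            / Fraction(math.comb(n, col_margin)))


def fisher_exact_2x2(table: Iterable[Iterable[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by exact enumeration.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities no larger than the observed table's, in exact rational
    arithmetic (so no floating-point threshold fudge is needed).
    """
    t = np.asarray(list(map(list, table)), dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("fisher_exact_2x2 needs a non-negative 2x2 table")
    if t.sum() == 0:
        raise DegenerateTableError("all-zero 2x2 table")
    a_margin = int(t[0].sum())
    b_margin = int(t[1].sum())
    col_margin = int(t[:, 0].sum())
    lo = max(0, col_margin - b_margin)
    hi = min(col_margin, a_margin)
    p_obs = _hypergeom_pmf_exact(int(t[0, 0]), a_margin, b_margin, col_margin)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        p_k = _hypergeom_pmf_exact(k, a_margin, b_margin, col_margin)
        if p_k <= p_obs:
            total += p_k
    return float(min(total, Fraction(1)))


def mcnemar_2x2(discordant_b: int, discordant_c: int) -> float:
    """Exact McNemar test p for paired positivity (non-default variant).

    ``discordant_b``/``discordant_c`` are the two off-diagonal counts of the
    paired 2x2 (positive by one CTC type only).  Two-sided exact binomial.
    """
    from scipy.stats import binomtest
    n = discordant_b + discordant_c
    if n == 0:
        return 1.0
    return float(binomtest(discordant_b, n, 0.5).pvalue)


def heterogeneity_summary(annotations: Sequence[CellAnnotation],
                          ) -> Dict[str, object]:
    """Within-patient category diversity.

    A patient is multi-category when their cells span two or more distinct
    classes among {1, 2, 3, 4, "other"}.  ``combo_fractions`` gives, for
    each category pair observed in some multi-category patient, the fraction
    of multi-category patients whose category set contains that pair.
    """
    sets: Dict[str, set] = {}
    for a in annotations:
        if a.category is None:
            raise ValidationError(f"cell {a.cell_id} has no category")
        sets.setdefault(a.patient_id, set()).add(a.category)
    multi = {p: s for p, s in sets.items() if len(s) >= 2}
    n_multi = len(multi)
    combo_counts: Dict[Tuple, int] = {}
    for s in multi.values():
        for pair in combinations(sorted(s, key=str), 2):
            combo_counts[pair] = combo_counts.get(pair, 0) + 1
    combo_fractions = {pair: cnt / n_multi
                       for pair, cnt in combo_counts.items()} if n_multi else {}
    return {"n_multi_category": n_multi, "combo_fractions": combo_fractions}
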