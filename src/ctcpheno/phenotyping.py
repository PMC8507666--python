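"""Marker-panel scoring and group assignment for retained CTCs.

Each retained cell gets three panel scores (epithelial, stem, EMT), defined
as the sum of log10(TPM + 1) over the panel's genes — the same log scale the
marker heatmaps are drawn on.  Cells are then clustered twice with Ward
linkage on Euclidean distances of the log-transformed marker submatrices:

* epithelial axis — 14 genes (epithelial panel + PTPRC + PECAM1), cut at
  k = 3, clusters named Low / Middle / High by ascending mean epithelial
  score;
* EMT/stem axis — 18 genes (stem + EMT panels), cut at k = 4; the cluster
  with the highest mean stem score is named HighStem_LowEMT and the
  remaining three are ranked by descending mean EMT score into
  LowStem_HighEMT / LowStem_MiddleEMT / LowStem_LowEMT.

Group naming is by empirical score ordering, never by cluster index, so the
labels are invariant to cell ordering.  Ties in cluster mean scores are
broken by cluster size (larger cluster takes the lower epithelial / higher
stem / higher EMT name) and logged.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu

from . import markers
from .config import PipelineConfig
from .core import CellAnnotation, ExpressionMatrix
from .errors import CardinalityError, ValidationError

logger = logging.getLogger(__name__)


def log_transform(values) -> np.ndarray:
    """Elementwise log10(TPM + 1); rejects negative input."""
    arr = np.asarray(values, dtype=float)
    if arr.size and (arr < 0).any():
        raise ValidationError("log_transform requires non-negative TPM")
    return np.log10(arr + 1.0)


def gene_set_score(cell: pd.Series, panel: markers.MarkerPanel,
                   method: str = "sum") -> float:
    """Panel score of one cell: sum (or mean) of log10(TPM+1) over panel genes.

    ``cell`` is indexed by gene symbol (matched case-insensitively); genes
    absent from the profile contribute zero.
    """
    lut = {str(g).upper(): v for g, v in cell.items()}
    logged = [float(log_transform(lut.get(g.upper(), 0.0))) for g in panel]
    total = float(np.sum(logged))
    if method == "mean":
        return total / len(panel)
    return total


def cluster_cells(log_matrix: pd.DataFrame, k: int) -> np.ndarray:
    """Ward/Euclidean agglomerative clustering cut to exactly ``k`` clusters.

    ``log_matrix`` is cells-as-rows over the marker genes, already on the
    log10(TPM+1) scale.  Returns integer labels (1..k) in row order.
    Deterministic for a fixed row ordering.
    """
    n = log_matrix.shape[0]
    if n < k:
        raise CardinalityError(f"cannot cut {n} cells into {k} clusters")
    if k == 1:
        return np.ones(n, dtype=int)
    Z = linkage(log_matrix.to_numpy(), method="ward", metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust")


def _cluster_stats(labels: np.ndarray, scores: Sequence[float]):
    scores = np.asarray(scores, dtype=float)
    out = {}
    for lab in np.unique(labels):
        mask = labels == lab
        out[int(lab)] = (float(scores[mask].mean()), int(mask.sum()))
    return out


def name_epithelial_groups(labels: np.ndarray,
                           epithelial_scores: Sequence[float],
                           ) -> List[str]:
    """Name 3 clusters Low/Middle/High by ascending mean epithelial score."""
    stats = _cluster_stats(labels, epithelial_scores)
    if len(stats) != 3:
        raise CardinalityError(
            f"epithelial naming expects exactly 3 clusters, got {len(stats)}")
    means = {lab: m for lab, (m, _) in stats.items()}
    if len(set(means.values())) < len(means):
        logger.warning("tied epithelial cluster means; breaking ties by "
                       "cluster size (larger -> lower group)")
    # ascending mean; tie -> larger cluster first (lower group); then index
    order = sorted(stats, key=lambda lab: (stats[lab][0], -stats[lab][1], lab))
    name_of = dict(zip(order, ("Low", "Middle", "High")))
    return [name_of[int(lab)] for lab in labels]


def name_emt_stem_groups(labels: np.ndarray, stem_scores: Sequence[float],
                         emt_scores: Sequence[float]) -> List[str]:
    """Name 4 clusters by stem/EMT score ordering.

    Highest mean stem score -> HighStem_LowEMT; the rest by descending mean
    EMT score -> LowStem_HighEMT, LowStem_MiddleEMT, LowStem_LowEMT.
    """
    stem_stats = _cluster_stats(labels, stem_scores)
    if len(stem_stats) != 4:
        raise CardinalityError(
            f"EMT/stem naming expects exactly 4 clusters, got {len(stem_stats)}")
    stem_means = [m for m, _ in stem_stats.values()]
    if len(set(stem_means)) < len(stem_means):
        logger.warning("tied stem cluster means; breaking ties by size")
    # max stem mean; tie -> larger cluster; then index
    high_stem = min(stem_stats,
                    key=lambda lab: (-stem_stats[lab][0], -stem_stats[lab][1],
                                     lab))
    emt_stats = _cluster_stats(labels, emt_scores)
    rest = [lab for lab in stem_stats if lab != high_stem]
    rest.sort(key=lambda lab: (-emt_stats[lab][0], -emt_stats[lab][1], lab))
    name_of = {high_stem: "HighStem_LowEMT"}
    for lab, name in zip(rest, ("LowStem_HighEMT", "LowStem_MiddleEMT",
                                "LowStem_LowEMT")):
        name_of[lab] = name
    return [name_of[int(lab)] for lab in labels]


def compare_group_scores(scores_a: Sequence[float],
                         scores_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value between two score groups.

    Exact (permutation) p for small untied samples, normal approximation
    with tie correction otherwise; no continuity correction, so identical
    groups give p = 1 exactly.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CardinalityError("both score groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # zero variance: no evidence either way
        return 1.0
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto",
                       use_continuity=False)
    return float(min(res.pvalue, 1.0))


def annotate_cells(cells: ExpressionMatrix,
                   config: Optional[PipelineConfig] = None,
                   ) -> List[CellAnnotation]:
    """Score, cluster and group-label every cell of ``cells``.

    Expects QC-retained cells only; raises if there are fewer cells than
    the larger cluster count.
    """
    config = config or PipelineConfig()
    method = config.score_method
    epi_panel = markers.EPITHELIAL
    stem_panel = markers.STEM
    emt_panel = markers.EMT

    epi_log = log_transform(
        cells.panel_matrix(markers.EPITHELIAL_AXIS_GENES).to_numpy())
    es_log = log_transform(
        cells.panel_matrix(markers.EMT_STEM_AXIS_GENES).to_numpy())
    epi_df = pd.DataFrame(epi_log.T, index=cells.cell_ids)
    es_df = pd.DataFrame(es_log.T, index=cells.cell_ids)

    columns = cells.values
    epithelial_scores = [gene_set_score(columns[c], epi_panel, method)
                         for c in cells.cell_ids]
    stem_scores = [gene_set_score(columns[c], stem_panel, method)
                   for c in cells.cell_ids]
    emt_scores = [gene_set_score(columns[c], emt_panel, method)
                  for c in cells.cell_ids]

    epi_labels = cluster_cells(epi_df, config.k_epithelial)
    es_labels = cluster_cells(es_df, config.k_emt_stem)
    epi_groups = name_epithelial_groups(epi_labels, epithelial_scores)
    es_groups = name_emt_stem_groups(es_labels, stem_scores, emt_scores)

    annotations = []
    for i, cell_id in enumerate(cells.cell_ids):
        annotations.append(
            CellAnnotation(
                cell_id=cell_id,
                patient_id=str(cells.cell_meta.loc[cell_id, "patient_id"]),
                is_cluster=bool(cells.cell_meta.loc[cell_id, "is_cluster"]),
                epithelial_score=float(epithelial_scores[i]),
                stem_score=float(stem_scores[i]),
                emt_score=float(emt_scores[i]),
                epithelial_group=epi_groups[i],
                emt_stem_group=es_groups[i],
            )
        )
    return annotations


def group_score_tests(annotations: Sequence[CellAnnotation]) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of panel scores between groups.

    Epithelial groups are compared on the epithelial score; EMT/stem groups
    on both the stem and EMT scores.  Rows for group pairs with an empty
    side are omitted.
    """
    rows = []
    by_epi: Dict[str, List[float]] = {}
    by_es_stem: Dict[str, List[float]] = {}
    by_es_emt: Dict[str, List[float]] = {}
    for a in annotations:
        by_epi.setdefault(a.epithelial_group, []).append(a.epithelial_score)
        by_es_stem.setdefault(a.emt_stem_group, []).append(a.stem_score)
        by_es_emt.setdefault(a.emt_stem_group, []).append(a.emt_score)

    def _pairs(groups, score_map, axis, score_name):
        present = [g for g in groups if score_map.get(g)]
        for i, ga in enumerate(present):
            for gb in present[i + 1:]:
                rows.append({
                    "axis": axis,
                    "score": score_name,
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": len(score_map[ga]),
                    "n_b": len(score_map[gb]),
                    "p_value": compare_group_scores(score_map[ga],
                                                    score_map[gb]),
                })

    from .core import EMT_STEM_GROUPS, EPITHELIAL_GROUPS
    _pairs(EPITHELIAL_GROUPS, by_epi, "epithelial", "epithelial_score")
    _pairs(EMT_STEM_GROUPS, by_es_stem, "emt_stem", "stem_score")
    _pairs(EMT_STEM_GROUPS, by_es_emt, "emt_stem", "emt_score")
    return pd.DataFrame(rows)
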