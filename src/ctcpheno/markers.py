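"""Marker gene panels used for CTC phenotyping.

Five fixed panels drive the whole analysis: a 12-gene epithelial panel,
single-gene leukocyte (PTPRC/CD45) and endothelial (PECAM1/CD31) panels used
for contaminant elimination, an 11-gene cancer-stem-cell panel and a 7-gene
EMT panel used for EMT/stem phenotyping.  Panel membership and ordering are
fixed; gene symbols are HGNC and matched case-insensitively downstream.

Note: the stem panel deliberately lists ``ABCB2`` (not the more common stem
marker ABCG2) to match the published panel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple


@dataclass(frozen=True)
class MarkerPanel:
    """A named, ordered marker gene list.

    Parameters
    ----------
    name
        Panel role, one of ``epithelial``, ``leukocyte``, ``endothelial``,
        ``stem``, ``emt``.
    genes
        Ordered HGNC symbols; order is preserved in heatmap-style outputs.
    """

    name: str
    genes: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} has no genes")
        upper = [g.upper() for g in self.genes]
        if len(set(upper)) != len(upper):
            raise ValueError(f"panel {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


EPITHELIAL = MarkerPanel(
    "epithelial",
    (
        "CDH1", "EPCAM", "CLDN1", "CLDN2", "CLDN3", "CLDN4", "CLDN7",
        "KRT8", "KRT18", "KRT19", "KRT20", "VIL1",
    ),
)
LEUKOCYTE = MarkerPanel("leukocyte", ("PTPRC",))
ENDOTHELIAL = MarkerPanel("endothelial", ("PECAM1",))
STEM = MarkerPanel(
    "stem",
    (
        "LGR5", "ALDH2", "CD44", "PROM1", "ABCB2", "SALL4", "KLF4",
        "MYC", "NANOG", "SOX2", "POU5F1",
    ),
)
EMT = MarkerPanel(
    "emt",
    ("VIM", "SPARC", "ITGB1", "TFAP4", "ZEB2", "SNAI1", "CDH2"),
)

PANELS = {p.name: p for p in (EPITHELIAL, LEUKOCYTE, ENDOTHELIAL, STEM, EMT)}

#: genes used for the epithelial-axis clustering (14 genes)
EPITHELIAL_AXIS_GENES: Tuple[str, ...] = (
    EPITHELIAL.genes + LEUKOCYTE.genes + ENDOTHELIAL.genes
)
#: genes used for the EMT/stem-axis clustering (18 genes)
EMT_STEM_AXIS_GENES: Tuple[str, ...] = STEM.genes + EMT.genes

#: all 32 panel genes in panel order
ALL_PANEL_GENES: Tuple[str, ...] = (
    EPITHELIAL.genes + LEUKOCYTE.genes + ENDOTHELIAL.genes
    + STEM.genes + EMT.genes
)
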