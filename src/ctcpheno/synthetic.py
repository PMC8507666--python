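"""Synthetic single-cell TPM and cohort generator.

Cells are drawn from archetypes that emulate the phenotypes the pipeline is
built to separate: epithelial CTCs at middle and high marker breadth, EMT
CTCs (full mesenchymal program vs a core VIM/SPARC/ITGB1 program), stem-like
CTC clusters co-expressing the high-epithelial set with CD44/ALDH2/MYC, and
the contaminant classes (leukocytes, endothelial cells, clusters with
conjugated leukocytes).  For each cell, every archetype "on" gene is drawn
log-normal on the log10-TPM scale, ``10**N(on_log_mean, on_log_sd)``, then
zeroed with probability ``dropout_prob`` (technical dropout); background
genes — the gene universe minus all panel genes — are independently nonzero
with ``background_rate`` at ``10**N(background_log_mean, on_log_sd)``.
Contaminant archetypes carry a much lower dropout for their identifying
marker: PTPRC/PECAM1 are constitutively abundant in their lineages and
dropout is strongly anti-correlated with abundance.

Cohorts attach cells to patients (candidate count per patient Poisson with
mean 3, emulating sparse clinical CTC counts of range roughly 1-9 with
median 2) and simulate survival with exponential event times whose hazard
is multiplied by ``hazard_ratio_emt`` for patients carrying at least
``emt_burden_threshold`` true EMT CTCs, under independent uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import markers
from .core import ExpressionMatrix, PatientRecord
from .errors import ConfigurationError

CTC_ARCHETYPES = ("epithelial_mid", "epithelial_high", "emt", "stem_cluster",
                  "emt_mid")
CONTAMINANT_ARCHETYPES = ("leukocyte", "endothelial", "mixed_cluster")
ARCHETYPE_NAMES = CTC_ARCHETYPES + CONTAMINANT_ARCHETYPES

#: expected phenotype labels per CTC archetype, used for recovery scoring
EXPECTED_EPITHELIAL_GROUP = {
    "epithelial_mid": "Middle",
    "epithelial_high": "High",
    "stem_cluster": "High",
    "emt": "Low",
    "emt_mid": "Low",
}
EXPECTED_EMT_STEM_GROUP = {
    "epithelial_mid": "LowStem_LowEMT",
    "epithelial_high": "LowStem_LowEMT",
    "stem_cluster": "HighStem_LowEMT",
    "emt": "LowStem_HighEMT",
    "emt_mid": "LowStem_MiddleEMT",
}

_EPI_MID_GENES = ("EPCAM", "CLDN4", "KRT8", "KRT18", "KRT19", "KRT20")
_EPI_HIGH_GENES = _EPI_MID_GENES + ("CLDN3", "CLDN7")
_STEM_CORE = ("CD44", "ALDH2", "MYC")
_EMT_CORE = ("VIM", "SPARC", "ITGB1")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative model of one cell class."""

    name: str
    on_genes: Tuple[str, ...]
    on_log_mean: float = 2.0
    on_log_sd: float = 0.5
    dropout_prob: float = 0.2
    background_log_mean: float = 0.5
    background_rate: float = 0.05
    is_cluster: bool = False

    def __post_init__(self) -> None:
        if not self.on_genes:
            raise ConfigurationError(f"archetype {self.name} has no on-genes")
        for p, label in ((self.dropout_prob, "dropout_prob"),
                         (self.background_rate, "background_rate")):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{label} must lie in [0, 1]")
        if self.on_log_sd <= 0:
            raise ConfigurationError("on_log_sd must be positive")


def default_archetypes(dropout_prob: float = 0.2,
                       on_log_sd: float = 0.5) -> List[ArchetypeSpec]:
    """The eight default archetypes at the stated noise level.

    Class means were fixed by a separation analysis (documented in the
    methods note) so that every adjacent class boundary sits several noise
    standard deviations from both centroids.
    """
    common = dict(on_log_sd=on_log_sd, dropout_prob=dropout_prob)
    # abundant lineage markers (PTPRC, PECAM1) rarely drop out; never more
    # often than the global rate
    contaminant = dict(on_log_sd=on_log_sd,
                       dropout_prob=min(0.02, dropout_prob))
    return [
        ArchetypeSpec("epithelial_mid", _EPI_MID_GENES, on_log_mean=2.0,
                      **common),
        ArchetypeSpec("epithelial_high", _EPI_HIGH_GENES, on_log_mean=2.4,
                      **common),
        ArchetypeSpec("emt", markers.EMT.genes, on_log_mean=2.4, **common),
        ArchetypeSpec("stem_cluster", _EPI_HIGH_GENES + _STEM_CORE,
                      on_log_mean=2.4, is_cluster=True, **common),
        ArchetypeSpec("emt_mid", _EMT_CORE, on_log_mean=2.0, **common),
        ArchetypeSpec("leukocyte", ("PTPRC",), on_log_mean=3.0,
                      **contaminant),
        ArchetypeSpec("endothelial", ("PECAM1",), on_log_mean=3.0,
                      **contaminant),
        ArchetypeSpec("mixed_cluster", _EPI_MID_GENES + ("PTPRC",),
                      on_log_mean=2.5, is_cluster=True, **contaminant),
    ]


def default_universe(n_background: int = 468) -> List[str]:
    """All 32 panel genes plus ``n_background`` background genes."""
    background = [f"BG{i:04d}" for i in range(1, n_background + 1)]
    return list(markers.ALL_PANEL_GENES) + background


@dataclass
class CohortSpec:
    """Cohort-level generative parameters."""

    n_patients: int = 27
    ctc_count_mean: float = 3.0
    archetype_mixture: Dict[str, float] = field(default_factory=lambda: {
        "epithelial_mid": 0.09,
        "epithelial_high": 0.03,
        "emt": 0.25,
        "stem_cluster": 0.06,
        "emt_mid": 0.08,
        "leukocyte": 0.37,
        "endothelial": 0.06,
        "mixed_cluster": 0.06,
    })
    baseline_hazard: float = 0.009          # per day; PFS scale
    os_hazard_factor: float = 0.35          # OS hazard = factor * baseline
    hazard_ratio_emt: float = 3.0
    emt_burden_threshold: int = 2
    censor_time_range: Tuple[float, float] = (100.0, 800.0)
    first_line_fraction: float = 0.185
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        total = sum(self.archetype_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("archetype mixture must sum to 1")
        if self.baseline_hazard <= 0 or self.hazard_ratio_emt <= 0:
            raise ConfigurationError("hazards must be positive")
        lo, hi = self.censor_time_range
        if not 0 < lo <= hi:
            raise ConfigurationError("censor_time_range must be positive")


def generate_cells(archetypes: Sequence[ArchetypeSpec],
                   counts: Dict[str, int],
                   universe: Optional[Sequence[str]] = None,
                   seed: int = 0,
                   rng: Optional[np.random.Generator] = None,
                   patient_ids: Optional[Sequence[str]] = None,
                   ) -> Tuple[ExpressionMatrix, pd.Series]:
    """Draw cells per archetype; returns (matrix, true labels).

    ``counts`` maps archetype name to number of cells.  Cells are emitted
    grouped by archetype in the order of ``archetypes``.  ``patient_ids``
    optionally assigns one patient per cell (matrix-wide order); default is
    a single synthetic patient.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    universe = list(universe) if universe is not None else default_universe()
    uni_index = {g: i for i, g in enumerate(universe)}
    spec_of = {a.name: a for a in archetypes}
    unknown = set(counts) - set(spec_of)
    if unknown:
        raise ConfigurationError(f"counts name unknown archetypes {sorted(unknown)}")
    for a in archetypes:
        missing = [g for g in a.on_genes if g not in uni_index]
        if missing:
            raise ConfigurationError(
                f"archetype {a.name} on-genes absent from universe: {missing}")
    panel_set = {g.upper() for g in markers.ALL_PANEL_GENES}
    background_idx = np.array(
        [i for i, g in enumerate(universe) if g.upper() not in panel_set],
        dtype=int)

    columns, labels, meta_rows = [], [], []
    cell_no = 0
    for a in archetypes:
        n = int(counts.get(a.name, 0))
        for _ in range(n):
            col = np.zeros(len(universe))
            on_idx = np.array([uni_index[g] for g in a.on_genes], dtype=int)
            on_vals = 10.0 ** rng.normal(a.on_log_mean, a.on_log_sd,
                                         size=on_idx.size)
            keep = rng.random(on_idx.size) >= a.dropout_prob
            col[on_idx[keep]] = on_vals[keep]
            if background_idx.size and a.background_rate > 0:
                bg_on = rng.random(background_idx.size) < a.background_rate
                col[background_idx[bg_on]] = 10.0 ** rng.normal(
                    a.background_log_mean, a.on_log_sd, size=int(bg_on.sum()))
            cell_no += 1
            cell_id = f"C{cell_no:04d}"
            columns.append(pd.Series(col, index=universe, name=cell_id))
            labels.append(a.name)
            meta_rows.append({
                "cell_id": cell_id,
                "patient_id": "S0",
                "unique_reads": int(10 ** rng.normal(6.3, 0.35)),
                "is_cluster": a.is_cluster,
            })
    if not columns:
        values = pd.DataFrame(index=universe)
        meta = pd.DataFrame(columns=["patient_id", "unique_reads",
                                     "is_cluster"]).astype(
            {"unique_reads": np.int64, "is_cluster": bool})
        return (ExpressionMatrix(values, meta),
                pd.Series([], dtype=object, name="archetype"))
    values = pd.concat(columns, axis=1)
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    if patient_ids is not None:
        if len(patient_ids) != len(columns):
            raise ConfigurationError("patient_ids length mismatch")
        meta["patient_id"] = list(patient_ids)
    label_series = pd.Series(labels, index=values.columns, name="archetype")
    return ExpressionMatrix(values, meta), label_series


def _simulate_patient_survival(rng: np.random.Generator, spec: CohortSpec,
                               emt_high: bool) -> Dict[str, object]:
    hr = spec.hazard_ratio_emt if emt_high else 1.0
    lo, hi = spec.censor_time_range
    out: Dict[str, object] = {}
    for endpoint, hazard in (("pfs", spec.baseline_hazard),
                             ("os", spec.baseline_hazard
                              * spec.os_hazard_factor)):
        t_event = rng.exponential(1.0 / (hazard * hr))
        t_cens = rng.uniform(lo, hi)
        observed = t_event <= t_cens
        t = max(min(t_event, t_cens), 1e-3)  # strictly positive days
        out[f"{endpoint}_days"] = float(t)
        out[f"{endpoint}_event"] = bool(observed)
    return out


def generate_cohort(spec: CohortSpec,
                    archetypes: Optional[Sequence[ArchetypeSpec]] = None,
                    with_expression: bool = True,
                    ) -> Tuple[Optional[ExpressionMatrix],
                               List[PatientRecord], pd.DataFrame]:
    """Simulate a full cohort: expression, clinical records and truth table.

    The truth table has one row per patient with the true per-archetype cell
    counts, derived EMT / epithelial CTC counts, and the high-EMT-burden
    indicator actually used to set the hazard.  ``with_expression=False``
    skips matrix generation (for survival-only simulations) and returns
    ``None`` in its place.
    """
    archetypes = list(archetypes) if archetypes is not None \
        else default_archetypes()
    rng = np.random.default_rng(spec.seed)
    names = [a.name for a in archetypes]
    probs = np.array([spec.archetype_mixture.get(n, 0.0) for n in names])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigurationError("mixture does not cover the given archetypes")

    per_patient_assignments: List[List[str]] = []
    truth_rows = []
    records = []
    emt_like = {"emt", "emt_mid"}
    epi_like = {"epithelial_mid", "epithelial_high", "stem_cluster"}
    for i in range(spec.n_patients):
        pid = f"P{i + 1:03d}"
        n_cand = int(rng.poisson(spec.ctc_count_mean))
        assigned = list(rng.choice(names, size=n_cand, p=probs)) if n_cand \
            else []
        per_patient_assignments.append(assigned)
        arch_counts = {n: assigned.count(n) for n in names}
        emt_count = sum(v for k, v in arch_counts.items() if k in emt_like)
        epi_count = sum(v for k, v in arch_counts.items() if k in epi_like)
        emt_high = emt_count >= spec.emt_burden_threshold
        surv = _simulate_patient_survival(rng, spec, emt_high)
        line = 1 if rng.random() < spec.first_line_fraction \
            else int(2 + rng.integers(0, 3))
        records.append(PatientRecord(patient_id=pid, treatment_line=line,
                                     **surv))
        truth_rows.append({
            "patient_id": pid, "n_candidates": n_cand,
            **{f"n_{n}": arch_counts[n] for n in names},
            "emt_ctc_count": emt_count,
            "epithelial_ctc_count": epi_count,
            "emt_high_burden": emt_high,
        })
    truth = pd.DataFrame(truth_rows)

    matrix = None
    if with_expression:
        counts = {n: sum(a.count(n) for a in per_patient_assignments)
                  for n in names}
        # cells are drawn grouped by archetype; map them back to patients
        # in a deterministic order
        patient_of: Dict[str, List[str]] = {n: [] for n in names}
        for pid, assigned in zip(truth["patient_id"], per_patient_assignments):
            for n in assigned:
                patient_of[n].append(pid)
        ordered_patients = [pid for a in archetypes
                            for pid in patient_of[a.name]]
        matrix, labels = generate_cells(archetypes, counts, rng=rng,
                                        patient_ids=ordered_patients)
        truth = truth.set_index("patient_id")
        truth["true_labels"] = [
            ";".join(labels[matrix.cell_meta["patient_id"] == pid])
            for pid in truth.index
        ]
        truth = truth.reset_index()
        matrix.cell_meta["true_archetype"] = labels
    return matrix, records, truth
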