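"""Survival analysis: Kaplan-Meier estimation and the Gehan generalized
Wilcoxon test, plus CTC-burden stratification of the cohort.

The two-sample test is Gehan's censored-data generalization of the
Wilcoxon test.  Each observation i receives the score

    U_i = #{j : j definitely later than i} - #{j : j definitely earlier},

where "i definitely earlier than j" requires i to be an event occurring
strictly before t_j (or at t_j when j is censored there; events precede
censorings at tied times).  The statistic is W = sum of U_i over one
stratum; under the permutation null Var(W) = n_a n_b sum(U^2) / (N(N-1)).
For small samples the exact permutation distribution of W is enumerated;
otherwise a standard normal approximation of W / sqrt(Var) is used.  With
no censoring W reduces (up to sign) to twice the centred rank-sum, i.e.
the classical two-sample Wilcoxon ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy.stats import norm

from .core import PatientRecord
from .errors import CardinalityError, JoinError, ValidationError

EXACT_ENUMERATION_LIMIT = 20_000  # max C(N, n_a) for the exact path


@dataclass
class SurvivalSample:
    patient_id: str
    time_days: float
    event: bool
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time_days) and self.time_days > 0):
            raise ValidationError("time_days must be positive and finite")
        self.event = bool(self.event)


@dataclass
class StratificationRule:
    """Split a cohort by CTC-type burden.

    ``exclusive=True`` additionally requires that no *other* CTC type be
    detectable in the patient (the "only had detectable EMT CTCs" reading).
    """

    ctc_type: str  # emt | epithelial | epithelial_or_emt
    min_count: int = 1
    exclusive: bool = False

    def __post_init__(self) -> None:
        if self.ctc_type not in {"emt", "epithelial", "epithelial_or_emt"}:
            raise ValidationError(f"unknown CTC type {self.ctc_type!r}")
        if self.min_count < 1:
            raise ValidationError("min_count must be >= 1")

    @property
    def label(self) -> str:
        excl = " only" if self.exclusive else ""
        return f"{self.ctc_type}{excl} >={self.min_count}"


@dataclass
class KMEstimate:
    """Product-limit survival curve with median and its confidence interval."""

    times: np.ndarray
    survival: np.ndarray
    median: Optional[float]
    median_ci: Tuple[Optional[float], Optional[float]]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(samples: Sequence[SurvivalSample],
                alpha: float = 0.05) -> KMEstimate:
    """Kaplan-Meier estimate with Brookmeyer-Crowley-style median CI.

    The median is the smallest time with S(t) <= 0.5 (undefined, ``None``,
    when the curve never reaches 0.5); its CI is read off the pointwise
    log-log confidence band.
    """
    if not samples:
        raise CardinalityError("km_estimate needs at least one sample")
    times = [s.time_days for s in samples]
    events = [s.event for s in samples]
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    med = kmf.median_survival_time_
    median = None if math.isinf(med) else float(med)
    ci_frame = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci_frame.iloc[0, 0]), float(ci_frame.iloc[0, 1])
    median_ci = (None if math.isinf(lo) else lo,
                 None if math.isinf(hi) else hi)
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=median,
        median_ci=median_ci,
        n=len(samples),
        n_events=int(sum(events)),
    )


def gehan_scores(times: Sequence[float], events: Sequence[bool]) -> np.ndarray:
    """Gehan U score for every observation of the pooled sample."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n = t.size
    U = np.zeros(n, dtype=np.int64)

    def definitely_before(i: int, j: int) -> bool:
        return bool(e[i]) and (t[i] < t[j] or (t[i] == t[j] and not e[j]))

    for i in range(n):
        later = sum(definitely_before(i, j) for j in range(n) if j != i)
        earlier = sum(definitely_before(j, i) for j in range(n) if j != i)
        U[i] = later - earlier
    return U


def gehan_wilcoxon_test(a: Sequence[SurvivalSample],
                        b: Sequence[SurvivalSample],
                        method: str = "auto") -> Dict[str, float]:
    """Two-sided Gehan generalized Wilcoxon test between strata ``a`` and ``b``.

    ``method``: ``"exact"`` enumerates the permutation distribution of W,
    ``"asymptotic"`` uses the normal approximation with permutation
    variance, ``"auto"`` picks exact when C(N, n_a) is small.
    """
    if not a or not b:
        raise CardinalityError("both strata must be nonempty")
    na, nb = len(a), len(b)
    pooled = list(a) + list(b)
    times = [s.time_days for s in pooled]
    events = [s.event for s in pooled]
    U = gehan_scores(times, events)
    W = int(U[:na].sum())
    N = na + nb
    var = na * nb * float((U.astype(float) ** 2).sum()) / (N * (N - 1))

    if method == "auto":
        method = ("exact" if math.comb(N, na) <= EXACT_ENUMERATION_LIMIT
                  else "asymptotic")
    if method == "exact":
        total = 0
        extreme = 0
        for idx in combinations(range(N), na):
            w = int(U[list(idx)].sum())
            total += 1
            if abs(w) >= abs(W):
                extreme += 1
        p = extreme / total
        z = W / math.sqrt(var) if var > 0 else 0.0
    elif method == "asymptotic":
        if var == 0:
            if W != 0:
                raise ValidationError("zero variance with nonzero statistic")
            return {"statistic": float(W), "z": 0.0, "p": 1.0,
                    "method": "asymptotic"}
        z = W / math.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": float(W), "z": float(z), "p": float(min(p, 1.0)),
            "method": method}


def stratify(patients: Sequence[PatientRecord], counts: pd.DataFrame,
             rule: StratificationRule, line_filter: int = 1,
             ) -> Tuple[List[PatientRecord], List[PatientRecord]]:
    """Split patients into (rule-positive, rule-negative) strata.

    ``counts`` has one row per patient with columns ``patient_id``,
    ``epithelial``, ``emt``, ``epithelial_or_emt``; patients missing from
    ``counts`` are treated as having zero CTCs of every type.  The cohort
    is first restricted to ``treatment_line >= line_filter``.
    """
    known = {r.patient_id for r in patients}
    unknown = set(counts["patient_id"].astype(str)) - known
    if unknown:
        raise JoinError(f"counts reference unknown patients {sorted(unknown)}")
    lut = counts.set_index(counts["patient_id"].astype(str))
    pos, neg = [], []
    other_types = {"emt": ("epithelial",), "epithelial": ("emt",),
                   "epithelial_or_emt": ()}[rule.ctc_type]
    for rec in patients:
        if rec.treatment_line < line_filter:
            continue
        if rec.patient_id in lut.index:
            row = lut.loc[rec.patient_id]
            count = int(row[rule.ctc_type])
            others = sum(int(row[t]) for t in other_types)
        else:
            count, others = 0, 0
        hit = count >= rule.min_count
        if rule.exclusive and others > 0:
            hit = False
        (pos if hit else neg).append(rec)
    return pos, neg


def _samples(records: Sequence[PatientRecord], endpoint: str,
             stratum: str) -> List[SurvivalSample]:
    time_attr, event_attr = ((f"{endpoint}_days", f"{endpoint}_event"))
    out = []
    for r in records:
        t = getattr(r, time_attr)
        if t is None:
            continue
        out.append(SurvivalSample(patient_id=r.patient_id, time_days=t,
                                  event=bool(getattr(r, event_attr)),
                                  stratum=stratum))
    return out


DEFAULT_RULES: Tuple[StratificationRule, ...] = tuple(
    StratificationRule(ctc_type=t, min_count=k)
    for t in ("emt", "epithelial", "epithelial_or_emt")
    for k in (1, 2)
)


def survival_report(patients: Sequence[PatientRecord], counts: pd.DataFrame,
                    rules: Sequence[StratificationRule] = DEFAULT_RULES,
                    line_filter: int = 2) -> pd.DataFrame:
    """Median/CI and Gehan test per stratification rule and endpoint.

    One output row per (rule, endpoint, stratum); the p-value is repeated on
    both stratum rows, and marked not-computable (NaN) when either stratum
    is empty.
    """
    rows = []
    for rule in rules:
        pos, neg = stratify(patients, counts, rule, line_filter=line_filter)
        for endpoint in ("pfs", "os"):
            pos_s = _samples(pos, endpoint, "positive")
            neg_s = _samples(neg, endpoint, "negative")
            p_value = float("nan")
            if pos_s and neg_s:
                p_value = gehan_wilcoxon_test(pos_s, neg_s)["p"]
            for stratum, samples in (("negative", neg_s),
                                     ("positive", pos_s)):
                if samples:
                    est = km_estimate(samples)
                    median, (lo, hi) = est.median, est.median_ci
                    n = est.n
                else:
                    median, lo, hi, n = None, None, None, 0
                rows.append({
                    "rule": rule.ctc_type,
                    "threshold": rule.min_count,
                    "exclusive": rule.exclusive,
                    "endpoint": endpoint,
                    "stratum": stratum,
                    "n": n,
                    "median": median,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": p_value,
                })
    return pd.DataFrame(rows)
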