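"""Individual-patient-data survival analysis of lesion-level FES heterogeneity.

A lesion is FES-positive when its SUVmax is at or above the positivity
threshold (1.8 in the primary analysis); a patient is *heterogeneous* when
at least one lesion is FES-negative. Progression-free survival is contrasted
between the all-FES-positive and heterogeneous groups with Kaplan-Meier
curves and a binary-covariate Cox proportional-hazards model, and the whole
classification-plus-contrast is re-run over a grid of thresholds (1.8-4.0 in
0.1 steps in the primary sweep).

Kaplan-Meier estimation is delegated to lifelines (Greenwood variance,
log(-log) confidence band, median CI in the Brookmeyer-Crowley style). The
Cox model is a purpose-built single-parameter Newton solver with Efron tie
handling, because monthly-resolution PFS times make ties common; it exposes
its score and information so the fit can be audited against the explicit
partial likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from fesmeta.evidence import PatientRecord

DEFAULT_THRESHOLD = 1.8  # primary SUVmax positivity cutoff
_Z95 = float(stats.norm.ppf(0.975))


class HeterogeneityClass(str, Enum):
    all_positive = "all_positive"
    heterogeneous = "heterogeneous"
    all_negative = "all_negative"


@dataclass(frozen=True)
class PatientClass:
    """A patient's FES-heterogeneity classification at a given threshold."""

    label: HeterogeneityClass
    n_lesions: int
    n_negative_lesions: int
    threshold: float


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve summary.

    ``median_months`` is None when the curve never falls to 0.5 (or there are
    no events); CI bounds may be infinite when the confidence band never
    crosses 0.5.
    """

    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    median_months: float | None
    median_ci: tuple[float, float]
    n: int
    n_events: int

    def to_frame(self, group: str = "") -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
            }
        )
        df["group"] = group
        return df


@dataclass(frozen=True)
class CoxFit:
    """Binary-covariate Cox proportional-hazards fit (Wald inference)."""

    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p_wald: float
    n_events: int
    converged: bool
    iterations: int
    monotone: bool = False


def classify_lesion(suv_max: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True when the lesion is FES-positive, i.e. SUVmax at or above threshold."""
    return suv_max >= threshold


def classify_patient(
    p: PatientRecord, threshold: float = DEFAULT_THRESHOLD
) -> PatientClass:
    """Classify a patient as all-positive, heterogeneous, or all-negative.

    Heterogeneity means at least one FES-negative lesion alongside at least
    one FES-positive lesion; all lesions below threshold is all-negative.
    """
    n = len(p.lesions)
    if n == 0:
        raise ValueError(f"{p.patient_id}: cannot classify a patient with no lesions")
    n_neg = sum(1 for l in p.lesions if not classify_lesion(l.suv_max, threshold))
    if n_neg == 0:
        label = HeterogeneityClass.all_positive
    elif n_neg == n:
        label = HeterogeneityClass.all_negative
    else:
        label = HeterogeneityClass.heterogeneous
    return PatientClass(label, n, n_neg, threshold)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def km_curve(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit estimator with Greenwood-based median CI.

    ``times`` are PFS months, ``events`` True for observed progression/death
    and False for right-censoring.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("all times must be positive")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    ev = tbl[(tbl["observed"] > 0) & (tbl.index > 0)]
    event_times = tuple(float(x) for x in ev.index)
    survival = tuple(
        float(s) for s in kmf.survival_function_at_times(ev.index).to_numpy()
    )
    at_risk = tuple(int(x) for x in ev["at_risk"].to_numpy())

    med = kmf.median_survival_time_
    median = None if math.isinf(med) else float(med)
    if e.sum() == 0:
        median = None
        median_ci = (math.inf, math.inf)
    else:
        ci_df = median_survival_times(kmf.confidence_interval_)
        lo, hi = (float(x) for x in ci_df.iloc[0].to_numpy())
        median_ci = (lo, hi)
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        median_months=median,
        median_ci=median_ci,
        n=int(len(t)),
        n_events=int(e.sum()),
    )


# ---------------------------------------------------------------------------
# Cox model (binary covariate, Efron ties)
# ---------------------------------------------------------------------------


def _event_time_stats(
    t: np.ndarray, e: np.ndarray, x: np.ndarray
) -> list[tuple[int, int, int, int]]:
    """Per distinct event time: (n0 at risk, n1 at risk, e0 events, e1 events)."""
    out = []
    for tau in np.unique(t[e]):
        at_risk = t >= tau
        tied = e & (t == tau)
        out.append(
            (
                int((at_risk & (x == 0)).sum()),
                int((at_risk & (x == 1)).sum()),
                int((tied & (x == 0)).sum()),
                int((tied & (x == 1)).sum()),
            )
        )
    return out


def cox_loglik_score_info(
    beta: float,
    times: Sequence[float],
    events: Sequence[bool],
    group: Sequence[bool],
) -> tuple[float, float, float]:
    """Efron partial log-likelihood, score and information at ``beta``.

    For a binary covariate the risk-set sums reduce to counts: at each
    distinct event time with d tied events, S0 = n0 + n1 e^beta and the
    Efron correction subtracts l/d of the tied-set contribution from the
    l-th factor.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(group, dtype=int)
    eb = math.exp(beta)
    ll = score = info = 0.0
    for n0, n1, e0, e1, d in (
        (n0, n1, e0, e1, e0 + e1) for n0, n1, e0, e1 in _event_time_stats(t, e, x)
    ):
        s0, s1 = n0 + n1 * eb, n1 * eb
        s0h, s1h = e0 + e1 * eb, e1 * eb
        ll += beta * e1
        for l in range(d):
            f = l / d
            den = s0 - f * s0h
            num = s1 - f * s1h
            ll -= math.log(den)
            score -= num / den
            info += num / den - (num / den) ** 2
        score += e1
    return ll, score, info


def cox_binary(
    times: Sequence[float],
    events: Sequence[bool],
    group: Sequence[bool],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox proportional-hazards model with one binary covariate.

    Newton-Raphson from beta = 0 on the Efron partial likelihood, converging
    when |score| < ``tol``. A monotone partial likelihood (e.g. every event
    in one group precedes any overlap with the other) is flagged rather than
    iterated to infinity: the fit reports the diverging sign with an
    unbounded Wald CI on that side.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(group, dtype=int)
    if not (t.shape == e.shape == x.shape):
        raise ValueError("times, events and group must have equal length")
    if e.sum() == 0:
        raise ValueError("no events observed; Cox model undefined")
    if len(np.unique(x)) < 2:
        raise ValueError("both group labels must be present")

    beta = 0.0
    monotone = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, score, info = cox_loglik_score_info(beta, t, e, x)
        if abs(score) < tol:
            converged = True
            break
        if info <= 1e-12:
            monotone = True
            break
        step = score / info
        beta += max(-2.0, min(2.0, step))  # damp huge first steps
        if abs(beta) > 10.0:  # HR beyond e^10: separated groups, not a real fit
            monotone = True
            break

    _, _, info = cox_loglik_score_info(beta, t, e, x)
    if monotone or info <= 1e-12 or abs(beta) > 10.0:
        # CI unbounded on the side the likelihood diverges toward
        return CoxFit(
            log_hr=beta,
            se=math.inf,
            hr=math.exp(beta) if beta < 700 else math.inf,
            ci_low=0.0,
            ci_high=math.inf,
            p_wald=1.0,
            n_events=int(e.sum()),
            converged=False,
            iterations=it,
            monotone=True,
        )
    se = 1.0 / math.sqrt(info)

    def _exp(v: float) -> float:
        return math.exp(v) if v < 700.0 else math.inf

    return CoxFit(
        log_hr=beta,
        se=se,
        hr=_exp(beta),
        ci_low=_exp(beta - _Z95 * se),
        ci_high=_exp(beta + _Z95 * se),
        p_wald=2.0 * float(stats.norm.sf(abs(beta) / se)),
        n_events=int(e.sum()),
        converged=converged,
        iterations=it,
    )


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepRow:
    threshold: float
    n_all_positive: int
    n_other: int
    cox: CoxFit | None
    cox_reason: str | None
    median_all_positive: float | None
    median_other: float | None


@dataclass(frozen=True)
class SweepResult:
    """Per-threshold group sizes, Cox contrast and group KM medians."""

    rows: tuple[SweepRow, ...]

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(r.threshold for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "threshold": r.threshold,
                    "n_all_pos": r.n_all_positive,
                    "n_other": r.n_other,
                    "hr": r.cox.hr if r.cox else math.nan,
                    "hr_lo": r.cox.ci_low if r.cox else math.nan,
                    "hr_hi": r.cox.ci_high if r.cox else math.nan,
                    "median_all_pos": math.nan
                    if r.median_all_positive is None
                    else r.median_all_positive,
                    "median_other": math.nan
                    if r.median_other is None
                    else r.median_other,
                }
            )
        return pd.DataFrame(recs)


def threshold_grid(lo: float, hi: float, step: float) -> list[float]:
    """Inclusive grid built by integer stepping, robust to 0.1 float drift."""
    if step <= 0:
        raise ValueError("step must be positive")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    n = int(round((hi - lo) / step)) + 1
    return [round(lo + i * step, 10) for i in range(n)]


def threshold_sweep(
    patients: Sequence[PatientRecord],
    lo: float = 1.8,
    hi: float = 4.0,
    step: float = 0.1,
) -> SweepResult:
    """Re-run the heterogeneity contrast over a grid of positivity thresholds.

    At each threshold the cohort splits into all-FES-positive versus
    not-all-positive (heterogeneous or all-negative — raising the threshold
    can only move patients out of the all-positive arm, so its size is
    nonincreasing along the grid). Degenerate splits (an empty arm, or no
    events) yield an undefined Cox entry with a reason, never an abort.
    """
    if len(patients) == 0:
        raise ValueError("empty cohort")
    t = np.array([p.pfs_months for p in patients])
    e = np.array([p.event for p in patients])
    rows = []
    for thr in threshold_grid(lo, hi, step):
        labels = np.array(
            [
                classify_patient(p, thr).label is HeterogeneityClass.all_positive
                for p in patients
            ]
        )
        n_pos = int(labels.sum())
        n_other = len(patients) - n_pos
        cox = None
        reason = None
        if n_pos == 0 or n_other == 0:
            reason = "one group is empty"
        elif e.sum() == 0:
            reason = "no events"
        else:
            try:
                cox = cox_binary(t, e, ~labels)  # HR: not-all-positive vs all-positive
            except ValueError as exc:  # pragma: no cover - guarded above
                reason = str(exc)
        med_pos = km_curve(t[labels], e[labels]).median_months if n_pos else None
        med_other = km_curve(t[~labels], e[~labels]).median_months if n_other else None
        rows.append(
            SweepRow(
                threshold=thr,
                n_all_positive=n_pos,
                n_other=n_other,
                cox=cox,
                cox_reason=reason,
                median_all_positive=med_pos,
                median_other=med_other,
            )
        )
    return SweepResult(tuple(rows))
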