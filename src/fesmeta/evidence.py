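"""Domain types for study-level and patient-level evidence, CSV ingest, and
the built-in published-table fixture.

Two layers of evidence flow through the package:

* **study-level** summaries extracted from publications: an effect point
  (hazard ratio, ratio of medians, odds ratio, standardized mean difference)
  or a group's median PFS, each with a 95% CI, from which a log-scale
  standard error is reconstructed for inverse-variance pooling;
* **individual-patient data (IPD)**: per-lesion FES SUVmax values plus
  per-patient PFS time and event indicator.

An unbounded upper confidence limit (a survival curve that never crosses the
bound) is represented as ``math.inf`` — an ordinary IEEE value, not a magic
number — and serialized as an empty cell (accepted on read) or ``"Inf"``
(written).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

UNBOUNDED = math.inf
"""Upper confidence limit of a CI that never closes (e.g. "4.8 to infinity")."""


class SchemaError(ValueError):
    """A required column is missing or the CSV layout is not recognised."""


class ValidationError(ValueError):
    """A row carries a value that violates the record's invariants."""


class Endpoint(str, Enum):
    """Analysis endpoints; all but ``smd`` are ratio-scale and pool on log scale."""

    hazard_ratio = "hazard_ratio"
    median_ratio = "median_ratio"
    median_pfs = "median_pfs"
    odds_ratio = "odds_ratio"
    smd = "smd"

    @property
    def is_ratio_scale(self) -> bool:
        return self is not Endpoint.smd


class Site(str, Enum):
    """Coarse lesion-site classes used in the IPD cohort."""

    bone = "bone"
    lymph_node = "lymph_node"
    lung = "lung"
    other = "other"


@dataclass(frozen=True)
class EffectEstimate:
    """One study's effect point with CI on its analysis scale.

    ``log_se`` is the standard error on the pooling scale: natural-log scale
    for ratio endpoints, identity scale for the SMD endpoint. It is unitless
    in both cases.
    """

    study_id: str
    endpoint: Endpoint
    point: float
    ci_low: float
    ci_high: float  # may be UNBOUNDED (math.inf)
    log_se: float
    ci_level: float = 0.95
    n: int | None = None
    zero_cell_corrected: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ValidationError(f"ci_level must be in (0,1), got {self.ci_level}")
        if self.endpoint.is_ratio_scale:
            if self.point <= 0 or self.ci_low <= 0:
                raise ValidationError(
                    f"{self.study_id}: ratio-scale endpoint requires positive "
                    f"point and lower bound (point={self.point}, ci_low={self.ci_low})"
                )
        if math.isfinite(self.ci_high) and not (
            self.ci_low <= self.point <= self.ci_high
        ):
            raise ValidationError(
                f"{self.study_id}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket the point {self.point}"
            )
        if self.log_se < 0:
            raise ValidationError(f"{self.study_id}: negative SE {self.log_se}")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"{self.study_id}: non-positive n {self.n}")


@dataclass(frozen=True)
class SurvivalGroupSummary:
    """A study arm's median PFS (months) with a possibly unbounded 95% CI."""

    study_id: str
    group: str  # "heterogeneous" or "all_positive"
    median_months: float
    ci_low_months: float
    ci_high_months: float  # may be UNBOUNDED
    n: int

    def __post_init__(self) -> None:
        if self.median_months <= 0 or self.ci_low_months <= 0:
            raise ValidationError(
                f"{self.study_id}/{self.group}: median and lower bound must be "
                f"positive months"
            )
        if self.ci_low_months > self.median_months:
            raise ValidationError(
                f"{self.study_id}/{self.group}: lower bound exceeds median"
            )
        if math.isfinite(self.ci_high_months) and self.ci_high_months < self.median_months:
            raise ValidationError(
                f"{self.study_id}/{self.group}: upper bound below median"
            )
        if self.n <= 0:
            raise ValidationError(f"{self.study_id}/{self.group}: n must be positive")


@dataclass(frozen=True)
class LesionRecord:
    """A single FES-quantified lesion: dimensionless SUVmax plus site class."""

    patient_id: str
    suv_max: float
    site: Site = Site.other

    def __post_init__(self) -> None:
        if self.suv_max < 0:
            raise ValidationError(f"{self.patient_id}: negative SUVmax {self.suv_max}")


@dataclass(frozen=True)
class PatientRecord:
    """A patient's lesions together with PFS follow-up.

    ``event`` is True when progression or death was observed; False means the
    patient was censored alive and progression-free at ``pfs_months``.
    Lesion order carries no meaning.
    """

    patient_id: str
    lesions: tuple[LesionRecord, ...]
    pfs_months: float
    event: bool

    def __post_init__(self) -> None:
        if len(self.lesions) == 0:
            raise ValidationError(f"{self.patient_id}: patient has no lesions")
        if self.pfs_months <= 0:
            raise ValidationError(
                f"{self.patient_id}: non-positive PFS {self.pfs_months}"
            )


# ---------------------------------------------------------------------------
# CSV ingest / egress
# ---------------------------------------------------------------------------

_SURVIVAL_COLS = ["study_id", "group", "median_months", "ci_low", "ci_high", "n"]
_EFFECT_COLS = ["study_id", "endpoint", "point", "ci_low", "ci_high", "n"]


def _parse_upper(cell: object) -> float:
    """Empty cell, NaN or 'Inf' (any case) means an unbounded upper limit."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return UNBOUNDED
    if isinstance(cell, str):
        s = cell.strip()
        if s == "" or s.lower() in {"inf", "infinity", "+inf"}:
            return UNBOUNDED
        return float(s)
    return float(cell)


def read_study_table(path: str | Path) -> list[SurvivalGroupSummary] | list[EffectEstimate]:
    """Read a study-level summary CSV, returning records in input order.

    Two layouts are accepted and distinguished by their header:

    * survival layout: ``study_id,group,median_months,ci_low,ci_high,n``
    * effect layout:   ``study_id,endpoint,point,ci_low,ci_high,n``

    An empty or ``Inf`` upper-CI cell yields an unbounded upper limit. For
    effect rows the log-scale SE is reconstructed from the CI width; an
    unbounded upper limit is first imputed by log-scale symmetry about the
    point.
    """
    from fesmeta.reconstruct import impute_symmetric_upper, log_se_from_ci

    df = pd.read_csv(path, dtype={"ci_high": str}, float_precision="round_trip")
    cols = set(df.columns)
    if "median_months" in cols:
        missing = [c for c in _SURVIVAL_COLS if c not in cols]
        layout = "survival"
    elif "endpoint" in cols:
        missing = [c for c in _EFFECT_COLS if c not in cols]
        layout = "effect"
    else:
        raise SchemaError(
            "unrecognised study table: expected a 'median_months' or 'endpoint' "
            f"column, found {sorted(cols)}"
        )
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 2 = first data line
        try:
            hi = _parse_upper(row.ci_high)
            if layout == "survival":
                records.append(
                    SurvivalGroupSummary(
                        study_id=str(row.study_id),
                        group=str(row.group),
                        median_months=float(row.median_months),
                        ci_low_months=float(row.ci_low),
                        ci_high_months=hi,
                        n=int(row.n),
                    )
                )
            else:
                endpoint = Endpoint(str(row.endpoint))
                point, lo = float(row.point), float(row.ci_low)
                hi_res = impute_symmetric_upper(point, lo) if math.isinf(hi) else hi
                se = log_se_from_ci(point, lo, hi_res) if endpoint.is_ratio_scale else (
                    (hi_res - lo) / (2.0 * 1.959963984540054)
                )
                records.append(
                    EffectEstimate(
                        study_id=str(row.study_id),
                        endpoint=endpoint,
                        point=point,
                        ci_low=lo,
                        ci_high=hi,
                        log_se=se,
                        n=None if pd.isna(row.n) else int(row.n),
                    )
                )
        except ValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"line {i}: {exc}") from exc
    return records


def write_study_table(
    records: Sequence[SurvivalGroupSummary] | Sequence[EffectEstimate],
    path: str | Path,
) -> None:
    """Write records back to CSV; unbounded upper limits become ``"Inf"``."""
    rows = []
    for r in records:
        if isinstance(r, SurvivalGroupSummary):
            rows.append(
                {
                    "study_id": r.study_id,
                    "group": r.group,
                    "median_months": repr(r.median_months),
                    "ci_low": repr(r.ci_low_months),
                    "ci_high": "Inf" if math.isinf(r.ci_high_months) else repr(r.ci_high_months),
                    "n": r.n,
                }
            )
        else:
            rows.append(
                {
                    "study_id": r.study_id,
                    "endpoint": r.endpoint.value,
                    "point": repr(r.point),
                    "ci_low": repr(r.ci_low),
                    "ci_high": "Inf" if math.isinf(r.ci_high) else repr(r.ci_high),
                    "n": "" if r.n is None else r.n,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ipd_tables(
    lesion_path: str | Path, survival_path: str | Path
) -> list[PatientRecord]:
    """Join the lesion CSV (``patient_id,suv_max,site``) with the survival CSV
    (``patient_id,pfs_months,event``) into PatientRecords.

    Patient ids must match one-to-one between the two tables; offenders on
    either side are listed in the error.
    """
    lesions = pd.read_csv(lesion_path, float_precision="round_trip")
    surv = pd.read_csv(survival_path, float_precision="round_trip")
    for col in ("patient_id", "suv_max"):
        if col not in lesions.columns:
            raise SchemaError(f"lesion table: missing required column(s): {col}")
    for col in ("patient_id", "pfs_months", "event"):
        if col not in surv.columns:
            raise SchemaError(f"survival table: missing required column(s): {col}")

    lesion_ids = set(lesions["patient_id"].astype(str))
    surv_ids = set(surv["patient_id"].astype(str))
    if lesion_ids != surv_ids:
        only_lesions = sorted(lesion_ids - surv_ids)
        only_surv = sorted(surv_ids - lesion_ids)
        raise ValidationError(
            "patient ids do not match between lesion and survival tables; "
            f"lesion-only: {only_lesions}; survival-only: {only_surv}"
        )

    has_site = "site" in lesions.columns
    by_patient: dict[str, list[LesionRecord]] = {}
    for row in lesions.itertuples(index=False):
        pid = str(row.patient_id)
        site = Site(str(row.site)) if has_site else Site.other
        by_patient.setdefault(pid, []).append(
            LesionRecord(patient_id=pid, suv_max=float(row.suv_max), site=site)
        )

    patients = []
    for row in surv.itertuples(index=False):
        pid = str(row.patient_id)
        ev = int(row.event)
        if ev not in (0, 1):
            raise ValidationError(f"{pid}: event must be 0 or 1, got {row.event}")
        patients.append(
            PatientRecord(
                patient_id=pid,
                lesions=tuple(by_patient[pid]),
                pfs_months=float(row.pfs_months),
                event=bool(ev),
            )
        )
    return patients


def write_ipd_tables(
    patients: Sequence[PatientRecord],
    lesion_path: str | Path,
    survival_path: str | Path,
) -> None:
    """Write the two IPD CSVs for a patient list."""
    lrows = [
        {"patient_id": p.patient_id, "suv_max": repr(l.suv_max), "site": l.site.value}
        for p in patients
        for l in p.lesions
    ]
    srows = [
        {
            "patient_id": p.patient_id,
            "pfs_months": repr(p.pfs_months),
            "event": int(p.event),
        }
        for p in patients
    ]
    pd.DataFrame(lrows).to_csv(lesion_path, index=False)
    pd.DataFrame(srows).to_csv(survival_path, index=False)


# ---------------------------------------------------------------------------
# Built-in published-table fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table1Fixture:
    """The five-study PFS-by-FES-heterogeneity evidence table, as printed.

    Per-study medians (months, with 95% CI and group n) for the
    FES-heterogeneous and all-FES-positive arms, the printed ratios of
    medians, and the four available hazard ratios. One study (Gennari 2024)
    reported no HR; it is listed in ``missing_hr_studies`` and excluded from
    HR pooling. Another (Boers 2020) reported an unbounded upper PFS limit
    for its all-FES-positive arm, stored as infinity.
    """

    heterogeneous: tuple[SurvivalGroupSummary, ...]
    all_positive: tuple[SurvivalGroupSummary, ...]
    median_ratios: tuple[EffectEstimate, ...]
    hazard_ratios: tuple[EffectEstimate, ...]
    missing_hr_studies: tuple[str, ...] = field(default=("Gennari2024",))

    @property
    def survival_summaries(self) -> tuple[SurvivalGroupSummary, ...]:
        return self.heterogeneous + self.all_positive

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(s.study_id for s in self.heterogeneous)


_HET = [
    ("Liu2020", 5.5, 2.3, 8.7, 12),
    ("He2020", 7.2, 3.0, 11.4, 10),
    ("Boers2020", 6.2, 3.2, 11.3, 20),
    ("Liu2022", 2.4, 1.1, 3.7, 10),
    ("Gennari2024", 12.4, 3.1, 59.6, 12),
]
_ALLPOS = [
    ("Liu2020", 18.4, 12.2, 29.8, 23),
    ("He2020", 14.6, 8.4, 20.8, 26),
    ("Boers2020", 16.8, 4.8, UNBOUNDED, 7),
    ("Liu2022", 23.6, 15.8, 31.4, 46),
    ("Gennari2024", 18.0, 11.2, 23.1, 113),
]
_RATIOS = [
    ("Liu2020", 0.30, 0.14, 0.62),
    ("He2020", 0.49, 0.24, 1.01),
    ("Boers2020", 0.37, 0.09, 1.49),
    ("Liu2022", 0.10, 0.05, 0.19),
    ("Gennari2024", 0.69, 0.15, 3.16),
]
# Boers combined its heterogeneous and all-FES-negative patients in the
# published HR; stored as printed, without subgroup reconstruction.
_HRS = [
    ("Liu2020", 6.6, 2.6, 17.0),
    ("He2020", 2.3, 0.9, 5.9),
    ("Boers2020", 2.1, 0.8, 6.9),
    ("Liu2022", 25.0, 7.7, 100.0),
]


def table1_fixture() -> Table1Fixture:
    """Build the published five-study evidence bundle with reconstructed SEs."""
    from fesmeta.reconstruct import log_se_from_ci

    het = tuple(
        SurvivalGroupSummary(sid, "heterogeneous", m, lo, hi, n)
        for sid, m, lo, hi, n in _HET
    )
    allpos = tuple(
        SurvivalGroupSummary(sid, "all_positive", m, lo, hi, n)
        for sid, m, lo, hi, n in _ALLPOS
    )
    ratios = tuple(
        EffectEstimate(
            sid, Endpoint.median_ratio, p, lo, hi, log_se=log_se_from_ci(p, lo, hi)
        )
        for sid, p, lo, hi in _RATIOS
    )
    hrs = tuple(
        EffectEstimate(
            sid, Endpoint.hazard_ratio, p, lo, hi, log_se=log_se_from_ci(p, lo, hi)
        )
        for sid, p, lo, hi in _HRS
    )
    return Table1Fixture(
        heterogeneous=het,
        all_positive=allpos,
        median_ratios=ratios,
        hazard_ratios=hrs,
    )
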