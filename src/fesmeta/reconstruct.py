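"""Reconstruction of log-scale effect estimates from published summaries.

Meta-analysis of ratio-scale endpoints (hazard ratios, odds ratios, medians
and their ratios) is carried out on the natural-log scale, so each published
point-plus-CI must be converted to a log effect with a standard error. The
conversions here cover:

* SE from a Wald CI: ``SE = (ln hi - ln lo) / (2 z)`` with ``z`` the normal
  quantile at ``(1 + level)/2``;
* symmetric imputation of a missing (unbounded) upper limit about the point,
  applied on the log scale for consistency with log-scale pooling;
* ratio of two group medians via the delta method, treating the arms as
  independent patient groups so the log-ratio variance is the sum of the two
  log-median variances;
* Hedges-corrected standardized mean difference (identity scale);
* odds ratio from a 2x2 table with the Haldane-Anscombe half-integer
  correction when a cell is empty.
"""

from __future__ import annotations

import math

from scipy import stats

from fesmeta.evidence import EffectEstimate, Endpoint, SurvivalGroupSummary


class DegenerateTableError(ValueError):
    """A 2x2 table with an all-zero row or column has no defined odds ratio."""


def _z(level: float) -> float:
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    return float(stats.norm.ppf(0.5 * (1.0 + level)))


def log_se_from_ci(
    point: float, ci_low: float, ci_high: float, level: float = 0.95
) -> float:
    """Log-scale SE reconstructed from a ratio-scale Wald CI.

    Depends only on the CI width on the log scale, not on the point, and is
    therefore invariant to rescaling all three arguments by a common factor.
    """
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError(f"CI bounds must be positive, got ({ci_low}, {ci_high})")
    if ci_low > ci_high:
        raise ValueError(f"lower bound {ci_low} exceeds upper bound {ci_high}")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * _z(level))


def impute_symmetric_upper(point: float, ci_low: float) -> float:
    """Impute an unreported upper CI limit by log-scale symmetry about the point.

    Mirrors the reported lower bound: ``exp(2 ln point - ln ci_low)``, so the
    imputed log CI is symmetric about the log point — the scale on which
    pooling operates.
    """
    if ci_low <= 0 or point <= 0:
        raise ValueError("point and lower bound must be positive")
    if ci_low > point:
        raise ValueError(f"lower bound {ci_low} exceeds point {point}")
    return math.exp(2.0 * math.log(point) - math.log(ci_low))


def median_pfs_effect(
    s: SurvivalGroupSummary, level: float = 0.95
) -> EffectEstimate:
    """Convert a group's median PFS summary into a log-scale pooling effect.

    An unbounded upper limit is first resolved by symmetric log-scale
    imputation from the lower bound.
    """
    hi = s.ci_high_months
    if math.isinf(hi):
        hi = impute_symmetric_upper(s.median_months, s.ci_low_months)
    return EffectEstimate(
        study_id=s.study_id,
        endpoint=Endpoint.median_pfs,
        point=s.median_months,
        ci_low=s.ci_low_months,
        ci_high=s.ci_high_months,
        log_se=log_se_from_ci(s.median_months, s.ci_low_months, hi, level),
        ci_level=level,
        n=s.n,
    )


def ratio_of_medians(
    num: SurvivalGroupSummary, den: SurvivalGroupSummary, level: float = 0.95
) -> EffectEstimate:
    """Ratio of two group medians with a delta-method log-scale SE.

    The two arms are distinct patient groups, so their log-median variances
    add: ``se = sqrt(se_num^2 + se_den^2)``. Unbounded upper limits are
    resolved by symmetric imputation before SE reconstruction. The returned
    CI is the Wald interval ``exp(ln ratio ± z se)``; it can differ from a
    CI printed in an original study, which may derive from patient-level data.
    """
    se_num = median_pfs_effect(num, level).log_se
    se_den = median_pfs_effect(den, level).log_se
    point = num.median_months / den.median_months
    se = math.hypot(se_num, se_den)
    z = _z(level)
    return EffectEstimate(
        study_id=num.study_id,
        endpoint=Endpoint.median_ratio,
        point=point,
        ci_low=point * math.exp(-z * se),
        ci_high=point * math.exp(z * se),
        log_se=se,
        ci_level=level,
    )


def smd_hedges(
    m1: float,
    s1: float,
    n1: int,
    m2: float,
    s2: float,
    n2: int,
    study_id: str = "",
    level: float = 0.95,
) -> EffectEstimate:
    """Hedges' g: small-sample-corrected standardized mean difference.

    Cohen's d with the pooled SD is shrunk by ``J = 1 - 3/(4 df - 1)`` with
    ``df = n1 + n2 - 2``; the sampling variance is the usual large-sample
    approximation ``(n1+n2)/(n1 n2) + g^2/(2 (n1+n2))``. The estimate lives
    on the identity scale (no log transform at pooling time).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        raise ValueError("pooled SD is zero; SMD undefined")
    d = (m1 - m2) / math.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    var = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))
    se = math.sqrt(var)
    z = _z(level)
    return EffectEstimate(
        study_id=study_id,
        endpoint=Endpoint.smd,
        point=g,
        ci_low=g - z * se,
        ci_high=g + z * se,
        log_se=se,
        ci_level=level,
        n=n1 + n2,
    )


def odds_ratio(
    a: int, b: int, c: int, d: int, study_id: str = "", level: float = 0.95
) -> EffectEstimate:
    """Odds ratio from a 2x2 table ``[[a, b], [c, d]]`` with Woolf log-SE.

    ``a``/``b`` are responders/non-responders in the exposed row, ``c``/``d``
    in the reference row. If any cell is zero, 0.5 is added to every cell
    (Haldane-Anscombe) and the result is flagged ``zero_cell_corrected``.
    An all-zero row or column leaves the OR undefined.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be nonnegative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise DegenerateTableError(
            f"2x2 table {cells} has an empty row or column; OR undefined"
        )
    corrected = any(x == 0 for x in cells)
    if corrected:
        a, b, c, d = (x + 0.5 for x in cells)
    point = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = _z(level)
    return EffectEstimate(
        study_id=study_id,
        endpoint=Endpoint.odds_ratio,
        point=point,
        ci_low=point * math.exp(-z * se),
        ci_high=point * math.exp(z * se),
        log_se=se,
        ci_level=level,
        zero_cell_corrected=corrected,
    )
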