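"""Inverse-variance pooling with heterogeneity statistics.

Fixed-effect (FEM) and random-effects (REM) pooling operate on the analysis
scale selected by the endpoint: natural log for ratio endpoints, identity
for the standardized mean difference. Weights are the reciprocal variances;
REM adds a DerSimonian-Laird between-study variance tau^2 to every study
variance. Heterogeneity is summarised by Cochran's Q (chi-square with k-1
df under homogeneity) and the I-squared percentage ``max(0, (Q-df)/Q)*100``.

The point estimate, CI, Q, I-squared and tau^2 are kept at full precision;
rounding is a presentation concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fesmeta.evidence import EffectEstimate, Endpoint


@dataclass(frozen=True)
class PooledResult:
    """A pooled effect with its weights and heterogeneity diagnostics.

    ``point``, ``ci_low`` and ``ci_high`` are back-transformed to the ratio
    scale for log-scale endpoints. ``weights`` are normalized to sum to one,
    in input-study order. ``p_Q`` is NaN when k = 1 (no heterogeneity test).
    """

    model: str  # "FEM" | "REM"
    endpoint: Endpoint
    point: float
    ci_low: float
    ci_high: float
    weights: tuple[float, ...]
    Q: float
    df: int
    p_Q: float
    i_squared: float
    tau2: float
    k: int


def _theta_se(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray, Endpoint]:
    if len(effects) == 0:
        raise ValueError("cannot pool an empty list of effects")
    endpoints = {e.endpoint for e in effects}
    if len(endpoints) > 1:
        raise ValueError(f"cannot pool mixed endpoints: {sorted(e.value for e in endpoints)}")
    endpoint = effects[0].endpoint
    for e in effects:
        if e.log_se <= 0:
            raise ValueError(f"study {e.study_id!r} has zero SE; cannot weight it")
    se = np.array([e.log_se for e in effects])
    if endpoint.is_ratio_scale:
        theta = np.log([e.point for e in effects])
    else:
        theta = np.array([e.point for e in effects])
    return theta, se, endpoint


def _pool(
    theta: np.ndarray,
    var: np.ndarray,
    endpoint: Endpoint,
    model: str,
    tau2: float,
    level: float,
) -> PooledResult:
    w = 1.0 / var
    sw = w.sum()
    mean = float((w * theta).sum() / sw)
    z = float(stats.norm.ppf(0.5 * (1.0 + level)))
    half = z / math.sqrt(sw)
    lo, hi = mean - half, mean + half

    # Q is always computed with fixed-effect weights about the FEM mean.
    k = len(theta)
    w_fe = 1.0 / (var - tau2) if model == "REM" else w
    mean_fe = float((w_fe * theta).sum() / w_fe.sum())
    Q = float((w_fe * (theta - mean_fe) ** 2).sum())
    df = k - 1
    p_Q = float(stats.chi2.sf(Q, df)) if df >= 1 else math.nan
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0

    if endpoint.is_ratio_scale:
        point, lo, hi = math.exp(mean), math.exp(lo), math.exp(hi)
    else:
        point = mean
    return PooledResult(
        model=model,
        endpoint=endpoint,
        point=point,
        ci_low=lo,
        ci_high=hi,
        weights=tuple(w / sw),
        Q=Q,
        df=df,
        p_Q=p_Q,
        i_squared=i2,
        tau2=tau2,
        k=k,
    )


def fixed_effect_pool(
    effects: Sequence[EffectEstimate], level: float = 0.95
) -> PooledResult:
    """Fixed-effect inverse-variance pooling on the endpoint's analysis scale.

    With a single study the pooled point and CI equal that study's own (on
    the Wald reconstruction), and the heterogeneity fields are vacuous.
    """
    theta, se, endpoint = _theta_se(effects)
    return _pool(theta, se**2, endpoint, "FEM", 0.0, level)


def dl_tau2(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance.

    ``tau^2 = max(0, (Q - df) / C)`` with ``C = sum(w) - sum(w^2)/sum(w)``
    computed from fixed-effect weights; truncated at zero when Q falls below
    its degrees of freedom.
    """
    theta, se, _ = _theta_se(effects)
    if len(effects) < 2:
        raise ValueError("tau^2 estimation needs at least 2 studies")
    w = 1.0 / se**2
    sw = w.sum()
    mean = (w * theta).sum() / sw
    Q = (w * (theta - mean) ** 2).sum()
    C = sw - (w**2).sum() / sw
    return float(max(0.0, (Q - (len(effects) - 1)) / C))


def random_effects_pool(
    effects: Sequence[EffectEstimate], level: float = 0.95
) -> PooledResult:
    """Random-effects pooling with DerSimonian-Laird tau^2 added to each variance.

    When tau^2 truncates to zero the result coincides with the fixed-effect
    pool on every field except the model tag.
    """
    theta, se, endpoint = _theta_se(effects)
    tau2 = dl_tau2(effects)
    return _pool(theta, se**2 + tau2, endpoint, "REM", tau2, level)


def heterogeneity(
    effects: Sequence[EffectEstimate],
) -> tuple[float, int, float, float]:
    """Cochran Q about the fixed-effect mean, its df, chi-square p, and I^2 (%)."""
    if len(effects) < 2:
        raise ValueError("heterogeneity assessment needs at least 2 studies")
    res = fixed_effect_pool(effects)
    return res.Q, res.df, res.p_Q, res.i_squared


def forest_table(
    effects: Sequence[EffectEstimate],
    fem: PooledResult | None = None,
    rem: PooledResult | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Plot-ready forest table: one row per study plus pooled-model rows.

    Columns: ``study_id, point, ci_low, ci_high, weight_pct``; pooled rows
    carry the model tag as study_id, and a heterogeneity footer row reports
    Q / p / I^2 when at least two studies are pooled.
    """
    if fem is None:
        fem = fixed_effect_pool(effects, level)
    rows = [
        {
            "study_id": e.study_id,
            "point": e.point,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "weight_pct": 100.0 * w,
        }
        for e, w in zip(effects, fem.weights)
    ]
    for pooled in (fem, rem):
        if pooled is not None:
            rows.append(
                {
                    "study_id": f"pooled_{pooled.model}",
                    "point": pooled.point,
                    "ci_low": pooled.ci_low,
                    "ci_high": pooled.ci_high,
                    "weight_pct": 100.0,
                }
            )
    df = pd.DataFrame(rows)
    if fem.df >= 1:
        footer = pd.DataFrame(
            [
                {
                    "study_id": f"heterogeneity Q={fem.Q:.4g} df={fem.df} "
                    f"p={fem.p_Q:.4g} I2={fem.i_squared:.1f}%",
                    "point": math.nan,
                    "ci_low": math.nan,
                    "ci_high": math.nan,
                    "weight_pct": math.nan,
                }
            ]
        )
        df = pd.concat([df, footer], ignore_index=True)
    return df
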