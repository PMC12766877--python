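"""Publication-bias diagnostics: funnel coordinates and the Begg-Mazumdar test.

The rank-correlation test correlates standardized effect deviates with their
variances. Under no small-study bias the deviates

    t_i = (theta_i - theta_FEM) / sqrt(v_i - 1/sum(w))

are exchangeable with respect to the variances, so Kendall's tau between
``t`` and ``v`` is centred at zero; a positive correlation suggests that
less precise studies report systematically larger effects. The variance of
each deviate subtracts the pooled-mean variance because theta_FEM is
estimated from the same data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fesmeta.evidence import EffectEstimate
from fesmeta.pooling import fixed_effect_pool

_VAR_FLOOR = 1e-12  # floor for v_i - 1/sum(w) when it degenerates numerically


@dataclass(frozen=True)
class FunnelData:
    """Funnel-plot coordinates: log effects vs their SEs, SE ascending."""

    study_ids: tuple[str, ...]
    log_effects: tuple[float, ...]
    ses: tuple[float, ...]
    reference: float  # pooled fixed-effect log-scale point

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": self.study_ids,
                "log_effect": self.log_effects,
                "se": self.ses,
            }
        )


@dataclass(frozen=True)
class BeggResult:
    """Begg-Mazumdar rank-correlation outcome (Kendall tau-b and two-sided p)."""

    tau: float
    p: float
    method: str  # "exact" | "normal"
    k: int
    all_ties: bool = False


def funnel_coordinates(effects: Sequence[EffectEstimate]) -> FunnelData:
    """Pair each study's pooling-scale effect with its SE, sorted by SE."""
    pooled = fixed_effect_pool(effects)
    log_ref = (
        math.log(pooled.point) if pooled.endpoint.is_ratio_scale else pooled.point
    )
    pts = [
        (
            e.study_id,
            math.log(e.point) if e.endpoint.is_ratio_scale else e.point,
            e.log_se,
        )
        for e in effects
    ]
    pts.sort(key=lambda t: t[2])
    ids, effs, ses = zip(*pts)
    return FunnelData(ids, effs, ses, log_ref)


def _kendall_S(x: np.ndarray, y: np.ndarray) -> int:
    """Concordant-minus-discordant pair count (tied pairs contribute zero)."""
    s = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))
    return s


@lru_cache(maxsize=None)
def _inversion_counts(n: int) -> tuple[int, ...]:
    """Number of permutations of n distinct items by inversion count.

    Coefficients of prod_{j=1..n} (1 + x + ... + x^{j-1}); index = number of
    discordant pairs when the other ranking is sorted.
    """
    poly = [1]
    for j in range(1, n + 1):
        new = [0] * (len(poly) + j - 1)
        for i, c in enumerate(poly):
            for d in range(j):
                new[i + d] += c
        poly = new
    return tuple(poly)


def _exact_p_no_ties(n: int, s_obs: int) -> float:
    """Two-sided exact p for Kendall S with n untied observations."""
    counts = _inversion_counts(n)
    total = math.factorial(n)
    npairs = n * (n - 1) // 2
    acc = 0
    for d, c in enumerate(counts):
        if abs(npairs - 2 * d) >= abs(s_obs):
            acc += c
    return acc / total


def _exact_p_enumerate(t: np.ndarray, v: np.ndarray, s_obs: int) -> float:
    """Two-sided permutation p by full enumeration (handles tied values)."""
    n = len(t)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        s = _kendall_S(t[list(perm)], v)
        total += 1
        if abs(s) >= abs(s_obs):
            hits += 1
    return hits / total


def _normal_p(t: np.ndarray, v: np.ndarray, s_obs: int) -> float:
    """Normal approximation with continuity correction and tie adjustment."""
    n = len(t)
    var = n * (n - 1) * (2 * n + 5) / 18.0

    def _tie_terms(x: np.ndarray) -> tuple[float, float, float]:
        _, counts = np.unique(x, return_counts=True)
        c = counts[counts > 1].astype(float)
        return (
            float((c * (c - 1) * (2 * c + 5)).sum()),
            float((c * (c - 1) * (c - 2)).sum()),
            float((c * (c - 1)).sum()),
        )

    vt, wt1, wt2 = _tie_terms(t)
    vu, wu1, wu2 = _tie_terms(v)
    var -= (vt + vu) / 18.0
    if n > 2:
        var += wt1 * wu1 / (9.0 * n * (n - 1) * (n - 2))
    var += wt2 * wu2 / (2.0 * n * (n - 1))
    if var <= 0:
        return 1.0
    z = max(0.0, abs(s_obs) - 1.0) / math.sqrt(var)
    return 2.0 * float(stats.norm.sf(z))


def begg_rank_test(
    effects: Sequence[EffectEstimate], exact_max_k: int = 8
) -> BeggResult:
    """Begg-Mazumdar rank-correlation test for small-study (publication) bias.

    Kendall's tau-b between the standardized deviates and the study
    variances, with a two-sided p from the exact permutation distribution
    when k <= ``exact_max_k`` (full enumeration stays below 8! = 40,320
    orderings) and from the tie-corrected normal approximation with
    continuity correction otherwise.
    """
    k = len(effects)
    if k < 3:
        raise ValueError(f"rank-correlation test needs at least 3 studies, got {k}")
    pooled = fixed_effect_pool(effects)
    log_ref = (
        math.log(pooled.point) if pooled.endpoint.is_ratio_scale else pooled.point
    )
    theta = np.array(
        [
            math.log(e.point) if e.endpoint.is_ratio_scale else e.point
            for e in effects
        ]
    )
    v = np.array([e.log_se**2 for e in effects])
    v_pooled = 1.0 / (1.0 / v).sum()
    dv = v - v_pooled
    if np.any(dv <= 0):
        warnings.warn(
            "deviate variance v_i - 1/sum(w) non-positive for some study; "
            f"flooring at {_VAR_FLOOR}",
            RuntimeWarning,
            stacklevel=2,
        )
        dv = np.maximum(dv, _VAR_FLOOR)
    resid = theta - log_ref
    scale = max(1.0, float(np.abs(theta).max()))
    if np.all(np.abs(resid) < 1e-12 * scale):  # effectively identical effects
        return BeggResult(tau=0.0, p=1.0, method="degenerate", k=k, all_ties=True)
    t = resid / np.sqrt(dv)

    if np.all(t == t[0]) or np.all(v == v[0]):
        return BeggResult(tau=0.0, p=1.0, method="degenerate", k=k, all_ties=True)

    tau = float(stats.kendalltau(t, v).statistic)
    s_obs = _kendall_S(t, v)
    t_ties = len(np.unique(t)) < k
    v_ties = len(np.unique(v)) < k
    if k <= exact_max_k:
        if t_ties or v_ties:
            p = _exact_p_enumerate(t, v, s_obs)
        else:
            p = _exact_p_no_ties(k, s_obs)
        method = "exact"
    else:
        p = min(1.0, _normal_p(t, v, s_obs))
        method = "normal"
    return BeggResult(tau=tau, p=p, method=method, k=k)
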