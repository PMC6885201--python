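"""Begg-Mazumdar rank-correlation test for funnel-plot asymmetry.

Each effect is standardized against the fixed-effect pooled estimate:
t_i = (theta_i - theta_hat) / sqrt(v_i - 1/sum w_j), the subtraction in
the denominator removing the correlation induced by theta_hat. Kendall's
rank correlation between t_i and v_i is then tested: small studies
(large v) systematically showing larger effects is the funnel-asymmetry
signature of publication bias. For k <= 8 the permutation null of the
Kendall score is enumerated exactly; otherwise the continuity-corrected
normal approximation (with tie corrections) is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import sqrt
from typing import Sequence

import numpy as np
from scipy import stats

from .effect_size import EffectEstimate
from .pooling import Z95, PooledResult, pool_fixed

EXACT_MAX_K = 8


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of Begg's test.

    ``kendall_statistic`` is the Kendall score T (concordant minus
    discordant pairs); ``tau`` the normalized correlation. ``method`` is
    ``"exact"`` (enumerated permutation null) or ``"normal"``.
    ``degenerate`` flags the undefined case of identical variances.
    """

    kendall_statistic: float
    tau: float
    z_score: float
    p_value: float
    k: int
    method: str
    score_variance: float = 0.0
    degenerate: bool = False


def _kendall_score(x: np.ndarray, y: np.ndarray) -> int:
    """Concordant minus discordant pairs; tied pairs contribute zero."""
    t = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            t += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))
    return t


def _tie_counts(v: np.ndarray) -> np.ndarray:
    _, counts = np.unique(v, return_counts=True)
    return counts[counts > 1]


def _kendall_var(x: np.ndarray, y: np.ndarray) -> float:
    """Null variance of the Kendall score with tie corrections."""
    n = len(x)
    tx, ty = _tie_counts(x), _tie_counts(y)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(tx * (tx - 1) * (2 * tx + 5)))
    vu = float(np.sum(ty * (ty - 1) * (2 * ty + 5)))
    var = (v0 - vt - vu) / 18.0
    if n > 2:
        var += (
            float(np.sum(tx * (tx - 1) * (tx - 2)))
            * float(np.sum(ty * (ty - 1) * (ty - 2)))
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var += (
        float(np.sum(tx * (tx - 1)))
        * float(np.sum(ty * (ty - 1)))
        / (2.0 * n * (n - 1))
    )
    return var


def begg_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Begg's rank-correlation test for publication bias (two-sided).

    With all variances identical the rank correlation is undefined; the
    test then returns p = 1 with ``degenerate=True``.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("Begg's test needs k >= 3 studies")
    theta = np.array([e.effect for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    mu = float(np.sum(w * theta) / np.sum(w))
    v_star = v - 1.0 / np.sum(w)
    if np.ptp(v) == 0.0:
        return BiasTestResult(0.0, 0.0, 0.0, 1.0, k, "degenerate", degenerate=True)
    v_star = np.maximum(v_star, 1e-300)
    t_std = (theta - mu) / np.sqrt(v_star)

    score = _kendall_score(t_std, v)
    n0 = k * (k - 1) / 2
    tau = score / n0

    if k <= EXACT_MAX_K:
        # exact permutation null of the score, conditional on the observed ties
        hits = 0
        total = 0
        for perm in permutations(range(k)):
            total += 1
            if abs(_kendall_score(t_std[list(perm)], v)) >= abs(score):
                hits += 1
        p = hits / total
        var = _kendall_var(t_std, v)
        z = np.sign(score) * max(abs(score) - 1, 0) / sqrt(var)
        return BiasTestResult(float(score), float(tau), float(z), float(p), k, "exact", var)

    var = _kendall_var(t_std, v)
    z = np.sign(score) * max(abs(score) - 1, 0) / sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return BiasTestResult(float(score), float(tau), float(z), float(p), k, "normal", var)


@dataclass(frozen=True)
class FunnelData:
    """Funnel-plot coordinates: study points, center line and pseudo-CI bounds."""

    effects: np.ndarray
    standard_errors: np.ndarray
    study_ids: tuple[str, ...]
    center: float
    bound_se: np.ndarray
    bound_low: np.ndarray
    bound_high: np.ndarray
    pooled: PooledResult


def funnel_coordinates(effects: Sequence[EffectEstimate], n_grid: int = 50) -> FunnelData:
    """Per-study (effect, SE) points and 95% pseudo-confidence funnel bounds.

    The funnel is centered on the fixed-effect pooled estimate; bounds
    are center +/- 1.96*SE over an SE grid from 0 to just past the
    largest observed SE.
    """
    if len(effects) == 0:
        raise ValueError("need at least one effect")
    pooled = pool_fixed(effects)
    se = np.array([e.se for e in effects])
    grid = np.linspace(0.0, float(se.max()) * 1.05, n_grid)
    return FunnelData(
        effects=np.array([e.effect for e in effects]),
        standard_errors=se,
        study_ids=tuple(e.study_id for e in effects),
        center=pooled.estimate,
        bound_se=grid,
        bound_low=pooled.estimate - Z95 * grid,
        bound_high=pooled.estimate + Z95 * grid,
        pooled=pooled,
    )
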