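"""Fixed- and random-effects inverse-variance pooling.

The random-effects model is DerSimonian-Laird: the between-study variance
tau^2 is the method-of-moments estimate from Cochran's Q, truncated at
zero, and studies are re-weighted by 1/(v_i + tau^2). Heterogeneity is
summarized by Q (chi-square with k-1 df under homogeneity) and
I^2 = max(0, (Q - (k-1))/Q). Model selection follows the conventional
screening rule: random effects when the data look heterogeneous
(Q p-value below threshold and/or I^2 above threshold), fixed effect
otherwise. Confidence intervals are Wald intervals with the normal
quantile 1.959964 (no Hartung-Knapp adjustment), matching standard
forest-plot software output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .effect_size import HEDGES_G, EffectEstimate, normalize_smd_kind, smd
from .study_data import StudySummary

logger = logging.getLogger(__name__)

Z95 = 1.959964
FIXED = "fixed"
RANDOM = "random"


@dataclass(frozen=True)
class PooledResult:
    """A pooled effect with heterogeneity statistics.

    ``weights`` are normalized (sum to 1) and aligned with ``study_ids``.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    weights: np.ndarray
    study_ids: tuple[str, ...]
    q: float
    q_pvalue: float
    i_squared: float
    tau_squared: float
    model: str
    k: int

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def _heterogeneity(effects: Sequence[EffectEstimate]):
    """Fixed-effect weights, pooled estimate, Q, its p-value and I^2."""
    theta = np.array([e.effect for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    mu = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - mu) ** 2))
    k = len(effects)
    q_p = float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return theta, v, w, mu, q, q_p, i2


def _assemble(effects, w_star, q, q_p, i2, tau2, model) -> PooledResult:
    theta = np.array([e.effect for e in effects])
    mu = float(np.sum(w_star * theta) / np.sum(w_star))
    se = float(np.sqrt(1.0 / np.sum(w_star)))
    return PooledResult(
        estimate=mu,
        se=se,
        ci_low=mu - Z95 * se,
        ci_high=mu + Z95 * se,
        weights=w_star / np.sum(w_star),
        study_ids=tuple(e.study_id for e in effects),
        q=q,
        q_pvalue=q_p,
        i_squared=i2,
        tau_squared=tau2,
        model=model,
        k=len(effects),
    )


def pool_fixed(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling (common-effect model)."""
    if len(effects) == 0:
        raise ValueError("cannot pool an empty list of effects")
    _, _, w, _, q, q_p, i2 = _heterogeneity(effects)
    return _assemble(effects, w, q, q_p, i2, 0.0, FIXED)


def pool_random_dl(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with the
    fixed-effect weights w_i = 1/v_i, then re-weight by 1/(v_i + tau^2).
    When tau^2 truncates to zero the result coincides with
    :func:`pool_fixed` exactly.
    """
    if len(effects) < 2:
        raise ValueError("random-effects pooling needs k >= 2; use pool_fixed")
    _, v, w, _, q, q_p, i2 = _heterogeneity(effects)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    k = len(effects)
    tau2 = max(0.0, (q - (k - 1)) / c)
    w_star = 1.0 / (v + tau2)
    return _assemble(effects, w_star, q, q_p, i2, tau2, RANDOM)


def select_model(
    effects: Sequence[EffectEstimate],
    p_threshold: float = 0.05,
    i2_threshold: float = 0.50,
    rule: str = "or",
) -> PooledResult:
    """Pool under the heterogeneity-screened model.

    The fixed-effect Q test and I^2 are computed first; the random-effects
    model is used when the data look heterogeneous. ``rule`` sets whether
    *either* condition (``"or"``, the default) or *both* (``"and"``) must
    hold: Q p-value < ``p_threshold``, I^2 > ``i2_threshold``.
    """
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    if len(effects) == 0:
        raise ValueError("cannot pool an empty list of effects")
    if len(effects) == 1:
        return pool_fixed(effects)
    _, _, _, _, q, q_p, i2 = _heterogeneity(effects)
    conds = (q_p < p_threshold, i2 > i2_threshold)
    heterogeneous = any(conds) if rule == "or" else all(conds)
    return pool_random_dl(effects) if heterogeneous else pool_fixed(effects)


@dataclass(frozen=True)
class LeaveOneOutResult:
    """All k leave-one-out poolings plus a min/max stability summary."""

    omitted_ids: tuple[str, ...]
    results: tuple[PooledResult, ...]
    min_estimate: float
    max_estimate: float


def leave_one_out(
    effects: Sequence[EffectEstimate],
    p_threshold: float = 0.05,
    i2_threshold: float = 0.50,
    rule: str = "or",
) -> LeaveOneOutResult:
    """Sensitivity analysis: re-pool k times, omitting one study each time.

    Each re-pooling applies the same model-selection rule as the full
    analysis. The result is stable when the pooled estimate (and its
    significance) does not hinge on any single study.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("leave-one-out needs k >= 3")
    results = []
    for i in range(k):
        subset = [e for j, e in enumerate(effects) if j != i]
        results.append(select_model(subset, p_threshold, i2_threshold, rule))
    ests = [r.estimate for r in results]
    return LeaveOneOutResult(
        omitted_ids=tuple(e.study_id for e in effects),
        results=tuple(results),
        min_estimate=min(ests),
        max_estimate=max(ests),
    )


def pool_subgroup(
    studies: Sequence[StudySummary],
    key: Callable[[StudySummary], str | None],
    kind: str = HEDGES_G,
    p_threshold: float = 0.05,
    i2_threshold: float = 0.50,
    rule: str = "or",
) -> dict[str, PooledResult]:
    """Pool independently within subgroups defined by ``key``.

    ``key`` maps a study to its subgroup label (e.g. ``lambda s:
    s.sample_type``); studies mapped to ``None``/empty are omitted with a
    logged note. A singleton subgroup falls back to the study's own effect
    and CI rather than erroring.
    """
    kind = normalize_smd_kind(kind)
    groups: dict[str, list[StudySummary]] = {}
    skipped = 0
    for s in studies:
        label = key(s)
        if label is None or label == "":
            skipped += 1
            continue
        groups.setdefault(label, []).append(s)
    if skipped:
        logger.info("pool_subgroup: %d study(ies) without a subgroup label omitted", skipped)
    out: dict[str, PooledResult] = {}
    for label, members in groups.items():
        effects = [smd(s, kind) for s in members]
        if len(effects) == 1:
            out[label] = pool_fixed(effects)
        else:
            out[label] = select_model(effects, p_threshold, i2_threshold, rule)
    return out
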