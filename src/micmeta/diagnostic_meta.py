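"""Diagnostic-accuracy meta-analysis: 2x2 tables, pooled sensitivity/
specificity/DOR, and the Moses-Littenberg SROC curve.

Continuous expression is dichotomized per dataset (elevated MIC-1 is the
test-positive state); each dataset then contributes a 2x2 table.
Proportions are pooled on the logit scale, the diagnostic odds ratio on
the log scale, both under the same heterogeneity-screened model rule as
the effect-size pooling. The summary ROC follows Moses-Littenberg: with
D = logit(TPR) - logit(FPR) and S = logit(TPR) + logit(FPR), an
unweighted line D = a + bS is fitted across tables and back-solved to a
TPR(FPR) curve whose area is integrated numerically. The model assumes
|b| < 1; outside that range the curve is degenerate and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .effect_size import EffectEstimate, TwoByTwo, log_odds_ratio
from .pooling import PooledResult, pool_fixed, select_model
from .study_data import SampleDataset

__all__ = [
    "TwoByTwo",
    "dichotomize",
    "pool_proportions",
    "pool_dor",
    "sroc_moses",
    "diagnostic_summary",
    "PooledProportion",
    "PooledDOR",
    "SROCFit",
    "DiagnosticSummary",
]


def dichotomize(data: SampleDataset, rule: str | float = "youden") -> TwoByTwo:
    """Dichotomize a per-sample dataset into a 2x2 table.

    ``rule="youden"`` scans the observed expression values and picks the
    threshold maximizing Youden's J = sensitivity + specificity - 1,
    classifying ``expression > threshold`` as test-positive (MIC-1 is
    elevated in cases). Ties are broken toward the lower threshold. A
    float ``rule`` is used directly as a fixed cut-point. The
    fixed-quantile alternative ``("quantile", q)`` — shorthand
    ``"median"`` for q=0.5 — cuts at the q-th quantile of all observed
    values; unlike the in-sample Youden optimum it does not overfit the
    operating point, which matters when the tables feed the SROC fit.
    """
    case, ctrl = data.case_values, data.control_values
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError(f"{data.dataset_id}: both arms must be non-empty")
    if rule == "median":
        rule = ("quantile", 0.5)
    if isinstance(rule, tuple):
        name, q = rule
        if name != "quantile" or not 0 < q < 1:
            raise ValueError(f"unknown dichotomization rule {rule!r}")
        threshold = float(np.quantile(data.expression, q))
    elif isinstance(rule, str):
        if rule != "youden":
            raise ValueError(f"unknown dichotomization rule {rule!r}")
        thresholds = np.unique(data.expression)
        best_t, best_j = thresholds[0], -np.inf
        for t in thresholds:
            j = np.mean(case > t) + np.mean(ctrl <= t) - 1.0
            if j > best_j:  # strict: ties keep the lower threshold
                best_t, best_j = t, j
        threshold = float(best_t)
    else:
        threshold = float(rule)
    tp = int(np.sum(case > threshold))
    fp = int(np.sum(ctrl > threshold))
    return TwoByTwo(
        study_id=data.dataset_id,
        tp=tp,
        fp=fp,
        fn=len(case) - tp,
        tn=len(ctrl) - fp,
        threshold=threshold,
    )


def _logit_proportion(x: int, n: int) -> tuple[float, float]:
    """Logit and its variance for x successes of n, 0.5-corrected at the boundary."""
    if x == 0 or x == n:
        xf, nf = x + 0.5, n + 1.0
    else:
        xf, nf = float(x), float(n)
    return math.log(xf / (nf - xf)), 1.0 / xf + 1.0 / (nf - xf)


@dataclass(frozen=True)
class PooledProportion:
    """A pooled sensitivity or specificity, back-transformed from the logit scale."""

    which: str
    estimate: float
    ci_low: float
    ci_high: float
    logit_pooled: PooledResult


def pool_proportions(
    tables: Sequence[TwoByTwo],
    which: str,
    p_threshold: float = 0.05,
    i2_threshold: float = 0.50,
    rule: str = "or",
) -> PooledProportion:
    """Pool per-study sensitivity or specificity on the logit scale.

    Boundary proportions (0 or 1) get a 0.5 continuity correction in the
    affected table only. Pooling uses the heterogeneity-screened model
    rule; the CI is back-transformed from the logit-scale Wald CI.
    """
    if which not in ("sensitivity", "specificity"):
        raise ValueError("which must be 'sensitivity' or 'specificity'")
    effects = []
    for t in tables:
        x, n = (t.tp, t.n_case) if which == "sensitivity" else (t.tn, t.n_control)
        lg, var = _logit_proportion(x, n)
        effects.append(
            EffectEstimate(t.study_id, lg, var, "logit_" + which, t.n_case, t.n_control)
        )
    if len(effects) > 1:
        pooled = select_model(effects, p_threshold, i2_threshold, rule)
    else:
        pooled = pool_fixed(effects)
    return PooledProportion(
        which=which,
        estimate=float(expit(pooled.estimate)),
        ci_low=float(expit(pooled.ci_low)),
        ci_high=float(expit(pooled.ci_high)),
        logit_pooled=pooled,
    )


@dataclass(frozen=True)
class PooledDOR:
    """Pooled diagnostic odds ratio, exponentiated from the log scale."""

    estimate: float
    ci_low: float
    ci_high: float
    log_pooled: PooledResult


def pool_dor(
    tables: Sequence[TwoByTwo],
    correction: float = 0.5,
    p_threshold: float = 0.05,
    i2_threshold: float = 0.50,
    rule: str = "or",
) -> PooledDOR:
    """Pool per-table log diagnostic odds ratios and exponentiate."""
    effects = [log_odds_ratio(t, correction) for t in tables]
    if len(effects) > 1:
        pooled = select_model(effects, p_threshold, i2_threshold, rule)
    else:
        pooled = pool_fixed(effects)
    return PooledDOR(
        estimate=math.exp(pooled.estimate),
        ci_low=math.exp(pooled.ci_low),
        ci_high=math.exp(pooled.ci_high),
        log_pooled=pooled,
    )


@dataclass(frozen=True)
class SROCFit:
    """Moses-Littenberg SROC fit: intercept a, slope b, and the curve's AUC."""

    intercept: float
    slope: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    k: int
    degenerate: bool

    def curve(self, fpr: np.ndarray) -> np.ndarray:
        """TPR as a function of FPR along the fitted summary ROC."""
        fpr = np.asarray(fpr, dtype=float)
        tpr = np.empty_like(fpr)
        interior = (fpr > 0) & (fpr < 1)
        u = logit(fpr[interior])
        tpr[interior] = expit((self.intercept + (1 + self.slope) * u) / (1 - self.slope))
        tpr[fpr <= 0] = 0.0
        tpr[fpr >= 1] = 1.0
        return tpr


def _auc_from_line(a: float, b: float, n_grid: int) -> float:
    if abs(b) >= 1:
        return float("nan")
    fpr = np.linspace(0.0, 1.0, n_grid)
    u = logit(np.clip(fpr, 1e-12, 1 - 1e-12))
    tpr = expit((a + (1 + b) * u) / (1 - b))
    tpr[0], tpr[-1] = 0.0, 1.0
    return float(np.trapezoid(tpr, fpr))


def sroc_moses(
    tables: Sequence[TwoByTwo],
    correction: float = 0.5,
    n_grid: int = 2001,
    ci_draws: int = 2000,
    ci_seed: int = 0,
) -> SROCFit:
    """Fit the Moses-Littenberg summary ROC and integrate its AUC.

    Tables with any zero cell get the 0.5 correction before the logits.
    The line D = a + bS is fitted by unweighted least squares; the AUC is
    a trapezoid integral of the back-solved TPR(FPR) over the full [0,1]
    FPR range on an ``n_grid``-point grid. The AUC interval is a
    parametric draw from the normal approximation of (a, b) — a fixed
    ``ci_seed`` keeps it reproducible. ``|b| >= 1`` leaves no valid
    curve: the fit is returned with ``degenerate=True`` and NaN AUC.
    """
    if len(tables) < 3:
        raise ValueError("SROC regression needs k >= 3 tables")
    d_vals, s_vals = [], []
    for t in tables:
        cells = [t.tp, t.fp, t.fn, t.tn]
        if min(cells) == 0:
            cells = [c + correction for c in cells]
        tp, fp, fn, tn = cells
        lt = math.log(tp / fn)
        lf = math.log(fp / tn)
        d_vals.append(lt - lf)
        s_vals.append(lt + lf)
    d = np.array(d_vals)
    s = np.array(s_vals)
    x = np.column_stack([np.ones_like(s), s])
    coef, res_ss, *_ = np.linalg.lstsq(x, d, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    degenerate = abs(b) >= 1
    auc = _auc_from_line(a, b, n_grid)

    # parametric CI from the OLS coefficient covariance
    dof = len(tables) - 2
    if dof > 0 and ci_draws > 0 and not degenerate:
        resid = d - x @ coef
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.pinv(x.T @ x)
        cov = (cov + cov.T) / 2.0  # symmetrize against round-off
        rng = np.random.default_rng(ci_seed)
        draws = rng.multivariate_normal(coef, cov, size=ci_draws, method="svd")
        aucs = np.array([_auc_from_line(ai, bi, 201) for ai, bi in draws])
        aucs = aucs[np.isfinite(aucs)]
        lo, hi = (np.percentile(aucs, [2.5, 97.5]) if len(aucs) else (np.nan, np.nan))
    else:
        lo = hi = float("nan")
    return SROCFit(
        intercept=a,
        slope=b,
        auc=auc,
        auc_ci_low=float(lo),
        auc_ci_high=float(hi),
        k=len(tables),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class DiagnosticSummary:
    """Pooled diagnostic accuracy of elevated MIC-1 for T2DM."""

    sensitivity: PooledProportion
    specificity: PooledProportion
    dor: PooledDOR
    sroc: SROCFit


def diagnostic_summary(
    tables: Sequence[TwoByTwo],
    p_threshold: float = 0.05,
    i2_threshold: float = 0.50,
    rule: str = "or",
) -> DiagnosticSummary:
    """Pooled sensitivity, specificity, DOR and SROC for a set of 2x2 tables."""
    return DiagnosticSummary(
        sensitivity=pool_proportions(tables, "sensitivity", p_threshold, i2_threshold, rule),
        specificity=pool_proportions(tables, "specificity", p_threshold, i2_threshold, rule),
        dor=pool_dor(tables, 0.5, p_threshold, i2_threshold, rule),
        sroc=sroc_moses(tables),
    )
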