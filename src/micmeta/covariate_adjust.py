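"""Covariate-adjusted group differences: per-dataset ANCOVA least-squares
means (age, BMI) and their pooling.

Each per-sample dataset is fitted with the linear model
``expression ~ group + age + bmi`` by ordinary least squares. The
least-squares (adjusted) mean of each group is the model prediction at
the dataset's grand-mean covariates, so the LS-mean difference is the
group effect net of covariate imbalance. With a single response variable
the multivariate analysis of covariance reduces to this univariate
ANCOVA. Adjusted differences are standardized by the ANCOVA residual SD
(the within-group SD net of covariates) and pooled with
DerSimonian-Laird random effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .effect_size import EffectEstimate, hedges_j, normalize_smd_kind, HEDGES_G
from .pooling import PooledResult, pool_random_dl
from .study_data import SampleDataset

DEFAULT_COVARIATES = ("age", "bmi")


@dataclass(frozen=True)
class AdjustedSummary:
    """ANCOVA least-squares means for one dataset.

    ``lsmean_*`` are group means evaluated at the grand means of the
    covariates; ``residual_sd`` is the root mean squared error of the
    ANCOVA fit (the standardizer for the adjusted SMD).
    """

    dataset_id: str
    lsmean_case: float
    lsmean_control: float
    se_case: float
    se_control: float
    residual_sd: float
    n_case: int
    n_control: int
    covariates_used: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.residual_sd > 0:
            raise ValueError(f"{self.dataset_id}: residual SD must be positive")

    @property
    def difference(self) -> float:
        return self.lsmean_case - self.lsmean_control


def ancova_lsmeans(
    data: SampleDataset, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> AdjustedSummary:
    """Fit ``expression ~ group + covariates`` and return least-squares means.

    Covariates are centered at the per-dataset grand mean, so the
    intercept and intercept+group coefficients are directly the LS means;
    their SEs come from the coefficient covariance. A constant covariate
    makes the design rank-deficient and raises, naming the covariate.
    """
    cov_arrays = []
    for name in covariates:
        v = getattr(data, name, None)
        if v is None:
            raise ValueError(f"{data.dataset_id}: covariate '{name}' not present")
        v = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{data.dataset_id}: covariate '{name}' has missing values")
        if np.ptp(v) == 0.0:
            raise ValueError(
                f"{data.dataset_id}: covariate '{name}' is constant (rank-deficient design)"
            )
        cov_arrays.append(v - v.mean())

    n = len(data.expression)
    p = 2 + len(cov_arrays)  # intercept, group, covariates
    if n <= p + 1:
        raise ValueError(
            f"{data.dataset_id}: n={n} leaves insufficient residual df for {p} parameters"
        )
    is_case = (data.group == "case").astype(float)
    x = np.column_stack([np.ones(n), is_case] + cov_arrays)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"{data.dataset_id}: rank-deficient ANCOVA design")
    fit = sm.OLS(data.expression, x).fit()

    # centered covariates: LS mean(control) = b0, LS mean(case) = b0 + b1
    c_ctrl = np.zeros(x.shape[1])
    c_ctrl[0] = 1.0
    c_case = c_ctrl.copy()
    c_case[1] = 1.0
    cov_b = fit.cov_params()
    return AdjustedSummary(
        dataset_id=data.dataset_id,
        lsmean_case=float(c_case @ fit.params),
        lsmean_control=float(c_ctrl @ fit.params),
        se_case=float(np.sqrt(c_case @ cov_b @ c_case)),
        se_control=float(np.sqrt(c_ctrl @ cov_b @ c_ctrl)),
        residual_sd=float(np.sqrt(fit.mse_resid)),
        n_case=data.n_case,
        n_control=data.n_control,
        covariates_used=tuple(covariates),
    )


def adjusted_effect(summary: AdjustedSummary, kind: str = HEDGES_G) -> EffectEstimate:
    """Adjusted SMD: LS-mean difference standardized by the ANCOVA residual SD."""
    kind = normalize_smd_kind(kind)
    n1, n2 = summary.n_case, summary.n_control
    n_tot = n1 + n2
    d = summary.difference / summary.residual_sd
    var = n_tot / (n1 * n2) + d * d / (2 * n_tot)
    if kind == HEDGES_G:
        j = hedges_j(n_tot)
        d *= j
        var *= j * j
    return EffectEstimate(
        study_id=summary.dataset_id,
        effect=d,
        variance=var,
        effect_kind=kind,
        n_case=n1,
        n_control=n2,
    )


def pool_adjusted(
    summaries: Sequence[AdjustedSummary], kind: str = HEDGES_G
) -> PooledResult:
    """Pool covariate-adjusted SMDs across datasets (DL random effects)."""
    if len(summaries) < 2:
        raise ValueError("pooling adjusted differences needs k >= 2 datasets")
    effects = [adjusted_effect(s, kind) for s in summaries]
    return pool_random_dl(effects)
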