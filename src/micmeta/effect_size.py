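"""Per-study effect estimates: standardized mean differences and log odds ratios.

The SMD standardizes the case-minus-control mean difference by the pooled
within-group SD, making studies on arbitrary platform scales commensurate
(the bundled studies span raw means from ~0.1 to ~870). Cohen's d is the
plain ratio; Hedges' g applies the small-sample bias correction
J = 1 - 3/(4N - 9).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

COHEN_D = "cohen_d"
HEDGES_G = "hedges_g"
LOG_OR = "log_or"

_SMD_ALIASES = {
    "cohen": COHEN_D,
    "cohen_d": COHEN_D,
    "d": COHEN_D,
    "hedges": HEDGES_G,
    "hedges_g": HEDGES_G,
    "g": HEDGES_G,
}


@dataclass(frozen=True)
class EffectEstimate:
    """One study's effect (SMD or log-OR) with its sampling variance."""

    study_id: str
    effect: float
    variance: float
    effect_kind: str
    n_case: int = 0
    n_control: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.effect):
            raise ValueError(f"{self.study_id}: effect is not finite")
        if not self.variance > 0:
            raise ValueError(f"{self.study_id}: variance must be positive")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 diagnostic table: cases split TP/FN, controls split FP/TN."""

    study_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError(f"{self.study_id}: cell counts must be non-negative")

    @property
    def n_case(self) -> int:
        return self.tp + self.fn

    @property
    def n_control(self) -> int:
        return self.fp + self.tn


def normalize_smd_kind(kind: str) -> str:
    try:
        return _SMD_ALIASES[kind.lower()]
    except KeyError:
        raise ValueError(f"unknown SMD kind {kind!r}; use cohen_d or hedges_g") from None


def hedges_j(n_total: int) -> float:
    """Small-sample bias correction factor J = 1 - 3/(4N - 9)."""
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def smd(study, kind: str = HEDGES_G) -> EffectEstimate:
    """Standardized mean difference (case minus control) for one study.

    d = (mean_case - mean_control) / s_p with
    s_p^2 = [(n1-1) s1^2 + (n2-1) s2^2] / (n1 + n2 - 2);
    Var(d) = N/(n1 n2) + d^2/(2N). Hedges' g multiplies d by J (and the
    variance by J^2). Positive values mean higher expression in cases.

    A zero pooled SD with equal means yields effect 0 (with a warning);
    with unequal means the effect is undefined and raises.
    """
    kind = normalize_smd_kind(kind)
    n1, n2 = study.n_case, study.n_control
    if n1 < 2 or n2 < 2:
        raise ValueError(f"{study.study_id}: SMD needs n >= 2 in both arms")
    sp2 = ((n1 - 1) * study.sd_case**2 + (n2 - 1) * study.sd_control**2) / (n1 + n2 - 2)
    diff = study.mean_case - study.mean_control
    n_tot = n1 + n2
    if sp2 <= 0.0:
        if diff != 0.0:
            raise ValueError(
                f"{study.study_id}: pooled SD is zero with unequal means; SMD undefined"
            )
        warnings.warn(
            f"{study.study_id}: zero pooled SD with equal means; effect set to 0",
            stacklevel=2,
        )
        d = 0.0
    else:
        d = diff / math.sqrt(sp2)
    var = n_tot / (n1 * n2) + d * d / (2 * n_tot)
    if kind == HEDGES_G:
        j = hedges_j(n_tot)
        d *= j
        var *= j * j
    return EffectEstimate(
        study_id=study.study_id,
        effect=d,
        variance=var,
        effect_kind=kind,
        n_case=n1,
        n_control=n2,
    )


def log_odds_ratio(table: TwoByTwo, correction: float = 0.5) -> EffectEstimate:
    """Log odds ratio (TP*TN)/(FP*FN) from a 2x2 table.

    If any cell is zero, ``correction`` is added to *all four* cells of
    that table (and only of tables that need it). The variance is the
    Woolf sum of reciprocals of the (corrected) cells. A table with an
    empty margin (no cases, no controls, no positives, or no negatives)
    has no defined OR and raises.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if tp + fn == 0 or fp + tn == 0 or tp + fp == 0 or fn + tn == 0:
        raise ValueError(f"{table.study_id}: a margin of the 2x2 table is zero; OR undefined")
    cells = [tp, fp, fn, tn]
    if min(cells) == 0:
        cells = [c + correction for c in cells]
    a, b, c, d = cells
    eff = math.log((a * d) / (b * c))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return EffectEstimate(
        study_id=table.study_id,
        effect=eff,
        variance=var,
        effect_kind=LOG_OR,
        n_case=table.n_case,
        n_control=table.n_control,
    )
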