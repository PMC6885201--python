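"""End-to-end pipeline: configuration, stage orchestration, tabular report writers.

``run_full_pipeline`` replays the whole evidence synthesis on a study
summary table (and optionally a directory of per-sample datasets):
inclusion filtering, per-study SMDs, heterogeneity-screened pooling
overall and per sample type, Begg's test with funnel coordinates, the
leave-one-out sensitivity analysis, and — when per-sample data are
available — dichotomization, diagnostic pooling with the SROC curve, and
ANCOVA-adjusted pooling. Every stage writes one delimited table; machine
output keeps full precision while the run summary rounds effects to 2
decimals and p-values to 3, and a run log records versions, the
configuration and the seed so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariate_adjust import ancova_lsmeans, pool_adjusted
from .diagnostic_meta import diagnostic_summary, dichotomize
from .effect_size import HEDGES_G, normalize_smd_kind, smd
from .pooling import (
    PooledResult,
    leave_one_out,
    pool_fixed,
    pool_random_dl,
    pool_subgroup,
    select_model,
)
from .publication_bias import begg_test, funnel_coordinates
from .study_data import (
    InclusionFilter,
    apply_inclusion,
    read_series_matrix,
    read_summary_table,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full pipeline; defaults mirror the main analysis."""

    effect_kind: str = HEDGES_G
    model: str = "auto"  # auto | fixed | random
    p_threshold: float = 0.05
    i2_threshold: float = 0.50
    heterogeneity_rule: str = "or"  # either condition (or) vs both (and)
    continuity_correction: float = 0.5
    dichotomization_rule: str = "youden"
    covariates: tuple[str, ...] = ("age", "bmi")
    min_total_samples: int = 10
    subgroup_column: str = "sample_type"
    probe_id: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        normalize_smd_kind(self.effect_kind)
        if self.model not in ("auto", "fixed", "random"):
            raise ValueError("model must be auto, fixed or random")
        if self.heterogeneity_rule not in ("or", "and"):
            raise ValueError("heterogeneity_rule must be 'or' or 'and'")
        if not (
            self.dichotomization_rule in ("youden", "median")
            or _is_number(self.dichotomization_rule)
        ):
            raise ValueError(
                "dichotomization_rule must be 'youden', 'median' or a numeric cut-point"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key=value (or key: value) text config."""
        kwargs: dict = {}
        casts = {f.name: f.type for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.replace(":", "=", 1).partition("=")
            key, value = key.strip(), value.strip()
            if key not in casts:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = _cast_config_value(key, value)
        return cls(**kwargs)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def _cast_config_value(key: str, value: str):
    if key in ("p_threshold", "i2_threshold", "continuity_correction"):
        return float(value)
    if key in ("min_total_samples", "seed"):
        return int(value)
    if key == "covariates":
        return tuple(v.strip() for v in value.split(",") if v.strip())
    if key == "probe_id":
        return value or None
    return value


def _pool(effects, config: PipelineConfig) -> PooledResult:
    if config.model == "fixed":
        return pool_fixed(effects)
    if config.model == "random":
        return pool_random_dl(effects)
    return select_model(effects, config.p_threshold, config.i2_threshold, config.heterogeneity_rule)


def _pooled_row(label: str, r: PooledResult) -> dict:
    return {
        "group": label,
        "k": r.k,
        "estimate": r.estimate,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "se": r.se,
        "q": r.q,
        "q_pvalue": r.q_pvalue,
        "i_squared": r.i_squared,
        "tau_squared": r.tau_squared,
        "model": r.model,
    }


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def run_full_pipeline(
    config: PipelineConfig,
    summary_table: str | Path,
    sample_dir: str | Path | None = None,
    out_dir: str | Path = "micmeta_out",
) -> dict[str, Path]:
    """Execute the full evidence-synthesis pipeline; returns report paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict[str, Path] = {}
    log_lines = [
        f"micmeta {__version__} (python {platform.python_version()})",
        f"config: {config}",
        f"seed: {config.seed}",
        f"summary_table: {summary_table}",
    ]

    stage = "read_summary_table"
    try:
        studies = read_summary_table(summary_table)
        log_lines.append(f"studies read: {len(studies)}")

        stage = "inclusion"
        included = apply_inclusion(studies, InclusionFilter(config.min_total_samples))
        log_lines.append(f"inclusion filter (>= {config.min_total_samples} total): "
                         f"kept {len(included)} of {len(studies)}")
        reports["included_studies"] = _write(
            pd.DataFrame([dataclasses.asdict(s) for s in included]),
            out / "included_studies.tsv",
        )

        stage = "effect_size"
        effects = [smd(s, config.effect_kind) for s in included]
        reports["study_effects"] = _write(
            pd.DataFrame(
                [
                    {
                        "study_id": e.study_id,
                        "effect": e.effect,
                        "variance": e.variance,
                        "se": e.se,
                        "ci_low": e.effect - 1.959964 * e.se,
                        "ci_high": e.effect + 1.959964 * e.se,
                        "effect_kind": e.effect_kind,
                    }
                    for e in effects
                ]
            ),
            out / "study_effects.tsv",
        )

        stage = "pooling"
        overall = _pool(effects, config)
        rows = [_pooled_row("overall", overall)]
        stage = "subgroup_pooling"
        subgroups = pool_subgroup(
            included,
            key=lambda s: getattr(s, config.subgroup_column, None),
            kind=config.effect_kind,
            p_threshold=config.p_threshold,
            i2_threshold=config.i2_threshold,
            rule=config.heterogeneity_rule,
        )
        rows += [_pooled_row(label, r) for label, r in sorted(subgroups.items())]
        reports["pooled"] = _write(pd.DataFrame(rows), out / "pooled.tsv")

        stage = "publication_bias"
        bias = begg_test(effects)
        reports["publication_bias"] = _write(
            pd.DataFrame(
                [
                    {
                        "k": bias.k,
                        "kendall_statistic": bias.kendall_statistic,
                        "tau": bias.tau,
                        "z": bias.z_score,
                        "p_value": bias.p_value,
                        "method": bias.method,
                    }
                ]
            ),
            out / "publication_bias.tsv",
        )
        funnel = funnel_coordinates(effects)
        reports["funnel_points"] = _write(
            pd.DataFrame(
                {
                    "study_id": funnel.study_ids,
                    "effect": funnel.effects,
                    "se": funnel.standard_errors,
                }
            ),
            out / "funnel_points.tsv",
        )
        reports["funnel_bounds"] = _write(
            pd.DataFrame(
                {
                    "se": funnel.bound_se,
                    "low": funnel.bound_low,
                    "center": funnel.center,
                    "high": funnel.bound_high,
                }
            ),
            out / "funnel_bounds.tsv",
        )

        stage = "leave_one_out"
        loo = leave_one_out(
            effects, config.p_threshold, config.i2_threshold, config.heterogeneity_rule
        )
        reports["leave_one_out"] = _write(
            pd.DataFrame(
                [
                    {"omitted": sid, **_pooled_row("loo", r)}
                    for sid, r in zip(loo.omitted_ids, loo.results)
                ]
            ).drop(columns="group"),
            out / "leave_one_out.tsv",
        )
        log_lines.append(
            f"leave-one-out estimates in [{loo.min_estimate:.4f}, {loo.max_estimate:.4f}]"
        )

        if sample_dir is not None:
            reports |= _per_sample_stages(config, Path(sample_dir), out, log_lines)
        else:
            log_lines.append("no per-sample directory given; diagnostic and "
                             "adjustment stages skipped")

        stage = "summary"
        reports["summary"] = _write_human_summary(out, overall, subgroups, bias, loo)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    reports["run_log"] = out / "run_log.txt"
    return reports


def _per_sample_stages(
    config: PipelineConfig, sample_dir: Path, out: Path, log_lines: list[str]
) -> dict[str, Path]:
    reports: dict[str, Path] = {}
    matrices = sorted(sample_dir.glob("*.txt"))
    if not matrices:
        log_lines.append(f"no series-matrix files in {sample_dir}; per-sample stages skipped")
        return reports
    datasets = []
    for m in matrices:
        gmap = m.parent / f"{m.stem}.groups.tsv"
        probe = config.probe_id or _first_probe(m)
        ds = read_series_matrix(m, probe, groups=gmap if gmap.exists() else None)
        cov = m.parent / f"{m.stem}.covariates.tsv"
        if cov.exists():
            ds = _attach_covariates(ds, cov)
        datasets.append(ds)
    log_lines.append(f"per-sample datasets read: {len(datasets)}")

    rule: str | float = config.dichotomization_rule
    if rule not in ("youden", "median"):
        rule = float(rule)
    tables = [dichotomize(ds, rule) for ds in datasets]
    reports["diagnostic_tables"] = _write(
        pd.DataFrame(
            [
                {
                    "study_id": t.study_id,
                    "tp": t.tp,
                    "fp": t.fp,
                    "fn": t.fn,
                    "tn": t.tn,
                    "threshold": t.threshold,
                }
                for t in tables
            ]
        ),
        out / "diagnostic_tables.tsv",
    )
    diag = diagnostic_summary(
        tables, config.p_threshold, config.i2_threshold, config.heterogeneity_rule
    )
    reports["diagnostic_summary"] = _write(
        pd.DataFrame(
            [
                {
                    "sensitivity": diag.sensitivity.estimate,
                    "sensitivity_low": diag.sensitivity.ci_low,
                    "sensitivity_high": diag.sensitivity.ci_high,
                    "specificity": diag.specificity.estimate,
                    "specificity_low": diag.specificity.ci_low,
                    "specificity_high": diag.specificity.ci_high,
                    "dor": diag.dor.estimate,
                    "dor_low": diag.dor.ci_low,
                    "dor_high": diag.dor.ci_high,
                    "sroc_intercept": diag.sroc.intercept,
                    "sroc_slope": diag.sroc.slope,
                    "auc": diag.sroc.auc,
                    "auc_low": diag.sroc.auc_ci_low,
                    "auc_high": diag.sroc.auc_ci_high,
                }
            ]
        ),
        out / "diagnostic_summary.tsv",
    )
    fpr = np.linspace(0.0, 1.0, 201)
    reports["sroc_curve"] = _write(
        pd.DataFrame({"fpr": fpr, "tpr": diag.sroc.curve(fpr)}),
        out / "sroc_curve.tsv",
    )

    with_cov = [d for d in datasets if d.age is not None and d.bmi is not None]
    log_lines.append(f"datasets with age/BMI covariates: {len(with_cov)}")
    if len(with_cov) >= 2:
        adjusted = [ancova_lsmeans(d, config.covariates) for d in with_cov]
        reports["adjusted_lsmeans"] = _write(
            pd.DataFrame([dataclasses.asdict(a) for a in adjusted]),
            out / "adjusted_lsmeans.tsv",
        )
        pooled_adj = pool_adjusted(adjusted, config.effect_kind)
        reports["adjusted_pooled"] = _write(
            pd.DataFrame([_pooled_row("adjusted", pooled_adj)]),
            out / "adjusted_pooled.tsv",
        )
    else:
        log_lines.append("fewer than 2 covariate-complete datasets; adjusted pooling skipped")
    return reports


def _first_probe(path: Path) -> str:
    header_seen = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            return line.split("\t", 1)[0].strip().strip('"')
    raise ValueError(f"{path.name}: no probe rows found")


def _attach_covariates(ds, cov_path: Path):
    cov = pd.read_csv(cov_path, sep="\t").set_index("sample_id")
    ids = ds.sample_ids or []
    missing = [s for s in ids if s not in cov.index]
    if missing:
        raise ValueError(f"{ds.dataset_id}: covariates missing for {missing[:3]}")
    ds.age = cov.loc[ids, "age"].to_numpy(dtype=float)
    ds.bmi = cov.loc[ids, "bmi"].to_numpy(dtype=float)
    return ds


def _write_human_summary(out: Path, overall, subgroups, bias, loo) -> Path:
    """Rounded, human-readable digest; every number also exists in a machine table."""
    lines = [
        "Pooled standardized mean differences (case minus control)",
        f"  overall: {overall.estimate:.2f} ({overall.ci_low:.2f}, {overall.ci_high:.2f}) "
        f"[{overall.model}, k={overall.k}, I2={overall.i_squared:.2f}, "
        f"Q p={overall.q_pvalue:.3f}]",
    ]
    for label, r in sorted(subgroups.items()):
        lines.append(
            f"  {label}: {r.estimate:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f}) "
            f"[{r.model}, k={r.k}]"
        )
    lines.append(f"Begg's test: p={bias.p_value:.3f} ({bias.method})")
    lines.append(
        f"Leave-one-out estimates: {loo.min_estimate:.2f} to {loo.max_estimate:.2f}"
    )
    path = out / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
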