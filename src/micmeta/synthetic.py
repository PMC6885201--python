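"""Seeded generators for study summaries and per-sample datasets with known truth.

The generators emulate the statistical structure the analysis assumes: a
two-group normal model per dataset with a standardized group shift drawn
from Normal(true_smd, tau_squared), on an arbitrary per-dataset scale and
offset. The arbitrary scale is deliberate — the bundled real studies span
raw means from ~0.1 to ~870 across platforms — so every downstream stage
must honor the affine invariance that justifies SMD pooling.

Defaults mirror the bundled study collection: 14 studies, a true
standardized shift of 0.54 with between-study variance 0.15, and per-arm
sizes from 5 to 180.

For summary-level generation, per-arm means are drawn as
Normal(mu, sigma^2/n) and SDs from the scaled chi distribution implied by
normal sampling (sigma * sqrt(chi2_{n-1}/(n-1))), so simulated SDs carry
realistic variance-of-variance. Optional age/BMI covariates follow a
linear model with standardized slopes (expression SDs per covariate SD)
and a case-control BMI shift for confounding scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .study_data import SampleDataset, StudySummary


@dataclass(frozen=True)
class CovariateModel:
    """Age/BMI covariate structure for per-sample generation.

    ``bmi_case_shift`` (kg/m^2) moves the case-group BMI mean, creating
    confounding when ``bmi_slope`` is nonzero. Slopes are standardized:
    expression SDs per covariate SD, so they are meaningful on every
    dataset scale.
    """

    age_mean: float = 54.0
    age_sd: float = 9.0
    bmi_mean: float = 29.0
    bmi_sd: float = 4.5
    bmi_case_shift: float = 0.0
    age_slope: float = 0.0
    bmi_slope: float = 0.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic study collection.

    ``true_smd`` is the mean standardized case-minus-control shift;
    per-study shifts are Normal(true_smd, tau_squared). ``scale_range``
    and ``offset_range`` set the per-dataset expression scale (SD
    multiplier) and baseline. ``missing_rate`` applies only when writing
    series-matrix files (cells coded ``null``).
    """

    k: int = 14
    true_smd: float = 0.54
    tau_squared: float = 0.15
    n_range: tuple[int, int] = (5, 180)
    scale_range: tuple[float, float] = (0.1, 200.0)
    offset_range: tuple[float, float] = (0.0, 500.0)
    covariate_model: CovariateModel | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_range[0] < 2:
            raise ValueError("n_range minimum must be >= 2")
        if self.n_range[0] > self.n_range[1]:
            raise ValueError("n_range must be (low, high) with low <= high")
        if self.tau_squared < 0:
            raise ValueError("tau_squared must be non-negative")
        if self.scale_range[0] <= 0:
            raise ValueError("scale_range must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _draw_frame(rng: np.random.Generator, spec: GeneratorSpec, i: int):
    """Per-dataset nuisance draws shared by both generators."""
    lo, hi = spec.n_range
    n1 = int(rng.integers(lo, hi + 1))
    n2 = int(rng.integers(lo, hi + 1))
    theta = float(rng.normal(spec.true_smd, math.sqrt(spec.tau_squared)))
    sigma = float(rng.uniform(*spec.scale_range))
    offset = float(rng.uniform(*spec.offset_range))
    return n1, n2, theta, sigma, offset


def generate_summaries(spec: GeneratorSpec) -> list[StudySummary]:
    """Draw ``spec.k`` study summaries consistent with two-group normal sampling.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.k):
        n1, n2, theta, sigma, offset = _draw_frame(rng, spec, i)
        mu_ctrl = offset
        mu_case = offset + theta * sigma
        mean_case = float(rng.normal(mu_case, sigma / math.sqrt(n1)))
        mean_ctrl = float(rng.normal(mu_ctrl, sigma / math.sqrt(n2)))
        sd_case = sigma * math.sqrt(rng.chisquare(n1 - 1) / (n1 - 1))
        sd_ctrl = sigma * math.sqrt(rng.chisquare(n2 - 1) / (n2 - 1))
        out.append(
            StudySummary(
                study_id=f"SYN{i + 1:03d}",
                n_case=n1,
                mean_case=mean_case,
                sd_case=float(sd_case),
                n_control=n2,
                mean_control=mean_ctrl,
                sd_control=float(sd_ctrl),
                sample_type="synthetic",
                substance="mRNA",
            )
        )
    return out


def generate_samples(spec: GeneratorSpec) -> list[SampleDataset]:
    """Draw ``spec.k`` per-sample datasets with known standardized truth.

    Expression is ``offset + sigma * (theta * case + slopes . z_covariates
    + noise)`` with unit-SD noise, so the *direct* group effect in
    residual-SD units is exactly the drawn theta. Covariates are attached
    only when ``spec.covariate_model`` is set. Deterministic given seed.
    """
    rng = np.random.default_rng(spec.seed)
    cm = spec.covariate_model
    out = []
    for i in range(spec.k):
        n1, n2, theta, sigma, offset = _draw_frame(rng, spec, i)
        n = n1 + n2
        is_case = np.concatenate([np.ones(n1), np.zeros(n2)])
        lin = theta * is_case
        age = bmi = None
        if cm is not None:
            age = rng.normal(cm.age_mean, cm.age_sd, n)
            bmi = rng.normal(cm.bmi_mean + cm.bmi_case_shift * is_case, cm.bmi_sd, n)
            lin = lin + cm.age_slope * (age - cm.age_mean) / cm.age_sd
            lin = lin + cm.bmi_slope * (bmi - cm.bmi_mean) / cm.bmi_sd
        expr = offset + sigma * (lin + rng.standard_normal(n))
        group = np.where(is_case == 1, "case", "control").astype(object)
        ds_id = f"SYN{i + 1:03d}"
        out.append(
            SampleDataset(
                dataset_id=ds_id,
                expression=expr,
                group=group,
                age=age,
                bmi=bmi,
                sample_ids=[f"{ds_id}_S{j + 1:03d}" for j in range(n)],
            )
        )
    return out


# ---------------------------------------------------------------------------
# series-matrix writing (round-trip fixtures for the parser)


def write_series_matrix(
    data: SampleDataset,
    path: str | Path,
    probe_id: str = "PROBE_1",
    n_decoy_probes: int = 2,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> int:
    """Write a dataset in the series-matrix dialect; returns #cells coded missing.

    The target probe carries the dataset's expression vector; decoy
    probes are noise. ``missing_rate`` replaces that fraction of the
    target probe's cells with ``null`` (as real matrices sometimes do),
    which the reader resolves by dropping the affected samples.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    path = Path(path)
    ids = data.sample_ids or [f"S{j + 1:03d}" for j in range(len(data.expression))]
    n = len(ids)
    missing = rng.random(n) < missing_rate
    lines = [
        f"!Series_title\t\"synthetic two-group expression ({data.dataset_id})\"",
        "!Series_platform_id\t\"GPL0000\"",
        "!Sample_geo_accession\t" + "\t".join(f'"{s}"' for s in ids),
        "!Sample_characteristics_ch1\t"
        + "\t".join(
            f'"disease state: {"T2DM" if g == "case" else "nondiabetic control"}"'
            for g in data.group
        ),
        "!series_matrix_table_begin",
        "\t".join(['"ID_REF"'] + [f'"{s}"' for s in ids]),
    ]
    row = [probe_id] + [
        "null" if m else format(v, ".10g") for v, m in zip(data.expression, missing)
    ]
    lines.append("\t".join(row))
    for d in range(n_decoy_probes):
        noise = rng.standard_normal(n)
        lines.append("\t".join([f"DECOY_{d + 1}"] + [format(v, ".10g") for v in noise]))
    lines.append("!series_matrix_table_end")
    path.write_text("\n".join(lines) + "\n")
    return int(missing.sum())


def write_group_map(data: SampleDataset, path: str | Path) -> None:
    """Write the explicit sample->group mapping file for a dataset."""
    ids = data.sample_ids or [f"S{j + 1:03d}" for j in range(len(data.expression))]
    lines = ["sample_id\tgroup"] + [f"{s}\t{g}" for s, g in zip(ids, data.group)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_covariates(data: SampleDataset, path: str | Path) -> None:
    """Write per-sample age/BMI covariates as a delimited sidecar file."""
    if data.age is None or data.bmi is None:
        raise ValueError(f"{data.dataset_id}: no covariates to write")
    ids = data.sample_ids or [f"S{j + 1:03d}" for j in range(len(data.expression))]
    lines = ["sample_id\tage\tbmi"] + [
        f"{s}\t{a:.6f}\t{b:.6f}" for s, a, b in zip(ids, data.age, data.bmi)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset_files(
    datasets: Sequence[SampleDataset],
    out_dir: str | Path,
    probe_id: str = "PROBE_1",
    missing_rate: float = 0.0,
    seed: int = 0,
) -> list[Path]:
    """Write each dataset as series matrix + group map (+ covariates if present)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for ds in datasets:
        sm_path = out_dir / f"{ds.dataset_id}.txt"
        write_series_matrix(ds, sm_path, probe_id=probe_id, missing_rate=missing_rate, rng=rng)
        write_group_map(ds, out_dir / f"{ds.dataset_id}.groups.tsv")
        if ds.age is not None and ds.bmi is not None:
            write_covariates(ds, out_dir / f"{ds.dataset_id}.covariates.tsv")
        paths.append(sm_path)
    return paths
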