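"""Domain types and I/O for study-level summaries and per-sample expression data.

Two levels of data feed the meta-analysis:

* **study summaries** — per-study two-group statistics (n, mean, SD per arm)
  as published in expression-profiling reports; the bundled table of
  MIC-1/GDF15 studies in type 2 diabetes is the canonical example, and
* **per-sample datasets** — one expression value per sample (a single
  gene/probe) with case/control labels and optional age/BMI covariates,
  read from GEO-style series-matrix files or produced synthetically.

Expression values are kept on whatever scale the source used (log or
linear); nothing here transforms them. Downstream standardized effects are
scale-free, which is what licenses pooling across platforms.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SUBSTANCES = ("mRNA", "protein")
BMI_STRATA = ("obese", "nonobese")

_REQUIRED_COLUMNS = (
    "study_id",
    "n_case",
    "mean_case",
    "sd_case",
    "n_control",
    "mean_control",
    "sd_control",
    "sample_type",
)
_OPTIONAL_COLUMNS = ("substance", "country", "year", "bmi_stratum")

#: tokens treated as a missing expression cell in series-matrix files
_MISSING_TOKENS = {"", "null", "na", "nan", "n/a"}


class SchemaError(ValueError):
    """A required column is absent from a summary table."""


class RowError(ValueError):
    """A data row violates a type invariant or fails to parse."""

    def __init__(self, row: int, column: str, message: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column '{column}': {message}")


class SeriesMatrixError(ValueError):
    """A series-matrix file is malformed or lacks the requested probe."""


@dataclass(frozen=True)
class StudySummary:
    """Two-group summary statistics for one study.

    ``mean``/``sd`` are in the source platform's expression units; the
    case arm is the T2DM group. Standard deviations use the n-1
    (sample) convention.
    """

    study_id: str
    n_case: int
    mean_case: float
    sd_case: float
    n_control: int
    mean_control: float
    sd_control: float
    sample_type: str = ""
    substance: str | None = None
    country: str | None = None
    year: int | None = None
    bmi_stratum: str | None = None

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError(f"{self.study_id}: each arm needs n >= 1")
        if self.sd_case < 0 or self.sd_control < 0:
            raise ValueError(f"{self.study_id}: SD must be non-negative")
        for name in ("mean_case", "sd_case", "mean_control", "sd_control"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{self.study_id}: {name} is not finite")
        if self.substance is not None and self.substance not in SUBSTANCES:
            raise ValueError(f"{self.study_id}: substance must be one of {SUBSTANCES}")
        if self.bmi_stratum is not None and self.bmi_stratum not in BMI_STRATA:
            raise ValueError(f"{self.study_id}: bmi_stratum must be one of {BMI_STRATA}")

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


@dataclass(frozen=True)
class InclusionFilter:
    """Study-level inclusion rule: at least ``min_total_samples`` in total.

    ``require_human`` is metadata-based and vacuous on the bundled table
    (all rows are human); it exists so a caller mixing in scraped GEO
    metadata can assert the species criterion explicitly.
    """

    min_total_samples: int = 10
    require_human: bool = True

    def __post_init__(self) -> None:
        if self.min_total_samples < 1:
            raise ValueError("min_total_samples must be >= 1")


@dataclass
class SampleDataset:
    """Per-sample expression values for one dataset, single gene/probe.

    Vectors are aligned; ``group`` entries are ``"case"`` or
    ``"control"``. No missing expression values are allowed here —
    missingness is resolved (sample-wise drop) at parse time.
    """

    dataset_id: str
    expression: np.ndarray
    group: np.ndarray
    age: np.ndarray | None = None
    bmi: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        n = len(self.expression)
        if len(self.group) != n:
            raise ValueError(f"{self.dataset_id}: group/expression length mismatch")
        for name in ("age", "bmi"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                if len(v) != n:
                    raise ValueError(f"{self.dataset_id}: {name} length mismatch")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise ValueError(f"{self.dataset_id}: sample_ids length mismatch")
        bad = set(self.group) - {"case", "control"}
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown group labels {sorted(bad)}")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError(f"{self.dataset_id}: missing/non-finite expression values")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError(f"{self.dataset_id}: need at least one sample per arm")

    @property
    def n_case(self) -> int:
        return int(np.sum(self.group == "case"))

    @property
    def n_control(self) -> int:
        return int(np.sum(self.group == "control"))

    @property
    def case_values(self) -> np.ndarray:
        return self.expression[self.group == "case"]

    @property
    def control_values(self) -> np.ndarray:
        return self.expression[self.group == "control"]


# ---------------------------------------------------------------------------
# summary-table I/O


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_summary_table(path: str | Path, delimiter: str | None = None) -> list[StudySummary]:
    """Read a delimited study-summary table into :class:`StudySummary` records.

    The header must name at least the required columns
    (``study_id, n_case, mean_case, sd_case, n_control, mean_control,
    sd_control, sample_type``); ``substance, country, year, bmi_stratum``
    are optional. Rows violating type invariants raise :class:`RowError`
    naming the offending row and column.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        out: list[StudySummary] = []
        for i, row in enumerate(reader, start=1):
            out.append(_parse_row(i, row))
    return out


def _parse_row(i: int, row: Mapping[str, str]) -> StudySummary:
    def num(col: str, conv: Callable[[str], float]):
        raw = (row.get(col) or "").strip()
        try:
            return conv(raw)
        except (TypeError, ValueError):
            raise RowError(i, col, f"cannot parse {raw!r} as a number") from None

    kwargs: dict = {
        "study_id": (row.get("study_id") or "").strip(),
        "n_case": num("n_case", int),
        "mean_case": num("mean_case", float),
        "sd_case": num("sd_case", float),
        "n_control": num("n_control", int),
        "mean_control": num("mean_control", float),
        "sd_control": num("sd_control", float),
        "sample_type": (row.get("sample_type") or "").strip(),
    }
    for col in _OPTIONAL_COLUMNS:
        raw = (row.get(col) or "").strip()
        if not raw:
            continue
        kwargs[col] = num(col, int) if col == "year" else raw
    try:
        return StudySummary(**kwargs)
    except ValueError as exc:
        raise RowError(i, "-", str(exc)) from None


def write_summary_table(studies: Iterable[StudySummary], path: str | Path, delimiter: str = ",") -> None:
    """Write studies back out in the format :func:`read_summary_table` accepts."""
    cols = list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(cols)
        for s in studies:
            writer.writerow(
                ["" if (v := getattr(s, c)) is None else v for c in cols]
            )


def load_bundled_studies() -> list[StudySummary]:
    """The packaged table of MIC-1/GDF15 expression studies in T2DM (14 rows)."""
    ref = resources.files("micmeta.data").joinpath("mic1_t2dm_studies.csv")
    with resources.as_file(ref) as p:
        return read_summary_table(p)


# ---------------------------------------------------------------------------
# inclusion accounting


def apply_inclusion(
    studies: Sequence[StudySummary], filter: InclusionFilter = InclusionFilter()
) -> list[StudySummary]:
    """Retain studies with ``n_case + n_control >= min_total_samples``; order preserved."""
    kept = [s for s in studies if s.n_total >= filter.min_total_samples]
    if len(kept) < len(studies):
        logger.info("inclusion filter: kept %d of %d studies", len(kept), len(studies))
    return kept


def total_counts(studies: Sequence[StudySummary]) -> tuple[int, int]:
    """Total cases and controls across studies."""
    return sum(s.n_case for s in studies), sum(s.n_control for s in studies)


# ---------------------------------------------------------------------------
# series-matrix parsing

_CASE_RE = re.compile(r"t2dm|type\s*2|\bt2d\b|diabet", re.IGNORECASE)
_NONCASE_RE = re.compile(r"non[-\s]?diabet|control|healthy|normal", re.IGNORECASE)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) delimited file into a mapping."""
    mapping: dict[str, str] = {}
    path = Path(path)
    delim = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delim):
            if not row or row[0].strip().lower() in ("sample_id", ""):
                continue
            sid, grp = row[0].strip(), row[1].strip().lower()
            if grp not in ("case", "control"):
                raise ValueError(f"group for {sid} must be case/control, got {grp!r}")
            mapping[sid] = grp
    return mapping


def _unquote(tok: str) -> str:
    return tok.strip().strip('"')


def read_series_matrix(
    path: str | Path,
    probe_id: str,
    groups: Mapping[str, str] | str | Path | None = None,
) -> SampleDataset:
    """Extract one probe's expression vector from a GEO-style series matrix.

    Lines starting ``!`` are metadata; the first non-metadata line is the
    sample header (``ID_REF`` then sample IDs); subsequent tab-separated
    rows are probes. Cells coded empty/null/NA are treated as missing and
    the corresponding *samples are dropped* (with a logged count).

    ``groups`` maps sample IDs to ``case``/``control`` (a dict or the path
    of a two-column file). When omitted, a best-effort inference scans
    per-sample metadata lines (titles/characteristics) for diabetes vs
    control keywords; supply an explicit mapping whenever the metadata is
    ambiguous — inference failure is an error, never a guess.
    """
    path = Path(path)
    meta: dict[str, list[str]] = {}
    header: list[str] | None = None
    target: list[str] | None = None
    n_probes = 0
    found = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("!"):
                toks = line.split("\t")
                key = toks[0].lstrip("!")
                meta.setdefault(key, []).extend(_unquote(t) for t in toks[1:])
                continue
            toks = [_unquote(t) for t in line.split("\t")]
            if header is None:
                header = toks
                continue
            if len(toks) != len(header):
                raise SeriesMatrixError(
                    f"{path.name}:{lineno}: expected {len(header)} fields, got {len(toks)}"
                )
            n_probes += 1
            if toks[0] == probe_id:
                target = toks[1:]
                found = True
    if header is None:
        raise SeriesMatrixError(f"{path.name}: no sample-header line found")
    if not found:
        raise SeriesMatrixError(
            f"{path.name}: probe {probe_id!r} not found ({n_probes} probes available)"
        )
    sample_ids = header[1:]

    if groups is None:
        mapping = _infer_groups(sample_ids, meta, path.name)
    elif isinstance(groups, (str, Path)):
        mapping = read_group_map(groups)
    else:
        mapping = dict(groups)
    missing_grp = [s for s in sample_ids if s not in mapping]
    if missing_grp:
        raise SeriesMatrixError(
            f"{path.name}: no group label for sample(s) {missing_grp[:5]}"
        )

    expr, grp, kept_ids = [], [], []
    n_missing = 0
    for sid, cell in zip(sample_ids, target):
        if cell.strip().lower() in _MISSING_TOKENS:
            n_missing += 1
            continue
        try:
            val = float(cell)
        except ValueError:
            raise SeriesMatrixError(
                f"{path.name}: non-numeric cell {cell!r} for probe {probe_id!r}, sample {sid}"
            ) from None
        expr.append(val)
        grp.append(mapping[sid])
        kept_ids.append(sid)
    if n_missing:
        logger.info("%s: dropped %d sample(s) with missing values for %s", path.name, n_missing, probe_id)
    return SampleDataset(
        dataset_id=path.stem,
        expression=np.array(expr),
        group=np.array(grp, dtype=object),
        sample_ids=kept_ids,
    )


def _infer_groups(
    sample_ids: Sequence[str], meta: Mapping[str, list[str]], name: str
) -> dict[str, str]:
    per_sample = ["" for _ in sample_ids]
    for key, values in meta.items():
        if not key.lower().startswith("sample"):
            continue
        if len(values) == len(sample_ids):
            per_sample = [a + " | " + b for a, b in zip(per_sample, values)]
    mapping: dict[str, str] = {}
    unresolved = []
    for sid, text in zip(sample_ids, per_sample):
        text = text + " " + sid
        if _NONCASE_RE.search(text):
            mapping[sid] = "control"
        elif _CASE_RE.search(text):
            mapping[sid] = "case"
        else:
            unresolved.append(sid)
    if unresolved:
        raise SeriesMatrixError(
            f"{name}: cannot infer case/control for {len(unresolved)} sample(s) "
            f"(e.g. {unresolved[:3]}); supply an explicit group mapping"
        )
    return mapping


# ---------------------------------------------------------------------------
# summarization


def summarize_dataset(data: SampleDataset) -> StudySummary:
    """Reduce per-sample data to the two-group summary used for effect sizes.

    SDs use the sample (n-1) denominator; an arm with a single sample has
    no defined SD and raises.
    """
    case, ctrl = data.case_values, data.control_values
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"{data.dataset_id}: SD undefined for an arm with n=1 "
            f"(n_case={len(case)}, n_control={len(ctrl)})"
        )
    return StudySummary(
        study_id=data.dataset_id,
        n_case=len(case),
        mean_case=float(np.mean(case)),
        sd_case=float(np.std(case, ddof=1)),
        n_control=len(ctrl),
        mean_control=float(np.mean(ctrl)),
        sd_control=float(np.std(ctrl, ddof=1)),
    )
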