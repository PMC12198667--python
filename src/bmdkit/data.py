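"""Data containers and delimited-text I/O for dose–response analysis.

The package works on individual-animal continuous dose–response data: one
row per animal, a dose in mg/kg bw/d and a strictly positive response in
endpoint units.  Positivity is required because the analysis assumes
lognormally distributed responses; zero or negative values are rejected at
load time rather than offset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseDataset",
    "GroupSummary",
    "EndpointResultRow",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_dataset",
    "read_group_summaries",
    "summarize",
    "write_result_table",
    "read_result_table",
    "format_sig",
]


class DatasetFormatError(ValueError):
    """Raised when an input file does not have the expected columns."""


class DatasetValidationError(ValueError):
    """Raised when data violate the assumptions of the analysis."""


@dataclass
class DoseResponseDataset:
    """Individual responses grouped by dose for one endpoint of one study.

    Doses are stored sorted ascending (stable within ties).  Invariants
    enforced on construction: all responses strictly positive (lognormal
    support), a control group (dose 0) present, and at least two distinct
    nonzero doses so that a dose–response curve is identifiable.
    """

    study_id: str
    endpoint_id: str
    doses: np.ndarray
    responses: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape or self.doses.ndim != 1:
            raise DatasetValidationError(
                "doses and responses must be 1-d arrays of equal length"
            )
        if self.doses.size < 2:
            raise DatasetValidationError("dataset needs at least two observations")
        if np.any(~np.isfinite(self.doses)) or np.any(self.doses < 0):
            raise DatasetValidationError("doses must be finite and non-negative")
        bad = np.flatnonzero(~np.isfinite(self.responses) | (self.responses <= 0))
        if bad.size:
            raise DatasetValidationError(
                f"non-positive or non-finite response at row {bad[0]} "
                f"(value {self.responses[bad[0]]!r}); lognormal responses must be > 0"
            )
        order = np.argsort(self.doses, kind="stable")
        self.doses = self.doses[order]
        self.responses = self.responses[order]
        distinct = np.unique(self.doses)
        if distinct[0] != 0.0:
            raise DatasetValidationError("a control group (dose 0) is required")
        if distinct.size - 1 < 2:
            raise DatasetValidationError(
                "at least two distinct nonzero dose groups are required for fitting"
            )

    @property
    def n_obs(self) -> int:
        return int(self.doses.size)

    @property
    def distinct_doses(self) -> np.ndarray:
        return np.unique(self.doses)

    @property
    def max_dose(self) -> float:
        return float(self.doses.max())

    @property
    def lowest_nonzero_dose(self) -> float:
        d = self.distinct_doses
        return float(d[d > 0].min())

    def group_responses(self) -> dict[float, np.ndarray]:
        return {float(d): self.responses[self.doses == d] for d in self.distinct_doses}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": self.study_id,
                "endpoint_id": self.endpoint_id,
                "dose": self.doses,
                "response": self.responses,
            }
        )


@dataclass(frozen=True)
class GroupSummary:
    """Per-dose-group summary statistics on the natural scale."""

    dose: float
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DatasetValidationError("group size must be >= 1")
        if self.sd < 0:
            raise DatasetValidationError("sd must be non-negative")
        if self.sd == 0 and self.n > 1 and self.mean <= 0:
            raise DatasetValidationError("group mean must be positive")


@dataclass
class EndpointResultRow:
    """One endpoint's line of the result table.

    ``ratio_bmd_bmdl`` and ``ratio_bmdu_bmdl`` are computed from the
    unrounded bounds when not supplied; they are NaN exactly when bmdl is
    zero or a bound is unavailable.
    """

    endpoint_id: str
    ces_signed: float
    bmdl: float
    bmd: float
    bmdu: float
    qc_pass: bool
    study_id: str = ""
    ratio_bmd_bmdl: float | None = None
    ratio_bmdu_bmdl: float | None = None
    model_weights: dict[str, float] = field(default_factory=dict)
    qc_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ratio_bmd_bmdl is None:
            self.ratio_bmd_bmdl = self._ratio(self.bmd)
        if self.ratio_bmdu_bmdl is None:
            self.ratio_bmdu_bmdl = self._ratio(self.bmdu)

    def _ratio(self, upper: float) -> float:
        if self.bmdl is None or not np.isfinite(self.bmdl) or self.bmdl <= 0:
            return float("nan")
        if upper is None or not np.isfinite(upper):
            return float("nan")
        return float(upper) / float(self.bmdl)


def _read_delimited(path) -> pd.DataFrame:
    # comma default, tab accepted: decide from the header line
    with open(path) as fh:
        header = next((ln for ln in fh if ln.strip() and not ln.startswith("#")), "")
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_dataset(path, study_id: str = "", endpoint_id: str = "") -> DoseResponseDataset:
    """Load an individual-animal dataset from a delimited text file.

    The file must have ``dose`` and ``response`` columns; ``study_id``,
    ``endpoint_id`` and ``animal_id`` columns are optional.  When the file
    carries study/endpoint columns and identifiers are given, rows are
    filtered to the requested combination.
    """
    df = _read_delimited(path)
    for col in ("dose", "response"):
        if col not in df.columns:
            raise DatasetFormatError(f"{path}: missing required column '{col}'")
    if study_id and "study_id" in df.columns:
        df = df[df["study_id"].astype(str) == study_id]
    if endpoint_id and "endpoint_id" in df.columns:
        df = df[df["endpoint_id"].astype(str) == endpoint_id]
    if df.empty:
        raise DatasetValidationError(
            f"{path}: no rows for study={study_id!r} endpoint={endpoint_id!r}"
        )
    units = ""
    if "units" in df.columns and len(df["units"].dropna()):
        units = str(df["units"].dropna().iloc[0])
    return DoseResponseDataset(
        study_id=study_id or (str(df["study_id"].iloc[0]) if "study_id" in df.columns else ""),
        endpoint_id=endpoint_id
        or (str(df["endpoint_id"].iloc[0]) if "endpoint_id" in df.columns else ""),
        doses=df["dose"].to_numpy(dtype=float),
        responses=df["response"].to_numpy(dtype=float),
        units=units,
    )


def read_group_summaries(path) -> list[GroupSummary]:
    """Load per-group summaries from a file with dose,n,mean,sd columns."""
    df = _read_delimited(path)
    for col in ("dose", "n", "mean", "sd"):
        if col not in df.columns:
            raise DatasetFormatError(f"{path}: missing required column '{col}'")
    out = []
    for _, r in df.iterrows():
        if int(r["n"]) > 1 and float(r["sd"]) == 0.0:
            warnings.warn(
                f"group at dose {r['dose']}: sd = 0 with n > 1 (zero-variance group)",
                stacklevel=2,
            )
        out.append(
            GroupSummary(
                dose=float(r["dose"]), n=int(r["n"]), mean=float(r["mean"]), sd=float(r["sd"])
            )
        )
    return out


def summarize(dataset: DoseResponseDataset) -> list[GroupSummary]:
    """Per-dose-group n/mean/SD on the natural scale.

    Emits a warning for zero-variance groups with n > 1; those make the
    lognormal likelihood degenerate if every group is affected.
    """
    out = []
    for dose, y in dataset.group_responses().items():
        n = y.size
        sd = float(np.std(y, ddof=1)) if n > 1 else 0.0
        if n > 1 and sd == 0.0:
            warnings.warn(
                f"{dataset.endpoint_id}: zero-variance group at dose {dose}", stacklevel=2
            )
        out.append(GroupSummary(dose=dose, n=int(n), mean=float(np.mean(y)), sd=sd))
    return out


def format_sig(x, sig: int = 3) -> str:
    """Render a value to `sig` significant figures without exponent notation."""
    if x is None:
        return "NA"
    x = float(x)
    if not math.isfinite(x):
        return "NA"
    if x == 0:
        return "0"
    d = sig - 1 - math.floor(math.log10(abs(x)))
    y = round(x, d)
    if d <= 0:
        return str(int(y))
    s = f"{y:.{d}f}"
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


def _fmt_ratio(x) -> str:
    if x is None or not np.isfinite(x):
        return "NA"
    return f"{float(x):.1f}"


_RESULT_COLUMNS = [
    "study_id",
    "endpoint_id",
    "ces",
    "bmdl",
    "bmd",
    "bmdu",
    "bmd_bmdl_ratio",
    "bmdu_bmdl_ratio",
    "qc_pass",
]


def write_result_table(rows: list[EndpointResultRow], path) -> None:
    """Write the result table: BMD quantities at 3 significant figures,
    ratios at 1 decimal, NA for unavailable values; one weight column per
    model present in any row."""
    if not rows:
        raise ValueError("result table must have at least one row")
    weight_models: list[str] = []
    for row in rows:
        for m in row.model_weights:
            if m not in weight_models:
                weight_models.append(m)
    records = []
    for row in rows:
        rec = {
            "study_id": row.study_id,
            "endpoint_id": row.endpoint_id,
            "ces": f"{row.ces_signed:+.2f}",
            "bmdl": format_sig(row.bmdl),
            "bmd": format_sig(row.bmd),
            "bmdu": format_sig(row.bmdu),
            "bmd_bmdl_ratio": _fmt_ratio(row.ratio_bmd_bmdl),
            "bmdu_bmdl_ratio": _fmt_ratio(row.ratio_bmdu_bmdl),
            "qc_pass": int(bool(row.qc_pass)),
        }
        for m in weight_models:
            w = row.model_weights.get(m)
            rec[f"weight_{m}"] = "NA" if w is None else f"{w:.4f}"
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_result_table(path) -> list[EndpointResultRow]:
    """Read back a table written by :func:`write_result_table`.

    Values come back at the rendered precision; ratios are taken from the
    file rather than recomputed, so write→read→write is byte-stable.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing result columns {missing}")
    weight_cols = [c for c in df.columns if c.startswith("weight_")]
    rows = []
    for _, r in df.iterrows():
        weights = {}
        for c in weight_cols:
            if pd.notna(r[c]):
                weights[c[len("weight_") :]] = float(r[c])
        rows.append(
            EndpointResultRow(
                study_id=str(r["study_id"]) if pd.notna(r["study_id"]) else "",
                endpoint_id=str(r["endpoint_id"]),
                ces_signed=float(r["ces"]),
                bmdl=float(r["bmdl"]) if pd.notna(r["bmdl"]) else float("nan"),
                bmd=float(r["bmd"]) if pd.notna(r["bmd"]) else float("nan"),
                bmdu=float(r["bmdu"]) if pd.notna(r["bmdu"]) else float("nan"),
                ratio_bmd_bmdl=float(r["bmd_bmdl_ratio"])
                if pd.notna(r["bmd_bmdl_ratio"])
                else float("nan"),
                ratio_bmdu_bmdl=float(r["bmdu_bmdl_ratio"])
                if pd.notna(r["bmdu_bmdl_ratio"])
                else float("nan"),
                qc_pass=bool(int(r["qc_pass"])),
                model_weights=weights,
            )
        )
    return rows
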