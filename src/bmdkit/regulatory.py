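"""Point-of-departure to DNEL arithmetic and POD-vs-NOAEL comparisons.

A derived no-effect level (DNEL) is obtained from a point of departure
(POD, here a BMDL or NOAEL in mg/kg bw/d) as

    DNEL = POD × absorption_correction / total_assessment_factor

reported to two significant figures.  The defaults (assessment factor 100,
oral absorption 0.7) match the factors used in ECHA's DEHP restriction
calculation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "DnelInputs",
    "RegulatoryRecord",
    "derive_dnel",
    "read_regulatory_table",
    "load_repeated_dose_noaels",
    "load_reproductive_noaels",
    "load_reported_bmd_table",
    "compare_pods",
    "plot_pod_comparison",
]


@dataclass(frozen=True)
class DnelInputs:
    pod: float
    total_assessment_factor: float = 100.0
    absorption_correction: float = 0.7

    def __post_init__(self) -> None:
        if not self.pod > 0:
            raise ValueError("POD must be positive")
        if not self.total_assessment_factor > 0:
            raise ValueError("assessment factor must be positive")
        if not 0.0 < self.absorption_correction <= 1.0:
            raise ValueError("absorption correction must be in (0, 1]")


def _round_sig(x: float, sig: int) -> float:
    return float(f"{x:.{sig}g}")


def derive_dnel(inputs: DnelInputs | float, **kwargs) -> float:
    """DNEL from a POD; accepts a DnelInputs or a bare POD plus keyword
    overrides.  Result is rounded to 2 significant figures."""
    if not isinstance(inputs, DnelInputs):
        inputs = DnelInputs(pod=float(inputs), **kwargs)
    dnel = inputs.pod * inputs.absorption_correction / inputs.total_assessment_factor
    return _round_sig(dnel, 2)


@dataclass(frozen=True)
class RegulatoryRecord:
    """One externally reported NOAEL/LOAEL.  Sex-specific values from the
    same study are separate records sharing a dataset_id; unique-study
    counting therefore goes by dataset_id."""

    dataset_id: str
    species: str
    duration_days: str
    value: float
    value_type: str  # NOAEL or LOAEL
    sex: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("effect level must be positive")
        if self.value_type not in ("NOAEL", "LOAEL"):
            raise ValueError("value_type must be NOAEL or LOAEL")


def read_regulatory_table(path) -> list[RegulatoryRecord]:
    """Read a delimited NOAEL/LOAEL table (columns: dataset_id, species,
    duration_days, value, value_type and optionally sex)."""
    from .data import _read_delimited

    df = _read_delimited(path)
    required = {"dataset_id", "species", "duration_days", "value", "value_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        RegulatoryRecord(
            dataset_id=str(r["dataset_id"]),
            species=str(r["species"]),
            duration_days=str(r["duration_days"]),
            value=float(r["value"]),
            value_type=str(r["value_type"]),
            sex=str(r.get("sex", "") or "") if pd.notna(r.get("sex", "")) else "",
        )
        for _, r in df.iterrows()
    ]


def _packaged(name: str):
    return resources.files("bmdkit.datasets").joinpath(name)


def load_repeated_dose_noaels() -> list[RegulatoryRecord]:
    """Packaged example table: repeated-dose toxicity NOAEL/LOAELs for DEHP
    (<100-day in vivo studies including females) from the public ECHA
    registration databases."""
    with resources.as_file(_packaged("dehp_repeated_dose_noaels.csv")) as p:
        return read_regulatory_table(p)


def load_reproductive_noaels() -> list[RegulatoryRecord]:
    """Packaged example table: reproductive (fertility) toxicity
    NOAEL/LOAELs for DEHP from the public ECHA registration databases."""
    with resources.as_file(_packaged("dehp_reproductive_noaels.csv")) as p:
        return read_regulatory_table(p)


def load_reported_bmd_table() -> pd.DataFrame:
    """Packaged example table: published model-averaged BMDL/BMD/BMDU
    values, CES signs and QC acceptance for the four DEHP studies."""
    with resources.as_file(_packaged("dehp_reported_bmd.csv")) as p:
        return pd.read_csv(p, na_values=["NA"], keep_default_na=False)


def compare_pods(
    bmdls: list[tuple[str, float]], records: list[RegulatoryRecord]
) -> pd.DataFrame:
    """For each labelled BMDL, count and list the regulatory records whose
    effect level falls below it (unique studies by dataset_id)."""
    rows = []
    for label, bmdl in bmdls:
        below = [r for r in records if r.value < bmdl]
        below_ids = sorted({r.dataset_id for r in below})
        rows.append(
            {
                "pod_label": label,
                "pod_value": float(bmdl),
                "n_records": len(records),
                "n_unique_datasets": len({r.dataset_id for r in records}),
                "n_unique_below": len(below_ids),
                "datasets_below": ";".join(below_ids),
                "values_below": ";".join(
                    str(r.value) for r in sorted(below, key=lambda r: r.value)
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("pod_value", ignore_index=True)


def plot_pod_comparison(
    bmdls: list[tuple[str, float]], records: list[RegulatoryRecord], ax=None
):
    """Dot plot of regulatory effect levels with the candidate PODs as
    horizontal reference lines (log dose axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ids = sorted({r.dataset_id for r in records})
    pos = {d: i for i, d in enumerate(ids)}
    for r in records:
        marker = "o" if r.value_type == "NOAEL" else "^"
        ax.plot(pos[r.dataset_id], r.value, marker, color="0.3", ms=5)
    for label, bmdl in bmdls:
        ax.axhline(bmdl, ls="--", lw=1)
        ax.annotate(f"{label} ({bmdl:g})", (len(ids) - 0.5, bmdl), fontsize=7,
                    ha="right", va="bottom")
    ax.set_yscale("log")
    ax.set_xticks(range(len(ids)))
    ax.set_xticklabels(ids, rotation=90, fontsize=6)
    ax.set_ylabel("effect level (mg/kg bw/d)")
    return ax
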