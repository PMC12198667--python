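"""Benchmark-dose computation, model averaging of BMD posteriors, quality
control and endpoint ranking.

The benchmark dose at a critical effect size (CES) is the dose where the
median response curve crosses background·(1 + direction·magnitude).  Each
posterior draw yields one BMD (or NA when that draw's curve never reaches
the target); the model-averaged BMD posterior is a weight-proportional
resample of the per-model draw sets.  The reported BMD is the mixture
median and BMDL/BMDU are the 5th/95th percentiles of the 90% credible
interval; a non-positive lower bound is clamped to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .averaging import ModelWeights
from .data import EndpointResultRow
from .mcmc import ModelFit
from .models import DoseResponseModel

__all__ = [
    "CesSpec",
    "BmdEstimate",
    "QcCriteria",
    "QcVerdict",
    "InsufficientInformationError",
    "bmd_from_params",
    "compute_bmd_draws",
    "averaged_bmd",
    "apply_qc",
    "rank_endpoints",
]

MIN_VALID_DRAWS = 100
DIRECTION_INCONSISTENT_FRACTION = 0.5
DEFAULT_RESAMPLE_SIZE = 10_000


@dataclass(frozen=True)
class CesSpec:
    """Critical effect size: relative change in the central tendency deemed
    adverse, with the sign giving the adverse direction.  ±5% is customary
    for body/organ weights and ±10% for endocrine endpoints."""

    magnitude: float
    direction: int

    def __post_init__(self) -> None:
        if not 0.0 < self.magnitude < 1.0:
            raise ValueError("CES magnitude must be in (0, 1)")
        if self.direction not in (+1, -1):
            raise ValueError("CES direction must be +1 or -1")

    @classmethod
    def from_signed(cls, value: float) -> "CesSpec":
        if value == 0:
            raise ValueError("signed CES must be nonzero")
        return cls(magnitude=abs(value), direction=+1 if value > 0 else -1)

    @property
    def signed(self) -> float:
        return self.direction * self.magnitude


@dataclass
class BmdEstimate:
    """Model-averaged BMDL/BMD/BMDU with bookkeeping of draw validity."""

    bmdl: float
    bmd: float
    bmdu: float
    ces: CesSpec
    credible_level: float = 0.90
    clamped: bool = False
    n_valid_draws: int = 0
    n_total_draws: int = 0
    direction_inconsistent: bool = False


@dataclass(frozen=True)
class QcCriteria:
    """Exclusion thresholds for unreliable BMD estimates: BMD/BMDL > 20,
    BMDU/BMDL > 50, or BMDL more than 10-fold below the lowest nonzero
    dose."""

    max_bmd_bmdl_ratio: float = 20.0
    max_bmdu_bmdl_ratio: float = 50.0
    min_bmdl: float = 0.0

    def __post_init__(self) -> None:
        if self.max_bmd_bmdl_ratio <= 0 or self.max_bmdu_bmdl_ratio <= 0:
            raise ValueError("ratio thresholds must be positive")

    @classmethod
    def for_design(cls, lowest_nonzero_dose: float) -> "QcCriteria":
        return cls(min_bmdl=lowest_nonzero_dose / 10.0)


@dataclass(frozen=True)
class QcVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # verdict usable directly as a boolean
        return self.passed


class InsufficientInformationError(RuntimeError):
    """Too few valid BMD draws to form a credible interval."""


def bmd_from_params(
    model: DoseResponseModel, params, ces: CesSpec, max_dose: float | None = None
) -> float:
    """BMD for one parameter vector; NaN when the curve cannot reach the
    CES target (in the adverse direction, within the extrapolation cap)."""
    return model.bmd(params, ces, max_dose=max_dose)


def compute_bmd_draws(
    fit: ModelFit, model: DoseResponseModel, ces: CesSpec, max_dose: float | None = None
) -> np.ndarray:
    """Per-draw BMDs for a fitted model; stored on the fit and returned."""
    out = np.fromiter(
        (model.bmd(theta[:-1], ces, max_dose=max_dose) for theta in fit.draws),
        dtype=float,
        count=fit.n_draws,
    )
    fit.bmd_draws = out
    return out


def averaged_bmd(
    fits: list[ModelFit],
    weights: ModelWeights,
    ces: CesSpec,
    credible_level: float = 0.90,
    seed: int = 0,
    n_resample: int = DEFAULT_RESAMPLE_SIZE,
) -> BmdEstimate:
    """Model-averaged BMD estimate from per-model BMD draw sets.

    Draws are resampled from each model proportionally to its posterior
    weight (multinomial allocation, seeded), pooled, and summarized by the
    median and the (1±credible_level)/2 percentiles over valid (non-NA)
    draws.  NA draws — curves that never reach the CES target — are
    excluded but counted: more than 50% NA flags the endpoint as
    direction-inconsistent.
    """
    if not 0.0 < credible_level < 1.0:
        raise ValueError("credible_level must be in (0, 1)")
    by_name = {f.model_name: f for f in fits}
    names = [m for m in weights.posterior if m in by_name]
    if not names:
        raise ValueError("no fitted model matches the weight table")
    w = np.array([weights.posterior[m] for m in names])
    w = w / w.sum()
    for m in names:
        if by_name[m].bmd_draws is None:
            raise ValueError(f"model {m} has no per-draw BMDs; run compute_bmd_draws")

    rng = np.random.Generator(np.random.PCG64(seed))
    counts = rng.multinomial(n_resample, w)
    pooled = []
    for m, k in zip(names, counts):
        if k == 0:
            continue
        src = by_name[m].bmd_draws
        pooled.append(src[rng.integers(0, src.size, size=k)])
    pooled = np.concatenate(pooled)

    valid = pooled[np.isfinite(pooled)]
    n_valid = int(valid.size)
    if n_valid < MIN_VALID_DRAWS:
        raise InsufficientInformationError(
            f"only {n_valid} valid BMD draws (need {MIN_VALID_DRAWS})"
        )
    direction_inconsistent = (1.0 - n_valid / pooled.size) > DIRECTION_INCONSISTENT_FRACTION

    alpha = (1.0 - credible_level) / 2.0
    bmdl, bmd, bmdu = np.percentile(valid, [100 * alpha, 50, 100 * (1 - alpha)])
    clamped = False
    if bmdl <= 0:
        bmdl = 0.0
        clamped = True
    return BmdEstimate(
        bmdl=float(bmdl),
        bmd=float(bmd),
        bmdu=float(bmdu),
        ces=ces,
        credible_level=credible_level,
        clamped=clamped,
        n_valid_draws=n_valid,
        n_total_draws=int(pooled.size),
        direction_inconsistent=bool(direction_inconsistent),
    )


def apply_qc(estimate, criteria: QcCriteria) -> QcVerdict:
    """Evaluate the exclusion criteria; reasons enumerate every violation.

    Accepts a :class:`BmdEstimate` or any object with bmdl/bmd/bmdu
    attributes (e.g. a result row built from printed values).
    """
    bmdl, bmd, bmdu = estimate.bmdl, estimate.bmd, estimate.bmdu
    reasons: list[str] = []
    if bmdl is None or not np.isfinite(bmdl) or bmdl <= 0:
        reasons.append("bmdl_zero_or_na")
    if bmd is None or not np.isfinite(bmd) or bmdu is None or not np.isfinite(bmdu):
        reasons.append("bound_na")
    if not reasons:
        if bmd / bmdl > criteria.max_bmd_bmdl_ratio:
            reasons.append("bmd_bmdl_ratio")
        if bmdu / bmdl > criteria.max_bmdu_bmdl_ratio:
            reasons.append("bmdu_bmdl_ratio")
        if bmdl < criteria.min_bmdl:
            reasons.append("bmdl_below_dose_floor")
    return QcVerdict(passed=not reasons, reasons=tuple(reasons))


def rank_endpoints(rows: list[EndpointResultRow]) -> list[EndpointResultRow]:
    """Sensitivity ranking: QC-passing rows ascending by BMDL (ties broken
    by BMD), then failing rows, flagged by their qc_pass field."""

    def key(row: EndpointResultRow):
        bmdl = row.bmdl if np.isfinite(row.bmdl) else math.inf
        bmd = row.bmd if np.isfinite(row.bmd) else math.inf
        return (bmdl, bmd, row.study_id, row.endpoint_id)

    passing = sorted((r for r in rows if r.qc_pass), key=key)
    failing = sorted((r for r in rows if not r.qc_pass), key=key)
    return passing + failing
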