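"""Synthetic-study generator.

Real individual-animal data for the DEHP studies this package was built
around are not publicly deposited, so every pipeline stage is exercised on
simulated studies whose designs mirror the originals: four nonzero dose
groups plus control spanning 0.02–240 mg/kg bw/d, group sizes of 6–10
female mice, and continuous endpoints (serum hormones, follicle counts, %
days in a cycle stage, body/organ weights) with multiplicative lognormal
noise — exactly the distributional assumption the analysis itself makes.
Truth-known simulation is the point: parameters are documented
archetypes, not estimates of the unpublished data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .data import DoseResponseDataset
from .models import get_model

__all__ = ["StudyDesign", "SimulatedStudy", "generate_study", "study_design_suite",
           "ORAL_DOSES", "DIETARY_DOSES"]

ORAL_DOSES = (0.0, 0.02, 0.2, 20.0, 200.0)
DIETARY_DOSES = (0.0, 0.024, 0.24, 24.0, 240.0)


@dataclass(frozen=True)
class StudyDesign:
    """Design and ground truth for one simulated endpoint."""

    study_id: str
    endpoint_id: str
    doses: tuple[float, ...]
    n_per_group: int
    true_model: str
    true_params: tuple[float, ...]
    log_sd: float
    seed: int
    direction: int = +1  # adverse direction; drives exp3/exp5 curve shape
    units: str = ""
    round_to_int: bool = False  # counts reported as whole numbers

    def __post_init__(self) -> None:
        if 0.0 not in self.doses:
            raise ValueError("design must include a control dose of 0")
        if len(set(self.doses)) != len(self.doses):
            raise ValueError("doses must be distinct")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.log_sd >= 0:
            raise ValueError("log_sd must be non-negative")

    def model(self):
        return get_model(self.true_model, direction=self.direction)

    def true_mean(self, dose):
        return self.model().mean(np.asarray(self.true_params), dose)

    def true_bmd(self, ces) -> float:
        return self.model().bmd(np.asarray(self.true_params), ces)


class SimulatedStudy(NamedTuple):
    design: StudyDesign
    dataset: DoseResponseDataset


def generate_study(design: StudyDesign) -> DoseResponseDataset:
    """Draw one dataset: response = f(dose) × exp(ε), ε ~ N(0, log_sd²).

    Seeded and reproducible; |doses| × n_per_group rows in total.
    """
    model = design.model()
    params = np.asarray(design.true_params, dtype=float)
    means = model.mean(params, np.asarray(design.doses))
    if np.any(~np.isfinite(means)) or np.any(means <= 0):
        raise ValueError(
            f"{design.endpoint_id}: true mean non-positive at a design dose"
        )
    rng = np.random.Generator(np.random.PCG64(design.seed))
    doses = np.repeat(np.asarray(design.doses, dtype=float), design.n_per_group)
    mu = np.repeat(means, design.n_per_group)
    y = mu * np.exp(rng.normal(0.0, design.log_sd, size=doses.size))
    if design.round_to_int:
        y = np.maximum(np.rint(y), 1.0)
    return DoseResponseDataset(
        study_id=design.study_id,
        endpoint_id=design.endpoint_id,
        doses=doses,
        responses=y,
        units=design.units,
    )


# --- study-suite archetypes -------------------------------------------------
#
# Endpoint archetypes per study, mirroring the four designs: oral 10-d
# (n=8, HPO endpoints), oral 10-d organ-weight study (n=6), oral 30-d
# (n=8), dietary 30-d (n=10, doses shifted ×1.2).  Directions deliberately
# disagree across studies for progesterone and primordial follicles, as
# they did in the real data.  log-SDs: hormones ~0.4, follicle counts
# ~0.3, cycle percentages ~0.25, organ weights ~0.1–0.2.

def _hpo_archetypes(doses, shifted: bool):
    c = 60.0 if not shifted else 72.0
    return [
        # serum progesterone (ng/ml): hill; rises at 10 d, falls at 30 d
        ("serum_progesterone", "hill", (8.0, 8.0, c, 1.2), 0.40, +1, "ng/ml"),
        ("serum_estradiol", "michaelis_menten", (30.0, -13.0, c / 2), 0.40, -1, "pg/ml"),
        ("primordial_follicles", "exp5", (900.0, 1.2 / doses[-1], 0.55, 1.0), 0.30, -1,
         "count"),
        ("pct_days_estrus", "linear", (25.0, 0.05 * 200.0 / doses[-1]), 0.25, +1, "%"),
    ]


def study_design_suite(seed: int) -> list[SimulatedStudy]:
    """Four-study fixture suite emulating the published designs.

    Returns one :class:`SimulatedStudy` (design + dataset) per endpoint:
    oral 10-d study I (n=8, HPO), oral 10-d study II (n=6, body/organ
    weights), oral 30-d (n=8, HPO), dietary 30-d (n=10, HPO, doses
    0.024–240).
    """
    ss = np.random.SeedSequence(seed)
    specs: list[tuple[str, tuple[float, ...], int, list]] = []

    specs.append(("oral10_I", ORAL_DOSES, 8, _hpo_archetypes(ORAL_DOSES, False)))

    organ = [
        ("final_body_weight", "linear", (27.0, -27.0 * 0.06 / 200.0), 0.08, -1, "g"),
        ("uterus_weight", "michaelis_menten", (0.12, -0.035, 40.0), 0.25, -1, "g"),
        ("ovary_weight", "linear", (0.021, 0.021 * 0.08 / 200.0), 0.20, +1, "g"),
        ("liver_weight", "linear", (1.45, -1.45 * 0.07 / 200.0), 0.12, -1, "g"),
    ]
    specs.append(("oral10_II", ORAL_DOSES, 6, organ))

    oral30 = _hpo_archetypes(ORAL_DOSES, False)
    # at 30 d progesterone falls instead of rising (HPO feedback)
    oral30[0] = ("serum_progesterone", "michaelis_menten", (8.0, -3.2, 50.0), 0.40, -1,
                 "ng/ml")
    specs.append(("oral30", ORAL_DOSES, 8, oral30))

    diet30 = _hpo_archetypes(DIETARY_DOSES, True)
    # primordial counts rise in the dietary study (direction disagreement)
    diet30[2] = ("primordial_follicles", "exp5",
                 (900.0, 1.2 / 240.0, 1.6, 1.0), 0.30, +1, "count")
    specs.append(("diet30", DIETARY_DOSES, 10, diet30))

    out: list[SimulatedStudy] = []
    children = ss.spawn(sum(len(arch) for _, _, _, arch in specs))
    k = 0
    for study_id, doses, n, archetypes in specs:
        for endpoint_id, model, params, log_sd, direction, units in archetypes:
            child_seed = int(children[k].generate_state(1)[0] & 0x7FFFFFFF)
            k += 1
            design = StudyDesign(
                study_id=study_id,
                endpoint_id=endpoint_id,
                doses=tuple(doses),
                n_per_group=n,
                true_model=model,
                true_params=tuple(params),
                log_sd=log_sd,
                seed=child_seed,
                direction=direction,
                units=units,
            )
            out.append(SimulatedStudy(design=design, dataset=generate_study(design)))
    return out
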