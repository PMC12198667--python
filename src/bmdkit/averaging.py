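"""Posterior model weights and exponential-variant selection."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ModelWeights", "posterior_model_weights", "select_exponential"]

_EXP_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ModelWeights:
    """Prior and posterior probability of each model in the averaging set."""

    prior: dict[str, float]
    posterior: dict[str, float]

    def __post_init__(self) -> None:
        for w in (self.prior, self.posterior):
            if abs(sum(w.values()) - 1.0) > 1e-8:
                raise ValueError("model weights must sum to 1")
            if any(v < 0 for v in w.values()):
                raise ValueError("model weights must be non-negative")


def posterior_model_weights(
    evidences: dict[str, float], priors: dict[str, float] | None = None
) -> ModelWeights:
    """w_k ∝ π_k · exp(log ML_k), computed shift-invariantly.

    Models with non-finite evidence are dropped and the remaining prior
    weights renormalized; at least one model must survive.
    """
    names = list(evidences)
    if priors is None:
        priors = {m: 1.0 / len(names) for m in names}
    if abs(sum(priors[m] for m in names) - 1.0) > 1e-8:
        raise ValueError("prior model weights must sum to 1")

    kept = [m for m in names if math.isfinite(evidences[m])]
    if not kept:
        raise ValueError("no model has finite evidence")
    prior_total = sum(priors[m] for m in kept)
    prior = {m: priors[m] / prior_total for m in kept}

    logml = np.array([evidences[m] for m in kept])
    logw = np.log([prior[m] for m in kept]) + (logml - logml.max())
    w = np.exp(logw)
    w /= w.sum()
    posterior = {m: float(x) for m, x in zip(kept, w)}
    return ModelWeights(prior=prior, posterior=posterior)


def select_exponential(evidence_exp3: float, evidence_exp5: float) -> str:
    """Pick the better-fitting exponential variant by marginal likelihood.

    Ties (within 1e-9 log units) and the all-non-finite case resolve to
    exp5.
    """
    if not math.isfinite(evidence_exp3):
        return "exp5"
    if not math.isfinite(evidence_exp5):
        return "exp3"
    return "exp3" if evidence_exp3 > evidence_exp5 + _EXP_TIE_TOL else "exp5"
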