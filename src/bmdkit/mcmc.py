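"""Adaptive random-walk Metropolis sampling of the model posteriors.

A single chain of `iterations` proposals is run and the first
`warmup_fraction` discarded.  Proposal adaptation — a global step-size
tuned toward ~30% acceptance plus, in the second half of warm-up, an
empirical-covariance proposal (Haario-style) — happens during warm-up
only; the proposal is frozen afterwards, which preserves detailed balance
for the retained draws.  Everything is driven by one numpy Generator, so a
seed plus inputs fully determines the draw matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import DoseResponseDataset
from .models import DoseResponseModel, default_priors, log_likelihood

__all__ = ["McmcSettings", "ModelFit", "DegenerateLikelihoodError", "run_mcmc"]

_TARGET_ACCEPT = 0.30


class DegenerateLikelihoodError(RuntimeError):
    """All dose groups have zero variance: σ→0 makes the likelihood improper."""


@dataclass(frozen=True)
class McmcSettings:
    """MCMC run settings; defaults follow a 30,000-iteration single chain
    with a 50% warm-up rate."""

    iterations: int = 30000
    warmup_fraction: float = 0.5
    chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 2:
            raise ValueError("iterations must be >= 2")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")

    @property
    def n_warmup(self) -> int:
        return int(self.iterations * self.warmup_fraction)

    @property
    def n_retained(self) -> int:
        return self.iterations - self.n_warmup


@dataclass
class ModelFit:
    """Posterior draws and evidence for one dose–response model."""

    model_name: str
    param_names: tuple[str, ...]
    draws: np.ndarray  # (n_retained × chains, n_params); last column is σ
    log_marginal_likelihood: float = math.nan
    diagnostics: dict = field(default_factory=dict)
    bmd_draws: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return int(self.draws.shape[0])

    def posterior_median(self) -> dict[str, float]:
        med = np.median(self.draws, axis=0)
        return dict(zip(self.param_names, med.tolist()))


def _split_rhat(chain_draws: list[np.ndarray]) -> np.ndarray:
    """Split-R̂ per parameter from one array of draws per chain."""
    halves = []
    for d in chain_draws:
        h = d.shape[0] // 2
        halves.append(d[:h])
        halves.append(d[h : 2 * h])
    x = np.stack(halves)  # (m, n, p)
    m, n, _ = x.shape
    means = x.mean(axis=1)
    b = n * means.var(axis=0, ddof=1)
    w = x.var(axis=1, ddof=1).mean(axis=0)
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / w)


def _run_single_chain(log_post, x0, box, iterations, n_warmup, rng):
    p = x0.size
    x = x0.copy()
    lp = log_post(x)
    if not math.isfinite(lp):
        raise RuntimeError("initial point has non-finite posterior density")

    scale = np.maximum(np.abs(x0) * 0.05, 1e-4 * (box.upper - box.lower))
    scale = np.maximum(scale, 1e-8)
    log_step = 0.0
    chol = np.diag(scale)

    draws = np.empty((iterations, p))
    n_accept = 0
    window_accept = 0
    window = 50
    adapt_cov_from = n_warmup // 2

    for i in range(iterations):
        step = math.exp(log_step)
        prop = x + step * (chol @ rng.standard_normal(p))
        lp_prop = log_post(prop) if box.contains(prop) else -math.inf
        if math.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            n_accept += 1
            window_accept += 1
        draws[i] = x

        if i < n_warmup and (i + 1) % window == 0:
            rate = window_accept / window
            log_step += 0.5 * (rate - _TARGET_ACCEPT)
            window_accept = 0
            if i + 1 >= adapt_cov_from:
                hist = draws[max(0, i + 1 - 2000) : i + 1]
                cov = np.cov(hist, rowvar=False)
                cov = np.atleast_2d(cov) + 1e-10 * np.eye(p) * np.maximum(
                    scale**2, 1e-12
                )
                try:
                    chol = np.linalg.cholesky((2.38**2 / p) * cov)
                except np.linalg.LinAlgError:
                    pass  # keep previous proposal

    return draws[n_warmup:], n_accept / iterations


def run_mcmc(
    dataset: DoseResponseDataset, model: DoseResponseModel, settings: McmcSettings
) -> ModelFit:
    """Sample the posterior of (model parameters, σ) under flat box priors.

    Returns a :class:`ModelFit` whose evidence is still NaN; see
    :mod:`bmdkit.evidence` for the bridge-sampling step.
    """
    groups = dataset.group_responses()
    if all(np.allclose(y, y[0]) for y in groups.values()):
        raise DegenerateLikelihoodError(
            "every dose group has zero variance; the lognormal likelihood is degenerate"
        )

    box = default_priors(model, dataset)
    log_prior_const = -box.log_volume

    def log_post(theta: np.ndarray) -> float:
        # box membership is checked by the caller; flat prior adds a constant
        return (
            log_likelihood(dataset, model, theta[:-1], theta[-1]) + log_prior_const
        )

    x0 = model.initial_params(dataset)
    x0 = np.clip(x0, box.lower + 1e-9 * (box.upper - box.lower), box.upper)
    if not math.isfinite(log_post(x0)):
        # fall back to a flat curve at the control geometric mean
        x0[1] = 1e-6 if model.name in ("exp3", "exp5") else 0.0
        if not math.isfinite(log_post(x0)):
            raise RuntimeError(f"{model.name}: could not find a valid starting point")

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    chain_draws = []
    accept_rates = []
    for ss in seeds:
        rng = np.random.Generator(np.random.PCG64(ss))
        d, acc = _run_single_chain(
            log_post, x0, box, settings.iterations, settings.n_warmup, rng
        )
        chain_draws.append(d)
        accept_rates.append(acc)

    diagnostics = {"acceptance_rate": float(np.mean(accept_rates))}
    if settings.chains > 1:
        diagnostics["split_rhat"] = _split_rhat(chain_draws)

    return ModelFit(
        model_name=model.name,
        param_names=box.names,
        draws=np.concatenate(chain_draws, axis=0),
        diagnostics=diagnostics,
    )
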