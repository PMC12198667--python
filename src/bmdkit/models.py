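"""Continuous dose–response mean functions, bounds, priors and likelihood.

Six parametric central-tendency curves are available; ``a`` is always the
background response so that ``mean(params, 0) == a``:

==================  =========================================  ==========
name                median response f(d)                       parameters
==================  =========================================  ==========
linear              a + b·d                                    a, b
power               a + b·d^g                                  a, b, g
michaelis_menten    a + b·d/(c + d)                            a, b, c
hill                a + b·d^g/(c^g + d^g)                      a, b, c, g
exp3                a·exp(s·(b·d)^g),  s = ±1 fixed direction  a, b, g
exp5                a·(c − (c − 1)·exp(−(b·d)^g))              a, b, c, g
==================  =========================================  ==========

Responses are modeled as lognormal around the curve: log y ~ Normal(log
f(d), σ²) with σ constant across doses, i.e. f(d) is the *median* (the
geometric mean) of the response distribution.

Every model carries a ``dose_scale``; internally the curve is evaluated on
u = d/dose_scale.  Fitting sets dose_scale to the top dose so that flat
prior boxes on b, c and g are comparable across endpoints whose doses span
four orders of magnitude.  With the default dose_scale of 1 the formulas
above hold verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import DoseResponseDataset

__all__ = [
    "MODEL_NAMES",
    "DoseResponseModel",
    "ErrorModel",
    "PriorBox",
    "get_model",
    "model_mean",
    "log_likelihood",
    "default_priors",
]

MODEL_NAMES = ("linear", "power", "michaelis_menten", "hill", "exp3", "exp5")

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

# search cap for benchmark doses, as a multiple of the top dose
BMD_EXTRAPOLATION_CAP = 1e4


@dataclass(frozen=True)
class ErrorModel:
    """Constant log-scale standard deviation of the lognormal errors."""

    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class PriorBox:
    """Independent uniform (flat) priors over a rectangular box.

    Proper (bounded) by construction, which is what bridge-sampling
    marginal likelihoods require.  The last coordinate is always the
    lognormal σ.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    @property
    def log_volume(self) -> float:
        return float(np.sum(np.log(self.upper - self.lower)))

    def log_pdf(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if np.all(x > self.lower) and np.all(x <= self.upper):
            return -self.log_volume
        return -math.inf

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x > self.lower) and np.all(x <= self.upper))


class DoseResponseModel:
    """Base class: subclasses implement the mean curve and its inversion."""

    name: str = ""
    param_names: tuple[str, ...] = ()

    def __init__(self, direction: int = +1, dose_scale: float = 1.0):
        if direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if not dose_scale > 0:
            raise ValueError("dose_scale must be positive")
        self.direction = int(direction)
        self.dose_scale = float(dose_scale)

    # -- curve ---------------------------------------------------------

    def mean(self, params, dose):
        """Central-tendency (median) response at `dose`; vectorized."""
        u = np.asarray(dose, dtype=float) / self.dose_scale
        return self._mean_u(np.asarray(params, dtype=float), u)

    def _mean_u(self, params, u):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- benchmark dose ------------------------------------------------

    def bmd(self, params, ces, max_dose: float | None = None) -> float:
        """Dose at which the curve crosses background·(1 + direction·magnitude).

        Closed-form inversion; NaN when the curve never reaches the target
        (wrong direction or asymptote short of it) or only beyond the
        extrapolation cap of ``BMD_EXTRAPOLATION_CAP × max_dose``.
        """
        params = np.asarray(params, dtype=float)
        u = self._bmd_u(params, 1.0 + ces.direction * ces.magnitude)
        if u is None or not np.isfinite(u) or u <= 0:
            return float("nan")
        d = u * self.dose_scale
        if max_dose is not None and d > BMD_EXTRAPOLATION_CAP * max_dose:
            return float("nan")
        return float(d)

    def _bmd_u(self, params, ratio):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- fitting support -----------------------------------------------

    def bounds(self, dataset: DoseResponseDataset) -> PriorBox:
        """Data-scaled flat-prior box over (parameters…, σ)."""
        ymax = float(dataset.responses.max())
        lo, hi = self._param_bounds(ymax)
        names = self.param_names + ("sigma",)
        lower = np.array(list(lo) + [0.0])
        upper = np.array(list(hi) + [10.0])
        return PriorBox(names=names, lower=lower, upper=upper)

    def _param_bounds(self, ymax):  # pragma: no cover - abstract
        raise NotImplementedError

    def initial_params(self, dataset: DoseResponseDataset) -> np.ndarray:
        """Data-driven starting point (inside the prior box) incl. σ."""
        groups = dataset.group_responses()
        doses = sorted(groups)
        g0 = float(np.exp(np.mean(np.log(groups[doses[0]]))))
        gtop = float(np.exp(np.mean(np.log(groups[doses[-1]]))))
        logsds = [np.std(np.log(y), ddof=1) for y in groups.values() if y.size > 1]
        sigma0 = float(np.clip(np.sqrt(np.mean(np.square(logsds))) if logsds else 0.3,
                               0.02, 5.0))
        x0 = self._initial(g0, gtop)
        return np.append(x0, sigma0)

    def _initial(self, g0, gtop):  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(DoseResponseModel):
    name = "linear"
    param_names = ("a", "b")

    def _mean_u(self, p, u):
        a, b = p
        return a + b * u

    def _bmd_u(self, p, ratio):
        a, b = p
        if b == 0:
            return None
        return a * (ratio - 1.0) / b

    def _param_bounds(self, ymax):
        return (0.0, -100.0 * ymax), (100.0 * ymax, 100.0 * ymax)

    def _initial(self, g0, gtop):
        return np.array([g0, gtop - g0])


class Power(DoseResponseModel):
    name = "power"
    param_names = ("a", "b", "g")

    def _mean_u(self, p, u):
        a, b, g = p
        with np.errstate(over="ignore", invalid="ignore"):
            return a + b * np.power(u, g)

    def _bmd_u(self, p, ratio):
        a, b, g = p
        if b == 0:
            return None
        x = a * (ratio - 1.0) / b
        if x <= 0:
            return None
        return x ** (1.0 / g)

    def _param_bounds(self, ymax):
        return (0.0, -100.0 * ymax, 0.0), (100.0 * ymax, 100.0 * ymax, 18.0)

    def _initial(self, g0, gtop):
        return np.array([g0, gtop - g0, 1.0])


class MichaelisMenten(DoseResponseModel):
    name = "michaelis_menten"
    param_names = ("a", "b", "c")

    def _mean_u(self, p, u):
        a, b, c = p
        return a + b * u / (c + u)

    def _bmd_u(self, p, ratio):
        a, b, c = p
        delta = a * (ratio - 1.0)
        if b == delta:
            return None
        u = c * delta / (b - delta)
        return u

    def _param_bounds(self, ymax):
        # c on the scaled dose axis: up to 30× the top dose
        return (0.0, -100.0 * ymax, 0.0), (100.0 * ymax, 100.0 * ymax, 30.0)

    def _initial(self, g0, gtop):
        return np.array([g0, gtop - g0, 0.3])


class Hill(DoseResponseModel):
    name = "hill"
    param_names = ("a", "b", "c", "g")

    def _mean_u(self, p, u):
        a, b, c, g = p
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ug = np.power(u, g)
            return a + b * ug / (np.power(c, g) + ug)

    def _bmd_u(self, p, ratio):
        a, b, c, g = p
        delta = a * (ratio - 1.0)
        if b == delta:
            return None
        x = delta * c**g / (b - delta)
        if x <= 0:
            return None
        return x ** (1.0 / g)

    def _param_bounds(self, ymax):
        return (0.0, -100.0 * ymax, 0.0, 0.0), (100.0 * ymax, 100.0 * ymax, 30.0, 18.0)

    def _initial(self, g0, gtop):
        return np.array([g0, gtop - g0, 0.3, 1.0])


class Exponential3(DoseResponseModel):
    """a·exp(s·(b·d)^g) with the sign s fixed to the adverse direction."""

    name = "exp3"
    param_names = ("a", "b", "g")

    def _mean_u(self, p, u):
        a, b, g = p
        with np.errstate(over="ignore", invalid="ignore"):
            return a * np.exp(self.direction * np.power(b * u, g))

    def _bmd_u(self, p, ratio):
        a, b, g = p
        if b <= 0:
            return None
        t = self.direction * math.log(ratio)
        if t <= 0:
            return None
        return t ** (1.0 / g) / b

    def _param_bounds(self, ymax):
        return (0.0, 0.0, 0.0), (100.0 * ymax, 100.0, 18.0)

    def _initial(self, g0, gtop):
        t = abs(math.log(max(gtop, 1e-300) / max(g0, 1e-300)))
        return np.array([g0, min(max(t, 0.05), 50.0), 1.0])


class Exponential5(DoseResponseModel):
    """a·(c − (c − 1)·exp(−(b·d)^g)); the asymptote a·c sits on the adverse
    side of background, so c is bounded in (1, 100] for increasing and in
    (0, 1) for decreasing responses."""

    name = "exp5"
    param_names = ("a", "b", "c", "g")

    def _mean_u(self, p, u):
        a, b, c, g = p
        with np.errstate(over="ignore", invalid="ignore"):
            return a * (c - (c - 1.0) * np.exp(-np.power(b * u, g)))

    def _bmd_u(self, p, ratio):
        a, b, c, g = p
        if b <= 0 or c == 1.0:
            return None
        frac = (c - ratio) / (c - 1.0)
        if not 0.0 < frac < 1.0:
            return None
        return (-math.log(frac)) ** (1.0 / g) / b

    def _param_bounds(self, ymax):
        if self.direction > 0:
            c_lo, c_hi = 1.0, 100.0
        else:
            c_lo, c_hi = 0.0, 1.0
        return (0.0, 0.0, c_lo, 0.0), (100.0 * ymax, 100.0, c_hi, 18.0)

    def _initial(self, g0, gtop):
        ratio = gtop / g0 if g0 > 0 else 1.0
        if self.direction > 0:
            c0 = min(max(ratio, 1.05), 99.0)
        else:
            c0 = min(max(ratio, 0.01), 0.95)
        return np.array([g0, 1.0, c0, 1.0])


_MODEL_CLASSES = {
    cls.name: cls
    for cls in (Linear, Power, MichaelisMenten, Hill, Exponential3, Exponential5)
}


def get_model(name: str, direction: int = +1, dose_scale: float = 1.0) -> DoseResponseModel:
    """Instantiate a model by its canonical name."""
    try:
        cls = _MODEL_CLASSES[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}") from None
    return cls(direction=direction, dose_scale=dose_scale)


def model_mean(model: DoseResponseModel, params, dose):
    """Median response at `dose`; raises if params sit outside plausibility.

    Only basic domain checks are applied here (shape parameters positive);
    full box membership is the prior's job during fitting.
    """
    params = np.asarray(params, dtype=float)
    if params.size != len(model.param_names):
        raise ValueError(
            f"{model.name} expects {len(model.param_names)} parameters "
            f"{model.param_names}, got {params.size}"
        )
    if params[0] <= 0:
        raise ValueError("background parameter a must be positive")
    for i, nm in enumerate(model.param_names):
        if nm in ("c", "g") and params[i] <= 0:
            raise ValueError(f"parameter {nm} must be positive")
    return model.mean(params, dose)


def log_likelihood(
    dataset: DoseResponseDataset, model: DoseResponseModel, params, sigma: float
) -> float:
    """Lognormal log-likelihood: log y_i ~ Normal(log f(d_i), σ²).

    Returns −inf (a rejected sample, not an exception) whenever the mean
    curve is non-positive at an observed dose.
    """
    if isinstance(sigma, ErrorModel):
        sigma = sigma.sigma
    if sigma <= 0:
        return -math.inf
    mu = model.mean(params, dataset.doses)
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        return -math.inf
    logy = np.log(dataset.responses)
    z = (logy - np.log(mu)) / sigma
    n = dataset.n_obs
    ll = -n * (_LOG_SQRT_2PI + math.log(sigma)) - 0.5 * float(z @ z) - float(logy.sum())
    return ll if math.isfinite(ll) else -math.inf


def default_priors(model: DoseResponseModel, dataset: DoseResponseDataset) -> PriorBox:
    """Flat, proper priors over data-scaled boxes (uninformative in the
    sense of equal prior probability across the plausible range)."""
    return model.bounds(dataset)
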