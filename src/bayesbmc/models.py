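"""The eight continuous dose-response mean functions and their likelihood.

All models describe the mean percent response (0-100 scale) as a function of
dose.  Internally every formula is written in terms of the rescaled dose
``u = dose / dose_scale`` (``dose_scale`` is normally the largest observed
dose), so that exponent parameters behave the same way on any dose ladder:

========================  ==================================================
name                      f(u)
========================  ==================================================
exp2                      a * exp(b*u)
exp3                      a * exp(b*u**g)
exp4                      a * (c - (c-1)*exp(-b*u))
exp5                      a * (c - (c-1)*exp(-b*u**g))
hill                      a + b * u**g / (c**g + u**g)
power                     a + b * u**g
michaelis_menten          a + b * u / (c + u)
linear                    a + b * u
========================  ==================================================

``a`` is the background response at dose 0 (percent) for every model; ``b``
controls the size/steepness of the dose effect; ``c`` is the asymptote
multiplier (exp4/exp5) or the half-saturation dose in rescaled units
(hill/michaelis_menten); ``g`` is a shape exponent.  With ``b > 0`` (and
``c > 1`` for exp4/exp5) every model is non-decreasing in dose.

The likelihood is normal with a common residual SD ``sigma`` (percent) across
dose groups, expressed through the per-group sufficient statistics
``(n_i, m_i, s_i)``; this equals the product of per-replicate normal
densities exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .data import DoseResponseDataset

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "ParameterVector",
    "Priors",
    "make_spec",
    "evaluate",
    "mean_function",
    "log_likelihood",
    "log_scale_summaries",
    "default_priors",
]

MODEL_NAMES = (
    "exp2",
    "exp3",
    "exp4",
    "exp5",
    "hill",
    "power",
    "michaelis_menten",
    "linear",
)

#: Human-readable labels used in report tables.
MODEL_LABELS = {
    "exp2": "Exponential model 2",
    "exp3": "Exponential model 3",
    "exp4": "Exponential model 4",
    "exp5": "Exponential model 5",
    "hill": "Hill model",
    "power": "Power model",
    "michaelis_menten": "Michaelis Menten model",
    "linear": "Linear model",
}

_PARAMS = {
    "exp2": ("a", "b"),
    "exp3": ("a", "b", "g"),
    "exp4": ("a", "b", "c"),
    "exp5": ("a", "b", "c", "g"),
    "hill": ("a", "b", "c", "g"),
    "power": ("a", "b", "g"),
    "michaelis_menten": ("a", "b", "c"),
    "linear": ("a", "b"),
}


def _f_exp2(p, u):
    return p["a"] * np.exp(p["b"] * u)


def _f_exp3(p, u):
    return p["a"] * np.exp(p["b"] * _pow(u, p["g"]))


def _f_exp4(p, u):
    return p["a"] * (p["c"] - (p["c"] - 1.0) * np.exp(-p["b"] * u))


def _f_exp5(p, u):
    return p["a"] * (p["c"] - (p["c"] - 1.0) * np.exp(-p["b"] * _pow(u, p["g"])))


def _f_hill(p, u):
    ug = _pow(u, p["g"])
    return p["a"] + p["b"] * ug / (_pow(p["c"], p["g"]) + ug)


def _f_power(p, u):
    return p["a"] + p["b"] * _pow(u, p["g"])


def _f_mm(p, u):
    return p["a"] + p["b"] * u / (p["c"] + u)


def _f_linear(p, u):
    return p["a"] + p["b"] * u


def _pow(u, g):
    # 0**g := 0 for g > 0 (the convention used throughout)
    with np.errstate(divide="ignore"):
        return np.power(u, g)


_FORMULAS: dict[str, Callable] = {
    "exp2": _f_exp2,
    "exp3": _f_exp3,
    "exp4": _f_exp4,
    "exp5": _f_exp5,
    "hill": _f_hill,
    "power": _f_power,
    "michaelis_menten": _f_mm,
    "linear": _f_linear,
}


@dataclass(frozen=True)
class ModelSpec:
    """One dose-response model tied to a dose scale.

    ``dose_scale`` (mg/L) converts natural doses into the rescaled ``u``
    coordinate the formulas use; parameters ``c`` (hill/michaelis_menten) are
    half-saturation doses in units of ``dose_scale``.
    """

    name: str
    dose_scale: float

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if self.dose_scale <= 0:
            raise ValueError("dose_scale must be positive")

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAMS[self.name]

    @property
    def label(self) -> str:
        return MODEL_LABELS[self.name]


@dataclass(frozen=True)
class ParameterVector:
    """A single point in parameter space: mean-function params + residual SD."""

    params: Mapping[str, float]
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class Priors:
    """Prior specification: flat box priors on mean-function parameters,
    half-Cauchy on sigma, plus a support cap on the fitted curve.

    ``bounds`` maps each parameter to (low, high) and doubles as the support
    of its flat prior.  ``response_cap`` truncates the joint support to
    parameter values whose mean response at the largest observed dose stays
    below the cap (keeps prior predictive curves on a sane percent scale).
    """

    bounds: Mapping[str, tuple[float, float]]
    sigma_scale: float
    response_cap: float
    #: normal prior on the background a (mean, sd); None leaves a flat.
    #: The control group measures the background directly, so anchoring a
    #: weakly to the observed control mean keeps misspecified models from
    #: trading background bias for shape.
    a_prior: tuple[float, float] | None = None
    #: parameters whose prior is uniform on log(theta - low) rather than on
    #: theta itself (scale parameters with unknown order of magnitude)
    log_scale_params: tuple[str, ...] = ()

    def validate(self, theta: ParameterVector, spec: ModelSpec) -> None:
        for name in spec.param_names:
            lo, hi = self.bounds[name]
            v = theta.params[name]
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside prior bounds ({lo}, {hi})")


def make_spec(name: str, dose_scale: float) -> ModelSpec:
    """Build a ModelSpec for a model name and a dose scale (mg/L)."""
    return ModelSpec(name, float(dose_scale))


def mean_function(spec: ModelSpec, params: Mapping[str, np.ndarray], dose) -> np.ndarray:
    """Vectorized mean response (%) at natural-scale dose(s).

    ``params`` values may be scalars or draw arrays; broadcasting applies.
    Overflow in the exponential models yields +inf rather than raising.
    """
    u = np.asarray(dose, dtype=float) / spec.dose_scale
    if np.any(u < 0):
        raise ValueError("dose must be non-negative")
    with np.errstate(over="ignore"):
        return _FORMULAS[spec.name](params, u)


def evaluate(spec: ModelSpec, theta: ParameterVector, dose) -> np.ndarray | float:
    """Mean response (%) of the model at dose (mg/L); vectorized over dose."""
    _check_params(spec, theta)
    out = mean_function(spec, theta.params, dose)
    return float(out) if np.isscalar(dose) else out


def _check_params(spec: ModelSpec, theta: ParameterVector) -> None:
    missing = set(spec.param_names) - set(theta.params)
    if missing:
        raise ValueError(f"missing parameters for {spec.name}: {sorted(missing)}")
    p = theta.params
    if p["a"] <= 0:
        raise ValueError("a must be positive (background response)")
    if spec.name in ("hill", "michaelis_menten") and p["c"] <= 0:
        raise ValueError("c must be positive for hill/michaelis_menten")
    if spec.name in ("exp4", "exp5") and p["c"] <= 1:
        raise ValueError("c must exceed 1 for exp4/exp5")
    if "g" in spec.param_names and p["g"] <= 0:
        raise ValueError("g must be positive")


_LOG_2PI = float(np.log(2.0 * np.pi))


def log_scale_summaries(
    dataset: DoseResponseDataset, floor: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Log-scale group means and SDs for the lognormal likelihood.

    Matched-moments conversion of the arithmetic summaries (m, s):
    mu_i = log(m_i / sqrt(1 + cv_i^2)), slog_i^2 = log(1 + cv_i^2) with
    cv_i = s_i / m_i.  Group means are floored at ``floor`` percent (a
    lognormal response cannot be exactly zero); a warning is emitted when the
    floor engages.
    """
    m = dataset.means
    if np.any(m < floor):
        warnings.warn(
            f"group mean(s) below {floor}% floored for the lognormal scale"
        )
    m = np.maximum(m, floor)
    cv2 = (dataset.sds / m) ** 2
    mu = np.log(m / np.sqrt(1.0 + cv2))
    slog = np.sqrt(np.log(1.0 + cv2))
    return mu, slog


def log_likelihood(
    spec: ModelSpec,
    theta: ParameterVector,
    dataset: DoseResponseDataset,
    likelihood: str = "normal",
) -> float:
    """Log-likelihood from group sufficient statistics.

    ``likelihood="normal"``: common residual SD sigma across groups; the
    value equals the sum of per-replicate Normal(f(d_i), sigma) log-densities
    exactly (constants included).  ``likelihood="lognormal"``: per-replicate
    responses are lognormal with median f(d_i) and common log-scale SD sigma
    (a constant coefficient of variation), evaluated through the log-scale
    summaries of ``log_scale_summaries``.
    """
    ll = pointwise_log_likelihood(
        spec,
        {k: np.asarray(v) for k, v in theta.params.items()},
        np.asarray(theta.sigma),
        dataset,
        likelihood=likelihood,
    )
    return float(np.sum(ll))


def pointwise_log_likelihood(
    spec: ModelSpec,
    params: Mapping[str, np.ndarray],
    sigma: np.ndarray,
    dataset: DoseResponseDataset,
    likelihood: str = "normal",
) -> np.ndarray:
    """Per-group log-likelihood, vectorized over draws.

    Parameter arrays of shape (...,) produce output of shape (..., n_groups).
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    n = dataset.n_reps.astype(float)
    p = {k: np.asarray(v, dtype=float)[..., None] for k, v in params.items()}
    sig = sigma[..., None]
    f = mean_function(spec, p, dataset.doses)
    if likelihood == "normal":
        m, s = dataset.means, dataset.sds
        ss = (n - 1.0) * s**2 + n * (m - f) ** 2
        return -0.5 * n * _LOG_2PI - n * np.log(sig) - ss / (2.0 * sig**2)
    if likelihood != "lognormal":
        raise ValueError("likelihood must be 'normal' or 'lognormal'")
    mu, slog = log_scale_summaries(dataset)
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.log(f)
    ss = (n - 1.0) * slog**2 + n * (mu - logf) ** 2
    # the -sum(log y_ij) change-of-variable term equals -n_i * mu_i
    return (
        -0.5 * n * _LOG_2PI - n * np.log(sig) - n * mu - ss / (2.0 * sig**2)
    )


def default_priors(
    spec: ModelSpec,
    dataset: DoseResponseDataset,
    restrict_g_ge_1: bool = True,
    likelihood: str = "lognormal",
    anchor_background: bool = False,
    overrides: Mapping[str, tuple[float, float]] | None = None,
) -> Priors:
    """Weakly-informative default priors scaled to the dataset.

    Flat priors on bounded boxes: ``a`` over (0, 2 x max response],
    ``b`` sign-constrained positive (an increasing endpoint), ``g`` in
    [1, 15] (the standard benchmark-dose restriction that keeps the slope
    finite at dose 0; pass ``restrict_g_ge_1=False`` for the unrestricted
    (0, 15] support), ``c`` in (1, 20] for exp4/exp5 (plateau at most 20 x
    background, which keeps those models identifiable on data without a
    visible plateau) and (0, 10] rescaled-dose units for hill/
    michaelis_menten (i.e. up to 10 x the largest dose).  ``sigma`` gets a
    half-Cauchy prior scaled to the typical within-group spread on the
    likelihood's own scale.  The joint support is truncated to curves whose
    mean at the largest observed dose stays below 3 x the largest observed
    mean, keeping prior predictive curves on a sane percent scale.
    ``anchor_background`` adds a normal prior on ``a`` centered at the
    observed control mean (2 x control SD wide).
    """
    ymax = float(max(dataset.means.max(), 10.0))
    cap = 3.0 * ymax
    a_hi = 2.0 * ymax
    g_lo = 1.0 if restrict_g_ge_1 else 0.05
    bounds: dict[str, tuple[float, float]] = {"a": (1e-6, a_hi)}
    if spec.name in ("exp2", "exp3"):
        bounds["b"] = (1e-6, 10.0)
    elif spec.name in ("exp4", "exp5"):
        bounds["b"] = (1e-6, 100.0)
    elif spec.name == "hill":
        bounds["b"] = (1e-6, cap)
    else:  # power, michaelis_menten, linear
        bounds["b"] = (1e-6, 5.0 * cap)
    if "g" in spec.param_names:
        bounds["g"] = (g_lo, 15.0)
    if spec.name in ("exp4", "exp5"):
        bounds["c"] = (1.0 + 1e-6, 20.0)
    elif spec.name in ("hill", "michaelis_menten"):
        bounds["c"] = (1e-4, 10.0)
    if overrides:
        bounds.update({k: tuple(v) for k, v in overrides.items()})
    if likelihood == "lognormal":
        _, slog = log_scale_summaries(dataset)
        sigma_scale = float(max(slog.mean(), 0.25))
    else:
        sigma_scale = float(max(dataset.sds.mean(), 1.0))
    a_prior = None
    if anchor_background:
        control = dataset.groups[0]
        a_prior = (control.mean, 2.0 * max(control.sd, 2.0))
    return Priors(
        bounds=bounds, sigma_scale=sigma_scale, response_cap=cap, a_prior=a_prior
    )
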