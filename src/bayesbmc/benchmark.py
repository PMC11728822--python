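"""Per-draw benchmark concentrations (BMC) and LC50/EC50 from posterior fits.

The BMC at benchmark response ``bmr`` is the smallest dose where the fitted
mean crosses the target response; with the default relative-change definition
the target is ``f(0) * (1 + bmr)``, i.e. a ``bmr``-fraction increase over the
model background.  The LC50/EC50 solves ``f(d) = 50`` on the absolute percent
scale.  Both are found by bisection on ``[0, search_upper_mult x max dose]``
(every model here is non-decreasing in dose under the positive-slope priors);
draws whose curve never reaches the target are recorded as undefined.

Closed-form inversions exist for all eight models and are exposed in
``closed_form_bmc`` / ``closed_form_response_dose`` — they serve as
independent cross-checks of the bisection path.

Posterior summaries report the median and the 5th/95th percentiles; for the
BMC these are the BMC/BMCL/BMCU triple (a two-sided 90% credible interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .inference import PosteriorFit
from .models import ModelSpec, ParameterVector

__all__ = [
    "BenchmarkConfig",
    "BenchmarkDraws",
    "DrawSummary",
    "benchmark_draws",
    "bmc_for_draw",
    "lc50_for_draw",
    "summarize_draws",
    "closed_form_bmc",
    "closed_form_response_dose",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Benchmark settings.

    ``bmr_type``: "relative" (target = f(0)*(1+bmr), default), "absolute"
    (target = f(0) + 100*bmr percent points) or "sd" (target = f(0) +
    bmr * residual SD, per draw).  ``response_level_for_lc50`` is the absolute
    percent response defining the LC50/EC50.  ``search_upper_mult`` bounds the
    bisection bracket as a multiple of the largest observed dose.
    """

    bmr: float = 0.10
    bmr_type: str = "relative"
    response_level_for_lc50: float = 50.0
    search_upper_mult: float = 10.0
    quantiles: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if not 0.0 < self.bmr < 1.0:
            raise ValueError("bmr must be in (0, 1)")
        if self.bmr_type not in ("relative", "absolute", "sd"):
            raise ValueError("bmr_type must be relative, absolute or sd")
        if not 0.0 < self.response_level_for_lc50 < 100.0:
            raise ValueError("response level must be in (0, 100)")
        if self.search_upper_mult <= 0:
            raise ValueError("search_upper_mult must be positive")


@dataclass(frozen=True)
class DrawSummary:
    median: float | None
    lower: float | None
    upper: float | None
    undefined_fraction: float
    n_defined: int


@dataclass
class BenchmarkDraws:
    """Per-draw BMC and LC50 values (mg/L) for one fitted model."""

    model_name: str
    bmc: np.ndarray
    lc50: np.ndarray
    config: BenchmarkConfig
    max_dose: float

    @property
    def bmc_summary(self) -> DrawSummary:
        return summarize_draws(self.bmc, self.config.quantiles)

    @property
    def lc50_summary(self) -> DrawSummary:
        return summarize_draws(self.lc50, self.config.quantiles)


# ---------------------------------------------------------------------------
# vectorized bisection
# ---------------------------------------------------------------------------

def _solve_dose(
    spec: ModelSpec,
    params: Mapping[str, np.ndarray],
    target: np.ndarray,
    upper: float,
    n_iter: int = 80,
) -> np.ndarray:
    """Smallest dose with f(dose) >= target, per draw; NaN when the curve
    stays below the target on [0, upper] or already exceeds it at dose 0."""
    from .models import _FORMULAS, mean_function

    target = np.asarray(target, dtype=float)
    f0 = np.asarray(mean_function(spec, params, 0.0), dtype=float)
    f_up = np.asarray(mean_function(spec, params, upper), dtype=float)
    f0, f_up, target = np.broadcast_arrays(f0, f_up, target)

    solvable = (f0 < target) & (f_up >= target)
    lo = np.zeros(target.shape)
    hi = np.full(target.shape, float(upper))
    u_scale = spec.dose_scale

    formula = _FORMULAS[spec.name]
    p = {k: np.asarray(v, dtype=float) for k, v in params.items()}
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            val = formula(p, mid / u_scale)
            above = val >= target
            hi = np.where(above, mid, hi)
            lo = np.where(above, lo, mid)
    out = 0.5 * (lo + hi)
    return np.where(solvable, out, np.nan)


def _bmr_target(config: BenchmarkConfig, f0: np.ndarray, sigma=None) -> np.ndarray:
    if config.bmr_type == "relative":
        return f0 * (1.0 + config.bmr)
    if config.bmr_type == "absolute":
        return f0 + 100.0 * config.bmr
    if sigma is None:
        raise ValueError("sd-type BMR needs per-draw sigma")
    return f0 + config.bmr * np.asarray(sigma, dtype=float)


def benchmark_draws(
    fit: PosteriorFit, config: BenchmarkConfig | None = None
) -> BenchmarkDraws:
    """Compute per-draw BMC and LC50 for a posterior fit."""
    config = config or BenchmarkConfig()
    max_dose = fit.spec.dose_scale
    upper = config.search_upper_mult * max_dose
    params = fit.params
    f0 = fit.params["a"] * np.ones_like(fit.sigma)
    target_bmc = _bmr_target(config, f0, fit.sigma)
    bmc = _solve_dose(fit.spec, params, target_bmc, upper)
    lc50 = _solve_dose(
        fit.spec, params, np.full_like(f0, config.response_level_for_lc50), upper
    )
    return BenchmarkDraws(fit.model_name, bmc, lc50, config, max_dose)


def bmc_for_draw(
    spec: ModelSpec,
    theta: ParameterVector,
    config: BenchmarkConfig | None = None,
    max_dose: float | None = None,
) -> float:
    """BMC (mg/L) for a single parameter draw; NaN when undefined."""
    config = config or BenchmarkConfig()
    max_dose = max_dose or spec.dose_scale
    params = {k: np.asarray([v], dtype=float) for k, v in theta.params.items()}
    f0 = params["a"]
    target = _bmr_target(config, f0, np.asarray([theta.sigma]))
    out = _solve_dose(spec, params, target, config.search_upper_mult * max_dose)
    return float(out[0])


def lc50_for_draw(
    spec: ModelSpec,
    theta: ParameterVector,
    config: BenchmarkConfig | None = None,
    max_dose: float | None = None,
) -> float:
    """Dose (mg/L) at the absolute 50% (or configured) response; NaN when the
    curve never reaches it inside the search bracket."""
    config = config or BenchmarkConfig()
    max_dose = max_dose or spec.dose_scale
    params = {k: np.asarray([v], dtype=float) for k, v in theta.params.items()}
    target = np.asarray([config.response_level_for_lc50])
    out = _solve_dose(spec, params, target, config.search_upper_mult * max_dose)
    return float(out[0])


def summarize_draws(
    values: np.ndarray, quantiles: tuple[float, float] = (0.05, 0.95)
) -> DrawSummary:
    """Median and outer quantiles over the defined (non-NaN) draws.

    Requires at least 100 defined draws; warns when more than 1% of draws are
    undefined.  Quantiles use linear interpolation between order statistics.
    """
    values = np.asarray(values, dtype=float)
    defined = values[np.isfinite(values)]
    frac_undef = 1.0 - defined.size / max(values.size, 1)
    if defined.size < 100:
        return DrawSummary(None, None, None, frac_undef, int(defined.size))
    if frac_undef > 0.01:
        warnings.warn(
            f"{100 * frac_undef:.1f}% of draws have no defined value inside "
            "the search bracket"
        )
    lo_q, hi_q = quantiles
    med, lo, hi = np.quantile(defined, [0.5, lo_q, hi_q])
    return DrawSummary(float(med), float(lo), float(hi), frac_undef, int(defined.size))


# ---------------------------------------------------------------------------
# closed forms (used as independent oracles for the bisection path)
# ---------------------------------------------------------------------------

def closed_form_bmc(
    spec: ModelSpec, theta: ParameterVector, bmr: float = 0.10
) -> float:
    """Analytic relative-change BMC (mg/L); NaN when undefined."""
    p = theta.params
    a, b = p["a"], p["b"]
    B = bmr
    s = spec.dose_scale
    name = spec.name
    try:
        if name == "linear":
            u = a * B / b
        elif name == "power":
            u = (a * B / b) ** (1.0 / p["g"])
        elif name == "exp2":
            u = np.log1p(B) / b
        elif name == "exp3":
            u = (np.log1p(B) / b) ** (1.0 / p["g"])
        elif name == "michaelis_menten":
            if b <= a * B:
                return float("nan")
            u = a * B * p["c"] / (b - a * B)
        elif name == "hill":
            if b <= a * B:
                return float("nan")
            u = p["c"] * (a * B / (b - a * B)) ** (1.0 / p["g"])
        elif name == "exp4":
            c = p["c"]
            if c - 1.0 <= B:
                return float("nan")
            u = -np.log((c - 1.0 - B) / (c - 1.0)) / b
        elif name == "exp5":
            c = p["c"]
            if c - 1.0 <= B:
                return float("nan")
            u = (-np.log((c - 1.0 - B) / (c - 1.0)) / b) ** (1.0 / p["g"])
        else:  # pragma: no cover
            raise ValueError(name)
    except (ZeroDivisionError, OverflowError):
        return float("nan")
    return float(u * s)


def closed_form_response_dose(
    spec: ModelSpec, theta: ParameterVector, level: float = 50.0
) -> float:
    """Analytic dose (mg/L) at an absolute percent response; NaN when the
    model cannot reach the level."""
    p = theta.params
    a, b = p["a"], p["b"]
    t = level
    s = spec.dose_scale
    name = spec.name
    if t <= a:
        return float("nan")
    try:
        if name == "linear":
            u = (t - a) / b
        elif name == "power":
            u = ((t - a) / b) ** (1.0 / p["g"])
        elif name == "exp2":
            u = np.log(t / a) / b
        elif name == "exp3":
            u = (np.log(t / a) / b) ** (1.0 / p["g"])
        elif name == "michaelis_menten":
            if a + b <= t:
                return float("nan")
            u = p["c"] * (t - a) / (a + b - t)
        elif name == "hill":
            if a + b <= t:
                return float("nan")
            u = p["c"] * ((t - a) / (a + b - t)) ** (1.0 / p["g"])
        elif name in ("exp4", "exp5"):
            c = p["c"]
            ratio = t / a
            if ratio >= c:
                return float("nan")
            inner = -np.log((c - ratio) / (c - 1.0)) / b
            u = inner if name == "exp4" else inner ** (1.0 / p["g"])
        else:  # pragma: no cover
            raise ValueError(name)
    except (ZeroDivisionError, OverflowError):
        return float("nan")
    return float(u * s)
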