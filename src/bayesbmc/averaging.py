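"""Fit-based model weights and model-averaged benchmark distributions.

Weights follow the pseudo-Bayesian-model-averaging construction: each model's
leave-one-group-out expected log predictive density (elpd) is exponentiated
after subtracting the best model's elpd and normalized, so better-predicting
models dominate.  Models failing the convergence/fit gates (Rhat > 1.05 or a
posterior predictive p-value outside 0.05-0.95) are excluded before
normalization.  The model-average BMC/LC50 distribution is a seeded mixture
resample: each mixture draw picks a model with probability equal to its
weight, then one of that model's defined draws uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .benchmark import BenchmarkDraws, DrawSummary, summarize_draws
from .inference import PosteriorFit

__all__ = [
    "AveragedResult",
    "compute_weights",
    "combine",
    "species_extrapolation",
]


@dataclass
class AveragedResult:
    """Model weights plus mixed BMC/LC50 draws and their summaries."""

    endpoint: str
    weights: dict[str, float]
    excluded: tuple[str, ...]
    bmc_mixture: np.ndarray
    lc50_mixture: np.ndarray
    model_median_lc50_mean: float | None

    @property
    def bmc_summary(self) -> DrawSummary:
        return summarize_draws(self.bmc_mixture)

    @property
    def lc50_summary(self) -> DrawSummary:
        return summarize_draws(self.lc50_mixture)


def compute_weights(
    fits: Sequence[PosteriorFit],
    scheme: str = "pseudo-bma",
    apply_gates: bool = True,
) -> tuple[dict[str, float], tuple[str, ...]]:
    """Per-model weights from predictive fit.

    ``scheme``: "pseudo-bma" uses LOO elpd, "waic" uses the WAIC elpd
    recomputed from the stored pointwise log-likelihoods.  Returns the weight
    mapping (summing to 1 over included models, 0 for excluded ones) and the
    names of models excluded by the diagnostics gates.
    """
    if not fits:
        raise ValueError("no fits supplied")
    if scheme not in ("pseudo-bma", "waic"):
        raise ValueError("scheme must be 'pseudo-bma' or 'waic'")

    excluded = []
    included = []
    for f in fits:
        if apply_gates and not f.passes_gates:
            warnings.warn(
                f"{f.model_name}: diagnostics gates failed "
                f"(max Rhat {f.max_rhat:.3f}, PPP {f.ppp:.3f}); "
                "excluded from averaging"
            )
            excluded.append(f.model_name)
        else:
            included.append(f)
    if not included:
        raise ValueError("every model failed the diagnostics gates")

    if scheme == "pseudo-bma" and all(f.loo.method == "psis-loo" for f in included):
        elpd = np.array([f.loo_elpd for f in included])
    else:
        from .inference import _waic

        if scheme == "pseudo-bma":
            warnings.warn(
                "one or more models fell back to WAIC; using WAIC elpd for "
                "all models so the weights compare like with like"
            )
        elpd = np.array([_waic(f.loglik_pointwise).elpd for f in included])

    log_w = elpd - logsumexp(elpd)
    w = np.exp(log_w)
    weights = {f.model_name: 0.0 for f in fits}
    weights.update({f.model_name: float(wi) for f, wi in zip(included, w)})
    return weights, tuple(excluded)


def combine(
    weights: Mapping[str, float],
    bench: Mapping[str, BenchmarkDraws],
    total_draws: int = 15_000,
    seed: int | np.random.SeedSequence = 0,
    endpoint: str = "endpoint",
) -> AveragedResult:
    """Resample a weighted mixture of per-model benchmark draws.

    Models with positive weight must have at least 100 defined BMC draws.
    The LC50 mixture is built the same way; if every positively weighted
    model has no defined LC50 draws the averaged LC50 is undefined (empty).
    """
    names = [n for n, w in weights.items() if w > 0.0]
    if not names:
        raise ValueError("all weights are zero")
    w = np.array([weights[n] for n in names], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("positive weights must sum to 1")

    for n in names:
        if np.isfinite(bench[n].bmc).sum() < 100:
            raise ValueError(f"{n}: fewer than 100 defined BMC draws")

    rng = np.random.default_rng(seed)
    choice = rng.choice(len(names), size=total_draws, p=w)

    def _mix(attr: str) -> np.ndarray:
        pools = {}
        for i, n in enumerate(names):
            v = getattr(bench[n], attr)
            pools[i] = v[np.isfinite(v)]
        out = np.empty(total_draws)
        out.fill(np.nan)
        for i in range(len(names)):
            mask = choice == i
            pool = pools[i]
            if pool.size == 0:
                continue
            out[mask] = pool[rng.integers(0, pool.size, size=int(mask.sum()))]
        return out[np.isfinite(out)]

    bmc_mix = _mix("bmc")
    lc50_mix = _mix("lc50")

    # mean of per-model LC50 medians, an alternative "Average" construction
    medians = [
        bench[n].lc50_summary.median
        for n in names
        if bench[n].lc50_summary.median is not None
    ]
    alt = float(np.mean(medians)) if medians else None

    return AveragedResult(
        endpoint=endpoint,
        weights=dict(weights),
        excluded=tuple(n for n, ww in weights.items() if ww == 0.0),
        bmc_mixture=bmc_mix,
        lc50_mixture=lc50_mix,
        model_median_lc50_mean=alt,
    )


def species_extrapolation(
    ufs_mammals: float,
    lc50_pairs: Sequence[tuple[float, float]],
    noael_humans: float,
) -> tuple[float, float]:
    """Cross-species uncertainty-factor conversion and guidance value.

    UFs_zebrafish = UFs_mammals / 10**mean(log10(LC50_zebrafish) /
    log10(LC50_mammal)) over the supplied pairs, and HBGV = NOAEL_humans /
    UFs_zebrafish.  Every LC50 must be positive and the mammalian LC50s must
    differ from 1 (log ratio defined).
    """
    if ufs_mammals <= 0:
        raise ValueError("ufs_mammals must be positive")
    if not lc50_pairs:
        raise ValueError("need at least one LC50 pair")
    ratios = []
    for z, m in lc50_pairs:
        if z <= 0 or m <= 0:
            raise ValueError("LC50 values must be positive")
        if np.log10(m) == 0.0:
            raise ValueError("mammalian LC50 of 1 gives an undefined log ratio")
        ratios.append(np.log10(z) / np.log10(m))
    ufs_zebrafish = ufs_mammals / 10.0 ** float(np.mean(ratios))
    hbgv = noael_humans / ufs_zebrafish
    return float(ufs_zebrafish), float(hbgv)
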