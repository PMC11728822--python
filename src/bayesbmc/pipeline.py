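"""End-to-end reproduction pipeline: summary table -> fits -> diagnostics ->
per-model and model-averaged LC50/EC50 and BMC/BMCL/BMCU tables -> NOAEL/LOAEL.

Seeding: each (endpoint, model) fit receives its own deterministic child of
the master seed via ``numpy.random.SeedSequence([master, endpoint_index,
model_index])``; the mixture resampler for an endpoint uses
``SeedSequence([master, endpoint_index, 10_000])``.  A completed run's
manifest (config + seeds + package version) reproduces every output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .averaging import AveragedResult, combine, compute_weights
from .benchmark import BenchmarkConfig, BenchmarkDraws, benchmark_draws
from .data import (
    DoseResponseDataset,
    NoaelLoaelResult,
    anova_lsd,
    loael_majority,
    read_summary_csv,
)
from .inference import McmcConfig, PosteriorFit, fit
from .models import MODEL_LABELS, MODEL_NAMES, default_priors, make_spec

__all__ = ["PipelineConfig", "EndpointResult", "RunResult", "run_endpoint", "run_all"]

log = logging.getLogger("bayesbmc")

MIXTURE_KEY = 10_000


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that determines a full run."""

    mcmc: McmcConfig = field(default_factory=McmcConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    models: tuple[str, ...] = MODEL_NAMES
    likelihood: str = "lognormal"
    weight_scheme: str = "pseudo-bma"
    apply_gates: bool = True
    mixture_draws: int = 15_000
    assumed_n_reps: int = 6
    alpha: float = 0.05

    @property
    def master_seed(self) -> int:
        return self.mcmc.seed


@dataclass
class EndpointResult:
    endpoint: str
    dataset: DoseResponseDataset
    fits: dict[str, PosteriorFit]
    bench: dict[str, BenchmarkDraws]
    averaged: AveragedResult
    noael: NoaelLoaelResult

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = []
        for name, f in self.fits.items():
            rows.append(
                {
                    "endpoint": self.endpoint,
                    "model": MODEL_LABELS[name],
                    "rhat": round(f.max_rhat, 3),
                    "ppp": round(f.ppp, 3),
                    "loo_elpd": round(f.loo_elpd, 2),
                    "loo_method": f.loo.method,
                    "accept_rate": round(f.accept_rate, 3),
                }
            )
        return pd.DataFrame(rows)

    def lc50_frame(self) -> pd.DataFrame:
        """Per-model and model-averaged LC50/EC50 (median, 5th, 95th)."""
        rows = []
        for name, f in self.fits.items():
            s = self.bench[name].lc50_summary
            rows.append(
                {
                    "endpoint": self.endpoint,
                    "model": MODEL_LABELS[name],
                    "rhat": round(f.max_rhat, 3),
                    "ppp": round(f.ppp, 3),
                    "lc50": _r(s.median),
                    "lc50_p5": _r(s.lower),
                    "lc50_p95": _r(s.upper),
                }
            )
        s = self.averaged.lc50_summary
        rows.append(
            {
                "endpoint": self.endpoint,
                "model": "Model average",
                "rhat": None,
                "ppp": None,
                "lc50": _r(s.median),
                "lc50_p5": _r(s.lower),
                "lc50_p95": _r(s.upper),
            }
        )
        return pd.DataFrame(rows)

    def bmc_frame(self) -> pd.DataFrame:
        """Per-model and model-averaged weights and BMC/BMCL/BMCU."""
        rows = []
        s = self.averaged.bmc_summary
        rows.append(
            {
                "endpoint": self.endpoint,
                "model": "Model average",
                "weight_pct": None,
                "bmc": _r(s.median),
                "bmcl": _r(s.lower),
                "bmcu": _r(s.upper),
            }
        )
        for name in self.fits:
            s = self.bench[name].bmc_summary
            rows.append(
                {
                    "endpoint": self.endpoint,
                    "model": MODEL_LABELS[name],
                    "weight_pct": round(100.0 * self.averaged.weights[name], 2),
                    "bmc": _r(s.median),
                    "bmcl": _r(s.lower),
                    "bmcu": _r(s.upper),
                }
            )
        return pd.DataFrame(rows)


def _r(x, nd=2):
    return None if x is None else round(float(x), nd)


@dataclass
class RunResult:
    config: PipelineConfig
    endpoints: dict[str, EndpointResult]
    skipped: dict[str, str]

    @property
    def loael_majority_call(self) -> float | None:
        return loael_majority(r.noael for r in self.endpoints.values())

    def lc50_table(self) -> pd.DataFrame:
        return pd.concat(
            [r.lc50_frame() for r in self.endpoints.values()], ignore_index=True
        )

    def bmc_table(self) -> pd.DataFrame:
        return pd.concat(
            [r.bmc_frame() for r in self.endpoints.values()], ignore_index=True
        )

    def diagnostics_table(self) -> pd.DataFrame:
        return pd.concat(
            [r.diagnostics_frame() for r in self.endpoints.values()],
            ignore_index=True,
        )

    def noael_table(self) -> pd.DataFrame:
        rows = [r.noael.to_dict() for r in self.endpoints.values()]
        df = pd.DataFrame(rows)
        return df[["endpoint", "loael_mg_L", "noael_mg_L", "anova_F", "anova_p",
                   "monotone_flag_pattern"]]

    def manifest(self) -> dict:
        return {
            "package": "bayesbmc",
            "version": __version__,
            "config": {
                "mcmc": asdict(self.config.mcmc),
                "benchmark": asdict(self.config.benchmark),
                "models": list(self.config.models),
                "likelihood": self.config.likelihood,
                "weight_scheme": self.config.weight_scheme,
                "apply_gates": self.config.apply_gates,
                "mixture_draws": self.config.mixture_draws,
                "assumed_n_reps": self.config.assumed_n_reps,
                "alpha": self.config.alpha,
            },
            "seed_scheme": (
                "fit: SeedSequence([master, endpoint_index, model_index]); "
                f"mixture: SeedSequence([master, endpoint_index, {MIXTURE_KEY}])"
            ),
            "endpoints": list(self.endpoints),
            "skipped": self.skipped,
        }


def run_endpoint(
    dataset: DoseResponseDataset,
    config: PipelineConfig | None = None,
    endpoint_index: int = 0,
) -> EndpointResult:
    """Fit all configured models to one endpoint and average them."""
    config = config or PipelineConfig()
    master = config.master_seed
    fits: dict[str, PosteriorFit] = {}
    bench: dict[str, BenchmarkDraws] = {}
    for j, name in enumerate(config.models):
        spec = make_spec(name, dataset.max_dose)
        priors = default_priors(spec, dataset, likelihood=config.likelihood)
        ss = np.random.SeedSequence([master, endpoint_index, j])
        log.info("fitting %s on %s", name, dataset.endpoint)
        f = fit(
            spec, dataset, config.mcmc, priors, seed_sequence=ss,
            likelihood=config.likelihood,
        )
        fits[name] = f
        bench[name] = benchmark_draws(f, config.benchmark)

    weights, excluded = compute_weights(
        list(fits.values()), scheme=config.weight_scheme,
        apply_gates=config.apply_gates,
    )
    averaged = combine(
        weights,
        bench,
        total_draws=config.mixture_draws,
        seed=np.random.SeedSequence([master, endpoint_index, MIXTURE_KEY]),
        endpoint=dataset.endpoint,
    )
    noael = anova_lsd(dataset, alpha=config.alpha)
    return EndpointResult(dataset.endpoint, dataset, fits, bench, averaged, noael)


def run_all(
    datasets: Mapping[str, DoseResponseDataset] | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    save_draws: bool = False,
) -> RunResult:
    """Run the full analysis over every endpoint in ``datasets``.

    ``datasets`` may be a mapping of endpoint -> dataset or a path to a
    summary CSV.  Endpoints whose responses are all identical are skipped
    with a logged reason.  When ``out_dir`` is given, the LC50, BMC,
    diagnostics and NOAEL tables plus a JSON manifest (and per-model draws
    CSVs when ``save_draws``) are written there.
    """
    config = config or PipelineConfig()
    if isinstance(datasets, (str, Path)):
        datasets = read_summary_csv(datasets)
        datasets = {
            k: v.with_n_reps(config.assumed_n_reps) for k, v in datasets.items()
        }

    results: dict[str, EndpointResult] = {}
    skipped: dict[str, str] = {}
    for i, (name, ds) in enumerate(datasets.items()):
        if np.ptp(ds.means) == 0.0:
            skipped[name] = "all group means identical; no dose-response signal"
            log.warning("skipping %s: %s", name, skipped[name])
            continue
        results[name] = run_endpoint(ds, config, endpoint_index=i)

    run = RunResult(config, results, skipped)
    if out_dir is not None:
        _write_outputs(run, Path(out_dir), save_draws)
    return run


def _write_outputs(run: RunResult, out_dir: Path, save_draws: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    run.lc50_table().to_csv(out_dir / "lc50_table.csv", index=False)
    run.bmc_table().to_csv(out_dir / "bmc_table.csv", index=False)
    run.diagnostics_table().to_csv(out_dir / "diagnostics.csv", index=False)
    run.noael_table().to_csv(out_dir / "noael_loael.csv", index=False)
    manifest = run.manifest()
    manifest["loael_majority_mg_L"] = run.loael_majority_call
    tables = {
        "lc50": run.lc50_table().to_dict(orient="records"),
        "bmc": run.bmc_table().to_dict(orient="records"),
        "noael_loael": [r.noael.to_dict() for r in run.endpoints.values()],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "tables.json").write_text(json.dumps(tables, indent=2))
    if save_draws:
        draws_dir = out_dir / "draws"
        draws_dir.mkdir(exist_ok=True)
        for name, r in run.endpoints.items():
            for model, f in r.fits.items():
                df = f.draws_frame()
                df["bmc"] = r.bench[model].bmc
                df["lc50"] = r.bench[model].lc50
                df.to_csv(draws_dir / f"{name}_{model}.csv", index=False)
    log.info("wrote outputs to %s", out_dir)
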