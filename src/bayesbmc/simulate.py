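"""Synthetic dose-response data with the structure the analysis assumes.

Two generators are provided.  ``simulate_summary`` draws per-replicate
percent responses as Normal(f(dose), sigma) truncated to [0, 100] and
collapses them to (n, mean, sd) summaries — the shape of the bundled
fluoride mortality table (14 dose groups from 0 to 300 mg/L, monotone trend,
saturation at 100%).  ``simulate_wells`` instead simulates well-level counts:
per-replicate deaths are Binomial(n_embryos, f(dose)/100 clamped to [0, 1]),
spread over days 1-5 with a severity-dependent death-day distribution, plus
hatching and malformation counts among survivors.

Both are bit-reproducible given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import (
    FLUORIDE_DOSES_MG_L,
    DoseResponseDataset,
    DoseGroupSummary,
    WellCounts,
)
from .models import ModelSpec, ParameterVector, evaluate

__all__ = ["SimulationDesign", "simulate_summary", "simulate_wells"]


@dataclass(frozen=True)
class SimulationDesign:
    """True model + noise + sampling layout for one synthetic endpoint.

    Defaults mirror the fluoride study: the 14-level dose ladder from 0 to
    300 mg/L, 6 replicates per dose (three experiments x two plates) and 40
    embryos per replicate group in well-level mode.
    """

    spec: ModelSpec
    theta: ParameterVector
    doses: tuple[float, ...] = FLUORIDE_DOSES_MG_L
    n_reps: int = 6
    sigma: float = 3.0
    seed: int = 0
    n_embryos: int = 40
    hatch_prob: float = 0.95
    endpoint: str = "synthetic"

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if 0.0 not in self.doses:
            raise ValueError("the dose ladder must include the control (0)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")


def simulate_summary(design: SimulationDesign) -> DoseResponseDataset:
    """Summary-format synthetic dataset (percent means +/- sample SDs)."""
    rng = np.random.default_rng(design.seed)
    groups = []
    for dose in sorted(design.doses):
        f = float(evaluate(design.spec, design.theta, float(dose)))
        reps = f + design.sigma * rng.standard_normal(design.n_reps)
        reps = np.clip(reps, 0.0, 100.0)
        sd = float(np.std(reps, ddof=1)) if design.n_reps > 1 else 0.0
        groups.append(
            DoseGroupSummary(float(dose), design.n_reps, float(np.mean(reps)), sd)
        )
    return DoseResponseDataset(design.endpoint, tuple(groups))


def _death_day_probs(p5: float) -> np.ndarray:
    """Distribution of the death day (1..5) given an embryo dies by 5 dpf.

    Geometric-type weights (1-p5)**(k-1): mild exposures spread deaths across
    days, while at p5 = 1 every death lands on day 1 (an immediately lethal
    dose kills immediately).
    """
    w = (1.0 - p5) ** np.arange(5)
    if w.sum() == 0.0:  # p5 == 1
        w = np.array([1.0, 0, 0, 0, 0])
    return w / w.sum()


def simulate_wells(design: SimulationDesign) -> list[WellCounts]:
    """Well-level synthetic counts for the mortality + malformation endpoints.

    The true curve supplies both the 5 dpf death probability and the
    malformation probability among hatched survivors (clamped to [0, 1]).
    """
    rng = np.random.default_rng(design.seed)
    wells: list[WellCounts] = []
    for dose in sorted(design.doses):
        f = float(evaluate(design.spec, design.theta, float(dose)))
        p5 = min(max(f / 100.0, 0.0), 1.0)
        day_probs = _death_day_probs(p5)
        for rep in range(design.n_reps):
            n_dead = int(rng.binomial(design.n_embryos, p5))
            days = rng.choice(5, size=n_dead, p=day_probs)
            cumulative = tuple(
                int(np.sum(days <= k)) for k in range(5)
            )
            survivors = design.n_embryos - n_dead
            n_hatched = int(rng.binomial(survivors, design.hatch_prob))
            n_malformed = int(rng.binomial(n_hatched, p5))
            wells.append(
                WellCounts(
                    dose=float(dose),
                    replicate_id=f"d{dose:g}_r{rep + 1}",
                    n_embryos=design.n_embryos,
                    n_dead_by_day=cumulative,
                    n_hatched=n_hatched,
                    n_malformed=n_malformed,
                )
            )
    return wells
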