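"""Dose-response data containers, toxicity endpoints and NOAEL/LOAEL calls.

Summary data are percent responses (0-100) per dose group: replicate count
``n``, mean and sample SD.  Endpoints supported are cumulative mortality (CM)
at 1-5 days post-fertilization and the cumulative malformation rate (CMA,
malformed / hatched) at 5 dpf, both computed from well-level counts.

NOAEL/LOAEL calls use Fisher's least-significant-difference test after a
one-way ANOVA, run directly on the per-group sufficient statistics
``(n, mean, sd)`` so that summary tables without raw replicates can be
analysed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WellCounts",
    "DoseGroupSummary",
    "DoseResponseDataset",
    "NoaelLoaelResult",
    "compute_cm",
    "compute_cma",
    "summarize_groups",
    "anova_lsd",
    "loael_majority",
    "read_summary_csv",
    "read_replicate_csv",
    "load_fluoride_table",
    "FLUORIDE_DOSES_MG_L",
    "ENDPOINTS",
]

#: Dose ladder used in the fluoride zebrafish study (mg/L), control first.
FLUORIDE_DOSES_MG_L = (
    0.0, 0.5, 1.0, 4.0, 10.0, 20.0, 50.0, 80.0, 100.0, 120.0, 150.0, 200.0,
    250.0, 300.0,
)

#: Canonical endpoint labels, in reporting order.
ENDPOINTS = ("cm_1dpf", "cm_2dpf", "cm_3dpf", "cm_4dpf", "cm_5dpf", "cma_5dpf")

_FIXTURE = "table3_fluoride_zebrafish.csv"


@dataclass(frozen=True)
class WellCounts:
    """Raw counts for one replicate (one plate) at one dose.

    ``n_dead_by_day`` holds cumulative dead counts for 1..5 dpf and must be
    non-decreasing; malformations are cumulative to 5 dpf and counted among
    hatched larvae only.
    """

    dose: float
    replicate_id: str
    n_embryos: int
    n_dead_by_day: tuple[int, int, int, int, int]
    n_hatched: int
    n_malformed: int

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.n_embryos <= 0:
            raise ValueError("n_embryos must be positive")
        if len(self.n_dead_by_day) != 5:
            raise ValueError("n_dead_by_day must cover days 1..5")
        d = self.n_dead_by_day
        if any(x < 0 or x > self.n_embryos for x in d):
            raise ValueError("daily dead counts must lie in [0, n_embryos]")
        if any(d[k + 1] < d[k] for k in range(4)):
            raise ValueError("cumulative dead counts must be non-decreasing")
        if not (0 <= self.n_malformed <= self.n_hatched <= self.n_embryos):
            raise ValueError("need 0 <= n_malformed <= n_hatched <= n_embryos")


@dataclass(frozen=True)
class DoseGroupSummary:
    """Summary statistics for one dose group: percent response mean +/- SD."""

    dose: float
    n_reps: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 <= self.mean <= 100.0:
            raise ValueError("mean response must lie in [0, 100] percent")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class DoseResponseDataset:
    """One endpoint's dose-response summary table, control group first."""

    endpoint: str
    groups: tuple[DoseGroupSummary, ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 3:
            raise ValueError("need at least 3 dose groups")
        doses = [g.dose for g in self.groups]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if doses[0] != 0.0:
            raise ValueError("the first group must be the dose-0 control")

    @property
    def doses(self) -> np.ndarray:
        return np.array([g.dose for g in self.groups])

    @property
    def n_reps(self) -> np.ndarray:
        return np.array([g.n_reps for g in self.groups])

    @property
    def means(self) -> np.ndarray:
        return np.array([g.mean for g in self.groups])

    @property
    def sds(self) -> np.ndarray:
        return np.array([g.sd for g in self.groups])

    @property
    def max_dose(self) -> float:
        return float(self.groups[-1].dose)

    def with_n_reps(self, n: int) -> "DoseResponseDataset":
        """Return a copy with every group's replicate count set to ``n``."""
        return DoseResponseDataset(
            self.endpoint,
            tuple(DoseGroupSummary(g.dose, n, g.mean, g.sd) for g in self.groups),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "endpoint": self.endpoint,
                "dose_mg_L": self.doses,
                "n": self.n_reps,
                "mean_pct": self.means,
                "sd_pct": self.sds,
            }
        )


@dataclass(frozen=True)
class NoaelLoaelResult:
    """Per-dose significance flags vs control and the derived NOAEL/LOAEL.

    ``loael`` is the smallest dose whose mean is significantly above the
    control mean (two-sided LSD p < alpha, adverse direction); ``noael`` is
    the largest dose below the LOAEL.  Either may be None (no significant
    dose, or no dose below the LOAEL).  ``monotone`` is False when a
    non-significant dose sits above the LOAEL.
    """

    endpoint: str
    doses: tuple[float, ...]
    p_values: tuple[float, ...]
    significant: tuple[bool, ...]
    loael: float | None
    noael: float | None
    monotone: bool
    anova_f: float
    anova_p: float

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "loael_mg_L": self.loael,
            "noael_mg_L": self.noael,
            "monotone_flag_pattern": self.monotone,
            "anova_F": self.anova_f,
            "anova_p": self.anova_p,
            "doses_mg_L": list(self.doses),
            "lsd_p_values": list(self.p_values),
            "significant": list(self.significant),
        }


# ---------------------------------------------------------------------------
# endpoint computation from well-level counts
# ---------------------------------------------------------------------------

def compute_cm(wells: Sequence[WellCounts], day: int) -> np.ndarray:
    """Per-replicate cumulative mortality (%) at ``day`` (1..5 dpf)."""
    if not wells:
        raise ValueError("no replicates supplied")
    if not 1 <= day <= 5:
        raise ValueError("day must be in 1..5")
    return np.array(
        [100.0 * w.n_dead_by_day[day - 1] / w.n_embryos for w in wells]
    )


def compute_cma(wells: Sequence[WellCounts]) -> np.ndarray:
    """Per-replicate cumulative malformation rate (%) at 5 dpf.

    Replicates with zero hatched larvae have an undefined rate and are
    excluded with a warning; if every replicate has zero hatched the endpoint
    is undefined and a ValueError is raised.
    """
    if not wells:
        raise ValueError("no replicates supplied")
    out = []
    n_excluded = 0
    for w in wells:
        if w.n_hatched == 0:
            n_excluded += 1
            continue
        out.append(100.0 * w.n_malformed / w.n_hatched)
    if not out:
        raise ValueError("all replicates have zero hatched larvae; CMA undefined")
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} replicate(s) with zero hatched larvae "
            "from the malformation rate"
        )
    return np.array(out)


def summarize_groups(
    responses_by_dose: Mapping[float, Sequence[float]], endpoint: str = "endpoint"
) -> DoseResponseDataset:
    """Collapse per-replicate percent responses into a summary dataset.

    SD uses the n-1 denominator; a single-replicate group gets sd = 0 with a
    warning.
    """
    groups = []
    for dose in sorted(responses_by_dose):
        r = np.asarray(responses_by_dose[dose], dtype=float)
        if r.size == 0:
            raise ValueError(f"dose {dose} has no replicates")
        if r.size == 1:
            warnings.warn(f"dose {dose} has a single replicate; sd set to 0")
            sd = 0.0
        else:
            sd = float(np.std(r, ddof=1))
        groups.append(DoseGroupSummary(float(dose), int(r.size), float(np.mean(r)), sd))
    return DoseResponseDataset(endpoint, tuple(groups))


# ---------------------------------------------------------------------------
# ANOVA + LSD on sufficient statistics
# ---------------------------------------------------------------------------

def anova_lsd(
    dataset: DoseResponseDataset, alpha: float = 0.05
) -> NoaelLoaelResult:
    """One-way ANOVA and per-dose LSD comparisons vs control.

    Works on the group sufficient statistics (n, mean, sd), which reproduces
    the raw-replicate ANOVA exactly.  Each treated dose is compared with the
    control via a two-sided t-test using the pooled mean squared error and the
    ANOVA error degrees of freedom; a dose is flagged adverse when p < alpha
    and its mean exceeds the control mean.
    """
    n = dataset.n_reps.astype(float)
    m = dataset.means
    s = dataset.sds
    if len(m) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(n < 2):
        raise ValueError("every group needs n_reps >= 2 for the ANOVA")

    N = n.sum()
    k = len(m)
    grand = float(np.sum(n * m) / N)
    ss_between = float(np.sum(n * (m - grand) ** 2))
    ss_within = float(np.sum((n - 1) * s**2))
    df_b, df_w = k - 1, int(N - k)
    mse = ss_within / df_w

    doses = tuple(float(d) for d in dataset.doses)
    if mse == 0.0:
        warnings.warn("pooled MSE is zero (all groups constant); no test run")
        pvals = tuple(1.0 for _ in doses[1:])
        flags = tuple(False for _ in doses[1:])
        return NoaelLoaelResult(
            dataset.endpoint, doses[1:], pvals, flags, None, doses[-1], True,
            float("nan"), float("nan"),
        )

    f_stat = (ss_between / df_b) / mse
    anova_p = float(stats.f.sf(f_stat, df_b, df_w))

    pvals, flags = [], []
    for i in range(1, k):
        se = np.sqrt(mse * (1.0 / n[0] + 1.0 / n[i]))
        t = (m[i] - m[0]) / se
        p = float(2.0 * stats.t.sf(abs(t), df_w))
        adverse = (p < alpha) and (m[i] > m[0])
        pvals.append(p)
        flags.append(bool(adverse))

    loael = noael = None
    sig_doses = [d for d, f in zip(doses[1:], flags) if f]
    if sig_doses:
        loael = min(sig_doses)
        below = [d for d in doses[1:] if d < loael]
        noael = max(below) if below else None
    else:
        noael = doses[-1]

    monotone = True
    if loael is not None:
        above = [f for d, f in zip(doses[1:], flags) if d > loael]
        if not all(above):
            monotone = False
            warnings.warn(
                f"{dataset.endpoint}: non-significant dose above the LOAEL "
                f"({loael} mg/L); flag pattern is non-monotone"
            )

    return NoaelLoaelResult(
        dataset.endpoint, doses[1:], tuple(pvals), tuple(flags), loael, noael,
        monotone, float(f_stat), anova_p,
    )


def loael_majority(results: Iterable[NoaelLoaelResult]) -> float | None:
    """The modal LOAEL across endpoints (the 'majority of indicators' call).

    Returns the dose called LOAEL by the largest number of endpoints, or None
    if no endpoint produced a LOAEL.  Ties go to the lower dose.
    """
    calls = [r.loael for r in results if r.loael is not None]
    if not calls:
        return None
    values, counts = np.unique(np.array(calls), return_counts=True)
    return float(values[np.lexsort((values, -counts))][0])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _dataset_from_summary_frame(df: pd.DataFrame) -> dict[str, DoseResponseDataset]:
    required = {"endpoint", "dose_mg_L", "n", "mean_pct", "sd_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary CSV is missing columns: {sorted(missing)}")
    out = {}
    for endpoint, sub in df.groupby("endpoint", sort=False):
        sub = sub.sort_values("dose_mg_L")
        groups = tuple(
            DoseGroupSummary(
                float(r.dose_mg_L), int(r.n), float(r.mean_pct), float(r.sd_pct)
            )
            for r in sub.itertuples()
        )
        out[str(endpoint)] = DoseResponseDataset(str(endpoint), groups)
    return out


def read_summary_csv(path) -> dict[str, DoseResponseDataset]:
    """Read a long-format summary CSV (endpoint, dose_mg_L, n, mean_pct, sd_pct)."""
    return _dataset_from_summary_frame(pd.read_csv(path))


def read_replicate_csv(path) -> dict[str, DoseResponseDataset]:
    """Read replicate-level CSV (endpoint, dose_mg_L, replicate, response_pct)."""
    df = pd.read_csv(path)
    required = {"endpoint", "dose_mg_L", "replicate", "response_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"replicate CSV is missing columns: {sorted(missing)}")
    out = {}
    for endpoint, sub in df.groupby("endpoint", sort=False):
        by_dose = {
            float(d): g["response_pct"].to_numpy()
            for d, g in sub.groupby("dose_mg_L")
        }
        out[str(endpoint)] = summarize_groups(by_dose, endpoint=str(endpoint))
    return out


def load_fluoride_table(n_reps: int | None = 6) -> dict[str, DoseResponseDataset]:
    """Load the bundled fluoride zebrafish summary table (six endpoints).

    The source table reports mean +/- SD per dose without the replicate count;
    ``n_reps`` sets the assumed per-group n (default 6, i.e. three independent
    experiments times two plates).  Pass None to keep the placeholder n from
    the file.
    """
    ref = resources.files("bayesbmc").joinpath("datafiles", _FIXTURE)
    with resources.as_file(ref) as p:
        datasets = read_summary_csv(p)
    if n_reps is not None:
        datasets = {k: v.with_n_reps(n_reps) for k, v in datasets.items()}
    return datasets
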