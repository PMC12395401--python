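"""Model checking: posterior predictive density overlap, convergence
reporting, and sensitivity analyses.

The posterior predictive check mirrors a kernel-density overlay of the
observed stature distribution against replicate datasets simulated from
the fitted model, summarised by the overlap coefficient
``integral of min(f_obs, f_rep)`` (1 = identical densities, 0 = disjoint).
The bandwidth is Silverman's rule computed on the observed sample and
shared with every replicate, so overlap differences reflect the data, not
bandwidth adaptation.

The measurement-count sensitivity analysis refits the model on subsets of
subjects with at least m measurements and reports how the population
landmarks move; the prior sweep refits with all prior scales multiplied by
a factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ContractError, DegenerateDistributionError
from .fit import SamplerConfig, SitarFit, fit_map, sample_posterior, _convergence_table
from .landmarks import population_landmarks
from .model import PriorConfig

__all__ = [
    "PPCResult",
    "SensitivityResult",
    "ppc_density_overlap",
    "convergence_report",
    "sensitivity_by_min_measurements",
    "prior_sensitivity_sweep",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# posterior predictive density overlap


def _silverman_bandwidth(sample: np.ndarray) -> float:
    n = sample.size
    sd = sample.std(ddof=1)
    iqr = np.subtract(*np.percentile(sample, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def _kde(sample: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """Gaussian kernel density on a fixed grid with fixed bandwidth."""
    dens = np.zeros_like(grid)
    norm = 1.0 / (sample.size * h * np.sqrt(2.0 * np.pi))
    for start in range(0, sample.size, 20000):  # chunked: bounded memory
        chunk = sample[start : start + 20000]
        z = (grid[:, None] - chunk[None, :]) / h
        dens += np.exp(-0.5 * z * z).sum(axis=1)
    dens *= norm
    area = np.trapezoid(dens, grid)
    return dens / area


@dataclass
class PPCResult:
    """Density-overlap summary of a posterior predictive check."""

    overlap: float
    per_replicate: np.ndarray
    grid: np.ndarray
    f_obs: np.ndarray
    f_rep: np.ndarray  # (n_replicates, grid)
    bandwidth: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.grid,
                "f_obs": self.f_obs,
                "f_rep_mean": self.f_rep.mean(axis=0),
                "f_rep_low": np.percentile(self.f_rep, 16, axis=0),
                "f_rep_high": np.percentile(self.f_rep, 84, axis=0),
            }
        )


def ppc_density_overlap(observed, replicates, n_grid: int = 512) -> PPCResult:
    """Overlap coefficient between observed and replicate stature densities.

    ``replicates`` is an iterable of 1-d samples (or DataFrames with a
    ``stature_cm`` column).  Per replicate the overlap is the integral of
    the pointwise minimum of the two kernel density estimates; the summary
    is the mean across replicates.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    reps = [
        np.asarray(r["stature_cm"] if isinstance(r, pd.DataFrame) else r, dtype=float).ravel()
        for r in replicates
    ]
    if len(reps) < 1:
        raise ContractError("at least one replicate is required")
    if observed.size < 30:
        raise ContractError(f"need >= 30 observed values, got {observed.size}")
    if np.ptp(observed) == 0:
        raise DegenerateDistributionError("observed sample is constant")
    for i, r in enumerate(reps):
        if np.ptp(r) == 0:
            raise DegenerateDistributionError(f"replicate {i} is constant")
    h = _silverman_bandwidth(observed)
    lo = min(observed.min(), min(r.min() for r in reps)) - 3 * h
    hi = max(observed.max(), max(r.max() for r in reps)) + 3 * h
    grid = np.linspace(lo, hi, n_grid)
    f_obs = _kde(observed, grid, h)
    f_rep = np.array([_kde(r, grid, h) for r in reps])
    per = np.array([np.trapezoid(np.minimum(f_obs, fr), grid) for fr in f_rep])
    return PPCResult(
        overlap=float(per.mean()),
        per_replicate=per,
        grid=grid,
        f_obs=f_obs,
        f_rep=f_rep,
        bandwidth=h,
    )


# ---------------------------------------------------------------------------
# convergence


def convergence_report(
    fit: SitarFit, rhat_threshold: float = 1.01, ess_threshold: float = 400.0
) -> pd.DataFrame:
    """Split R-hat and bulk ESS per population parameter with flags.

    Single-chain fits get R-hat/ESS marked unavailable (NaN) rather than
    an error.
    """
    table = fit.convergence if fit.convergence is not None else _convergence_table(fit)
    table = table.copy()
    table["flag"] = (table["rhat"] > rhat_threshold) | (table["ess_bulk"] < ess_threshold)
    table.loc[table["rhat"].isna(), "flag"] = False
    return table


# ---------------------------------------------------------------------------
# sensitivity analyses


@dataclass
class SensitivityResult:
    """Landmark estimates per minimum-measurement threshold."""

    table: pd.DataFrame  # threshold, n_subjects, atgv, tgv, aphv, phv
    dispersion: dict[str, float] = field(default_factory=dict)


def sensitivity_by_min_measurements(
    cohort: Cohort,
    thresholds=(4, 5, 6, 7, 8, 9, 10, 11),
    df: int = 5,
    prior: PriorConfig | None = None,
    method: str = "map",
    sampler: SamplerConfig | None = None,
    min_subjects: int = 10,
    search_window=None,
) -> SensitivityResult:
    """Refit on subjects with at least m measurements, for each m.

    Thresholds whose sub-cohort has fewer than ``min_subjects`` subjects
    are skipped with a log entry; all thresholds skipped is an error.  The
    dispersion summary is the SD across thresholds of each landmark's
    point estimate.
    """
    if not len(tuple(thresholds)):
        raise ContractError("thresholds must be non-empty")
    counts = cohort.counts_per_subject()
    rows = []
    for m in thresholds:
        ids = counts.index[counts >= int(m)]
        sub = Cohort(cohort.data[cohort.data["id"].isin(ids)])
        if sub.n_subjects < min_subjects:
            log.info("threshold %d skipped: only %d subjects", m, sub.n_subjects)
            continue
        if method == "map":
            fit = fit_map(sub, df=df, prior=prior)
        elif method == "mcmc":
            fit = sample_posterior(sub, df=df, prior=prior, sampler=sampler)
        else:
            raise ContractError(f"unknown method {method!r}")
        marks = population_landmarks(fit, search_window=search_window)
        rows.append(
            {
                "threshold": int(m),
                "n_subjects": sub.n_subjects,
                "atgv": marks.atgv[0],
                "tgv": marks.tgv[0],
                "aphv": marks.aphv[0],
                "phv": marks.phv[0],
            }
        )
    if not rows:
        raise ContractError("every threshold was skipped (too few subjects)")
    table = pd.DataFrame(rows).sort_values("threshold").reset_index(drop=True)
    if not table["n_subjects"].is_monotonic_decreasing:
        raise ContractError("subject counts must be non-increasing in the threshold")
    dispersion = {
        name: float(table[name].std(ddof=1)) if len(table) > 1 else 0.0
        for name in ("atgv", "tgv", "aphv", "phv")
    }
    return SensitivityResult(table=table, dispersion=dispersion)


def prior_sensitivity_sweep(
    cohort: Cohort,
    prior_scalings=(0.5, 1.0, 2.0),
    df: int = 5,
    prior: PriorConfig | None = None,
    search_window=None,
) -> pd.DataFrame:
    """Landmark estimates under rescaled prior scales.

    Refits (MAP) with every prior scale hyperparameter multiplied by each
    factor and reports shifts relative to factor 1.0 (fitted even if not
    requested).
    """
    factors = sorted(set(float(f) for f in prior_scalings) | {1.0})
    if min(factors) <= 0:
        raise ContractError("prior scale factors must be positive")
    base_prior = prior or PriorConfig.from_cohort(cohort)
    rows = {}
    for f in factors:
        fit = fit_map(cohort, df=df, prior=base_prior.scaled(f))
        marks = population_landmarks(fit, search_window=search_window)
        rows[f] = {
            "factor": f,
            "atgv": marks.atgv[0],
            "tgv": marks.tgv[0],
            "aphv": marks.aphv[0],
            "phv": marks.phv[0],
        }
    table = pd.DataFrame([rows[f] for f in factors])
    for name in ("atgv", "tgv", "aphv", "phv"):
        table[f"delta_{name}"] = table[name] - rows[1.0][name]
    return table
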