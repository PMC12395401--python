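"""The SITAR model: parameters, age transform, likelihood and priors.

The model for stature ``y_ij`` of subject ``i`` at age ``x_ij`` is

    y_ij = (a0 + a_i) + sum_k beta_k h_k(u_ij) + eps_ij,
    u_ij = (x_ij - x_bar - (z0 + z_i)) * exp(-(g0 + g_i)),
    eps_ij ~ Normal(0, sigma^2),

where ``h_k`` are natural cubic spline columns (:mod:`sitarbayes.basis`),
``a`` is size (cm, vertical shift), ``z`` is timing (years, horizontal
shift) and ``g`` is intensity (log age-scale: larger ``g`` stretches the
age axis and slows growth, velocity scales by ``exp(-g)``).  Individual
effects ``(a_i, z_i, g_i)`` are zero-mean trivariate normal with
sex-specific SDs and correlation.

Priors are weakly regularising and scaled to the data (SD of stature and
of age); concrete defaults live in :class:`PriorConfig` and are
config-overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .cohort import Cohort
from .errors import ContractError

__all__ = [
    "PopulationParameters",
    "RandomEffectDistribution",
    "IndividualEffects",
    "PriorConfig",
    "transform_age",
    "predict_height",
    "log_likelihood",
    "log_prior",
    "log_prior_terms",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PopulationParameters:
    """Population-level SITAR parameters."""

    alpha0: float  # size intercept, cm
    beta: np.ndarray  # K spline coefficients, cm
    zeta0: float  # timing, years
    gamma0: float  # log intensity, dimensionless
    sigma: float  # residual SD, cm

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        vals = [self.alpha0, self.zeta0, self.gamma0, self.sigma, *self.beta]
        if not np.all(np.isfinite(vals)):
            raise ContractError("population parameters must be finite")
        # sigma <= 0 is outside the model's domain; it is representable so
        # that the prior can answer with -inf instead of an exception.


@dataclass(frozen=True)
class RandomEffectDistribution:
    """Zero-mean trivariate normal over (size, timing, intensity) effects."""

    sd_alpha: float  # cm
    sd_zeta: float  # years
    sd_gamma: float  # dimensionless
    correlation: np.ndarray  # 3x3, unit diagonal, positive definite

    def __post_init__(self):
        corr = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "correlation", corr)
        if min(self.sd_alpha, self.sd_zeta, self.sd_gamma) < 0:
            raise ContractError("random-effect SDs must be non-negative")
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ContractError("correlation must be symmetric 3x3")
        if not np.allclose(np.diag(corr), 1.0):
            raise ContractError("correlation diagonal must be 1")

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_alpha, self.sd_zeta, self.sd_gamma])

    def covariance(self) -> np.ndarray:
        d = self.sds
        return self.correlation * np.outer(d, d)


class IndividualEffects:
    """Per-subject (alpha_i, zeta_i, gamma_i) triples.

    Thin mapping from subject id to a length-3 array; order is preserved.
    """

    def __init__(self, subject_ids, values):
        self.subject_ids = list(subject_ids)
        self.values = np.asarray(values, dtype=float).reshape(len(self.subject_ids), 3)
        if not np.all(np.isfinite(self.values)):
            raise ContractError("individual effects must be finite")
        self._index = {sid: i for i, sid in enumerate(self.subject_ids)}

    def __getitem__(self, subject_id: str) -> np.ndarray:
        try:
            return self.values[self._index[subject_id]]
        except KeyError:
            raise ContractError(f"no effects for subject {subject_id!r}") from None

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._index

    def __len__(self) -> int:
        return len(self.subject_ids)


def transform_age(x, x_bar: float, zeta_total, gamma_total):
    """SITAR age transform ``u = (x - x_bar - zeta) * exp(-gamma)``.

    Strictly increasing in ``x`` with slope ``exp(-gamma_total)``.
    """
    return (np.asarray(x, dtype=float) - x_bar - zeta_total) * np.exp(-gamma_total)


def inverse_transform_age(u, x_bar: float, zeta_total, gamma_total):
    """Inverse of :func:`transform_age`: ``x = x_bar + zeta + u * exp(gamma)``."""
    return x_bar + zeta_total + np.asarray(u, dtype=float) * np.exp(gamma_total)


def predict_height(pop: PopulationParameters, effects, basis, x_bar: float, x):
    """Noise-free predicted stature at age(s) ``x`` for one subject.

    ``effects`` is a length-3 ``(alpha_i, zeta_i, gamma_i)`` triple; pass
    zeros for the population mean curve.
    """
    a_i, z_i, g_i = np.asarray(effects, dtype=float)
    u = transform_age(x, x_bar, pop.zeta0 + z_i, pop.gamma0 + g_i)
    h = basis.evaluate(u, 0)
    return pop.alpha0 + a_i + h @ pop.beta


def log_likelihood(
    cohort: Cohort,
    pop: PopulationParameters,
    effects: IndividualEffects,
    basis,
    x_bar: float,
) -> float:
    """Gaussian log likelihood of the cohort under the model.

    Sum over all records of ``Normal(y; predicted, sigma)`` log density.
    Every subject in the cohort must have an effects triple.
    """
    total = 0.0
    for sid, grp in cohort.data.groupby("id", sort=False):
        if sid not in effects:
            raise ContractError(f"no effects for subject {sid!r}")
        pred = predict_height(pop, effects[sid], basis, x_bar, grp["age_years"].to_numpy())
        r = grp["stature_cm"].to_numpy() - pred
        total += -0.5 * len(r) * (_LOG_2PI + 2.0 * math.log(pop.sigma))
        total += -0.5 * float(r @ r) / pop.sigma**2
    return total


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorConfig:
    """Weakly regularising priors scaled to the data.

    alpha0 ~ Normal(mean stature, 2 * SD stature)
    beta_k ~ Normal(0, 5 * SD stature)
    zeta0  ~ Normal(0, SD age)
    gamma0 ~ Normal(0, 1.5)
    sigma  ~ Half-Student-t(3, SD stature)
    sd_alpha ~ Half-Normal(SD stature); sd_zeta ~ Half-Normal(SD age)
    sd_gamma ~ Half-Normal(0.5); correlation ~ LKJ(2)
    """

    alpha0_loc: float
    alpha0_scale: float
    beta_scale: float
    zeta0_scale: float
    gamma0_scale: float = 1.5
    sigma_scale: float = 10.0
    sigma_df: float = 3.0
    sd_alpha_scale: float = 10.0
    sd_zeta_scale: float = 2.0
    sd_gamma_scale: float = 0.5
    lkj_eta: float = 2.0

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "PriorConfig":
        y = cohort.data["stature_cm"].to_numpy()
        x = cohort.data["age_years"].to_numpy()
        sd_y = float(np.std(y, ddof=1))
        sd_x = float(np.std(x, ddof=1))
        return cls(
            alpha0_loc=float(np.mean(y)),
            alpha0_scale=2.0 * sd_y,
            beta_scale=5.0 * sd_y,
            zeta0_scale=sd_x,
            sigma_scale=sd_y,
            sd_alpha_scale=sd_y,
            sd_zeta_scale=sd_x,
        )

    def scaled(self, factor: float) -> "PriorConfig":
        """All scale hyperparameters multiplied by ``factor`` (sweep support)."""
        if factor <= 0:
            raise ValueError("prior scale factor must be positive")
        return replace(
            self,
            alpha0_scale=self.alpha0_scale * factor,
            beta_scale=self.beta_scale * factor,
            zeta0_scale=self.zeta0_scale * factor,
            gamma0_scale=self.gamma0_scale * factor,
            sigma_scale=self.sigma_scale * factor,
            sd_alpha_scale=self.sd_alpha_scale * factor,
            sd_zeta_scale=self.sd_zeta_scale * factor,
            sd_gamma_scale=self.sd_gamma_scale * factor,
        )


def _norm_logpdf(x, loc, scale):
    return -0.5 * _LOG_2PI - math.log(scale) - 0.5 * ((x - loc) / scale) ** 2


def _halfnorm_logpdf(x, scale):
    if x < 0:
        return -np.inf
    return math.log(2.0) + _norm_logpdf(x, 0.0, scale)


def _halft_logpdf(x, df, scale):
    if x <= 0:
        return -np.inf
    return math.log(2.0) + float(stats.t.logpdf(x / scale, df)) - math.log(scale)


def log_prior_terms(
    pop: PopulationParameters, red: RandomEffectDistribution, prior: PriorConfig
) -> dict[str, float]:
    """Per-component log prior densities (LKJ term unnormalised)."""
    terms = {
        "alpha0": _norm_logpdf(pop.alpha0, prior.alpha0_loc, prior.alpha0_scale),
        "beta": float(sum(_norm_logpdf(b, 0.0, prior.beta_scale) for b in pop.beta)),
        "zeta0": _norm_logpdf(pop.zeta0, 0.0, prior.zeta0_scale),
        "gamma0": _norm_logpdf(pop.gamma0, 0.0, prior.gamma0_scale),
        "sigma": _halft_logpdf(pop.sigma, prior.sigma_df, prior.sigma_scale),
        "sd_alpha": _halfnorm_logpdf(red.sd_alpha, prior.sd_alpha_scale),
        "sd_zeta": _halfnorm_logpdf(red.sd_zeta, prior.sd_zeta_scale),
        "sd_gamma": _halfnorm_logpdf(red.sd_gamma, prior.sd_gamma_scale),
    }
    sign, logdet = np.linalg.slogdet(red.correlation)
    terms["correlation"] = (prior.lkj_eta - 1.0) * logdet if sign > 0 else -np.inf
    return terms


def log_prior(
    pop: PopulationParameters, red: RandomEffectDistribution, prior: PriorConfig
) -> float:
    """Total log prior; ``-inf`` at domain boundaries (never an exception)."""
    return float(sum(log_prior_terms(pop, red, prior).values()))
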