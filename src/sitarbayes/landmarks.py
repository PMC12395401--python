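"""Velocity curves and pubertal growth landmarks.

Four landmarks summarise the pubertal spurt: the age at takeoff (ATGV, the
pre-spurt local minimum of the velocity curve), the velocity there (TGV),
the age at peak height velocity (APHV) and the peak velocity (PHV).

Under the SITAR transform the velocity curve of any draw is

    v(x) = exp(-g_tot) * sum_k beta_k h'_k(u(x)),
    u(x) = (x - x_bar - z_tot) * exp(-g_tot),

so extrema in age correspond one-to-one to extrema of the spline-gradient
``g(u) = sum_k beta_k h'_k(u)`` on the transformed scale.  The landmark
routines exploit this: the search runs once per posterior draw on ``g``,
and individual landmarks follow from the closed forms

    APHV_i = x_bar + z0 + z_i + u* exp(g0 + g_i)
    PHV_i  = exp(-(g0 + g_i)) * g(u*)

(and their takeoff analogues), which are exact because the transform is a
monotone affine map of age for fixed parameters.

Point estimates are posterior means of the per-draw landmark, and 68%
credible intervals are the central 16th-84th percentile of the per-draw
sample -- not the landmark of the posterior-mean curve, which differs
under nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ContractError, LandmarkInstabilityError, LandmarkNotFoundError
from .fit import SitarFit
from .model import transform_age

__all__ = [
    "VelocityCurve",
    "velocity",
    "find_peak",
    "find_takeoff",
    "GrowthLandmarks",
    "population_landmarks",
    "individual_landmarks",
    "IndividualLandmarks",
]

_GRID = 2001


@dataclass(frozen=True)
class VelocityCurve:
    """Velocity curve of one parameter draw (population or individual)."""

    basis: object
    x_bar: float
    beta: np.ndarray
    zeta_total: float
    gamma_total: float

    def u(self, x):
        return transform_age(x, self.x_bar, self.zeta_total, self.gamma_total)

    def velocity(self, x):
        scale = np.exp(-self.gamma_total)
        return scale * (self.basis.evaluate(self.u(x), 1) @ self.beta)

    def acceleration(self, x):
        scale = np.exp(-2.0 * self.gamma_total)
        return scale * (self.basis.evaluate(self.u(x), 2) @ self.beta)


def velocity(pop, effects, basis, x_bar: float, x):
    """Velocity (cm/year) at age(s) ``x`` for one draw's parameters.

    ``effects`` is the subject's (alpha_i, zeta_i, gamma_i); zeros give the
    population curve.  The size components never enter: velocity is the age
    derivative of predicted height and additive constants vanish.
    """
    a_i, z_i, g_i = np.asarray(effects, dtype=float)
    curve = VelocityCurve(
        basis=basis,
        x_bar=x_bar,
        beta=np.asarray(pop.beta, dtype=float),
        zeta_total=pop.zeta0 + z_i,
        gamma_total=pop.gamma0 + g_i,
    )
    return curve.velocity(x)


class _FunctionCurve:
    """Adapter giving any velocity callable the curve interface."""

    def __init__(self, vfun, afun=None, h: float = 1e-5):
        self._v = vfun
        self._a = afun
        self._h = h

    def velocity(self, x):
        return self._v(np.asarray(x, dtype=float))

    def acceleration(self, x):
        if self._a is not None:
            return self._a(np.asarray(x, dtype=float))
        x = np.asarray(x, dtype=float)
        return (self._v(x + self._h) - self._v(x - self._h)) / (2.0 * self._h)


def _as_curve(curve):
    if callable(curve) and not hasattr(curve, "velocity"):
        return _FunctionCurve(curve)
    return curve


def _accel_crossings(curve, lo, hi, n_grid=_GRID):
    grid = np.linspace(lo, hi, n_grid)
    acc = np.asarray(curve.acceleration(grid), dtype=float)
    sign = np.sign(acc)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    roots = []
    f = lambda t: float(curve.acceleration(t))
    for i in flips:
        a, b = float(grid[i]), float(grid[i + 1])
        fa, fb = f(a), f(b)
        if fa * fb > 0:  # roundoff phantom at a window edge (|acc| ~ eps)
            continue
        root = a if fa == 0 else (b if fb == 0 else brentq(f, a, b, xtol=1e-9))
        roots.append((root, float(sign[i])))  # sign before the crossing
    return roots, grid, acc


def find_peak(curve, search_window) -> tuple[float, float]:
    """Global maximum of the velocity curve inside the window.

    Located by root-finding on the analytic acceleration (refined below
    1e-6 years) with a dense-grid fallback; a window on which the curve is
    monotone raises :class:`LandmarkNotFoundError`.
    """
    curve = _as_curve(curve)
    lo, hi = search_window
    if not lo < hi:
        raise ContractError("search window must have lower < upper")
    roots, grid, _ = _accel_crossings(curve, lo, hi)
    maxima = [r for r, before in roots if before > 0]  # accel + -> - : local max
    if not maxima:
        vals = np.asarray(curve.velocity(grid), dtype=float)
        i = int(np.argmax(vals))
        if i in (0, len(grid) - 1):
            raise LandmarkNotFoundError(
                f"no interior velocity maximum in window [{lo}, {hi}]"
            )
        maxima = [grid[i]]  # grid fallback (acceleration numerically flat)
    best = max(maxima, key=lambda t: float(curve.velocity(t)))
    return float(best), float(curve.velocity(best))


def find_takeoff(curve, peak_age: float, search_window) -> tuple[float, float, bool]:
    """Pre-spurt local minimum of velocity before the peak.

    Returns ``(age, velocity, boundary)``: the last acceleration -/+ zero
    crossing before ``peak_age``; when the velocity is monotone on the
    window, the window minimum is returned with ``boundary=True``.
    """
    curve = _as_curve(curve)
    lo, hi = search_window
    hi = min(hi, peak_age)
    if not lo < hi:
        raise ContractError("takeoff window is empty")
    roots, grid, _ = _accel_crossings(curve, lo, hi)
    minima = [r for r, before in roots if before < 0 and r < peak_age]
    if minima:
        t = max(minima)  # the last minimum before the peak
        return float(t), float(curve.velocity(t)), False
    vals = np.asarray(curve.velocity(grid), dtype=float)
    i = int(np.argmin(vals))
    return float(grid[i]), float(vals[i]), True


# ---------------------------------------------------------------------------
# landmark containers


@dataclass(frozen=True)
class GrowthLandmarks:
    """Four pubertal landmarks with 68% credible intervals.

    Each field is ``(estimate, ci_low, ci_high)``; ``atgv``/``aphv`` in
    years, ``tgv``/``phv`` in cm/year.
    """

    atgv: tuple[float, float, float]
    tgv: tuple[float, float, float]
    aphv: tuple[float, float, float]
    phv: tuple[float, float, float]
    n_draws_used: int = 1
    n_draws_failed: int = 0
    takeoff_boundary_fraction: float = 0.0

    def to_frame(self, level: str = "pop", sex: str = "") -> pd.DataFrame:
        rows = []
        for name in ("atgv", "tgv", "aphv", "phv"):
            est, lo, hi = getattr(self, name)
            rows.append(
                {
                    "level": level,
                    "sex": sex,
                    "landmark": name,
                    "estimate": est,
                    "ci68_low": lo,
                    "ci68_high": hi,
                    "n_draws_used": self.n_draws_used,
                    "boundary_flag": self.takeoff_boundary_fraction > 0.5,
                }
            )
        return pd.DataFrame(rows)


def _ci68(values: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.mean(values)),
        float(np.percentile(values, 16)),
        float(np.percentile(values, 84)),
    )


def _default_window(fit: SitarFit):
    window = fit.meta.get("age_window")
    if window is None:
        raise ContractError("fit carries no default age window; pass search_window")
    return tuple(window)


def _uspace_landmarks_per_draw(fit: SitarFit, search_window):
    """Takeoff/peak of g(u) per draw, in transformed-age coordinates.

    Returns arrays (u_takeoff, g_takeoff, u_peak, g_peak, boundary, ok).
    """
    lo, hi = search_window
    S = fit.n_draws
    d = fit.draws
    out = np.full((S, 4), np.nan)
    boundary = np.zeros(S, dtype=bool)
    ok = np.zeros(S, dtype=bool)
    for s in range(S):
        u_lo = transform_age(lo, fit.x_bar, d.zeta0[s], d.gamma0[s])
        u_hi = transform_age(hi, fit.x_bar, d.zeta0[s], d.gamma0[s])
        beta = d.beta[s]
        g = _FunctionCurve(
            lambda u, b=beta: fit.basis.evaluate(u, 1) @ b,
            lambda u, b=beta: fit.basis.evaluate(u, 2) @ b,
        )
        try:
            u_pk, g_pk = find_peak(g, (u_lo, u_hi))
        except LandmarkNotFoundError:
            continue
        u_to, g_to, bnd = find_takeoff(g, u_pk, (u_lo, u_pk))
        out[s] = (u_to, g_to, u_pk, g_pk)
        boundary[s] = bnd
        ok[s] = True
    return out, boundary, ok


def population_landmarks(fit: SitarFit, search_window=None) -> GrowthLandmarks:
    """Population-curve landmarks over all posterior draws.

    For each draw the population velocity curve (individual effects zero)
    is searched; the point estimate is the mean over draws and the 68%
    interval the 16th-84th percentile.  Draws whose search fails are
    dropped and counted; more than 10% failures raises
    :class:`LandmarkInstabilityError`.
    """
    if fit.n_draws < 1:
        raise ContractError("fit has no draws")
    window = tuple(search_window) if search_window is not None else _default_window(fit)
    uspace, boundary, ok = _uspace_landmarks_per_draw(fit, window)
    n_fail = int((~ok).sum())
    if n_fail > 0.10 * fit.n_draws:
        raise LandmarkInstabilityError(
            f"landmark search failed in {n_fail}/{fit.n_draws} draws"
        )
    d = fit.draws
    e_g0 = np.exp(d.gamma0[ok])
    atgv = fit.x_bar + d.zeta0[ok] + uspace[ok, 0] * e_g0
    tgv = uspace[ok, 1] / e_g0
    aphv = fit.x_bar + d.zeta0[ok] + uspace[ok, 2] * e_g0
    phv = uspace[ok, 3] / e_g0
    return GrowthLandmarks(
        atgv=_ci68(atgv),
        tgv=_ci68(tgv),
        aphv=_ci68(aphv),
        phv=_ci68(phv),
        n_draws_used=int(ok.sum()),
        n_draws_failed=n_fail,
        takeoff_boundary_fraction=float(boundary[ok].mean()) if ok.any() else 0.0,
    )


@dataclass
class IndividualLandmarks:
    """Per-subject landmark estimates plus the per-draw samples behind them.

    ``draws[name]`` has shape (n_draws_used, n_subjects); ``estimates`` is a
    DataFrame with one row per subject.
    """

    subject_ids: list
    estimates: pd.DataFrame
    draws: dict[str, np.ndarray]
    n_draws_failed: int
    takeoff_boundary_fraction: float

    def landmarks_for(self, subject_id: str) -> GrowthLandmarks:
        j = self.subject_ids.index(subject_id)
        return GrowthLandmarks(
            atgv=_ci68(self.draws["atgv"][:, j]),
            tgv=_ci68(self.draws["tgv"][:, j]),
            aphv=_ci68(self.draws["aphv"][:, j]),
            phv=_ci68(self.draws["phv"][:, j]),
            n_draws_used=self.draws["atgv"].shape[0],
            n_draws_failed=self.n_draws_failed,
            takeoff_boundary_fraction=self.takeoff_boundary_fraction,
        )

    def to_frame(self, sex: str = "") -> pd.DataFrame:
        rows = []
        for j, sid in enumerate(self.subject_ids):
            for name in ("atgv", "tgv", "aphv", "phv"):
                est, lo, hi = _ci68(self.draws[name][:, j])
                rows.append(
                    {
                        "level": sid,
                        "sex": sex,
                        "landmark": name,
                        "estimate": est,
                        "ci68_low": lo,
                        "ci68_high": hi,
                        "n_draws_used": self.draws[name].shape[0],
                        "boundary_flag": self.takeoff_boundary_fraction > 0.5,
                    }
                )
        return pd.DataFrame(rows)


def individual_landmarks(fit: SitarFit, search_window=None) -> IndividualLandmarks:
    """Per-subject landmarks via the closed-form timing/intensity mapping.

    The per-draw u-scale extrema of ``g`` are shared by all subjects; each
    subject's landmarks follow from the closed forms above.  The
    subject-level point estimate is the posterior mean.
    """
    window = tuple(search_window) if search_window is not None else _default_window(fit)
    uspace, boundary, ok = _uspace_landmarks_per_draw(fit, window)
    n_fail = int((~ok).sum())
    if n_fail > 0.10 * max(fit.n_draws, 1):
        raise LandmarkInstabilityError(
            f"landmark search failed in {n_fail}/{fit.n_draws} draws"
        )
    d = fit.draws
    g_tot = d.gamma0[ok, None] + d.effects[ok][:, :, 2]  # (S_ok, n)
    z_tot = d.zeta0[ok, None] + d.effects[ok][:, :, 1]
    e_g = np.exp(g_tot)
    draws = {
        "atgv": fit.x_bar + z_tot + uspace[ok, 0][:, None] * e_g,
        "tgv": uspace[ok, 1][:, None] / e_g,
        "aphv": fit.x_bar + z_tot + uspace[ok, 2][:, None] * e_g,
        "phv": uspace[ok, 3][:, None] / e_g,
    }
    est = pd.DataFrame({"id": list(d.subject_ids)})
    for name, mat in draws.items():
        est[name] = mat.mean(axis=0)
    return IndividualLandmarks(
        subject_ids=list(d.subject_ids),
        estimates=est,
        draws=draws,
        n_draws_failed=n_fail,
        takeoff_boundary_fraction=float(boundary[ok].mean()) if ok.any() else 0.0,
    )
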