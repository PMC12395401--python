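"""Natural cubic spline basis with analytic derivatives.

The SITAR mean curve is a natural cubic spline in the transformed age
``u``.  This module builds the classic truncated-power natural spline basis
(the same function space as R's ``splines::ns``): piecewise cubic, twice
continuously differentiable, and *linear* beyond the boundary knots, so the
second derivative vanishes identically outside them.  The basis carries no
intercept column -- the model's size parameter absorbs the constant.

With knots ``k_1 < ... < k_m`` (``k_1``/``k_m`` the boundary, the rest
interior) the ``K = m - 1`` columns are::

    N_1(u)     = u
    N_{j+1}(u) = d_j(u) - d_{m-1}(u),   j = 1..m-2
    d_j(u)     = [ (u-k_j)_+^3 - (u-k_m)_+^3 ] / (k_m - k_j)

All derivative orders are evaluated from the closed-form piecewise
polynomials, not by numerical differentiation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["NaturalCubicBasis", "build_basis"]


@dataclass(frozen=True)
class NaturalCubicBasis:
    """Natural cubic spline basis on the transformed-age scale.

    Parameters
    ----------
    boundary_knots:
        ``(lo, hi)`` pair; the spline is linear outside this interval.
    interior_knots:
        Strictly increasing knots strictly inside the boundary.
    """

    boundary_knots: tuple[float, float]
    interior_knots: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        interior = np.asarray(self.interior_knots, dtype=float)
        object.__setattr__(self, "interior_knots", interior)
        if not lo < hi:
            raise ConfigurationError("boundary knots must satisfy lo < hi")
        if interior.size:
            if np.any(np.diff(interior) <= 0):
                raise ConfigurationError("interior knots must be strictly increasing")
            if interior[0] <= lo or interior[-1] >= hi:
                raise ConfigurationError("interior knots must lie strictly inside the boundary")

    @property
    def df(self) -> int:
        """Number of basis columns K (interior knots + 1)."""
        return self.interior_knots.size + 1

    @property
    def all_knots(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.concatenate([[lo], self.interior_knots, [hi]])

    def evaluate(self, u, order: int = 0) -> np.ndarray:
        """Evaluate all K columns (or their derivatives) at ``u``.

        Parameters
        ----------
        u:
            Scalar or array of transformed ages; extrapolation is allowed
            (the spline continues linearly beyond the boundary knots).
        order:
            Derivative order, 0, 1 or 2.

        Returns
        -------
        Array of shape ``u.shape + (K,)``.
        """
        if order not in (0, 1, 2):
            raise ConfigurationError(f"derivative order must be 0, 1 or 2, got {order}")
        u = np.asarray(u, dtype=float)
        scalar = u.ndim == 0
        u = np.atleast_1d(u)
        knots = self.all_knots
        m = knots.size
        k_last = knots[-1]
        out = np.empty(u.shape + (m - 1,))
        # linear column
        if order == 0:
            out[..., 0] = u
        elif order == 1:
            out[..., 0] = 1.0
        else:
            out[..., 0] = 0.0
        # truncated-power differences
        d = np.empty(u.shape + (m - 1,))
        for j in range(m - 1):
            d[..., j] = self._d(u, knots[j], k_last, order)
        for j in range(m - 2):
            out[..., j + 1] = d[..., j] - d[..., m - 2]
        if scalar:
            return out[0]
        return out

    @staticmethod
    def _d(u: np.ndarray, kj: float, km: float, order: int) -> np.ndarray:
        a = np.maximum(u - kj, 0.0)
        b = np.maximum(u - km, 0.0)
        if order == 0:
            num = a**3 - b**3
        elif order == 1:
            num = 3.0 * (a**2 - b**2)
        else:
            num = 6.0 * (a - b)
        return num / (km - kj)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "boundary_knots": [float(self.boundary_knots[0]), float(self.boundary_knots[1])],
            "interior_knots": [float(k) for k in self.interior_knots],
            "df": self.df,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, payload: dict) -> "NaturalCubicBasis":
        basis = cls(
            boundary_knots=tuple(payload["boundary_knots"]),
            interior_knots=np.asarray(payload["interior_knots"], dtype=float),
        )
        if "df" in payload and int(payload["df"]) != basis.df:
            raise ConfigurationError("stored df inconsistent with knot count")
        return basis

    @classmethod
    def from_json(cls, text: str) -> "NaturalCubicBasis":
        return cls.from_dict(json.loads(text))


def build_basis(u_values, df: int) -> NaturalCubicBasis:
    """Build a basis with boundary knots at the data range and interior
    knots at equally spaced quantiles.

    ``df = K`` basis columns require ``df - 1`` interior knots, placed at the
    ``i/df`` quantiles (``i = 1..df-1``) of ``u_values``.
    """
    if df < 2:
        raise ConfigurationError(f"df must be >= 2, got {df}")
    u = np.unique(np.asarray(u_values, dtype=float))
    if u.size < df + 2:
        raise ConfigurationError(
            f"need at least df + 2 = {df + 2} distinct values to place knots, got {u.size}"
        )
    probs = np.arange(1, df) / df
    interior = np.quantile(np.asarray(u_values, dtype=float), probs)
    return NaturalCubicBasis(boundary_knots=(float(u[0]), float(u[-1])), interior_knots=interior)
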