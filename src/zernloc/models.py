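"""Continuous ramp-edge and wedge-streak signal models on the unit disk.

These closed forms are the oracle layer for the whole package: analytic
moments, exact moment ratios, and the least-squares derivation of the streak
inversion coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RampEdgeModel",
    "WedgeStreakModel",
    "InversionCoefficients",
    "ramp_edge_intensity",
    "wedge_streak_intensity",
    "edge_moments_analytic",
    "streak_moments_analytic",
    "edge_ratio",
    "streak_ratio",
    "streak_ratio_limit",
    "fit_streak_inversion",
]


@dataclass(frozen=True)
class RampEdgeModel:
    """Linear ramp from intensity ``h`` to ``h + k``, full width ``2w``,
    midpoint at signed disk offset ``ell`` along the edge normal."""

    h: float
    k: float
    ell: float
    w: float

    def __post_init__(self):
        if self.w < 0:
            raise ValueError(f"w must be >= 0, got {self.w}")
        if abs(self.ell) + self.w > 1.0 + 1e-12:
            raise ValueError(
                f"|ell| + w = {abs(self.ell) + self.w:.4f} exceeds 1 "
                "(ramp extends outside the unit disk)"
            )

    @property
    def ell1(self) -> float:
        return self.ell - self.w

    @property
    def ell2(self) -> float:
        return self.ell + self.w

    @property
    def b1(self) -> float:
        return math.sqrt(max(0.0, 1.0 - self.ell1 ** 2))

    @property
    def b2(self) -> float:
        return math.sqrt(max(0.0, 1.0 - self.ell2 ** 2))


@dataclass(frozen=True)
class WedgeStreakModel:
    """Triangular wedge peaking at ``h + k`` at disk offset ``ell >= 0``,
    with feet at ``ell -/+ w`` back down to the background ``h``."""

    h: float
    k: float
    ell: float
    w: float

    def __post_init__(self):
        if self.w < 0:
            raise ValueError(f"w must be >= 0, got {self.w}")
        if self.ell < 0:
            raise ValueError(f"ell must be >= 0 for a streak, got {self.ell}")
        if self.ell + self.w > 1.0 + 1e-12:
            raise ValueError(
                f"ell + w = {self.ell + self.w:.4f} exceeds 1 "
                "(wedge extends outside the unit disk)"
            )

    @property
    def ell1(self) -> float:
        return self.ell - self.w

    @property
    def ell2(self) -> float:
        return self.ell + self.w

    @property
    def b1(self) -> float:
        return math.sqrt(max(0.0, 1.0 - self.ell1 ** 2))

    @property
    def b2(self) -> float:
        return math.sqrt(max(0.0, 1.0 - self.ell2 ** 2))

    @property
    def c(self) -> float:
        return math.sqrt(max(0.0, 1.0 - self.ell ** 2))


def ramp_edge_intensity(u_prime, model: RampEdgeModel):
    """Piecewise-linear ramp intensity as a function of the normal coordinate."""
    u = np.asarray(u_prime, dtype=float)
    if model.w == 0:
        ramp = np.where(u > model.ell, 1.0, 0.0)
    else:
        ramp = np.clip((u - model.ell1) / (2.0 * model.w), 0.0, 1.0)
    out = model.h + model.k * ramp
    return out if out.ndim else float(out)


def wedge_streak_intensity(u_prime, model: WedgeStreakModel):
    """Piecewise-linear wedge intensity as a function of the normal coordinate."""
    u = np.asarray(u_prime, dtype=float)
    if model.w == 0:
        tri = np.zeros_like(u)
    else:
        tri = np.clip(1.0 - np.abs(u - model.ell) / model.w, 0.0, 1.0)
    out = model.h + model.k * tri
    return out if out.ndim else float(out)


def edge_moments_analytic(model: RampEdgeModel) -> tuple[float, float]:
    """Exact (A11', A20') of the continuous ramp edge on the unit disk.

    A20' equals A20 (the m = 0 moment is rotation invariant).  The
    background level h contributes nothing to either moment.
    """
    if model.w <= 0:
        raise ValueError("analytic ramp moments require w > 0")
    k, w = model.k, model.w
    l1, l2, b1, b2 = model.ell1, model.ell2, model.b1, model.b2
    a11 = (k / (24.0 * w)) * (
        3.0 * math.asin(l2)
        + (5.0 - 2.0 * l2 ** 2) * l2 * b2
        - 3.0 * math.asin(l1)
        - (5.0 - 2.0 * l1 ** 2) * l1 * b1
    )
    a20 = (k / (15.0 * w)) * (b1 ** 5 - b2 ** 5)
    return a11, a20


def streak_moments_analytic(model: WedgeStreakModel) -> tuple[float, float]:
    """Exact (A11', A20') of the continuous wedge streak on the unit disk."""
    if model.w <= 0:
        raise ValueError("analytic wedge moments require w > 0")
    k, w, ell = model.k, model.w, model.ell
    l1, l2, b1, b2, c = model.ell1, model.ell2, model.b1, model.b2, model.c
    a11 = (k / (12.0 * w)) * (
        6.0 * math.asin(ell)
        - 3.0 * math.asin(l1)
        - 3.0 * math.asin(l2)
        + 2.0 * c * ell * (5.0 - 2.0 * ell ** 2)
        - b1 * l1 * (5.0 - 2.0 * l1 ** 2)
        - b2 * l2 * (5.0 - 2.0 * l2 ** 2)
    )
    a20 = (2.0 * k / (15.0 * w)) * (b1 ** 5 + b2 ** 5 - 2.0 * c ** 5)
    return a11, a20


def edge_ratio(model: RampEdgeModel, approximate: bool = False) -> float:
    """Moment ratio Q_E = A20'/A11' of the ramp edge.

    With ``approximate=True`` returns the closed-form small-w approximation
    ``ell * (1 - (1 + ell/2) w^2)`` used to derive the edge inversion.
    """
    if approximate:
        return model.ell * (1.0 - (1.0 + model.ell / 2.0) * model.w ** 2)
    a11, a20 = edge_moments_analytic(model)
    return a20 / a11


def streak_ratio(model: WedgeStreakModel) -> float:
    """Moment ratio Q_S = A20'/A11' of the wedge streak."""
    a11, a20 = streak_moments_analytic(model)
    return a20 / a11


def streak_ratio_limit(ell: float) -> float:
    """w -> 0 limit of the streak ratio, (4 ell^2 - 1) / (3 ell)."""
    if ell <= 0:
        raise ValueError("the w -> 0 ratio limit requires ell > 0")
    return (4.0 * ell ** 2 - 1.0) / (3.0 * ell)


@dataclass(frozen=True)
class InversionCoefficients:
    """Coefficients of the 3-parameter streak inversion
    ``ell = a1*Q + sqrt(a1^2 Q^2 + a3 w^2 + a5)``."""

    a1: float
    a3: float
    a5: float
    residual_rms: float
    n_points: int

    def predict(self, q_s, w):
        q_s = np.asarray(q_s, dtype=float)
        w = np.asarray(w, dtype=float)
        rad = self.a1 ** 2 * q_s ** 2 + self.a3 * w ** 2 + self.a5
        return self.a1 * q_s + np.sqrt(np.clip(rad, 0.0, None))


# Operating region of the refinement: |update| <= one pixel (0.4 disk units
# at Np = 5) and practical blur widths.  Wider grids drag the fitted a1 away
# from the exact small-w coefficient.
_DEFAULT_ELL_GRID = np.arange(0.02, 0.4 + 1e-9, 0.02)
_DEFAULT_W_GRID = np.arange(0.02, 0.2 + 1e-9, 0.02)


def fit_streak_inversion(
    ell_grid=None, w_grid=None
) -> InversionCoefficients:
    """Least-squares fit of the streak inversion to the exact ratio.

    Generates (Q_S, w) -> ell samples from the analytic wedge moments over
    the grid and fits the retained 3-parameter form.  The w -> 0 closed form
    (a1 = 3/8, a5 = 1/4) should be recovered; a3 comes out near -1/10.
    """
    ell_grid = _DEFAULT_ELL_GRID if ell_grid is None else np.asarray(ell_grid, float)
    w_grid = _DEFAULT_W_GRID if w_grid is None else np.asarray(w_grid, float)
    ells, qs, ws = [], [], []
    for w in w_grid:
        for ell in ell_grid:
            if ell + w > 1.0:
                continue
            if w == 0:
                q = streak_ratio_limit(ell)
            else:
                q = streak_ratio(WedgeStreakModel(h=0.0, k=1.0, ell=ell, w=w))
            ells.append(ell)
            qs.append(q)
            ws.append(w)
    if len(ells) < 3:
        raise ValueError("fewer than 3 valid (ell, w) grid points")
    ells = np.array(ells)
    qs = np.array(qs)
    ws = np.array(ws)

    def resid(params):
        a1, a3, a5 = params
        rad = a1 ** 2 * qs ** 2 + a3 * ws ** 2 + a5
        if np.any(rad < 0):
            return np.full_like(ells, 1e6)
        return a1 * qs + np.sqrt(rad) - ells

    sol = least_squares(resid, x0=[3.0 / 8.0, -0.1, 0.25])
    if not sol.success:
        raise RuntimeError(f"streak inversion fit failed: {sol.message}")
    a1, a3, a5 = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return InversionCoefficients(
        a1=float(a1), a3=float(a3), a5=float(a5),
        residual_rms=rms, n_points=len(ells),
    )
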