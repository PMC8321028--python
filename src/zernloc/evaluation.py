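"""Monte Carlo error evaluation over SNR x blur grids and width-factor
calibration.

Each trial renders one randomized straight feature (uniform orientation,
uniform subpixel offset in [-0.5, 0.5] px along the normal) through the
center pixel of a small image, refines the rounded-truth guess, and records
the perpendicular distance from the estimate to the true curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .localize import (
    K_EDGE_DEFAULT,
    K_STREAK_DEFAULT,
    LocalizerConfig,
    _feature_from_sample,
    disk_width,
)
from .moments import MomentSample, compute_moments
from .synth import LineGeometry, SceneTruth, SyntheticScene, render_scene
from .zernike import mask_set

__all__ = [
    "MonteCarloConfig",
    "CellStats",
    "MonteCarloResult",
    "run_monte_carlo",
    "calibrate_width_factor",
]


@dataclass(frozen=True)
class MonteCarloConfig:
    feature_kind: str = "edge"              # "edge" | "streak"
    snr_grid: tuple = (math.inf,)
    blur_grid: tuple = (0.5,)               # PSF sigma, pixels
    n_trials: int = 500
    patch_size: int = 5
    width_factor: float | None = None       # None -> mode default
    estimator: str = "ramp"                 # edges: "ramp" | "step" (w = 0)
    seed: int = 0
    image_size: int = 15
    supersample: int = 8
    h: float = 100.0
    k: float = 100.0

    def __post_init__(self):
        if self.feature_kind not in ("edge", "streak"):
            raise ValueError(f"feature_kind must be 'edge' or 'streak', "
                             f"got {self.feature_kind!r}")
        if self.estimator not in ("ramp", "step"):
            raise ValueError(f"estimator must be 'ramp' or 'step', "
                             f"got {self.estimator!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.snr_grid or not self.blur_grid:
            raise ValueError("snr_grid and blur_grid must be non-empty")

    @property
    def resolved_width_factor(self) -> float:
        if self.width_factor is not None:
            return self.width_factor
        return K_EDGE_DEFAULT if self.feature_kind == "edge" else K_STREAK_DEFAULT


@dataclass(frozen=True)
class CellStats:
    snr: float
    psf_sigma: float
    mean_abs_error: float
    rmse: float
    bias: float
    n_used: int
    n_clamped: int
    n_degenerate: int
    n_total: int


@dataclass(frozen=True)
class MonteCarloResult:
    config: MonteCarloConfig
    cells: list[CellStats]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.cells])


@dataclass(frozen=True)
class _Trial:
    sample: MomentSample
    truth: SceneTruth


def _generate_trials(
    feature_kind: str,
    snr: float,
    sigma: float,
    n_trials: int,
    rng: np.random.Generator,
    patch_size: int,
    image_size: int,
    supersample: int,
    h: float,
    k: float,
) -> list[_Trial]:
    masks = mask_set(patch_size)
    anchor = image_size // 2
    trials = []
    for _ in range(n_trials):
        phi = rng.uniform(0.0, 2.0 * math.pi)
        delta = rng.uniform(-0.5, 0.5)
        geom = LineGeometry(
            normal_angle=phi,
            u0=anchor + delta * math.cos(phi),
            v0=anchor + delta * math.sin(phi),
        )
        scene = SyntheticScene(
            geometry=geom,
            feature_kind=feature_kind,
            h=h,
            k=k,
            psf_sigma=sigma,
            snr=snr,
            image_shape=(image_size, image_size),
            supersample=supersample,
            seed=int(rng.integers(2 ** 63)),
        )
        img, truth = render_scene(scene)
        sample = compute_moments(img, [(anchor, anchor)], masks)[0]
        trials.append(_Trial(sample=sample, truth=truth))
    return trials


def _evaluate_trials(
    trials: list[_Trial], lc: LocalizerConfig, a11_floor: float
):
    abs_err, signed_err = [], []
    n_clamped = n_degenerate = 0
    for t in trials:
        feat = _feature_from_sample(t.sample, lc, a11_floor)
        if feat.status in ("degenerate", "border"):
            n_degenerate += 1
            continue
        if feat.status == "clamped":
            n_clamped += 1
        d = float(t.truth.geometry.signed_distance(feat.sub_u, feat.sub_v))
        signed_err.append(d)
        abs_err.append(abs(d))
    abs_err = np.array(abs_err)
    signed_err = np.array(signed_err)
    return abs_err, signed_err, n_clamped, n_degenerate


def _cell_stats(snr, sigma, trials, lc, a11_floor) -> CellStats:
    abs_err, signed_err, n_clamped, n_degenerate = _evaluate_trials(
        trials, lc, a11_floor
    )
    n_used = len(abs_err)
    return CellStats(
        snr=snr,
        psf_sigma=sigma,
        mean_abs_error=float(abs_err.mean()) if n_used else math.nan,
        rmse=float(np.sqrt((abs_err ** 2).mean())) if n_used else math.nan,
        bias=float(signed_err.mean()) if n_used else math.nan,
        n_used=n_used,
        n_clamped=n_clamped,
        n_degenerate=n_degenerate,
        n_total=len(trials),
    )


def _localizer_for(config: MonteCarloConfig, sigma: float) -> LocalizerConfig:
    mode = config.feature_kind
    factor = config.resolved_width_factor
    # the step-model baseline is the w = 0 special case of the ramp inversion
    eff_sigma = 0.0 if (mode == "edge" and config.estimator == "step") else sigma
    return LocalizerConfig(
        mode=mode,
        patch_size=config.patch_size,
        psf_sigma=eff_sigma,
        k_edge=factor if mode == "edge" else K_EDGE_DEFAULT,
        k_streak=factor if mode == "streak" else K_STREAK_DEFAULT,
    )


def run_monte_carlo(config: MonteCarloConfig) -> MonteCarloResult:
    """Perpendicular-error statistics for every (SNR, blur) grid cell."""
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(config.snr_grid) * len(config.blur_grid))
    a11_floor = 1e-9 * config.k
    cells = []
    idx = 0
    for snr in config.snr_grid:
        for sigma in config.blur_grid:
            rng = np.random.default_rng(children[idx])
            idx += 1
            trials = _generate_trials(
                config.feature_kind, snr, sigma, config.n_trials, rng,
                config.patch_size, config.image_size, config.supersample,
                config.h, config.k,
            )
            lc = _localizer_for(config, sigma)
            cells.append(_cell_stats(snr, sigma, trials, lc, a11_floor))
    return MonteCarloResult(config=config, cells=cells)


def calibrate_width_factor(
    feature_kind: str,
    factor_grid,
    snr: float = math.inf,
    blur_grid=(0.5, 1.0),
    n_trials: int = 100,
    patch_size: int = 5,
    seed: int = 0,
    image_size: int = 15,
    supersample: int = 8,
) -> tuple[float, pd.DataFrame]:
    """Sweep the width factor and return (argmin factor, error table).

    Trials are rendered once per blur value and shared across all factor
    values (the factor only enters the inversion), so the error-vs-factor
    curve is smooth in the factor.  ``n_trials`` is per blur value.

    A factor is only eligible when its disk-frame width is valid (< 1) at
    every blur value; ineligible factors get a NaN error and never win.
    """
    factor_grid = np.asarray(factor_grid, dtype=float)
    if np.any(factor_grid <= 0):
        raise ValueError("width factors must be positive")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(blur_grid))
    h = k = 100.0
    trial_sets = [
        (
            sigma,
            _generate_trials(
                feature_kind, snr, sigma, n_trials,
                np.random.default_rng(child), patch_size, image_size,
                supersample, h, k,
            ),
        )
        for sigma, child in zip(blur_grid, children)
    ]
    a11_floor = 1e-9 * k
    rows = []
    for factor in factor_grid:
        valid = all(
            disk_width(feature_kind, factor, sigma, patch_size) < 1.0
            for sigma in blur_grid
        )
        if not valid:
            rows.append({"factor": float(factor), "mean_abs_error": math.nan,
                         "n_used": 0})
            continue
        errs = []
        for sigma, trials in trial_sets:
            lc = LocalizerConfig(
                mode=feature_kind,
                patch_size=patch_size,
                psf_sigma=sigma,
                k_edge=factor if feature_kind == "edge" else K_EDGE_DEFAULT,
                k_streak=factor if feature_kind == "streak" else K_STREAK_DEFAULT,
            )
            abs_err, _, _, _ = _evaluate_trials(trials, lc, a11_floor)
            errs.append(abs_err)
        errs = np.concatenate(errs)
        rows.append({
            "factor": float(factor),
            "mean_abs_error": float(errs.mean()) if len(errs) else math.nan,
            "n_used": int(len(errs)),
        })
    table = pd.DataFrame(rows)
    best = float(table.loc[table["mean_abs_error"].idxmin(), "factor"])
    return best, table
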