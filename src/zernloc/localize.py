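"""Subpixel refinement: moments -> orientation, moment ratio, disk offset,
and the corrected pixel coordinate, for both edges and streaks."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .moments import MomentSample, compute_moments
from .zernike import ZernikeMaskSet, mask_set

__all__ = [
    "LocalizerConfig",
    "SubpixelFeature",
    "disk_width",
    "orientation",
    "rotated_a11",
    "edge_offset",
    "streak_offset",
    "subpixel_update",
    "localize_features",
]

K_EDGE_DEFAULT = 1.80
K_STREAK_DEFAULT = 0.90


def disk_width(mode: str, factor: float, psf_sigma: float, patch_size: int) -> float:
    """Model half-width on the unit disk from the PSF std in pixels.

    Edges: ``k_edge`` scales the patch-frame blur, w = k * sigma * (2/Np).
    Streaks: ``k_streak`` multiplies the pixel-frame sigma directly,
    w = k * sigma.  The two published factors (1.80 and 0.90) are calibrated
    under these respective conventions and are only mutually consistent this
    way; see the calibration sweep in :mod:`zernloc.evaluation`.
    """
    if mode == "edge":
        return factor * psf_sigma * 2.0 / patch_size
    return factor * psf_sigma


@dataclass(frozen=True)
class LocalizerConfig:
    """Settings of the refinement pipeline.

    ``psf_sigma`` is the Gaussian PSF std in pixels; the model half-width on
    the unit disk follows :func:`disk_width`.
    """

    mode: str = "edge"                      # "edge" | "streak"
    patch_size: int = 5
    psf_sigma: float = 0.5
    k_edge: float = K_EDGE_DEFAULT
    k_streak: float = K_STREAK_DEFAULT
    polarity: str = "bright"                # streaks: "bright" | "dark"
    max_update: float | None = None         # default 2/Np (one pixel)
    a11_floor_rel: float = 1e-9             # floor on |A11'| vs intensity range

    def __post_init__(self):
        if self.mode not in ("edge", "streak"):
            raise ValueError(f"mode must be 'edge' or 'streak', got {self.mode!r}")
        if self.polarity not in ("bright", "dark"):
            raise ValueError(f"polarity must be 'bright' or 'dark', got {self.polarity!r}")
        if self.k_edge <= 0 or self.k_streak <= 0:
            raise ValueError("width factors must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.disk_width >= 1.0:
            raise ValueError(
                f"disk-frame width {self.disk_width:.3f} >= 1; "
                "reduce psf_sigma or increase patch_size"
            )

    @property
    def width_factor(self) -> float:
        return self.k_edge if self.mode == "edge" else self.k_streak

    @property
    def disk_width(self) -> float:
        return disk_width(self.mode, self.width_factor, self.psf_sigma,
                          self.patch_size)

    @property
    def max_update_value(self) -> float:
        return 2.0 / self.patch_size if self.max_update is None else self.max_update


@dataclass(frozen=True)
class SubpixelFeature:
    """One refined point; ``status`` is ok | clamped | degenerate | border."""

    guess_u: int
    guess_v: int
    psi: float
    q_ratio: float
    ell_hat: float
    sub_u: float
    sub_v: float
    status: str


def orientation(re_a11: float, im_a11: float) -> float:
    """Feature normal angle from the components of A11 (four-quadrant)."""
    if re_a11 == 0.0 and im_a11 == 0.0:
        raise ValueError("orientation undefined for a flat patch (A11 = 0)")
    return math.atan2(im_a11, re_a11)


def rotated_a11(re_a11: float, im_a11: float, psi: float) -> float:
    """Real part of A11 in a frame rotated by ``psi``; equals |A11| when
    ``psi`` is the orientation angle."""
    return re_a11 * math.cos(psi) + im_a11 * math.sin(psi)


def edge_offset(q_e: float, w: float) -> tuple[float, bool]:
    """Invert the ramp-edge ratio for the disk offset.

    Returns ``(ell_hat, clamped)``; a negative discriminant (possible under
    noise) is clamped to zero and flagged.
    """
    if not 0.0 <= w < 1.0:
        raise ValueError(f"edge half-width must satisfy 0 <= w < 1, got {w}")
    if w < 1e-4:
        # series form of the closed expression; the direct formula loses all
        # precision to cancellation as w -> 0 (step-model limit is q_e)
        w2 = w * w
        return q_e / (1.0 - w2) + w2 * q_e * q_e / (2.0 * (1.0 - w2) ** 3), False
    w2 = w * w
    disc = (w2 - 1.0) ** 2 - 2.0 * w2 * q_e
    clamped = disc < 0.0
    ell = (1.0 - w2 - math.sqrt(max(disc, 0.0))) / w2
    return ell, clamped


def streak_offset(q_s: float, w: float) -> tuple[float, bool]:
    """Invert the wedge-streak ratio for the disk offset.

    Returns ``(ell_hat, clamped)``.  For w < 1 the radicand is always
    positive, but the clamp is kept for robustness.
    """
    if not 0.0 <= w < 1.0:
        raise ValueError(f"streak half-width must satisfy 0 <= w < 1, got {w}")
    t = 0.375 * q_s
    rad = t * t - w * w / 10.0 + 0.25
    clamped = rad < 0.0
    return t + math.sqrt(max(rad, 0.0)), clamped


def subpixel_update(
    guess_u: float, guess_v: float, patch_size: int, ell: float, psi: float
) -> tuple[float, float]:
    """Move the guess by ``Np * ell / 2`` pixels along the normal angle."""
    step = patch_size * ell / 2.0
    return guess_u + step * math.cos(psi), guess_v + step * math.sin(psi)


def _feature_from_sample(
    s: MomentSample, config: LocalizerConfig, a11_floor: float
) -> SubpixelFeature:
    if s.border:
        return SubpixelFeature(s.guess_u, s.guess_v, np.nan, np.nan, np.nan,
                               np.nan, np.nan, "border")
    a11_mag = math.hypot(s.re_a11, s.im_a11)
    if a11_mag <= a11_floor:
        return SubpixelFeature(s.guess_u, s.guess_v, np.nan, np.nan, np.nan,
                               np.nan, np.nan, "degenerate")
    psi = orientation(s.re_a11, s.im_a11)
    a11_prime = rotated_a11(s.re_a11, s.im_a11, psi)
    q = s.a20 / a11_prime
    w = config.disk_width
    if config.mode == "edge":
        ell, clamped = edge_offset(q, w)
    else:
        ell, clamped = streak_offset(q, w)
        if ell < 0.0:
            return SubpixelFeature(s.guess_u, s.guess_v, psi, q, ell,
                                   np.nan, np.nan, "degenerate")
    status = "clamped" if clamped else "ok"
    if abs(ell) > config.max_update_value:
        status = "clamped"
    sub_u, sub_v = subpixel_update(s.guess_u, s.guess_v, config.patch_size, ell, psi)
    return SubpixelFeature(s.guess_u, s.guess_v, psi, q, ell, sub_u, sub_v, status)


def localize_features(
    image, guesses, config: LocalizerConfig, masks: ZernikeMaskSet | None = None
) -> list[SubpixelFeature]:
    """Full refinement pipeline for a list of integer pixel-level guesses.

    Dark-on-bright streaks are handled by negating the patch intensities
    before the moments are taken.
    """
    if masks is None:
        masks = mask_set(config.patch_size)
    if masks.patch_size != config.patch_size:
        raise ValueError("mask patch size does not match the configuration")
    img = np.asarray(image, dtype=float)
    if config.mode == "streak" and config.polarity == "dark":
        img = -img
    rng = float(np.ptp(img)) if img.size else 0.0
    scale = float(np.max(np.abs(img))) + 1.0 if img.size else 1.0
    # absolute term catches flat patches whose moments are pure roundoff
    a11_floor = max(config.a11_floor_rel * rng, 1e-12 * scale)
    samples = compute_moments(img, guesses, masks)
    return [_feature_from_sample(s, config, a11_floor) for s in samples]
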