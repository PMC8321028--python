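"""Synthetic scenes with exactly known edge/streak geometry.

Rendering pipeline: supersampled area-averaged rasterization of the crisp
signal, Gaussian PSF blur applied at the supersampled resolution, block
averaging down to pixels, then optional additive Gaussian noise at a
prescribed SNR (contrast amplitude over noise std).

Pixel centers sit at integer (u, v) with u = column and v = row, origin at
the top-left pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, special

__all__ = [
    "LineGeometry",
    "CircleGeometry",
    "SyntheticScene",
    "SceneTruth",
    "render_scene",
    "add_noise",
    "pixel_level_guesses",
]


@dataclass(frozen=True)
class LineGeometry:
    """Straight feature through ``(u0, v0)`` with normal angle ``normal_angle``.

    The signed distance is positive on the bright side of an edge; a streak's
    centerline lies at zero distance.
    """

    normal_angle: float
    u0: float
    v0: float

    def signed_distance(self, u, v):
        c, s = math.cos(self.normal_angle), math.sin(self.normal_angle)
        return c * (np.asarray(u, float) - self.u0) + s * (np.asarray(v, float) - self.v0)

    def distance(self, u, v):
        return np.abs(self.signed_distance(u, v))

    def sample(self, spacing: float, half_length: float):
        n = max(int(2 * half_length / spacing) + 1, 2)
        t = np.linspace(-half_length, half_length, n)
        c, s = math.cos(self.normal_angle), math.sin(self.normal_angle)
        u = self.u0 - s * t
        v = self.v0 + c * t
        angles = np.full_like(t, self.normal_angle)
        return np.column_stack([u, v]), angles


@dataclass(frozen=True)
class CircleGeometry:
    """Circular feature; an edge is bright inside, a streak rides the circle."""

    center_u: float
    center_v: float
    radius: float

    def signed_distance(self, u, v):
        r = np.hypot(np.asarray(u, float) - self.center_u,
                     np.asarray(v, float) - self.center_v)
        return self.radius - r

    def distance(self, u, v):
        return np.abs(self.signed_distance(u, v))

    def sample(self, spacing: float, half_length: float | None = None):
        n = max(int(2 * math.pi * self.radius / spacing) + 1, 8)
        phi = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        u = self.center_u + self.radius * np.cos(phi)
        v = self.center_v + self.radius * np.sin(phi)
        # normal (dark -> bright / toward the streak) points inward
        angles = np.arctan2(-np.sin(phi), -np.cos(phi))
        return np.column_stack([u, v]), angles


@dataclass(frozen=True)
class SyntheticScene:
    geometry: LineGeometry | CircleGeometry
    feature_kind: str = "edge"          # "edge" | "streak"
    h: float = 100.0
    k: float = 100.0
    psf_sigma: float = 0.5
    snr: float = math.inf
    image_shape: tuple[int, int] = (64, 64)
    supersample: int = 8
    seed: int | None = None
    streak_crisp_width: float = 0.2     # crisp line width in pixels
    quantize: bool = False

    def __post_init__(self):
        if self.feature_kind not in ("edge", "streak"):
            raise ValueError(f"feature_kind must be 'edge' or 'streak', "
                             f"got {self.feature_kind!r}")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if not (self.snr > 0):
            raise ValueError("snr must be positive (or infinite)")


@dataclass(frozen=True)
class SceneTruth:
    """Ground-truth record emitted with every rendering."""

    geometry: LineGeometry | CircleGeometry
    feature_kind: str
    psf_sigma: float
    in_frame: bool = True

    def distance(self, u, v):
        """Perpendicular distance from (u, v) to the true feature curve."""
        return self.geometry.distance(u, v)

    def sample(self, spacing: float = 1.0, half_length: float = 64.0):
        return self.geometry.sample(spacing, half_length)


def _crisp_supersampled(scene: SyntheticScene, uu, vv, sub_px: float) -> np.ndarray:
    d = scene.geometry.signed_distance(uu, vv)
    if scene.feature_kind == "edge":
        cov = np.clip(d / sub_px + 0.5, 0.0, 1.0)
        return scene.h + scene.k * cov
    t = scene.streak_crisp_width
    sigma = scene.psf_sigma
    if sigma > 0:
        # scale the crisp line so the post-blur peak contrast equals k
        amp = scene.k / special.erf(t / (2.0 * math.sqrt(2.0) * sigma))
    else:
        amp = scene.k
    cov = np.clip((t / 2.0 - np.abs(d)) / sub_px + 0.5, 0.0, 1.0)
    return scene.h + amp * cov


def render_scene(scene: SyntheticScene) -> tuple[np.ndarray, SceneTruth]:
    """Render a scene; returns the image and its ground-truth record."""
    rows, cols = scene.image_shape
    ss = scene.supersample
    sub_px = 1.0 / ss
    pos_u = (np.arange(cols * ss) + 0.5) * sub_px - 0.5
    pos_v = (np.arange(rows * ss) + 0.5) * sub_px - 0.5
    uu, vv = np.meshgrid(pos_u, pos_v)
    img = _crisp_supersampled(scene, uu, vv, sub_px)
    if scene.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=scene.psf_sigma * ss, mode="nearest")
    img = img.reshape(rows, ss, cols, ss).mean(axis=(1, 3))
    if math.isfinite(scene.snr):
        img = add_noise(img, scene.snr, scene.k, scene.seed)
    if scene.quantize:
        img = np.clip(np.rint(img), 0, 65535)

    # does any part of the curve fall inside the frame?
    pts, _ = scene.geometry.sample(1.0, half_length=float(max(rows, cols)))
    in_frame = bool(
        np.any((pts[:, 0] >= 0) & (pts[:, 0] <= cols - 1)
               & (pts[:, 1] >= 0) & (pts[:, 1] <= rows - 1))
    )
    truth = SceneTruth(scene.geometry, scene.feature_kind, scene.psf_sigma, in_frame)
    return img, truth


def add_noise(image, snr: float, k: float, seed=None) -> np.ndarray:
    """Add zero-mean Gaussian noise with std ``k / snr`` (seeded)."""
    if math.isinf(snr):
        return np.asarray(image, dtype=float)
    if not snr > 0:
        raise ValueError(f"snr must be positive, got {snr}")
    rng = np.random.default_rng(seed)
    image = np.asarray(image, dtype=float)
    return image + rng.normal(0.0, k / snr, size=image.shape)


def pixel_level_guesses(
    truth: SceneTruth,
    image_shape: tuple[int, int],
    margin: int = 2,
    jitter: float = 0.0,
    seed=None,
    spacing: float = 1.0,
) -> list[tuple[int, int]]:
    """Integer guesses from rounded curve samples, emulating a pixel-level
    detector; optional uniform jitter (in pixels) along the normal."""
    rows, cols = image_shape
    pts, angles = truth.sample(spacing, half_length=float(max(rows, cols)))
    if jitter > 0:
        rng = np.random.default_rng(seed)
        off = rng.uniform(-jitter, jitter, size=len(pts))
        pts = pts + off[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    iu = np.rint(pts[:, 0]).astype(int)
    iv = np.rint(pts[:, 1]).astype(int)
    keep = (iu >= margin) & (iu < cols - margin) & (iv >= margin) & (iv < rows - margin)
    seen: dict[tuple[int, int], None] = {}
    for u, v in zip(iu[keep], iv[keep]):
        seen.setdefault((int(u), int(v)))
    return list(seen.keys())
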