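"""Raw Zernike moments (Re A11, Im A11, A20) at candidate pixels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .zernike import ZernikeMaskSet

__all__ = ["MomentSample", "compute_moments", "moment_field"]


@dataclass(frozen=True)
class MomentSample:
    """Moments of one patch centered at an integer pixel-level guess."""

    guess_u: int
    guess_v: int
    re_a11: float
    im_a11: float
    a20: float
    patch_size: int
    border: bool = False


def _as_float_image(image) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {image.shape}")
    return image.astype(float, copy=False)


def compute_moments(
    image, guesses, masks: ZernikeMaskSet
) -> list[MomentSample]:
    """Correlate the masks with the patch around each integer guess.

    Guesses closer than the patch half-width to any border are returned with
    ``border=True`` and NaN moments rather than silently dropped.
    """
    img = _as_float_image(image)
    p = masks.half_width
    rows, cols = img.shape
    out: list[MomentSample] = []
    for u, v in guesses:
        u, v = int(u), int(v)
        if not (p <= u < cols - p and p <= v < rows - p):
            out.append(MomentSample(u, v, np.nan, np.nan, np.nan,
                                    masks.patch_size, border=True))
            continue
        patch = img[v - p: v + p + 1, u - p: u + p + 1]
        re_a11 = float(np.sum(patch * masks.re_m11))
        im_a11 = float(np.sum(patch * masks.re_m11.T))
        a20 = float(np.sum(patch * masks.m20))
        out.append(MomentSample(u, v, re_a11, im_a11, a20, masks.patch_size))
    return out


def moment_field(image, masks: ZernikeMaskSet):
    """Whole-image correlation with the three masks.

    Returns ``(re_a11, im_a11, a20)`` grids matching the image shape, with
    the border band of width ``p`` set to NaN.  Interior values are
    identical to :func:`compute_moments` at the same pixels.
    """
    img = _as_float_image(image)
    p = masks.half_width
    if min(img.shape) < masks.patch_size:
        raise ValueError(
            f"image shape {img.shape} smaller than the {masks.patch_size}x"
            f"{masks.patch_size} mask"
        )
    fields = tuple(
        ndimage.correlate(img, m, mode="constant", cval=0.0)
        for m in (masks.re_m11, masks.re_m11.T, masks.m20)
    )
    for f in fields:
        f[:p, :] = np.nan
        f[-p:, :] = np.nan
        f[:, :p] = np.nan
        f[:, -p:] = np.nan
    return fields
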