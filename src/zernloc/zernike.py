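"""Zernike polynomials and discrete moment masks on a patch's inscribed disk.

A square ``Np x Np`` patch is mapped onto ``[-1, 1]^2`` so that each pixel
covers a square of side ``2/Np`` and the inscribed unit circle is tangent to
the patch border.  Moment masks are per-pixel integrals of a Zernike
polynomial restricted to that circle, computed by midpoint quadrature.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "DiskCoordinate",
    "ZernikeMaskSet",
    "radial_polynomial",
    "zernike_polynomial",
    "normalization_coefficient",
    "build_mask",
    "mask_set",
    "save_mask_set",
    "load_mask_set",
]

DEFAULT_SUBSAMPLES = 256


def _check_nm(n: int, m: int) -> None:
    if n < 0 or abs(m) > n:
        raise ValueError(f"require n >= |m| >= 0, got n={n}, m={m}")
    if (n - m) % 2 != 0:
        raise ValueError(f"require n - m even, got n={n}, m={m}")


@dataclass(frozen=True)
class DiskCoordinate:
    """A point in the scaled (disk-frame) patch coordinates.

    ``u_bar`` grows to the right (columns), ``v_bar`` grows downward (rows);
    ``psi_frame`` is the rotation angle of an optional feature-aligned frame.
    """

    u_bar: float
    v_bar: float
    psi_frame: float = 0.0

    @property
    def rho(self) -> float:
        return math.hypot(self.u_bar, self.v_bar)

    @property
    def theta(self) -> float:
        return math.atan2(self.v_bar, self.u_bar)

    @property
    def inside_disk(self) -> bool:
        return self.rho <= 1.0 + 1e-12

    @classmethod
    def from_pixel(
        cls, u: float, v: float, guess_u: float, guess_v: float, patch_size: int
    ) -> "DiskCoordinate":
        """Scale pixel coordinates relative to a patch center onto the disk."""
        s = 2.0 / patch_size
        return cls(u_bar=s * (u - guess_u), v_bar=s * (v - guess_v))

    def rotated(self, psi: float) -> "DiskCoordinate":
        """Coordinates of the same point in a frame rotated by ``psi``."""
        c, s = math.cos(psi), math.sin(psi)
        return DiskCoordinate(
            u_bar=c * self.u_bar + s * self.v_bar,
            v_bar=-s * self.u_bar + c * self.v_bar,
            psi_frame=psi,
        )


def radial_polynomial(n: int, m: int, rho):
    """Radial polynomial R_nm(rho), the standard finite factorial sum."""
    _check_nm(n, m)
    m = abs(m)
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        coeff = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out = out + coeff * rho ** (n - 2 * s)
    return out if out.ndim else float(out)


def zernike_polynomial(n: int, m: int, point: DiskCoordinate) -> complex:
    """P_nm = R_nm(rho) * exp(j m theta) at one disk point."""
    _check_nm(n, m)
    if not point.inside_disk:
        raise ValueError(f"point (rho={point.rho:.3f}) outside the unit disk")
    return radial_polynomial(n, m, point.rho) * np.exp(1j * m * point.theta)


def normalization_coefficient(n: int, m: int) -> float:
    """Disk-orthogonality normalization pi/(n+1)."""
    _check_nm(n, m)
    return math.pi / (n + 1)


def _eval_nm_grid(n: int, m: int, u_bar: np.ndarray, v_bar: np.ndarray) -> np.ndarray:
    rho = np.hypot(u_bar, v_bar)
    vals = radial_polynomial(n, m, rho).astype(complex)
    if m != 0:
        vals *= np.exp(1j * m * np.arctan2(v_bar, u_bar))
    return vals


def _inner_y_integral(n: int, m: int, x: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Closed-form integral of P_nm over y in [a, b] at abscissa x (complex)."""
    d1 = b - a
    d2 = (b * b - a * a) / 2.0
    d3 = (b ** 3 - a ** 3) / 3.0
    if (n, m) == (0, 0):
        return d1 + 0j
    if (n, m) == (1, 1):
        return x * d1 + 1j * d2
    if (n, m) == (2, 0):
        return (2.0 * x * x - 1.0) * d1 + 2.0 * d3 + 0j
    if (n, m) == (2, 2):
        return x * x * d1 - d3 + 2j * x * d2
    raise NotImplementedError(
        f"exact pixel integration implemented for (n, m) in "
        f"{{(0,0),(1,1),(2,0),(2,2)}}, got ({n}, {m})"
    )


def _pixel_integral_exact(n, m, x1, x2, y1, y2) -> complex:
    """Integral of P_nm over [x1,x2] x [y1,y2] intersected with the disk."""
    from scipy.integrate import quad

    x_lo = max(x1, -1.0)
    x_hi = min(x2, 1.0)
    if x_hi <= x_lo:
        return 0.0 + 0.0j

    def integrand(x, part):
        c = math.sqrt(max(0.0, 1.0 - x * x))
        a = max(y1, -c)
        b = min(y2, c)
        if b <= a:
            return 0.0
        val = _inner_y_integral(n, m, np.float64(x), np.float64(a), np.float64(b))
        return val.real if part == 0 else val.imag

    # breakpoints where the circle crosses the pixel's y-limits
    pts = []
    for y in (y1, y2):
        if abs(y) < 1.0:
            xc = math.sqrt(1.0 - y * y)
            for cand in (-xc, xc):
                if x_lo < cand < x_hi:
                    pts.append(cand)
    pts = sorted(set(pts))
    re = quad(integrand, x_lo, x_hi, args=(0,), points=pts or None,
              limit=200, epsabs=1e-13, epsrel=1e-12)[0]
    if m == 0:
        return re + 0.0j
    im = quad(integrand, x_lo, x_hi, args=(1,), points=pts or None,
              limit=200, epsabs=1e-13, epsrel=1e-12)[0]
    return re + 1j * im


def build_mask(
    n: int,
    m: int,
    patch_size: int,
    subsamples: int = DEFAULT_SUBSAMPLES,
    method: str = "midpoint",
):
    """Integrate P_nm over every pixel square, restricted to the inscribed disk.

    Returns an ``Np x Np`` real matrix, or an ``(real, imag)`` pair when
    ``m != 0``.  Entry ``[row, col]`` corresponds to the pixel at offset
    ``(col - p, row - p)`` from the patch center (u = column, v = row).

    ``method="midpoint"`` uses an ``subsamples x subsamples`` midpoint rule
    per pixel with a disk indicator; ``method="exact"`` integrates the inner
    (y) direction in closed form and the outer direction adaptively, which
    is what the shipped masks use (the midpoint rule converges only like
    ``subsamples**-1.5`` at the circle boundary).
    """
    _check_nm(n, m)
    if patch_size < 3 or patch_size % 2 == 0:
        raise ValueError(f"patch_size must be an odd integer >= 3, got {patch_size}")
    if method not in ("midpoint", "exact"):
        raise ValueError(f"method must be 'midpoint' or 'exact', got {method!r}")
    npx = patch_size
    if method == "exact":
        width = 2.0 / npx
        p = (npx - 1) // 2
        block = np.zeros((npx, npx), dtype=complex)
        for row in range(npx):
            y1 = (row - p) * width - width / 2.0
            for col in range(npx):
                x1 = (col - p) * width - width / 2.0
                block[row, col] = _pixel_integral_exact(
                    n, m, x1, x1 + width, y1, y1 + width
                )
    else:
        if subsamples < 1:
            raise ValueError(f"subsamples must be >= 1, got {subsamples}")
        s = subsamples
        # Midpoints of an (Np*s) x (Np*s) subgrid spanning [-1, 1]^2.
        t = (np.arange(npx * s) + 0.5) * (2.0 / (npx * s)) - 1.0
        uu, vv = np.meshgrid(t, t)  # vv varies along rows
        inside = uu * uu + vv * vv <= 1.0
        vals = _eval_nm_grid(n, m, uu, vv)
        vals = np.where(inside, vals, 0.0)
        cell_area = (2.0 / npx) ** 2 / (s * s)
        block = vals.reshape(npx, s, npx, s).sum(axis=(1, 3)) * cell_area
    if m == 0:
        return block.real.copy()
    return block.real.copy(), block.imag.copy()


@dataclass(frozen=True)
class ZernikeMaskSet:
    """Discrete masks for the A11 and A20 moments on one patch size.

    ``im_m11`` is stored for validation only; the localization path uses
    ``re_m11`` and its transpose.  ``subsamples == 0`` marks masks built
    with the exact (semi-analytic) pixel integration.
    """

    patch_size: int
    subsamples: int
    re_m11: np.ndarray
    im_m11: np.ndarray
    m20: np.ndarray

    def __post_init__(self):
        for name in ("re_m11", "im_m11", "m20"):
            arr = getattr(self, name)
            if arr.shape != (self.patch_size, self.patch_size):
                raise ValueError(f"{name} has shape {arr.shape}, "
                                 f"expected ({self.patch_size}, {self.patch_size})")

    @property
    def half_width(self) -> int:
        return (self.patch_size - 1) // 2

    @property
    def q11(self) -> float:
        return normalization_coefficient(1, 1)

    @property
    def q20(self) -> float:
        return normalization_coefficient(2, 0)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in ("re_m11", "im_m11", "m20"):
            h.update(np.ascontiguousarray(getattr(self, name)).tobytes())
        return h.hexdigest()


def _build_mask_set(patch_size: int, subsamples: int) -> ZernikeMaskSet:
    if subsamples == 0:
        re_m11, im_m11 = build_mask(1, 1, patch_size, method="exact")
        m20 = build_mask(2, 0, patch_size, method="exact")
    else:
        re_m11, im_m11 = build_mask(1, 1, patch_size, subsamples)
        m20 = build_mask(2, 0, patch_size, subsamples)
    return ZernikeMaskSet(
        patch_size=patch_size,
        subsamples=subsamples,
        re_m11=re_m11,
        im_m11=im_m11,
        m20=m20,
    )


def save_mask_set(masks: ZernikeMaskSet, path) -> None:
    """Write a mask set as JSON with hex floats (bit-exact round trip)."""
    payload = {
        "patch_size": masks.patch_size,
        "subsamples": masks.subsamples,
        "checksum": masks.checksum(),
    }
    for name in ("re_m11", "im_m11", "m20"):
        arr = getattr(masks, name)
        payload[name] = [[float(x).hex() for x in row] for row in arr]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_mask_set(path) -> ZernikeMaskSet:
    payload = json.loads(Path(path).read_text())
    arrays = {
        name: np.array(
            [[float.fromhex(x) for x in row] for row in payload[name]], dtype=float
        )
        for name in ("re_m11", "im_m11", "m20")
    }
    masks = ZernikeMaskSet(
        patch_size=int(payload["patch_size"]),
        subsamples=int(payload["subsamples"]),
        **arrays,
    )
    if masks.checksum() != payload["checksum"]:
        raise ValueError(f"mask fixture {path} failed its checksum")
    return masks


def _fixture_path(patch_size: int):
    return resources.files("zernloc.data") / "masks" / f"np{patch_size}.json"


@lru_cache(maxsize=None)
def mask_set(patch_size: int, subsamples: int = 0) -> ZernikeMaskSet:
    """Masks for ``patch_size``, from the shipped fixture when one matches.

    The default (``subsamples=0``) is exact pixel integration; pass a
    positive subsample count for the midpoint-rule variant.
    """
    try:
        fixture = _fixture_path(patch_size)
        if fixture.is_file():
            masks = load_mask_set(fixture)
            if masks.subsamples == subsamples:
                return masks
    except (FileNotFoundError, ModuleNotFoundError):
        pass
    return _build_mask_set(patch_size, subsamples)
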