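import math

import numpy as np
import pytest

from zernloc.zernike import mask_set


@pytest.fixture(scope="session")
def masks5():
    return mask_set(5)


@pytest.fixture(scope="session")
def masks7():
    return mask_set(7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def render_disk_patch(profile, patch_size=5, psi=0.0, supersample=64):
    """Area-averaged Np x Np patch of a 1-D intensity profile on the disk.

    ``profile`` maps the feature-normal coordinate u' (disk units) to
    intensity; the feature normal is rotated by ``psi`` in the patch frame.
    Used as the rendering oracle for moment tests.
    """
    npx, s = patch_size, supersample
    t = (np.arange(npx * s) + 0.5) * (2.0 / (npx * s)) - 1.0
    uu, vv = np.meshgrid(t, t)
    u_prime = uu * math.cos(psi) + vv * math.sin(psi)
    vals = profile(u_prime)
    return vals.reshape(npx, s, npx, s).mean(axis=(1, 3))


def disk_moments_quad(profile, breakpoints=None):
    """Independent 1-D-reduced quadrature of the disk moments of a profile.

    Integrates the numeric profile (not the closed forms) against the first
    and second basis functions, with the cross-disk direction integrated in
    closed form.  ``breakpoints`` flags profile kinks so narrow features are
    not missed by the adaptive rule.
    """
    from scipy.integrate import quad

    pts = None
    if breakpoints is not None:
        pts = sorted(p for p in breakpoints if -1 < p < 1)
    chord = lambda x: 2.0 * np.sqrt(max(0.0, 1.0 - x * x))
    a11 = quad(lambda x: profile(x) * x * chord(x), -1, 1,
               limit=400, points=pts)[0]
    a20 = quad(
        lambda x: profile(x)
        * ((2 * x * x - 1) * chord(x) + (chord(x) ** 3) / 6.0),
        -1, 1, limit=400, points=pts,
    )[0]
    return a11, a20


def disk_moments_dblquad(profile2d):
    """Fully 2-D adaptive quadrature of (A11', A20') over the unit disk."""
    from scipy.integrate import dblquad

    lim = lambda x: math.sqrt(max(0.0, 1.0 - x * x))
    a11 = dblquad(lambda y, x: profile2d(x, y) * x,
                  -1, 1, lambda x: -lim(x), lim)[0]
    a20 = dblquad(lambda y, x: profile2d(x, y) * (2 * (x * x + y * y) - 1),
                  -1, 1, lambda x: -lim(x), lim)[0]
    return a11, a20
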