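"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from veinmorph.synth import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_mask(rng, shape=(24, 24), density=0.4):
    return (rng.random(shape) < density).astype(np.uint8)


def tilted_band_spec(length, tilt_deg, thickness, n_gaps=0, n_holes=0,
                     speckle=0.0, seed=0, gap_len_px=8):
    """Straight-band phantom spec of given arc length and tilt."""
    dx = length * math.cos(math.radians(tilt_deg))
    dy = length * math.sin(math.radians(tilt_deg))
    m = 2 * thickness
    p0 = (m + 20.0, m + 20.0)
    return PhantomSpec(
        canvas=(int(dy) + 2 * m + 40, int(dx) + 2 * m + 40),
        centerline=(p0, (p0[0] + dx, p0[1] + dy)),
        thickness=thickness,
        n_gaps=n_gaps,
        gap_len_px=gap_len_px,
        n_holes=n_holes,
        speckle_density=speckle,
        seed=seed,
    )


@pytest.fixture
def horizontal_band():
    """Clean horizontal capsule band, L=400, T=20, plus its truth."""
    spec = PhantomSpec(
        canvas=(120, 520), centerline=((60.0, 60.0), (460.0, 60.0)),
        thickness=20, n_gaps=0, n_holes=0, speckle_density=0.0, seed=3,
    )
    rgb, mask, truth = generate_phantom(spec)
    return spec, mask, truth


# ---------------------------------------------------------------------------
# independent oracles


def brute_hull_vertices(points):
    """O(n^3) extreme-point oracle: a point is a hull vertex iff it lies
    neither inside a non-degenerate triangle of other points nor strictly
    between two other points on a segment."""
    pts = np.array(sorted(set(map(tuple, points))), dtype=float)
    n = len(pts)
    if n <= 2:
        return {(int(x), int(y)) for x, y in pts}
    out = set()
    for i in range(n):
        p = pts[i]
        others = np.delete(np.arange(n), i)
        if len(others) >= 3:
            tri = np.array(list(combinations(others, 3)))
            a, b, c = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
            area = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
            d1 = (b[:, 0] - a[:, 0]) * (p[1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (p[0] - a[:, 0])
            d2 = (c[:, 0] - b[:, 0]) * (p[1] - b[:, 1]) - (c[:, 1] - b[:, 1]) * (p[0] - b[:, 0])
            d3 = (a[:, 0] - c[:, 0]) * (p[1] - c[:, 1]) - (a[:, 1] - c[:, 1]) * (p[0] - c[:, 0])
            in_tri = (((d1 >= 0) & (d2 >= 0) & (d3 >= 0)) | ((d1 <= 0) & (d2 <= 0) & (d3 <= 0))) & (area != 0)
            if in_tri.any():
                continue
        pair = np.array(list(combinations(others, 2)))
        a2, b2 = pts[pair[:, 0]], pts[pair[:, 1]]
        cr = (b2[:, 0] - a2[:, 0]) * (p[1] - a2[:, 1]) - (b2[:, 1] - a2[:, 1]) * (p[0] - a2[:, 0])
        dot = (p[0] - a2[:, 0]) * (b2[:, 0] - a2[:, 0]) + (p[1] - a2[:, 1]) * (b2[:, 1] - a2[:, 1])
        seg2 = (b2[:, 0] - a2[:, 0]) ** 2 + (b2[:, 1] - a2[:, 1]) ** 2
        if ((cr == 0) & (dot > 0) & (dot < seg2)).any():
            continue
        out.add((int(p[0]), int(p[1])))
    return out


def otsu_oracle(img):
    """Exhaustive 256-level search maximizing w0*w1*(u0-u1)^2 directly on
    the two pixel classes."""
    g = np.asarray(img).ravel().astype(float)
    best, bestk = -1.0, None
    for k in range(256):
        lo, hi = g[g <= k], g[g > k]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0 = len(lo) / len(g)
        v = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2
        if v > best + 1e-12:
            best, bestk = v, k
    return bestk


def interior_background_components(mask):
    """Count background components not touching the raster border."""
    from scipy import ndimage

    m = np.asarray(mask)
    bg = m == 0
    lab, _ = ndimage.label(bg, structure=ndimage.generate_binary_structure(2, 1))
    border = np.zeros_like(bg)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(lab[border & bg]))
    return len(set(np.unique(lab[bg])) - border_labels - {0})
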