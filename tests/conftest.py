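"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive re-implementations (pure-Python
loops, full enumeration) used to cross-check the package; they never call
into the code paths they verify.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest


def naive_score(pixels, bit_depth, rect_fraction, alpha, beta, pixel_threshold):
    """Straightforward per-pixel scorer: background mean over the centered
    rectangle, subtract/clip, linear contrast, clip to [0, 255], count
    pixels >= threshold.  Pure Python loops, no vectorization."""
    h = len(pixels)
    w = len(pixels[0])
    scale = 257.0 if bit_depth == 16 else 1.0
    img = [[float(pixels[i][j]) / scale for j in range(w)] for i in range(h)]

    rh = max(1, int(math.floor(rect_fraction * h + 0.5)))
    rw = max(1, int(math.floor(rect_fraction * w + 0.5)))
    top = (h - rh) // 2
    left = (w - rw) // 2
    total = 0.0
    for i in range(top, top + rh):
        for j in range(left, left + rw):
            total += img[i][j]
    background = total / (rh * rw)

    score = 0
    for i in range(h):
        for j in range(w):
            v = img[i][j] - background
            if v < 0.0:
                v = 0.0
            v = v * alpha + beta
            if v < 0.0:
                v = 0.0
            elif v > 255.0:
                v = 255.0
            if v >= pixel_threshold:
                score += 1
    return score, background


def enumerate_mann_whitney(a, b):
    """Exact two-sided Mann-Whitney by full enumeration of all
    C(n_a + n_b, n_a) group assignments (tie-free inputs only)."""
    a, b = list(a), list(b)
    pooled = a + b
    na, nb = len(a), len(b)
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"

    def u_of(group_a):
        rest = list(pooled)
        ga = list(group_a)
        for x in ga:
            rest.remove(x)
        return sum(1 for x in ga for y in rest if x > y)

    u_obs = sum(1 for x in a for y in b if x > y)
    lo, hi = min(u_obs, na * nb - u_obs), max(u_obs, na * nb - u_obs)
    n_extreme = 0
    n_total = 0
    for idx in combinations(range(na + nb), na):
        u = u_of([pooled[i] for i in idx])
        n_total += 1
        if u <= lo or u >= hi:
            n_extreme += 1
    return u_obs, min(1.0, n_extreme / n_total)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_well():
    """A deterministic 64x64 synthetic well with two patches, no noise."""
    from organoscore.synthetic import SyntheticWellSpec, render_well

    spec = SyntheticWellSpec(
        image_size=(64, 64),
        organoid_radius_px=20,
        organoid_intensity=40.0,
        patches=(((26, 26), 4, 100.0), ((38, 38), 4, 100.0)),
        background_level=10.0,
        noise_sd=0.0,
    )
    return render_well(spec)
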