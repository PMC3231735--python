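import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_images(rng):
    """A batch of small random integer-valued test images."""
    return [
        rng.integers(0, 256, (16, 16)).astype(float) for _ in range(20)
    ]


# ---------------------------------------------------------------------------
# Independent oracle helpers: naive per-pixel re-implementations kept free of
# any import from the package's vectorised code paths.
# ---------------------------------------------------------------------------

def naive_bilinear(image, rr, cc):
    r0, c0 = int(math.floor(rr)), int(math.floor(cc))
    r0 = min(max(r0, 0), image.shape[0] - 2)
    c0 = min(max(c0, 0), image.shape[1] - 2)
    fr, fc = rr - r0, cc - c0
    return (
        image[r0, c0] * (1 - fr) * (1 - fc)
        + image[r0, c0 + 1] * (1 - fr) * fc
        + image[r0 + 1, c0] * fr * (1 - fc)
        + image[r0 + 1, c0 + 1] * fr * fc
    )


def naive_neighbors(image, row, col, n, r):
    vals = []
    for l in range(n):
        theta = 2.0 * math.pi * l / n
        dr = -r * math.sin(theta)
        dc = r * math.cos(theta)
        if abs(dr - round(dr)) < 1e-9:
            dr = round(dr)
        if abs(dc - round(dc)) < 1e-9:
            dc = round(dc)
        vals.append(naive_bilinear(image, row + dr, col + dc))
    return vals


def naive_transitions(code, n):
    bits = [(code >> l) & 1 for l in range(n)]
    return sum(bits[l] != bits[(l + 1) % n] for l in range(n))


def naive_uniform_bins(n):
    """code -> bin map: uniform codes in ascending order, catch-all last."""
    uniform = [c for c in range(2**n) if naive_transitions(c, n) <= 2]
    table = {c: len(uniform) for c in range(2**n)}
    for idx, c in enumerate(uniform):
        table[c] = idx
    return table, len(uniform)


def naive_band(intensity, tau=5.0, big_r=26.0):
    return tau if intensity < big_r else math.sqrt(intensity)


def naive_ternary_digit(diff, band):
    if diff >= band:
        return 1
    if diff <= -band:
        return -1
    return 0
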