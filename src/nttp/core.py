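"""Noise tolerant ternary pattern (NTTP) codes and feature vectors.

A local pattern code compares a pixel ``c`` with ``n`` neighbours on a
circle of radius ``r``.  NTTP thresholds each signed difference
``g_l - g_c`` against the adaptive noise band of the *center* pixel:
differences at or above ``+ANB(g_c)`` contribute +1, at or below
``-ANB(g_c)`` contribute -1, anything inside the band is 0.  The
ternary code is split losslessly into an upper binary code (the +1
bits) and a lower binary code (the -1 bits); a separate center bit
records whether ``g_c`` is at least the mean gray level of the whole
image.

The feature vector accumulates two 2-D histograms, center-bit x
uniform-pattern-index, one over the upper codes and one over the lower
codes, flattens each center-major, normalises each to unit sum and
concatenates upper-part then lower-part.  With n = 8 this gives
2 segments x 2 center states x 59 uniform bins = 236 dimensions.

Conventions (fixed so the baseline descriptors are bit-compatible):
images are (row, col) arrays with row increasing downward; neighbour
l = 0 sits east of the center, subsequent neighbours proceed
counter-clockwise; bit l has weight 2**l; off-grid samples are
bilinearly interpolated; pixels within ceil(r) of a border are not
coded, but the whole-image mean for the center bit uses every pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .noise_band import NoiseBandParams, anb_map

__all__ = [
    "NeighborhoodSpec",
    "TernaryCodeMaps",
    "UniformLookup",
    "FeatureVector",
    "sample_neighbors",
    "sample_neighbor_stack",
    "nttp_codes",
    "center_code",
    "uniform_index",
    "uniform_lookup",
    "build_feature_vector",
    "extract_nttp",
]

_ALLOWED_N = (4, 8, 16, 24)
_ALLOWED_R = (1, 2, 3, 4)


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Circular sampling geometry: ``n`` neighbours at radius ``r``."""

    n: int = 8
    r: int = 2

    def __post_init__(self) -> None:
        if self.n not in _ALLOWED_N:
            raise ValueError(f"n must be one of {_ALLOWED_N}")
        if self.r not in _ALLOWED_R:
            raise ValueError(f"r must be one of {_ALLOWED_R}")

    @property
    def margin(self) -> int:
        return math.ceil(self.r)

    def offsets(self) -> np.ndarray:
        """(n, 2) array of (d_row, d_col) sample displacements.

        Angles are measured from east, counter-clockwise on the screen,
        which with row-down image coordinates means d_row = -r sin(theta).
        Near-integer components are snapped so axial neighbours are read
        exactly rather than through degenerate interpolation.
        """
        ls = np.arange(self.n)
        theta = 2.0 * np.pi * ls / self.n
        off = np.stack([-self.r * np.sin(theta), self.r * np.cos(theta)], axis=1)
        snapped = np.round(off)
        off = np.where(np.abs(off - snapped) < 1e-9, snapped, off)
        return off


@dataclass
class TernaryCodeMaps:
    """Per-pixel upper/lower binary codes plus the center bit.

    ``upper`` and ``lower`` are integer maps over the interior (codable)
    pixels; ``center`` is the 0/1 map of the same shape; ``margin`` is
    the excluded border width; ``n`` the neighbour count.
    """

    upper: np.ndarray
    lower: np.ndarray
    center: np.ndarray
    margin: int
    n: int

    def ternary(self) -> np.ndarray:
        """Reconstruct base-3 ternary code values from the split codes.

        Digit l is +1 where the upper bit is set, -1 where the lower bit
        is set, 0 elsewhere; the map returns sum over l of digit * 3**l
        (so it can go negative, matching a direct evaluation of the
        ternary definition).
        """
        out = np.zeros(self.upper.shape, dtype=np.int64)
        for l in range(self.n):
            up = (self.upper >> l) & 1
            lo = (self.lower >> l) & 1
            out += (up.astype(np.int64) - lo.astype(np.int64)) * 3**l
        return out


class UniformLookup:
    """Map n-bit codes to uniform-pattern histogram bins.

    A circular binary code is *uniform* when it has at most two 0/1
    transitions; there are n*(n-1) + 2 such codes (58 for n = 8).  Each
    uniform code gets its own bin, indexed by ascending numeric code
    value; every non-uniform code shares the final catch-all bin, for
    n*(n-1) + 3 bins in total (59 for n = 8).
    """

    def __init__(self, n: int):
        if n not in _ALLOWED_N:
            raise ValueError(f"n must be one of {_ALLOWED_N}")
        self.n = n
        codes = np.arange(2**n, dtype=np.uint32)
        trans = _transition_counts(n)
        uniform = trans <= 2
        self.n_uniform = int(uniform.sum())
        self.n_bins = self.n_uniform + 1
        table = np.full(2**n, self.n_uniform, dtype=np.int64)
        table[uniform] = np.arange(self.n_uniform)
        self.table = table
        self._codes = codes

    def __getitem__(self, code):
        code = np.asarray(code)
        if code.size and ((code < 0).any() or (code >= 2**self.n).any()):
            raise ValueError(f"code out of range for n={self.n}")
        return self.table[code]


def _transition_counts(n: int) -> np.ndarray:
    codes = np.arange(2**n, dtype=np.uint32)
    rot = ((codes >> 1) | ((codes & 1) << (n - 1))) & ((1 << n) - 1)
    diff = codes ^ rot
    return np.array([bin(int(d)).count("1") for d in diff])


@lru_cache(maxsize=8)
def uniform_lookup(n: int) -> UniformLookup:
    """Cached :class:`UniformLookup` for a given neighbour count."""
    return UniformLookup(n)


def uniform_index(code: int, n: int) -> int:
    """Uniform-pattern bin index of a single n-bit code."""
    lut = uniform_lookup(n)
    return int(lut[np.asarray(code)])


@dataclass
class FeatureVector:
    """Concatenation of normalised histogram segments with layout metadata.

    ``layout`` holds one (segment_name, center_bit, bin_index) triple per
    entry; center_bit is -1 for segments without a center axis.
    """

    values: np.ndarray
    layout: list

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureVector)
            and self.layout == other.layout
            and np.array_equal(self.values, other.values)
        )


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if image.size == 0:
        raise ValueError("empty image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return image


def sample_neighbor_stack(image: np.ndarray, spec: NeighborhoodSpec) -> np.ndarray:
    """Bilinear neighbour samples for every interior pixel.

    Returns an array of shape (n, H - 2m, W - 2m) where m is the margin:
    plane l holds the l-th neighbour's interpolated intensity for each
    codable pixel.
    """
    image = _validate_image(image)
    m = spec.margin
    h, w = image.shape
    if h < 2 * m + 1 or w < 2 * m + 1:
        raise ValueError(f"image too small for radius {spec.r}")
    rows = np.arange(m, h - m, dtype=float)
    cols = np.arange(m, w - m, dtype=float)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty((spec.n,) + rr.shape)
    for l, (dr, dc) in enumerate(spec.offsets()):
        out[l] = _bilinear(image, rr + dr, cc + dc)
    return out


def _bilinear(image: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    r0 = np.floor(rr).astype(int)
    c0 = np.floor(cc).astype(int)
    r0 = np.clip(r0, 0, image.shape[0] - 2)
    c0 = np.clip(c0, 0, image.shape[1] - 2)
    fr = rr - r0
    fc = cc - c0
    # nested-lerp form: exact on constant patches (no weight round-off)
    top = image[r0, c0] + fc * (image[r0, c0 + 1] - image[r0, c0])
    bot = image[r0 + 1, c0] + fc * (image[r0 + 1, c0 + 1] - image[r0 + 1, c0])
    return top + fr * (bot - top)


def sample_neighbors(
    image: np.ndarray, pixel: tuple[int, int], spec: NeighborhoodSpec
) -> np.ndarray:
    """Ordered neighbour intensities for one pixel (row, col)."""
    image = _validate_image(image)
    m = spec.margin
    r, c = pixel
    if not (m <= r < image.shape[0] - m and m <= c < image.shape[1] - m):
        raise ValueError(f"pixel {pixel} within margin {m} of the border")
    off = spec.offsets()
    return _bilinear(
        image, np.full(spec.n, float(r)) + off[:, 0], np.full(spec.n, float(c)) + off[:, 1]
    )


def _split_codes(diffs: np.ndarray, band: np.ndarray, n: int):
    """Upper/lower binary codes from signed differences vs a band map."""
    weights = (1 << np.arange(n, dtype=np.int64))[:, None, None]
    upper = ((diffs >= band) * weights).sum(axis=0)
    lower = ((diffs <= -band) * weights).sum(axis=0)
    return upper, lower


def nttp_codes(
    image: np.ndarray,
    spec: NeighborhoodSpec | None = None,
    params: NoiseBandParams | None = None,
) -> TernaryCodeMaps:
    """Upper/lower NTTP code maps plus the center-bit map.

    The band is evaluated at the center pixel's intensity, so one pixel
    applies one threshold to all its neighbour differences.  Comparisons
    are inclusive: the upper bit fires at ``diff >= band``, the lower at
    ``diff <= -band`` (with a zero band both fire on equality, which is
    why the LBP-equivalence hook uses the upper code only).
    """
    spec = spec or NeighborhoodSpec()
    params = params or NoiseBandParams()
    image = _validate_image(image)
    samples = sample_neighbor_stack(image, spec)
    m = spec.margin
    centers = image[m:-m, m:-m]
    band = anb_map(centers, params)[None, :, :]
    upper, lower = _split_codes(samples - centers[None], band, spec.n)
    return TernaryCodeMaps(
        upper=upper,
        lower=lower,
        center=center_code(image)[m:-m, m:-m],
        margin=m,
        n=spec.n,
    )


def center_code(image: np.ndarray) -> np.ndarray:
    """Center bit: 1 where a pixel is at least the whole-image mean gray level."""
    image = _validate_image(image)
    return (image >= image.mean()).astype(np.int64)


def build_feature_vector(
    codes: TernaryCodeMaps, lookup: UniformLookup | None = None
) -> FeatureVector:
    """Assemble the concatenated joint-histogram feature vector.

    Two 2-D histograms are accumulated over all coded pixels, center
    bit against the uniform index of the upper (resp. lower) code; each
    is flattened center-major, normalised to unit sum and the upper part
    concatenated before the lower part.
    """
    lookup = lookup or uniform_lookup(codes.n)
    if lookup.n != codes.n:
        raise ValueError("lookup n does not match code maps")
    if codes.upper.size == 0:
        raise ValueError("no coded pixels")
    b = lookup.n_bins
    parts = []
    layout = []
    for name, code_map in (("U", codes.upper), ("L", codes.lower)):
        bins = lookup[code_map]
        joint = np.zeros((2, b))
        np.add.at(joint, (codes.center.ravel(), bins.ravel()), 1.0)
        flat = joint.reshape(-1)
        parts.append(flat / flat.sum())
        layout.extend((name, c, k) for c in range(2) for k in range(b))
    return FeatureVector(values=np.concatenate(parts), layout=layout)


def extract_nttp(
    image: np.ndarray,
    spec: NeighborhoodSpec | None = None,
    params: NoiseBandParams | None = None,
) -> FeatureVector:
    """Full NTTP descriptor of an image (code maps + histogram assembly)."""
    spec = spec or NeighborhoodSpec()
    codes = nttp_codes(image, spec, params)
    return build_feature_vector(codes, uniform_lookup(spec.n))
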