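"""Baseline local-pattern descriptors: LBP, LTP, LBPV and the CLBP family.

All descriptors share the sampling geometry, bit order and uniform
lookup of :mod:`nttp.core`, so the constant-band equivalences hold
bit-exactly: NTTP with a zero band reproduces LBP in its upper code,
and with a constant band alpha reproduces the LTP split codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    FeatureVector,
    NeighborhoodSpec,
    TernaryCodeMaps,
    UniformLookup,
    center_code,
    sample_neighbor_stack,
    uniform_lookup,
)

__all__ = [
    "LTPParams",
    "CLBPScheme",
    "lbp_codes",
    "lbp_histogram",
    "lbp_feature",
    "ltp_split_codes",
    "ltp_feature",
    "lbpv_feature",
    "clbp_feature",
]


@dataclass(frozen=True)
class LTPParams:
    """Fixed ternary threshold; differences within ±alpha code as 0."""

    alpha: float = 5.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


_SCHEMES = ("smc", "sc", "mc", "m_sc", "s_mc")


@dataclass(frozen=True)
class CLBPScheme:
    """How the CLBP sign (S), magnitude (M) and center (C) codes combine.

    ``smc`` builds the joint 3-D histogram C x S x M; ``sc``/``mc`` are
    2-D joints of one code with the center bit; ``m_sc`` flattens the
    S/C joint then concatenates the M histogram (``s_mc`` symmetric).
    ``encoding`` selects full 2**n codes (the original formulation) or
    uniform-pattern binning.
    """

    combination: str = "smc"
    encoding: str = "full"

    def __post_init__(self) -> None:
        if self.combination not in _SCHEMES:
            raise ValueError(f"combination must be one of {_SCHEMES}")
        if self.encoding not in ("full", "uniform"):
            raise ValueError("encoding must be 'full' or 'uniform'")


def _weights(n: int) -> np.ndarray:
    return (1 << np.arange(n, dtype=np.int64))[:, None, None]


def lbp_codes(image: np.ndarray, spec: NeighborhoodSpec | None = None) -> np.ndarray:
    """Per-pixel LBP codes: bit l set where neighbour l >= center."""
    spec = spec or NeighborhoodSpec()
    samples = sample_neighbor_stack(image, spec)
    m = spec.margin
    centers = np.asarray(image, dtype=float)[m:-m, m:-m]
    return ((samples - centers[None] >= 0) * _weights(spec.n)).sum(axis=0)


def lbp_histogram(
    codes: np.ndarray, lookup: UniformLookup | None = None, n: int = 8
) -> FeatureVector:
    """Normalised histogram of a code map.

    With a lookup the 59-bin uniform histogram is built (bins indexed by
    the lookup); without one the raw 2**n-bin histogram.
    """
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("empty code map")
    if lookup is not None:
        n = lookup.n
        binned = lookup[codes].ravel()
        n_bins = lookup.n_bins
    else:
        binned = codes.ravel()
        n_bins = 2**n
    hist = np.bincount(binned, minlength=n_bins).astype(float)
    return FeatureVector(
        values=hist / hist.sum(),
        layout=[("H", -1, k) for k in range(n_bins)],
    )


def lbp_feature(
    image: np.ndarray, spec: NeighborhoodSpec | None = None, uniform: bool = True
) -> FeatureVector:
    """LBP descriptor: uniform 59-bin histogram by default."""
    spec = spec or NeighborhoodSpec()
    codes = lbp_codes(image, spec)
    return lbp_histogram(codes, uniform_lookup(spec.n) if uniform else None, spec.n)


def ltp_split_codes(
    image: np.ndarray,
    spec: NeighborhoodSpec | None = None,
    params: LTPParams | None = None,
) -> TernaryCodeMaps:
    """LTP upper/lower binary code maps under the fixed threshold alpha.

    The ternary digit is +1 at ``diff >= alpha``, -1 at ``diff <= -alpha``
    and 0 between; the split stores the +1 bits and the -1 bits in two
    binary codes.  The center map is carried along for layout
    compatibility but is not part of the LTP descriptor.
    """
    spec = spec or NeighborhoodSpec()
    params = params or LTPParams()
    samples = sample_neighbor_stack(image, spec)
    m = spec.margin
    centers = np.asarray(image, dtype=float)[m:-m, m:-m]
    diffs = samples - centers[None]
    w = _weights(spec.n)
    upper = ((diffs >= params.alpha) * w).sum(axis=0)
    lower = ((diffs <= -params.alpha) * w).sum(axis=0)
    return TernaryCodeMaps(
        upper=upper,
        lower=lower,
        center=center_code(image)[m:-m, m:-m],
        margin=m,
        n=spec.n,
    )


def ltp_feature(
    image: np.ndarray,
    spec: NeighborhoodSpec | None = None,
    params: LTPParams | None = None,
) -> FeatureVector:
    """LTP descriptor: the two uniform histograms concatenated (118-dim for n=8)."""
    spec = spec or NeighborhoodSpec()
    codes = ltp_split_codes(image, spec, params)
    lut = uniform_lookup(spec.n)
    parts, layout = [], []
    for name, cmap in (("U", codes.upper), ("L", codes.lower)):
        hist = np.bincount(lut[cmap].ravel(), minlength=lut.n_bins).astype(float)
        parts.append(hist / hist.sum())
        layout.extend((name, -1, k) for k in range(lut.n_bins))
    return FeatureVector(values=np.concatenate(parts), layout=layout)


def lbpv_feature(
    image: np.ndarray, spec: NeighborhoodSpec | None = None, uniform: bool = True
) -> FeatureVector:
    """LBP-variance descriptor.

    The code is plain LBP, but each pixel contributes the population
    variance of its n sampled neighbour intensities to its histogram
    bin instead of a unit count.  A perfectly flat image has zero total
    weight and yields the all-zero vector.
    """
    spec = spec or NeighborhoodSpec()
    samples = sample_neighbor_stack(image, spec)
    m = spec.margin
    centers = np.asarray(image, dtype=float)[m:-m, m:-m]
    codes = ((samples - centers[None] >= 0) * _weights(spec.n)).sum(axis=0)
    weights = samples.var(axis=0)
    if uniform:
        lut = uniform_lookup(spec.n)
        binned = lut[codes].ravel()
        n_bins = lut.n_bins
    else:
        binned = codes.ravel()
        n_bins = 2**spec.n
    hist = np.bincount(binned, weights=weights.ravel(), minlength=n_bins)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return FeatureVector(
        values=hist, layout=[("H", -1, k) for k in range(n_bins)]
    )


def clbp_feature(
    image: np.ndarray,
    spec: NeighborhoodSpec | None = None,
    scheme: CLBPScheme | None = None,
) -> FeatureVector:
    """Completed LBP descriptor under the requested combination scheme.

    CLBP_S is the sign code (identical to LBP); CLBP_M thresholds the
    absolute differences |g_l - g_c| against their image-wide mean t,
    taken over all coded pixels' neighbour differences; CLBP_C compares
    the center intensity with the whole-image mean gray level.
    """
    spec = spec or NeighborhoodSpec()
    scheme = scheme or CLBPScheme()
    samples = sample_neighbor_stack(image, spec)
    m = spec.margin
    centers = np.asarray(image, dtype=float)[m:-m, m:-m]
    diffs = samples - centers[None]
    w = _weights(spec.n)
    s_codes = ((diffs >= 0) * w).sum(axis=0)
    mags = np.abs(diffs)
    t = mags.mean()
    m_codes = ((mags >= t) * w).sum(axis=0)
    c_bits = center_code(image)[m:-m, m:-m]

    if scheme.encoding == "uniform":
        lut = uniform_lookup(spec.n)
        s_bins, m_bins = lut[s_codes], lut[m_codes]
        nb = lut.n_bins
    else:
        s_bins, m_bins = s_codes, m_codes
        nb = 2**spec.n

    c = c_bits.ravel()
    s = s_bins.ravel()
    g = m_bins.ravel()

    def _joint(*axes_and_sizes):
        idx = 0
        for arr, size in axes_and_sizes:
            idx = idx * size + arr
        length = int(np.prod([size for _, size in axes_and_sizes]))
        hist = np.bincount(idx, minlength=length).astype(float)
        return hist / hist.sum()

    comb = scheme.combination
    if comb == "smc":
        values = _joint((c, 2), (s, nb), (g, nb))
        layout = [("SMC", -1, k) for k in range(values.size)]
        return FeatureVector(values=values, layout=layout)
    if comb == "sc":
        values = _joint((c, 2), (s, nb))
        return FeatureVector(values, [("SC", -1, k) for k in range(values.size)])
    if comb == "mc":
        values = _joint((c, 2), (g, nb))
        return FeatureVector(values, [("MC", -1, k) for k in range(values.size)])
    if comb == "m_sc":
        joint = _joint((c, 2), (s, nb))
        mh = np.bincount(g, minlength=nb).astype(float)
        values = np.concatenate([joint, mh / mh.sum()])
        layout = [("SC", -1, k) for k in range(joint.size)] + [
            ("M", -1, k) for k in range(nb)
        ]
        return FeatureVector(values, layout)
    # s_mc
    joint = _joint((c, 2), (g, nb))
    sh = np.bincount(s, minlength=nb).astype(float)
    values = np.concatenate([joint, sh / sh.sum()])
    layout = [("MC", -1, k) for k in range(joint.size)] + [
        ("S", -1, k) for k in range(nb)
    ]
    return FeatureVector(values, layout)
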