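"""Adaptive noise band (ANB) estimation.

Digital images carry signal-dependent sensor noise (photon shot noise)
whose standard deviation grows roughly with the square root of the
recorded intensity, plus a floor of signal-independent noise (read
noise, dark current) that dominates at low intensities.  The adaptive
noise band approximates the plausible noise excursion around a pixel of
intensity ``i`` as

    ANB(i) = tau        if i <  R
    ANB(i) = sqrt(i)    if i >= R

where ``R`` is the intensity at which the signal-dependent component
overtakes the constant floor, and ``tau`` is the half-width of that
floor.  Intensity differences smaller than the band are treated as
noise rather than texture by the NTTP descriptor.

The square-root approximation is valid whenever the signal-to-noise
ratio gamma = f/delta exceeds a bound that follows from requiring the
observed signal to dominate the noise; at the top of the 8-bit range
(f = 255) the bound evaluates to gamma >= 15.47655.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseBandParams",
    "NoiseEstimate",
    "NoiseEstimationError",
    "anb",
    "anb_map",
    "snr_lower_bound",
    "estimate_noise_boundary",
]

DEFAULT_TAU = 5.0
DEFAULT_R = 26.0


@dataclass(frozen=True)
class NoiseBandParams:
    """Parameters governing the per-pixel noise band.

    Parameters
    ----------
    tau : float
        Constant band half-width used below the region boundary, in
        intensity units.  Default 5.
    R : float
        Intensity at which signal-dependent noise overtakes the
        constant floor, in [0, 255].  Default 26.
    mode : {"adaptive", "constant"}
        ``adaptive`` applies the two-branch band above; ``constant``
        returns ``beta`` for every intensity (a hook that collapses the
        descriptor onto fixed-threshold baselines: beta=0 reproduces
        LBP, beta=alpha reproduces LTP).
    beta : float
        Band width in ``constant`` mode; ignored otherwise.
    """

    tau: float = DEFAULT_TAU
    R: float = DEFAULT_R
    mode: str = "adaptive"
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive", "constant"):
            raise ValueError(f"unknown band mode {self.mode!r}")
        if self.mode == "adaptive" and self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.R <= 255.0:
            raise ValueError("R must lie in [0, 255]")
        if self.mode == "constant" and self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass
class NoiseEstimate:
    """Result of single-image noise characterisation.

    Attributes
    ----------
    constant_sigma : float
        Mean noise SD of homogeneous low-intensity patches (the flat
        region of the photon-transfer characteristic, in image space).
    sdn_slope : float
        Coefficient ``a`` of the signal-dependent fit ``sigma = a*sqrt(i)``.
        Zero when no signal-dependent region was detected.
    sdn_intercept : float
        Intercept of the signal-dependent fit (kept at 0 for the
        through-origin square-root model).
    R_hat : float
        Estimated boundary intensity where the two noise curves cross,
        clamped to [0, 255].
    n_patches : int
        Number of homogeneous patches used.
    """

    constant_sigma: float
    sdn_slope: float
    R_hat: float
    sdn_intercept: float = 0.0
    n_patches: int = 0


class NoiseEstimationError(ValueError):
    """Raised when an image does not support noise-boundary estimation."""


def anb(intensity: float, params: NoiseBandParams | None = None) -> float:
    """Adaptive noise band half-width at a single intensity.

    Returns ``tau`` below the boundary ``R`` and ``sqrt(intensity)`` at
    or above it (``beta`` in constant mode).  The square root is kept
    continuous; integer displays elsewhere are rounding only.

    Raises
    ------
    ValueError
        If ``intensity`` falls outside [0, 255].
    """
    if params is None:
        params = NoiseBandParams()
    if not 0.0 <= intensity <= 255.0:
        raise ValueError(f"intensity {intensity} outside [0, 255]")
    if params.mode == "constant":
        return params.beta
    if intensity < params.R:
        return params.tau
    return math.sqrt(intensity)


def anb_map(intensities: np.ndarray, params: NoiseBandParams | None = None) -> np.ndarray:
    """Vectorised :func:`anb` over an intensity array."""
    if params is None:
        params = NoiseBandParams()
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size and (intensities.min() < 0 or intensities.max() > 255):
        raise ValueError("intensities outside [0, 255]")
    if params.mode == "constant":
        return np.full_like(intensities, params.beta)
    return np.where(intensities < params.R, params.tau, np.sqrt(intensities))


def snr_lower_bound(f_max: float) -> float:
    """Minimal signal-to-noise ratio gamma for the square-root band to hold.

    Solving f <= gamma**2 + gamma for gamma gives
    ``(-1 + sqrt(1 + 4*f)) / 2``; at the 8-bit maximum f = 255 this is
    15.47655.  The bound is the exact inverse of f = gamma**2 + gamma.
    """
    if f_max < 0:
        raise ValueError("f_max must be non-negative")
    return (-1.0 + math.sqrt(1.0 + 4.0 * f_max)) / 2.0


# internal constants of the boundary estimator
_N_STRATA = 16          # intensity strata for per-stratum homogeneity selection
_LOW_QUANTILE = 0.10    # patches below this intensity quantile define the floor
_HIGH_QUANTILE = 0.50   # patches above this quantile feed the sqrt fit
_SDN_FACTOR = 1.5       # SD must exceed floor by this factor to count as
                        # signal-dependent; below it the curves are deemed
                        # non-intersecting and R_hat is clamped to 255
_MIN_PATCHES = 20
_MIN_SDN_PATCHES = 5


def estimate_noise_boundary(
    image: np.ndarray,
    patch_size: int = 8,
    homogeneity_quantile: float = 0.5,
) -> NoiseEstimate:
    """Estimate the low-intensity region boundary R from one image.

    The image is tiled into ``patch_size`` squares; within each
    intensity stratum only the most homogeneous patches (lowest SD
    fraction ``homogeneity_quantile``) are kept so that texture-laden
    patches do not masquerade as noise.  The constant noise floor is
    the mean SD of homogeneous patches in the lowest intensity decile;
    a through-origin curve ``sigma = a*sqrt(i)`` is fitted to the
    homogeneous patches of the upper intensity half whose SD clearly
    exceeds the floor.  The two curves cross at ``(sigma_c/a)**2``,
    which is returned clamped to [0, 255].  When no patch shows
    signal-dependent noise the curves never intersect below the
    dynamic-range maximum and R_hat is 255.

    Raises
    ------
    NoiseEstimationError
        If the image tiles into fewer than 20 patches, has no intensity
        spread, or shows no measurable noise.
    """
    image = np.asarray(image, dtype=float)
    if not 0 < patch_size <= min(image.shape):
        raise NoiseEstimationError("patch_size larger than image")
    nr = image.shape[0] // patch_size
    nc = image.shape[1] // patch_size
    if nr * nc < _MIN_PATCHES:
        raise NoiseEstimationError(
            f"image tiles into only {nr * nc} patches; need >= {_MIN_PATCHES}"
        )
    tiles = image[: nr * patch_size, : nc * patch_size].reshape(
        nr, patch_size, nc, patch_size
    ).transpose(0, 2, 1, 3).reshape(nr * nc, -1)
    means = tiles.mean(axis=1)
    sds = tiles.std(axis=1)

    if means.max() - means.min() < 1.0:
        raise NoiseEstimationError("no intensity spread across patches")
    if sds.max() <= 1e-12:
        raise NoiseEstimationError("image is noiseless; no SD signal to fit")

    # per-stratum homogeneity selection
    edges = np.linspace(means.min(), means.max() + 1e-9, _N_STRATA + 1)
    keep = np.zeros(means.size, dtype=bool)
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_stratum = (means >= lo) & (means < hi)
        if not in_stratum.any():
            continue
        cutoff = np.quantile(sds[in_stratum], homogeneity_quantile)
        keep |= in_stratum & (sds <= cutoff)
    h_means, h_sds = means[keep], sds[keep]
    if h_means.size < _MIN_PATCHES // 2:
        raise NoiseEstimationError(
            f"only {h_means.size} homogeneous patches found"
        )

    low_cut = np.quantile(h_means, _LOW_QUANTILE)
    low = h_means <= low_cut
    constant_sigma = float(h_sds[low].mean())

    high_cut = np.quantile(h_means, _HIGH_QUANTILE)
    sdn = (h_means >= high_cut) & (h_sds >= _SDN_FACTOR * max(constant_sigma, 1e-12))
    if sdn.sum() < _MIN_SDN_PATCHES:
        # constant noise dominates everywhere: curves never cross in range
        return NoiseEstimate(
            constant_sigma=constant_sigma,
            sdn_slope=0.0,
            R_hat=255.0,
            n_patches=int(h_means.size),
        )

    root_i = np.sqrt(h_means[sdn])
    slope = float((h_sds[sdn] * root_i).sum() / (root_i * root_i).sum())
    r_hat = float(np.clip((constant_sigma / slope) ** 2, 0.0, 255.0))
    return NoiseEstimate(
        constant_sigma=constant_sigma,
        sdn_slope=slope,
        R_hat=r_hat,
        n_patches=int(h_means.size),
    )
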