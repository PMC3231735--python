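"""Seeded parametric textures and sensor-noise injection.

The generator stands in for photographic texture databases so that the
descriptors and the noise-robustness experiment run without any
downloads.  Four texture families cover the qualitative range of
natural micro-patterns: oriented sinusoidal gratings (periodic edges),
checkerboards (sharp corners), Gaussian random fields (smooth cluttered
texture) and blob fields (spots).  Noise models mirror a CCD/CMOS
sensor: additive white Gaussian noise with standard deviation sigma,
photon shot noise as a scaled Poisson process whose SD grows as
sqrt(gain * intensity) — the regime the adaptive noise band is built
for — and the mixture of both.  All randomness flows from explicit
integer seeds, so identical specifications reproduce identical pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import classify as _classify
from .descriptors import get_descriptor

__all__ = [
    "SyntheticSpec",
    "NoiseSpec",
    "TextureBenchmark",
    "generate_texture",
    "add_noise",
    "make_benchmark",
    "noise_robustness_benchmark",
    "FAMILIES",
]

FAMILIES = ("grating", "checkerboard", "grf", "blobs")

# benchmark conditions for the noise-robustness experiment: a 4-class
# problem with 40 samples per class, shot noise at unit gain plus
# Gaussian noise of SD 8 on the test half only
BENCHMARK_N_CLASSES = 4
BENCHMARK_SAMPLES_PER_CLASS = 40
BENCHMARK_SIGMA = 8.0
BENCHMARK_GAIN = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parametric texture description; identical spec + seed => identical image.

    ``params`` carries the family-specific knobs: ``period`` and
    ``orientation`` (radians) for gratings and checkerboards,
    ``corr_length`` for Gaussian random fields, ``density`` and
    ``radius`` for blob fields.  ``base`` and ``contrast`` set the mean
    level and amplitude in 8-bit intensity units; output is clamped to
    [0, 255].
    """

    family: str = "grating"
    size: int = 64
    base: float = 128.0
    contrast: float = 60.0
    seed: int = 0
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.size < 4:
            raise ValueError("size too small")

    def param_dict(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor noise model: gaussian(sigma), poisson_shot(gain) or mixed."""

    model: str = "gaussian"
    sigma: float = 8.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "poisson_shot", "mixed"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


def generate_texture(spec: SyntheticSpec) -> np.ndarray:
    """Render one texture image as a float array in [0, 255]."""
    rng = np.random.default_rng(spec.seed)
    p = spec.param_dict()
    size = spec.size
    yy, xx = np.mgrid[0:size, 0:size].astype(float)

    if spec.family == "grating":
        period = p.get("period", 8.0)
        theta = p.get("orientation", 0.0)
        phase = p.get("phase", 0.0)
        if period <= 0:
            raise ValueError("period must be positive")
        u = xx * np.cos(theta) + yy * np.sin(theta)
        img = spec.base + spec.contrast * np.sin(2 * np.pi * u / period + phase)
    elif spec.family == "checkerboard":
        period = p.get("period", 8.0)
        ox, oy = p.get("offset", (0.0, 0.0))
        if period <= 0:
            raise ValueError("period must be positive")
        cx = np.floor((xx + ox) / period).astype(int)
        cy = np.floor((yy + oy) / period).astype(int)
        img = spec.base + spec.contrast * np.where((cx + cy) % 2 == 0, 1.0, -1.0)
    elif spec.family == "grf":
        corr = p.get("corr_length", 3.0)
        if corr <= 0:
            raise ValueError("corr_length must be positive")
        from scipy.ndimage import gaussian_filter

        field_ = gaussian_filter(rng.standard_normal((size, size)), corr, mode="wrap")
        sd = field_.std()
        if sd > 0:
            field_ = field_ / sd
        img = spec.base + spec.contrast * field_
    else:  # blobs
        density = p.get("density", 0.02)
        radius = p.get("radius", 3.0)
        if density < 0 or radius <= 0:
            raise ValueError("invalid blob parameters")
        n_blobs = rng.poisson(density * size * size)
        img = np.full((size, size), spec.base - spec.contrast)
        for _ in range(n_blobs):
            r0, c0 = rng.uniform(0, size, 2)
            mask = (yy - r0) ** 2 + (xx - c0) ** 2 <= radius**2
            img[mask] = spec.base + spec.contrast

    return np.clip(img, 0.0, 255.0)


def add_noise(image: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Inject sensor noise; output is clamped back to [0, 255].

    Gaussian noise adds N(0, sigma^2) per pixel; shot noise resamples
    each pixel as gain * Poisson(i / gain), whose SD is approximately
    sqrt(gain * i); mixed applies shot noise first, then Gaussian.
    """
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(noise.seed)
    out = image
    if noise.model in ("poisson_shot", "mixed"):
        out = rng.poisson(np.clip(out, 0, None) / noise.gain) * noise.gain
    if noise.model in ("gaussian", "mixed") and noise.sigma > 0:
        out = out + rng.normal(0.0, noise.sigma, size=image.shape)
    return np.clip(out, 0.0, 255.0)


@dataclass
class TextureBenchmark:
    """Labelled train/test image halves produced by :func:`make_benchmark`."""

    train_images: list
    train_labels: np.ndarray
    test_images: list
    test_labels: np.ndarray


def _class_spec(class_idx: int, size: int, base: float, contrast: float) -> SyntheticSpec:
    """Canonical per-class texture: cycle families and shift parameters."""
    family = FAMILIES[class_idx % len(FAMILIES)]
    scale = 1 + class_idx // len(FAMILIES)
    if family == "grating":
        params = (("period", 6.0 * scale), ("orientation", 0.3 * class_idx))
    elif family == "checkerboard":
        params = (("period", 6.0 * scale),)
    elif family == "grf":
        params = (("corr_length", 2.0 * scale),)
    else:
        params = (("density", 0.02 / scale), ("radius", 2.5 * scale))
    return SyntheticSpec(
        family=family, size=size, base=base, contrast=contrast, params=params
    )


def _jitter(spec: SyntheticSpec, rng: np.random.Generator) -> SyntheticSpec:
    """Per-sample nuisance variation within a class: phase/offset/seed."""
    p = spec.param_dict()
    if spec.family == "grating":
        p["phase"] = rng.uniform(0, 2 * np.pi)
        p["orientation"] = p.get("orientation", 0.0) + rng.normal(0, 0.05)
    elif spec.family == "checkerboard":
        p["offset"] = tuple(rng.uniform(0, p.get("period", 8.0), 2))
    return replace(
        spec,
        params=tuple(sorted(p.items())),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_benchmark(
    n_classes: int = BENCHMARK_N_CLASSES,
    samples_per_class: int = BENCHMARK_SAMPLES_PER_CLASS,
    size: int = 64,
    base: float = 128.0,
    contrast: float = 60.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> TextureBenchmark:
    """Build a labelled texture dataset with disjoint train/test halves.

    Each class is one canonical texture with per-sample nuisance jitter
    (phase, grid offset, realisation seed).  When a ``noise`` spec is
    given it corrupts the *test* half only, probing descriptor
    robustness against a train/test noise mismatch.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if samples_per_class < 2:
        raise ValueError("need at least two samples per class")
    rng = np.random.default_rng(seed)
    train_images, train_labels, test_images, test_labels = [], [], [], []
    half = samples_per_class // 2
    for ci in range(n_classes):
        spec = _class_spec(ci, size, base, contrast)
        for si in range(samples_per_class):
            img = generate_texture(_jitter(spec, rng))
            if si < half:
                train_images.append(img)
                train_labels.append(ci)
            else:
                if noise is not None:
                    img = add_noise(
                        img, replace(noise, seed=int(rng.integers(0, 2**31 - 1)))
                    )
                test_images.append(img)
                test_labels.append(ci)
    return TextureBenchmark(
        train_images, np.asarray(train_labels), test_images, np.asarray(test_labels)
    )


def noise_robustness_benchmark(
    descriptors=("nttp", "ltp", "lbp"),
    seeds=(0, 1, 2, 3, 4),
    n_classes: int = BENCHMARK_N_CLASSES,
    samples_per_class: int = BENCHMARK_SAMPLES_PER_CLASS,
    size: int = 64,
    sigma: float = BENCHMARK_SIGMA,
    gain: float = BENCHMARK_GAIN,
    descriptor_kwargs: dict | None = None,
) -> dict:
    """Accuracy of each descriptor on the noisy synthetic benchmark.

    For every seed a fresh benchmark is generated with shot-plus-Gaussian
    noise on the test images; each descriptor's features feed the
    chi-square nearest-neighbour classifier.  Returns per-seed accuracy
    arrays and their means, keyed by descriptor name.
    """
    descriptor_kwargs = descriptor_kwargs or {}
    per_seed: dict = {name: [] for name in descriptors}
    for seed in seeds:
        noise = NoiseSpec(model="mixed", sigma=sigma, gain=gain, seed=seed)
        bench = make_benchmark(
            n_classes=n_classes,
            samples_per_class=samples_per_class,
            size=size,
            noise=noise,
            seed=seed,
        )
        for name in descriptors:
            fn = get_descriptor(name, **descriptor_kwargs.get(name, {}))
            train = _classify.LabeledDataset(
                [fn(im) for im in bench.train_images], bench.train_labels
            )
            pred = _classify.classify_all(
                train, [fn(im) for im in bench.test_images]
            )
            per_seed[name].append(_classify.accuracy(pred, bench.test_labels))
    return {
        name: {"per_seed": np.asarray(v), "mean": float(np.mean(v))}
        for name, v in per_seed.items()
    }
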