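"""Descriptor registry: map a name to an image -> FeatureVector callable."""

from __future__ import annotations

from .baselines import (
    CLBPScheme,
    LTPParams,
    clbp_feature,
    lbp_feature,
    lbpv_feature,
    ltp_feature,
)
from .core import NeighborhoodSpec, extract_nttp
from .noise_band import NoiseBandParams

__all__ = ["DESCRIPTOR_NAMES", "get_descriptor", "parse_descriptor_name"]

DESCRIPTOR_NAMES = ("nttp", "lbp", "ltp", "lbpv", "clbp")


def parse_descriptor_name(name: str) -> tuple[str, str | None]:
    """Split names like ``clbp:smc`` into (descriptor, scheme)."""
    base, _, scheme = name.partition(":")
    if base not in DESCRIPTOR_NAMES:
        raise ValueError(
            f"unknown descriptor {base!r}; choose from {DESCRIPTOR_NAMES}"
        )
    return base, scheme or None


def get_descriptor(
    name: str,
    spec: NeighborhoodSpec | None = None,
    band: NoiseBandParams | None = None,
    ltp: LTPParams | None = None,
    scheme: CLBPScheme | None = None,
):
    """Return a callable computing the named descriptor's feature vector."""
    base, scheme_name = parse_descriptor_name(name)
    spec = spec or NeighborhoodSpec()
    if base == "nttp":
        band = band or NoiseBandParams()
        return lambda image: extract_nttp(image, spec, band)
    if base == "lbp":
        return lambda image: lbp_feature(image, spec)
    if base == "ltp":
        ltp = ltp or LTPParams()
        return lambda image: ltp_feature(image, spec, ltp)
    if base == "lbpv":
        return lambda image: lbpv_feature(image, spec)
    scheme = scheme or CLBPScheme(combination=scheme_name or "smc")
    return lambda image: clbp_feature(image, spec, scheme)
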