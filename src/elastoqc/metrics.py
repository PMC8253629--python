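"""Elastography image-quality metrics: SNRe, CNRe, growth rates, strain ratio.

SNRe is the mean-to-standard-deviation ratio of a uniform region and tracks
the signal-to-noise level of the image.  CNRe compares a feature (lesion)
region against an equal-size background region, normalized by the two region
variances, and tracks lesion detectability.  The growth rates SNRe' and
CNRe' are the percent change of the respective metric between the original
and the denoised image.  The strain ratio SR is the background-to-feature
ratio of mean axial strain on an elastography strain image and proxies
relative lesion stiffness.

Two CNRe normalizations circulate in the elastography literature:

    linear_root :  2 (mu_a - mu_b)   / sqrt(sigma_a^2 + sigma_b^2)   (default)
    squared     :  2 (mu_a - mu_b)^2 /      (sigma_a^2 + sigma_b^2)

Both are implemented behind ``variant``; every report records which one was
used.  Degenerate regions (zero standard deviation where the metric divides
by it) raise :class:`DegenerateRegionError` rather than returning infinities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .imagecore import Image, Region, RegionStats, region_stats

CnreVariant = Literal["linear_root", "squared"]


class DegenerateRegionError(ValueError):
    """A region's statistics make the requested metric undefined."""


def snre(image: Image, region: Region, ddof: int = 0) -> float:
    """Elastic signal-to-noise ratio: region mean / region std."""
    st = region_stats(image, region, ddof=ddof)
    if st.std == 0.0:
        raise DegenerateRegionError(
            f"region {region.name or region.shape} has zero standard deviation"
        )
    return st.mean / st.std


def _check_equal_size(image_shape, feature: Region, background: Region) -> None:
    na = feature.pixel_count(image_shape)
    nb = background.pixel_count(image_shape)
    if na != nb:
        raise DegenerateRegionError(
            f"feature and background masks must be equal-size, got {na} vs {nb}"
        )


def cnre(
    image: Image,
    feature: Region,
    background: Region,
    variant: CnreVariant = "linear_root",
    ddof: int = 0,
) -> float:
    """Elastic contrast-to-noise ratio between equal-size feature/background regions."""
    _check_equal_size(image.pixels.shape, feature, background)
    a = region_stats(image, feature, ddof=ddof)
    b = region_stats(image, background, ddof=ddof)
    denom_sq = a.std**2 + b.std**2
    if denom_sq == 0.0:
        raise DegenerateRegionError("both regions have zero standard deviation")
    if variant == "linear_root":
        return 2.0 * (a.mean - b.mean) / math.sqrt(denom_sq)
    if variant == "squared":
        return 2.0 * (a.mean - b.mean) ** 2 / denom_sq
    raise ValueError(f"unknown CNRe variant {variant!r}")


def growth_rate(before: float, after: float) -> float:
    """Percent growth of a metric: 100 * (after / before - 1)."""
    if before <= 0:
        raise ValueError(f"growth rate needs a positive baseline, got {before}")
    return 100.0 * (after / before - 1.0)


def strain_ratio(strain_image: Image, feature: Region, background: Region) -> float:
    """Mean strain in the background region over mean strain in the feature region.

    Stiff lesions strain less than the surrounding tissue, so SR > 1 indicates
    a lesion stiffer than background.  Both region means must be positive and
    the two masks equal-size.
    """
    _check_equal_size(strain_image.pixels.shape, feature, background)
    bg = region_stats(strain_image, background)
    ft = region_stats(strain_image, feature)
    if bg.mean <= 0 or ft.mean <= 0:
        raise DegenerateRegionError(
            f"strain ratio requires positive region means, got bg={bg.mean}, feat={ft.mean}"
        )
    return bg.mean / ft.mean


@dataclass(frozen=True)
class MetricReport:
    """Before/after SNRe and CNRe over one ROI pair, plus percent growth rates."""

    snre_before: float
    snre_after: float
    cnre_before: float
    cnre_after: float
    snre_growth: float
    cnre_growth: float
    filter_label: str
    cnre_variant: CnreVariant
    feature_roi: dict
    background_roi: dict
    sr: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MetricReport":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def metric_report(
    before: Image,
    after: Image,
    feature: Region,
    background: Region,
    label: str = "",
    variant: CnreVariant = "linear_root",
    strain_image: Image | None = None,
) -> MetricReport:
    """Compute the full before/after metric panel for one filtering run.

    SNRe is evaluated on the background (uniform-tissue) region.  Growth
    rates are recomputed from the stored before/after values, so the report
    is internally consistent by construction.
    """
    if before.pixels.shape != after.pixels.shape:
        raise ValueError(
            f"before/after image dimensions differ: {before.pixels.shape} vs {after.pixels.shape}"
        )
    s_before = snre(before, background)
    s_after = snre(after, background)
    c_before = cnre(before, feature, background, variant=variant)
    c_after = cnre(after, feature, background, variant=variant)
    sr = None
    if strain_image is not None:
        sr = strain_ratio(strain_image, feature, background)
    return MetricReport(
        snre_before=s_before,
        snre_after=s_after,
        cnre_before=c_before,
        cnre_after=c_after,
        snre_growth=growth_rate(s_before, s_after),
        cnre_growth=growth_rate(c_before, c_after),
        filter_label=label,
        cnre_variant=variant,
        feature_roi=feature.to_dict(),
        background_roi=background.to_dict(),
        sr=sr,
    )
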