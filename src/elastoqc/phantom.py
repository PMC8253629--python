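"""Synthetic ultrasound speckle phantoms with known ground truth.

A phantom is a uniform tissue background with one embedded disc lesion.
The clean image has two intensity levels (``background_level`` and
``background_level * lesion_contrast`` inside the lesion); the noisy image
multiplies it by fully-developed-speckle noise modeled as unit-mean Gamma
variates with shape ``L`` ("looks"), optionally plus additive Gaussian
read noise.

Under this model a uniform region of the noisy image has mean equal to the
clean level and standard deviation level / sqrt(L), so the region SNRe of
the raw speckled image is sqrt(L) — which is the generator's own acceptance
check: measuring SNRe on the background ROI must recover sqrt(L).

The bundle also places an equal-size, non-overlapping feature/background
ROI pair (the geometry the CNRe definition requires): a disc concentric
with the lesion at 70% of its radius, and an equal-radius disc centered on
the same image row out in the background.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
import json
from pathlib import Path

import numpy as np

from .imagecore import Image, Region


class PhantomError(ValueError):
    """Invalid phantom geometry or noise parameters."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise parameters of one synthetic phantom."""

    height: int = 256
    width: int = 256
    background_level: float = 0.4
    lesion_center: tuple[int, int] = (128, 90)
    lesion_radius: float = 40.0
    lesion_contrast: float = 2.0
    speckle_looks: float = 4.0
    additive_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level <= 0:
            raise PhantomError(f"background_level must be positive, got {self.background_level}")
        if self.lesion_contrast <= 0:
            raise PhantomError(f"lesion_contrast must be positive, got {self.lesion_contrast}")
        if self.speckle_looks <= 0:
            raise PhantomError(f"speckle_looks must be positive, got {self.speckle_looks}")
        if self.additive_sigma < 0:
            raise PhantomError(f"additive_sigma must be >= 0, got {self.additive_sigma}")
        r, c = self.lesion_center
        rad = self.lesion_radius
        margin = 2
        if (
            r - rad < margin
            or c - rad < margin
            or r + rad > self.height - 1 - margin
            or c + rad > self.width - 1 - margin
        ):
            raise PhantomError(
                f"lesion (center {self.lesion_center}, radius {rad}) must fit inside "
                f"the {self.height}x{self.width} image with a 2-pixel margin"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PhantomSpec":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["lesion_center"] = tuple(d["lesion_center"])
        return cls(**d)


@dataclass(frozen=True)
class PhantomBundle:
    """Clean/noisy image pair plus the equal-size ROI pair used by the metrics."""

    clean: Image
    noisy: Image
    feature_roi: Region
    background_roi: Region
    spec: PhantomSpec


def _roi_pair(spec: PhantomSpec) -> tuple[Region, Region]:
    """Concentric feature disc at 70% lesion radius; equal-radius background
    disc on the same row, clear of the lesion boundary."""
    lr, lc = spec.lesion_center
    roi_r = 0.7 * spec.lesion_radius
    feature = Region(
        shape="disc", role="feature", name="lesion-core", center=(lr, lc), radius=roi_r
    )
    gap = 4.0
    # place on whichever side of the lesion has more room
    right_col = lc + spec.lesion_radius + gap + roi_r
    left_col = lc - spec.lesion_radius - gap - roi_r
    if right_col + roi_r <= spec.width - 1.5:
        bc = right_col
    elif left_col - roi_r >= 0.5:
        bc = left_col
    else:
        raise PhantomError("no room for an equal-size background ROI beside the lesion")
    # same row and same radius: integer-offset translate of the feature disc,
    # so the two masks have identical pixel counts
    background = Region(
        shape="disc",
        role="background",
        name="tissue",
        center=(lr, round(bc)),
        radius=roi_r,
    )
    return feature, background


def _clean_pixels(spec: PhantomSpec, lesion_level: float) -> np.ndarray:
    ii, jj = np.mgrid[0 : spec.height, 0 : spec.width]
    lr, lc = spec.lesion_center
    inside = (ii - lr) ** 2 + (jj - lc) ** 2 <= spec.lesion_radius**2
    px = np.full((spec.height, spec.width), spec.background_level, dtype=np.float64)
    px[inside] = lesion_level
    return px


def _apply_noise(clean: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    L = spec.speckle_looks
    speckle = rng.gamma(shape=L, scale=1.0 / L, size=clean.shape)
    noisy = clean * speckle
    if spec.additive_sigma > 0:
        noisy = noisy + rng.normal(0.0, spec.additive_sigma, size=clean.shape)
    return noisy


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate the clean/noisy lesion phantom for ``spec`` (deterministic in seed)."""
    lesion_level = spec.background_level * spec.lesion_contrast
    clean_px = _clean_pixels(spec, lesion_level)
    noisy_px = _apply_noise(clean_px, spec)
    vr = (min(0.0, float(noisy_px.min())), max(1.0, float(noisy_px.max())))
    feature, background = _roi_pair(spec)
    return PhantomBundle(
        clean=Image(clean_px, value_range=vr),
        noisy=Image(noisy_px, value_range=vr),
        feature_roi=feature,
        background_roi=background,
        spec=spec,
    )


def strain_phantom(spec: PhantomSpec, strain_contrast: float) -> PhantomBundle:
    """Synthetic axial-strain image: a stiff lesion strains less than background.

    The lesion level is background_level / strain_contrast, so the strain
    ratio (background mean / feature mean) of the clean image equals
    ``strain_contrast`` exactly by construction.
    """
    if strain_contrast <= 0:
        raise PhantomError(f"strain_contrast must be positive, got {strain_contrast}")
    lesion_level = spec.background_level / strain_contrast
    clean_px = _clean_pixels(spec, lesion_level)
    noisy_px = _apply_noise(clean_px, spec)
    vr = (min(0.0, float(noisy_px.min())), max(1.0, float(noisy_px.max())))
    feature, background = _roi_pair(spec)
    return PhantomBundle(
        clean=Image(clean_px, value_range=vr),
        noisy=Image(noisy_px, value_range=vr),
        feature_roi=feature,
        background_roi=background,
        spec=spec,
    )


def reseed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    """Copy of ``spec`` with a different noise seed."""
    return replace(spec, seed=seed)
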