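"""Colour deconvolution of brightfield H-DAB images.

Brightfield stains obey Beer-Lambert absorption: stain amounts add linearly
in optical density (OD = -log10 of the transmission fraction), so an RGB
pixel is a linear mixture of per-stain OD "signature" vectors.  Unmixing is
the inversion of the 3x3 matrix whose rows are those signatures
(hematoxylin, DAB, and a residual completion vector).

Default signatures are the widely used H-DAB pair of Ruifrok & Johnston as
distributed with the ImageJ colour-deconvolution plugin; they are
configurable because they are calibration constants, not physical laws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = float(np.linalg.norm(v))
    if norm <= 0:
        raise ConfigurationError("stain vector must be non-zero")
    return v / norm


#: Published H-DAB absorbance signatures (RGB optical-density space, unit norm).
HEMATOXYLIN_OD = _unit((0.650, 0.704, 0.286))
DAB_OD = _unit((0.269, 0.568, 0.778))


@dataclass(frozen=True)
class RasterField:
    """One RGB brightfield field image.

    ``pixels`` is (rows, cols, 3) with intensities in [0, 255].  Files on
    disk are 8-bit; in memory a float array is accepted so that
    synthetically rendered fields can be analysed without quantisation.
    """

    pixels: np.ndarray
    field_id: str = ""
    microns_per_pixel: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise ValueError("pixels must be a non-empty (rows, cols, 3) array")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


class StainSystem:
    """Hematoxylin/DAB/residual stain basis and its inversion machinery.

    The residual vector is the normalised cross product of the two stain
    signatures (the standard orthogonal completion), so the 3x3 OD matrix is
    always invertible for non-collinear stains.
    """

    def __init__(self, hematoxylin=HEMATOXYLIN_OD, dab=DAB_OD):
        s_h = _unit(hematoxylin)
        s_d = _unit(dab)
        residual = np.cross(s_h, s_d)
        norm = float(np.linalg.norm(residual))
        if norm < 1e-6:
            raise ConfigurationError("hematoxylin and DAB vectors are collinear")
        self.hematoxylin = s_h
        self.dab = s_d
        self.residual = residual / norm
        self.matrix = np.vstack([s_h, s_d, self.residual])
        cond = np.linalg.cond(self.matrix)
        if not np.isfinite(cond):
            raise ConfigurationError("stain matrix is singular")
        self.inverse = np.linalg.inv(self.matrix)

    @classmethod
    def from_config(cls, config: dict) -> "StainSystem":
        """Build from a ``{"stains": {"hematoxylin": [...], "dab": [...]}}`` mapping."""
        stains = config.get("stains", config)
        return cls(
            hematoxylin=stains.get("hematoxylin", HEMATOXYLIN_OD),
            dab=stains.get("dab", DAB_OD),
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"StainSystem(hematoxylin={np.round(self.hematoxylin, 3).tolist()}, "
            f"dab={np.round(self.dab, 3).tolist()})"
        )


def to_optical_density(image, i0: float = 255.0, eps: float = 1.0) -> np.ndarray:
    """Per-pixel optical density OD_c = log10(I0 / max(I_c, eps)).

    ``eps`` clamps fully absorbed pixels so the logarithm stays finite; with
    the default eps = 1 and I0 = 255 the maximum representable OD is
    log10(255) ~= 2.407 per channel.
    """
    if i0 <= 0:
        raise ValueError("I0 must be positive")
    px = image.pixels if isinstance(image, RasterField) else np.asarray(image)
    px = np.maximum(px.astype(float), eps)
    return np.log10(i0 / px)


@dataclass(frozen=True)
class UnmixedImage:
    """Per-pixel stain concentrations from colour deconvolution.

    ``hematoxylin``/``dab``/``residual`` are clipped at zero for direct use
    in thresholding; ``raw`` keeps the signed solution of the linear system
    for diagnostics and exact OD reconstruction.
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray
    raw: np.ndarray


def unmix(od: np.ndarray, stains: StainSystem | None = None) -> UnmixedImage:
    """Invert the stain matrix: OD = c @ M with rows S_H, S_D, S_R.

    Negative concentrations (noise pushing a pixel outside the stain
    simplex) are clipped to zero in the named channels and retained in
    ``raw``.
    """
    stains = stains or StainSystem()
    od = np.asarray(od, dtype=float)
    raw = od @ stains.inverse
    clipped = np.clip(raw, 0.0, None)
    return UnmixedImage(
        hematoxylin=clipped[..., 0],
        dab=clipped[..., 1],
        residual=clipped[..., 2],
        raw=raw,
    )


def compose(concentrations: np.ndarray, stains: StainSystem | None = None) -> np.ndarray:
    """Rebuild per-pixel OD from (..., 3) raw concentrations (round trip of :func:`unmix`)."""
    stains = stains or StainSystem()
    return np.asarray(concentrations, dtype=float) @ stains.matrix


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Transmitted intensity I_c = I0 * 10**(-OD_c), clipped to [0, 255]."""
    return np.clip(i0 * np.power(10.0, -np.asarray(od, dtype=float)), 0.0, 255.0)


def white_balance(image: RasterField, percentile: float = 99.0, i0: float = 255.0) -> RasterField:
    """Optional shading correction: scale each channel so its bright
    background (the given percentile) maps to ``i0``.

    Synthetic renders need none of this; real scans with uneven illumination
    may.  Off by default throughout the pipeline.
    """
    px = image.pixels.astype(float)
    ref = np.percentile(px.reshape(-1, 3), percentile, axis=0)
    ref = np.maximum(ref, 1.0)
    balanced = np.clip(px * (i0 / ref), 0.0, 255.0)
    return RasterField(balanced, field_id=image.field_id,
                       microns_per_pixel=image.microns_per_pixel)
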