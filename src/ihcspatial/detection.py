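"""Thresholding, mask clean-up, positive-cell detection and Area%.

The DAB concentration channel is thresholded into an immunoreactive-area
mask and the hematoxylin channel into a nuclei mask; nuclei whose overlap
with the immunoreactive mask exceeds a fraction of their area are called
marker-positive and reduced to their centroids.  Area% is the fraction of
field pixels covered by the immunoreactive mask, times 100.

Centroids use the package-wide raster convention: x = column, y = row,
pixel centers at integer coordinates, origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .errors import DegenerateHistogramError, ShapeMismatchError
from .geometry import PointPattern, Window


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster with a provenance tag (which stain produced it)."""

    pixels: np.ndarray
    stain: str = "dab"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


def threshold_channel(channel: np.ndarray, method: str = "otsu",
                      threshold: float | None = None, stain: str = "dab") -> BinaryMask:
    """Binarise a concentration channel.

    ``method='otsu'`` picks the threshold maximising between-class variance
    of the channel histogram; ``method='fixed'`` uses ``threshold`` as
    given.  Pixels strictly above the threshold are foreground.
    """
    channel = np.asarray(channel, dtype=float)
    if method == "otsu":
        if np.unique(channel).size < 2:
            raise DegenerateHistogramError(
                "Otsu thresholding needs at least two distinct values; "
                "use method='fixed' for constant images"
            )
        t = float(threshold_otsu(channel))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold value")
        t = float(threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryMask(channel > t, stain=stain)


def clean_mask(mask: BinaryMask, min_area: int = 0, opening_radius: int = 0) -> BinaryMask:
    """Morphological opening followed by small-object removal."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    px = mask.pixels
    if opening_radius > 0:
        px = ndimage.binary_opening(px, structure=disk(opening_radius))
    if min_area > 0:
        labels, n_comp = ndimage.label(px)
        if n_comp:
            sizes = np.bincount(labels.ravel())
            small = np.flatnonzero(sizes < min_area)
            px = px & ~np.isin(labels, small[small > 0])
    return BinaryMask(px, stain=mask.stain)


def detect_positive_cells(nuclei_mask: BinaryMask, immuno_mask: BinaryMask,
                          min_overlap_fraction: float = 0.5,
                          split_touching: bool = False,
                          field_id: str = "", marker: str = "synthetic") -> PointPattern:
    """Centroids of nuclei co-localised with the immunoreactive area.

    A connected nuclear component is marker-positive when at least
    ``min_overlap_fraction`` of its pixels fall inside ``immuno_mask``.
    ``split_touching`` optionally separates merged nuclei by a
    distance-transform watershed before the overlap test (off by default).
    """
    if nuclei_mask.shape != immuno_mask.shape:
        raise ShapeMismatchError(
            f"mask shapes differ: {nuclei_mask.shape} vs {immuno_mask.shape}"
        )
    nuc = nuclei_mask.pixels
    if split_touching:
        labels = _watershed_labels(nuc)
    else:
        labels = label(nuc)
    immuno = immuno_mask.pixels
    xs: list[float] = []
    ys: list[float] = []
    for region in regionprops(labels):
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        overlap = immuno[rows, cols].mean()
        if overlap >= min_overlap_fraction:
            cy, cx = region.centroid
            xs.append(cx)
            ys.append(cy)
    nrow, ncol = nuclei_mask.shape
    window = Window(float(ncol), float(nrow))
    return PointPattern(np.asarray(xs), np.asarray(ys), window,
                        field_id=field_id, marker=marker)


def _watershed_labels(mask: np.ndarray) -> np.ndarray:
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(dist, labels=mask, min_distance=3, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=int)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    if markers.max() == 0:
        return label(mask)
    return watershed(-dist, markers, mask=mask)


def area_percent(immuno_mask: BinaryMask) -> float:
    """Percent of field pixels covered by the immunoreactive mask."""
    px = immuno_mask.pixels
    if px.size == 0:
        raise ValueError("mask must be non-empty")
    return 100.0 * float(px.sum()) / float(px.size)
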