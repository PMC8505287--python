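"""Synthetic ground-truth data: point patterns, rendered H-DAB fields, cohorts.

Every downstream stage of the pipeline is testable against this module:
point-pattern generators span the clustered -> random -> regular spectrum
with known regime membership, the renderer produces Beer-Lambert two-stain
fields with exact positive/negative nucleus masks, and the cohort generator
reproduces the two-arm study layout (two groups of 15 samples with 10
equal-area fields each) with an independent, reproducible random stream per
field.

All generators condition on the number of points: the Monte-Carlo null used
by the spatial statistics matches the observed count of each field exactly,
so fixed-n patterns are the natural primitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .errors import InvalidSpecError
from .geometry import PointPattern, Window
from .stains import DAB_OD, HEMATOXYLIN_OD, RasterField, od_to_rgb

REGIMES = ("csr", "thomas_cluster", "jittered_lattice", "coincident")


@dataclass(frozen=True)
class PatternSpec:
    """Recipe for one point pattern.

    Parameters
    ----------
    regime : str
        One of ``csr`` (binomial process: complete spatial randomness
        conditioned on n), ``thomas_cluster`` (Gaussian offspring around
        Poisson parents), ``jittered_lattice`` (triangular lattice with
        uniform jitter) or ``coincident`` (all points at one location; the
        maximal-clustering degenerate case).
    n_points : int
        Exact number of points returned.
    parent_intensity : float, optional
        Thomas regime: expected parents per unit window area.
    offspring_spread : float, optional
        Thomas regime: isotropic Gaussian SD of offspring around a parent.
    spacing : float, optional
        Lattice regime: lattice constant; derived from ``n_points`` and the
        window when omitted.
    jitter : float
        Lattice regime: jitter fraction j in [0, 1]; each coordinate is
        perturbed uniformly in [-j*s/2, +j*s/2].
    min_distance : float
        CSR regime: optional hard-core distance enforced by dart throwing
        (used to place non-touching nuclei for rendering).
    seed : int, optional
        Seed of the pattern's own random stream when no generator is passed.
    """

    regime: str
    n_points: int
    parent_intensity: float | None = None
    offspring_spread: float | None = None
    spacing: float | None = None
    jitter: float = 0.0
    min_distance: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise InvalidSpecError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if int(self.n_points) != self.n_points or self.n_points < 0:
            raise InvalidSpecError("n_points must be a non-negative integer")
        if self.regime == "thomas_cluster":
            if self.parent_intensity is None or self.offspring_spread is None:
                raise InvalidSpecError("thomas_cluster needs parent_intensity and offspring_spread")
            if self.parent_intensity <= 0 or self.offspring_spread < 0:
                raise InvalidSpecError("thomas rates/spreads must be non-negative")
        if self.spacing is not None and self.spacing <= 0:
            raise InvalidSpecError("lattice spacing must be positive")
        if not 0.0 <= self.jitter <= 1.0:
            raise InvalidSpecError("jitter fraction must lie in [0, 1]")
        if self.min_distance < 0:
            raise InvalidSpecError("min_distance must be non-negative")


def generate_pattern(spec: PatternSpec, window: Window,
                     rng: np.random.Generator | None = None) -> PointPattern:
    """Draw one point pattern of exactly ``spec.n_points`` points.

    Identical seed (or generator state) gives a bitwise-identical pattern.
    Cluster offspring falling outside the window are resampled until inside,
    keeping both n and the within-cluster spread exact.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = int(spec.n_points)
    if n == 0:
        return PointPattern(np.empty(0), np.empty(0), window)
    if spec.regime == "csr":
        x, y = _csr(n, window, rng, spec.min_distance)
    elif spec.regime == "coincident":
        x0 = rng.uniform(0.0, window.width)
        y0 = rng.uniform(0.0, window.height)
        x, y = np.full(n, x0), np.full(n, y0)
    elif spec.regime == "thomas_cluster":
        x, y = _thomas(n, window, rng, spec.parent_intensity, spec.offspring_spread)
    else:
        x, y = _jittered_lattice(n, window, rng, spec.spacing, spec.jitter)
    return PointPattern(x, y, window)


def _csr(n: int, window: Window, rng: np.random.Generator,
         min_distance: float = 0.0, max_tries: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    if min_distance <= 0:
        return rng.uniform(0, window.width, n), rng.uniform(0, window.height, n)
    # dart throwing with a hard core
    xs: list[float] = []
    ys: list[float] = []
    tries = 0
    d2 = min_distance * min_distance
    while len(xs) < n:
        tries += 1
        if tries > max_tries * n:
            raise InvalidSpecError(
                f"could not place {n} points with min_distance={min_distance} "
                f"in a {window.width}x{window.height} window"
            )
        px = rng.uniform(0, window.width)
        py = rng.uniform(0, window.height)
        if xs:
            dx = np.asarray(xs) - px
            dy = np.asarray(ys) - py
            if (dx * dx + dy * dy).min() < d2:
                continue
        xs.append(px)
        ys.append(py)
    return np.asarray(xs), np.asarray(ys)


def _thomas(n: int, window: Window, rng: np.random.Generator,
            kappa: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    n_parents = max(1, int(rng.poisson(kappa * window.area)))
    px = rng.uniform(0, window.width, n_parents)
    py = rng.uniform(0, window.height, n_parents)
    parent = rng.integers(0, n_parents, n)
    x = px[parent] + rng.normal(0.0, sigma, n)
    y = py[parent] + rng.normal(0.0, sigma, n)
    outside = ~((x >= 0) & (x <= window.width) & (y >= 0) & (y <= window.height))
    while outside.any():
        m = int(outside.sum())
        x[outside] = px[parent[outside]] + rng.normal(0.0, sigma, m)
        y[outside] = py[parent[outside]] + rng.normal(0.0, sigma, m)
        outside = ~((x >= 0) & (x <= window.width) & (y >= 0) & (y <= window.height))
    return x, y


def _lattice_sites(window: Window, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    row_h = spacing * math.sqrt(3.0) / 2.0
    ny = max(1, int(window.height / row_h))
    nx = max(1, int(window.width / spacing))
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    x = (jj + 0.25) * spacing + (ii % 2) * spacing / 2.0
    y = (ii + 0.5) * row_h
    x, y = x.ravel(), y.ravel()
    keep = (x <= window.width) & (y <= window.height)
    return x[keep], y[keep]


def _jittered_lattice(n: int, window: Window, rng: np.random.Generator,
                      spacing: float | None, jitter: float) -> tuple[np.ndarray, np.ndarray]:
    if spacing is None:
        # triangular-lattice spacing whose site density matches n / |W|
        spacing = math.sqrt(2.0 * window.area / (math.sqrt(3.0) * n))
    x, y = _lattice_sites(window, spacing)
    if x.size > n:
        keep = rng.choice(x.size, size=n, replace=False)
        keep.sort()
        x, y = x[keep], y[keep]
    elif x.size < n:
        extra = n - x.size
        x = np.concatenate([x, rng.uniform(0, window.width, extra)])
        y = np.concatenate([y, rng.uniform(0, window.height, extra)])
    if jitter > 0:
        half = jitter * spacing / 2.0
        xj = x + rng.uniform(-half, half, n)
        yj = y + rng.uniform(-half, half, n)
        bad = ~((xj >= 0) & (xj <= window.width) & (yj >= 0) & (yj <= window.height))
        while bad.any():
            m = int(bad.sum())
            xj[bad] = x[bad] + rng.uniform(-half, half, m)
            yj[bad] = y[bad] + rng.uniform(-half, half, m)
            bad = ~((xj >= 0) & (xj <= window.width) & (yj >= 0) & (yj <= window.height))
        x, y = xj, yj
    return x, y


def hexagonal_lattice(nx: int, ny: int, spacing: float = 1.0) -> PointPattern:
    """Ideal regular array: a triangular lattice exactly tiling its window.

    The window is sized so the point intensity equals the lattice's
    2 / (sqrt(3) s^2) exactly and every point's nearest neighbour sits at
    distance s; this is the configuration that maximises the mean
    nearest-neighbour distance at fixed intensity.
    """
    if nx < 1 or ny < 1:
        raise InvalidSpecError("lattice dimensions must be >= 1")
    row_h = spacing * math.sqrt(3.0) / 2.0
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    x = (jj + 0.25) * spacing + (ii % 2) * spacing / 2.0
    y = (ii + 0.5) * row_h
    window = Window(nx * spacing, ny * row_h)
    return PointPattern(x.ravel(), y.ravel(), window)


# ---------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class RenderSpec:
    """Optical recipe for rendering a two-stain brightfield field.

    Nuclei are hard discs of constant absorbance amplitude; overlapping
    discs add in OD, as Beer-Lambert absorption does.  All nuclei carry the
    hematoxylin counterstain; marker-positive nuclei additionally carry DAB.
    """

    shape: tuple[int, int] = (256, 256)  # rows, cols
    background: float = 255.0
    hematoxylin_od: tuple[float, float, float] = tuple(HEMATOXYLIN_OD)
    dab_od: tuple[float, float, float] = tuple(DAB_OD)
    nucleus_radius: float = 5.0
    hematoxylin_amplitude: float = 0.6
    dab_amplitude: float = 0.8
    positive_fraction: float = 0.5
    noise_sd: float = 0.0
    seed: int | None = None
    quantize: bool = False

    def __post_init__(self) -> None:
        for name, vec in (("hematoxylin_od", self.hematoxylin_od), ("dab_od", self.dab_od)):
            if abs(float(np.linalg.norm(vec)) - 1.0) > 1e-6:
                raise InvalidSpecError(f"{name} must have unit Euclidean norm")
        if self.hematoxylin_amplitude < 0 or self.dab_amplitude < 0:
            raise InvalidSpecError("stain amplitudes must be non-negative")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise InvalidSpecError("positive_fraction must lie in [0, 1]")
        if self.nucleus_radius <= 0 or self.noise_sd < 0 or self.background <= 0:
            raise InvalidSpecError("radius and background must be positive, noise_sd >= 0")


@dataclass(frozen=True)
class RenderedField:
    """A rendered field plus its exact ground truth."""

    image: RasterField
    dab_mask: np.ndarray       # union of marker-positive nucleus discs
    nuclei_mask: np.ndarray    # union of all nucleus discs
    hematoxylin_truth: np.ndarray  # per-pixel hematoxylin amplitude
    dab_truth: np.ndarray          # per-pixel DAB amplitude


def _stamp_discs(canvas: np.ndarray, x: np.ndarray, y: np.ndarray,
                 radius: float, amplitude: float) -> None:
    nrow, ncol = canvas.shape
    r = int(math.ceil(radius))
    for cx, cy in zip(x, y):
        i0, i1 = max(0, int(cy) - r - 1), min(nrow, int(cy) + r + 2)
        j0, j1 = max(0, int(cx) - r - 1), min(ncol, int(cx) + r + 2)
        ii = np.arange(i0, i1)[:, None]
        jj = np.arange(j0, j1)[None, :]
        disc = (jj - cx) ** 2 + (ii - cy) ** 2 <= radius * radius
        canvas[i0:i1, j0:j1] += amplitude * disc


def render_field(points: PointPattern, negatives: PointPattern | None,
                 spec: RenderSpec) -> RenderedField:
    """Render marker-positive (``points``) and negative nuclei to an RGB field.

    Per-pixel intensity follows Beer-Lambert composition
    ``I_c = I0 * 10**(-A_c)`` with ``A = c_H * S_H + c_D * S_D`` summed over
    overlapping nucleus discs.  Returns the image together with the exact
    binary masks of DAB-positive regions and of all nuclei.
    """
    nrow, ncol = spec.shape
    for patt in (points, negatives):
        if patt is not None and patt.n:
            if patt.x.max() >= ncol or patt.y.max() >= nrow:
                raise InvalidSpecError("nucleus centers must lie inside the image bounds")
    rng = np.random.default_rng(spec.seed)
    amp_h = np.zeros(spec.shape, dtype=float)
    amp_d = np.zeros(spec.shape, dtype=float)
    _stamp_discs(amp_h, points.x, points.y, spec.nucleus_radius, spec.hematoxylin_amplitude)
    _stamp_discs(amp_d, points.x, points.y, spec.nucleus_radius, spec.dab_amplitude)
    if negatives is not None and negatives.n:
        _stamp_discs(amp_h, negatives.x, negatives.y, spec.nucleus_radius,
                     spec.hematoxylin_amplitude)
    s_h = np.asarray(spec.hematoxylin_od)
    s_d = np.asarray(spec.dab_od)
    od = amp_h[..., None] * s_h + amp_d[..., None] * s_d
    pixels = od_to_rgb(od, i0=spec.background)
    if spec.noise_sd > 0:
        pixels = np.clip(pixels + rng.normal(0.0, spec.noise_sd, pixels.shape), 0.0, 255.0)
    if spec.quantize:
        pixels = np.round(pixels).astype(np.uint8)
    field = RasterField(pixels, field_id=points.field_id or "synthetic")
    return RenderedField(
        image=field,
        dab_mask=amp_d > 0,
        nuclei_mask=amp_h > 0,
        hematoxylin_truth=amp_h,
        dab_truth=amp_d,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class FieldRecord:
    group: str
    sample_id: str
    field_id: str
    pattern: PointPattern


@dataclass(frozen=True)
class Cohort:
    """Two-arm collection of labelled per-field point patterns."""

    fields: tuple[FieldRecord, ...]

    def __iter__(self):
        return iter(self.fields)

    def __len__(self) -> int:
        return len(self.fields)

    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.fields:
            seen.setdefault(rec.group, None)
        return tuple(seen)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "group": [r.group for r in self.fields],
                "sample_id": [r.sample_id for r in self.fields],
                "field_id": [r.field_id for r in self.fields],
                "n_points": [r.pattern.n for r in self.fields],
            }
        )


def field_rng(master_seed: int, group_index: int, sample_index: int,
              field_index: int) -> np.random.Generator:
    """Independent stream per field, keyed by (seed, group, sample, field).

    Any single field can be regenerated without replaying the rest of the
    cohort, so partial re-runs are exactly reproducible.
    """
    return np.random.default_rng([int(master_seed), group_index, sample_index, field_index])


def generate_cohort(group_a_spec: PatternSpec, group_b_spec: PatternSpec,
                    window: Window, n_samples_per_group: int = 15,
                    n_fields_per_sample: int = 10, seed: int = 0,
                    labels: tuple[str, str] = ("A", "B"),
                    count_distribution: str = "poisson") -> Cohort:
    """Generate a full two-arm cohort of labelled point patterns.

    ``count_distribution='poisson'`` draws each field's point count from a
    Poisson law with mean ``spec.n_points`` (natural field-to-field count
    variation); ``'fixed'`` uses ``spec.n_points`` exactly.
    """
    if n_samples_per_group < 1 or n_fields_per_sample < 1:
        raise InvalidSpecError("cohort counts must be >= 1")
    if count_distribution not in ("poisson", "fixed"):
        raise InvalidSpecError("count_distribution must be 'poisson' or 'fixed'")
    records: list[FieldRecord] = []
    for gi, (label, spec) in enumerate(zip(labels, (group_a_spec, group_b_spec))):
        for si in range(n_samples_per_group):
            sample_id = f"{label}{si + 1:02d}"
            for fi in range(n_fields_per_sample):
                rng = field_rng(seed, gi, si, fi)
                n = spec.n_points
                if count_distribution == "poisson":
                    n = int(rng.poisson(spec.n_points))
                field_spec = replace(spec, n_points=n, seed=None)
                pattern = PointPattern(
                    *_coords_of(generate_pattern(field_spec, window, rng)),
                    window=window,
                    field_id=f"{sample_id}_f{fi + 1:02d}",
                )
                records.append(FieldRecord(label, sample_id, pattern.field_id, pattern))
    return Cohort(tuple(records))


def _coords_of(pattern: PointPattern) -> tuple[np.ndarray, np.ndarray]:
    return pattern.x, pattern.y
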