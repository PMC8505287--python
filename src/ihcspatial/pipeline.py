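"""Field- and cohort-level orchestration of the analysis stages.

``run_field`` takes one field (an RGB image, a point table, or in-memory
objects) through stain separation, thresholding, positive-cell detection,
Area%, the uniformity index and the Ripley-K envelope test, and returns a
:class:`FieldSummary`.  ``run_cohort`` maps it over a labelled collection of
fields, averages to sample level and runs the two-group comparisons.

Every per-field random stream is keyed by (config.seed, field id), so
results are deterministic under a config and independent of processing
order; output JSON embeds the fully resolved configuration and package
version for exact re-runs.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortResult, SampleSummary, compare_groups, summarize_sample
from .detection import (BinaryMask, area_percent, clean_mask,
                        detect_positive_cells, threshold_channel)
from .errors import ConfigurationError
from .geometry import PointPattern, Window
from .io import (read_image, read_pattern_csv, write_json)
from .spatial import (KFunctionResult, RipleyKAnalysis, UniformityResult,
                      default_d_grid, uniformity_index)
from .stains import RasterField, StainSystem, to_optical_density, unmix, white_balance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, with the documented defaults.

    ``mode`` selects the input kind: ``images`` runs the full imaging path,
    ``points`` starts from pre-extracted coordinate tables (Area% is then
    unavailable and reported as NaN).
    """

    mode: str = "points"
    # stain separation
    stain_hematoxylin: tuple[float, float, float] | None = None  # None = published H-DAB
    stain_dab: tuple[float, float, float] | None = None
    background_intensity: float = 255.0
    white_balance: bool = False
    # thresholding / morphology
    threshold_method: str = "otsu"
    dab_threshold: float | None = None       # used when threshold_method == "fixed"
    nuclei_threshold: float | None = None
    min_area: int = 20
    opening_radius: int = 1
    min_overlap_fraction: float = 0.5
    # spatial statistics
    n_grid_steps: int = 50
    dmax_fraction: float = 0.25
    n_sim: int = 100
    min_run_fraction: float = 0.2
    edge_correction: str | None = None
    # cohort statistics
    alpha: float = 0.05
    equal_var: bool = True
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("points", "images"):
            raise ConfigurationError("mode must be 'points' or 'images'")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigurationError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.dab_threshold is None:
            raise ConfigurationError("fixed thresholding requires dab_threshold")
        if not 0.0 <= self.min_overlap_fraction <= 1.0:
            raise ConfigurationError("min_overlap_fraction must lie in [0, 1]")
        if self.n_sim < 2 or self.n_grid_steps < 2:
            raise ConfigurationError("n_sim and n_grid_steps must be >= 2")
        if not 0.0 < self.dmax_fraction <= 0.5:
            raise ConfigurationError("dmax_fraction must lie in (0, 0.5]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.min_area < 0 or self.opening_radius < 0:
            raise ConfigurationError("morphology parameters must be >= 0")
        if not 0.0 <= self.min_run_fraction <= 1.0:
            raise ConfigurationError("min_run_fraction must lie in [0, 1]")

    def stain_system(self) -> StainSystem:
        kwargs = {}
        if self.stain_hematoxylin is not None:
            kwargs["hematoxylin"] = self.stain_hematoxylin
        if self.stain_dab is not None:
            kwargs["dab"] = self.stain_dab
        return StainSystem(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            import json

            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stain_hematoxylin", "stain_dab"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        data.update(overrides)
        return cls(**data)


def field_seed(config_seed: int, field_id: str) -> list[int]:
    """Stable per-field seed key: (config seed, CRC32 of the field id)."""
    return [int(config_seed), zlib.crc32(field_id.encode()) & 0x7FFFFFFF]


@dataclass(frozen=True)
class FieldSummary:
    """Everything measured on one field."""

    field_id: str
    sample_id: str
    group: str
    marker: str
    n_cells: int
    area_percent: float
    uniformity: UniformityResult
    k_result: KFunctionResult | None

    @property
    def uniformity_index(self) -> float:
        return self.uniformity.index

    @property
    def verdict(self) -> str:
        return self.k_result.verdict.label if self.k_result is not None else "undefined"

    def to_record(self, config: PipelineConfig | None = None) -> dict:
        rec = {
            "field_id": self.field_id,
            "sample_id": self.sample_id,
            "group": self.group,
            "marker": self.marker,
            "n_cells": self.n_cells,
            "area_percent": self.area_percent,
            "uniformity_index": self.uniformity.index,
            "mean_nn_distance": self.uniformity.mean_nn_distance,
            "expected_nn_distance": self.uniformity.expected_nn_distance,
            "verdict": self.verdict,
            "version": __version__,
        }
        if self.k_result is not None:
            rec.update(self.k_result.to_dict())
        if config is not None:
            rec["config"] = config.to_dict()
        return rec


def extract_pattern(image: RasterField, config: PipelineConfig,
                    sample_id: str = "", marker: str = "") -> tuple[PointPattern, float, dict]:
    """Imaging path: image -> OD -> unmix -> masks -> positive cells + Area%."""
    img = white_balance(image, i0=config.background_intensity) if config.white_balance else image
    od = to_optical_density(img, i0=config.background_intensity)
    stains = config.stain_system()
    unmixed = unmix(od, stains)
    if config.threshold_method == "fixed":
        dab_mask = threshold_channel(unmixed.dab, "fixed", config.dab_threshold, stain="dab")
        nuc_t = (config.nuclei_threshold if config.nuclei_threshold is not None
                 else config.dab_threshold)
        nuc_mask = threshold_channel(unmixed.hematoxylin, "fixed", nuc_t, stain="hematoxylin")
    else:
        dab_mask = threshold_channel(unmixed.dab, "otsu", stain="dab")
        nuc_mask = threshold_channel(unmixed.hematoxylin, "otsu", stain="hematoxylin")
    dab_mask = clean_mask(dab_mask, config.min_area, config.opening_radius)
    nuc_mask = clean_mask(nuc_mask, config.min_area, config.opening_radius)
    pattern = detect_positive_cells(nuc_mask, dab_mask,
                                    min_overlap_fraction=config.min_overlap_fraction,
                                    field_id=image.field_id, marker=marker or "synthetic")
    masks = {"dab": dab_mask, "nuclei": nuc_mask}
    return pattern, area_percent(dab_mask), masks


def analyze_pattern(pattern: PointPattern, config: PipelineConfig,
                    area_pct: float = float("nan"), sample_id: str = "",
                    group: str = "") -> FieldSummary:
    """Spatial statistics for one extracted point pattern.

    Fields with fewer than 2 cells are summarised with flagged, undefined
    statistics rather than raising, so cohort runs keep going.
    """
    ui = uniformity_index(pattern)
    k_result = None
    if pattern.n >= 2:
        d_grid = default_d_grid(pattern.window, config.n_grid_steps, config.dmax_fraction)
        model = RipleyKAnalysis(pattern, d_grid, edge_correction=config.edge_correction)
        rng = np.random.default_rng(field_seed(config.seed, pattern.field_id))
        k_result = model.fit(n_sim=config.n_sim, rng=rng,
                             min_run_fraction=config.min_run_fraction)
    else:
        logger.warning("field %s: n=%d < 2, spatial statistics undefined",
                       pattern.field_id, pattern.n)
    return FieldSummary(
        field_id=pattern.field_id,
        sample_id=sample_id,
        group=group,
        marker=pattern.marker,
        n_cells=pattern.n,
        area_percent=area_pct,
        uniformity=ui,
        k_result=k_result,
    )


def run_field(source, config: PipelineConfig, sample_id: str = "",
              group: str = "", out: str | Path | None = None) -> FieldSummary:
    """Analyse a single field given as a path, RasterField or PointPattern."""
    area_pct = float("nan")
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"field input not found: {path}")
        if path.suffix.lower() == ".csv":
            pattern = read_pattern_csv(path)
        else:
            image = read_image(path)
            pattern, area_pct, _ = extract_pattern(image, config, sample_id)
    elif isinstance(source, RasterField):
        pattern, area_pct, _ = extract_pattern(source, config, sample_id)
    elif isinstance(source, PointPattern):
        pattern = source
    else:
        raise TypeError(f"cannot analyse input of type {type(source)}")
    summary = analyze_pattern(pattern, config, area_pct, sample_id, group)
    if out is not None:
        write_json(summary.to_record(config), out)
    return summary


@dataclass(frozen=True)
class CohortReport:
    """Field table, sample table and per-(marker, parameter) test results."""

    field_frame: pd.DataFrame
    sample_frame: pd.DataFrame
    results: list[CohortResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def summary(self) -> str:
        return "\n\n".join(r.summary() for r in self.results)


def _iter_cohort_inputs(inputs, config: PipelineConfig):
    """Yield (group, sample_id, field_id, marker, source) from a Cohort or manifest."""
    from .synthetic import Cohort

    if isinstance(inputs, Cohort):
        for rec in inputs:
            yield rec.group, rec.sample_id, rec.field_id, "", rec.pattern
        return
    for entry in inputs:
        yield (entry["group"], entry["sample_id"], entry["field_id"],
               entry.get("marker", ""), entry.get("path", entry.get("pattern")))


def run_cohort(inputs, config: PipelineConfig, out_dir: str | Path | None = None,
               force: bool = False) -> CohortReport:
    """Analyse every field of a labelled cohort and compare the two groups.

    ``inputs`` is either a :class:`~ihcspatial.synthetic.Cohort` or a
    manifest: an iterable of dicts with keys ``group``, ``sample_id``,
    ``field_id`` and ``path`` (CSV point table or image file), plus an
    optional ``marker``.  Unreadable fields are skipped with a logged
    warning.  With ``out_dir`` set, per-field JSON is written and fields
    with an existing valid output are not recomputed unless ``force``.
    """
    from .io import read_json

    fields_dir = None
    if out_dir is not None:
        fields_dir = Path(out_dir) / "fields"
        fields_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    for group, sample_id, field_id, marker, source in _iter_cohort_inputs(inputs, config):
        out_path = fields_dir / f"{sample_id}_{field_id}.json" if fields_dir else None
        if out_path is not None and out_path.exists() and not force:
            try:
                rec = read_json(out_path)
                rows.append(rec)
                continue
            except Exception:
                logger.warning("field %s: invalid cached output, recomputing", field_id)
        try:
            summary = run_field(source, config, sample_id=sample_id, group=group,
                                out=out_path)
        except Exception as exc:
            logger.warning("field %s/%s skipped: %s", sample_id, field_id, exc)
            continue
        rec = summary.to_record()
        rec["group"] = group
        rec["marker"] = marker or rec.get("marker", "")
        rows.append(rec)

    if not rows:
        raise ValueError("cohort run produced no usable fields")

    field_frame = pd.DataFrame([
        {k: r.get(k) for k in ("group", "sample_id", "field_id", "marker",
                               "n_cells", "area_percent", "uniformity_index",
                               "verdict")}
        for r in rows
    ])

    summaries: list[SampleSummary] = []
    for (group, sample_id, marker), sub in field_frame.groupby(
            ["group", "sample_id", "marker"], dropna=False):
        summaries.append(summarize_sample(sub.to_dict("records"), sample_id,
                                          group, marker=str(marker)))
    sample_frame = pd.DataFrame([dataclasses.asdict(s) for s in summaries])

    groups = sorted(field_frame["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"cohort comparison needs exactly two groups, got {groups}")

    results: list[CohortResult] = []
    for marker in sorted(sample_frame["marker"].astype(str).unique()):
        sub = sample_frame[sample_frame["marker"].astype(str) == marker]
        sub = sub[sub["n_fields_used"] >= 1]  # listwise exclusion of flagged samples
        for param, col in (("area_percent", "mean_area_percent"),
                           ("uniformity_index", "mean_uniformity_index")):
            ga = sub.loc[sub["group"] == groups[0], col].to_numpy(float)
            gb = sub.loc[sub["group"] == groups[1], col].to_numpy(float)
            if (np.isfinite(ga).sum() < 2) or (np.isfinite(gb).sum() < 2):
                logger.warning("marker %s / %s: not enough usable samples, skipped",
                               marker, param)
                continue
            results.append(compare_groups(ga, gb, parameter=param, marker=marker,
                                          labels=(groups[0], groups[1]),
                                          equal_var=config.equal_var,
                                          alpha=config.alpha))

    report = CohortReport(field_frame, sample_frame, results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        report.to_frame().to_csv(out_dir / "cohort_results.csv", index=False)
        sample_frame.to_csv(out_dir / "sample_summaries.csv", index=False)
        write_json({"config": config.to_dict(), "version": __version__,
                    "results": [r.to_dict() for r in results]},
                   out_dir / "cohort_report.json")
    return report
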