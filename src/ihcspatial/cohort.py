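"""Sample-level aggregation and two-group cohort comparison.

Field-level measurements (Area%, uniformity index) are averaged within each
sample to give one representative value per sample and parameter; the two
groups are then compared per parameter with a two-sample Student's t-test
(equal-variance by default, Welch optional) at alpha = 0.05.

Fields with fewer than 2 detected cells carry no defined uniformity index;
such fields are excluded from the sample mean and the usable-field count is
recorded.  A sample with zero usable fields is flagged and excluded listwise
from the group comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PARAMETERS = ("area_percent", "uniformity_index")


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample means of the field-level parameters."""

    sample_id: str
    group: str
    marker: str
    mean_area_percent: float
    mean_uniformity_index: float
    n_fields_used: int
    n_fields_total: int

    @property
    def usable(self) -> bool:
        return self.n_fields_used >= 1

    def value(self, parameter: str) -> float:
        if parameter == "area_percent":
            return self.mean_area_percent
        if parameter == "uniformity_index":
            return self.mean_uniformity_index
        raise KeyError(parameter)


def _field_value(rec, key: str):
    if isinstance(rec, Mapping):
        return rec.get(key)
    return getattr(rec, key, None)


def summarize_sample(field_results: Iterable, sample_id: str, group: str,
                     marker: str = "") -> SampleSummary:
    """Average field-level results into one representative value per parameter.

    ``field_results`` is an iterable of mappings (or objects) exposing
    ``n_cells``, ``area_percent`` and ``uniformity_index``.  A field is
    usable when it holds at least 2 cells (so its uniformity index is
    defined); means are taken over usable fields only.
    """
    usable_area: list[float] = []
    usable_ui: list[float] = []
    total = 0
    for rec in field_results:
        total += 1
        n_cells = _field_value(rec, "n_cells")
        if n_cells is None:
            n_cells = _field_value(rec, "n")
        ui = _field_value(rec, "uniformity_index")
        if n_cells is None or n_cells < 2 or ui is None or not math.isfinite(ui):
            continue
        usable_ui.append(float(ui))
        ap = _field_value(rec, "area_percent")
        usable_area.append(float(ap) if ap is not None and math.isfinite(ap)
                           else float("nan"))
    if total == 0:
        raise ValueError("summarize_sample needs at least one field result")
    used = len(usable_ui)
    if used == 0:
        logger.warning("sample %s (%s): no usable fields, flagged for exclusion",
                       sample_id, group)
        return SampleSummary(sample_id, group, marker, float("nan"), float("nan"),
                             0, total)
    area = np.asarray(usable_area, dtype=float)
    area = area[np.isfinite(area)]
    return SampleSummary(
        sample_id=sample_id,
        group=group,
        marker=marker,
        mean_area_percent=float(area.mean()) if area.size else float("nan"),
        mean_uniformity_index=float(np.mean(usable_ui)),
        n_fields_used=used,
        n_fields_total=total,
    )


@dataclass(frozen=True)
class GroupStats:
    label: str
    n: int
    mean: float
    sd: float
    sem: float


@dataclass(frozen=True)
class CohortResult:
    """Two-group comparison of one parameter.

    Holds per-group descriptive statistics (mean, SD and SEM — figures in
    the field report error bars either way), the t statistic with its
    degrees of freedom, and the two-sided p-value.
    """

    parameter: str
    marker: str
    group_a: GroupStats
    group_b: GroupStats
    t: float
    p: float
    df: float
    alpha: float = 0.05
    equal_var: bool = True

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "parameter": self.parameter,
            "group_a": self.group_a.label, "n_a": self.group_a.n,
            "mean_a": self.group_a.mean, "sd_a": self.group_a.sd, "sem_a": self.group_a.sem,
            "group_b": self.group_b.label, "n_b": self.group_b.n,
            "mean_b": self.group_b.mean, "sd_b": self.group_b.sd, "sem_b": self.group_b.sem,
            "t": self.t, "df": self.df, "p": self.p,
            "alpha": self.alpha, "significant": self.significant,
        }

    def summary(self) -> str:
        a, b = self.group_a, self.group_b
        test = "Student" if self.equal_var else "Welch"
        lines = [
            f"Two-sample {test} t-test — {self.parameter}"
            + (f" ({self.marker})" if self.marker else ""),
            "-" * 48,
            f"{a.label}: n={a.n}  mean={a.mean:.4g}  SD={a.sd:.4g}  SEM={a.sem:.4g}",
            f"{b.label}: n={b.n}  mean={b.mean:.4g}  SD={b.sd:.4g}  SEM={b.sem:.4g}",
            f"t = {self.t:.4f}  (df = {self.df:g})   p = {self.p:.4g}"
            f"   {'significant' if self.significant else 'n.s.'} at alpha = {self.alpha}",
        ]
        return "\n".join(lines)


def _group_stats(label: str, values: np.ndarray) -> GroupStats:
    n = values.size
    sd = float(values.std(ddof=1)) if n > 1 else float("nan")
    return GroupStats(label, int(n), float(values.mean()), sd,
                      sd / math.sqrt(n) if n > 1 else float("nan"))


def compare_groups(group_a: Sequence[float], group_b: Sequence[float],
                   parameter: str = "", marker: str = "",
                   labels: tuple[str, str] = ("A", "B"),
                   equal_var: bool = True, alpha: float = 0.05) -> CohortResult:
    """Two-sample t-test between per-sample values of two groups.

    Equal-variance (classical Student) by default with
    df = n_a + n_b - 2; ``equal_var=False`` switches to Welch.  NaN sample
    values (flagged/excluded samples) are dropped listwise.  Degenerate
    zero-variance groups are resolved explicitly: equal means give t = 0,
    p = 1; unequal means give an infinite t and p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 usable samples")
    df = a.size + b.size - 2 if equal_var else _welch_df(a, b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, a.mean() - b.mean())
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return CohortResult(
        parameter=parameter,
        marker=marker,
        group_a=_group_stats(labels[0], a),
        group_b=_group_stats(labels[1], b),
        t=t, p=p, df=float(df), alpha=alpha, equal_var=equal_var,
    )


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        return float(a.size + b.size - 2)
    return (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))


class CohortComparison:
    """Two-group comparison model over per-sample summaries.

    Construct from a tidy DataFrame (one row per sample, a group column and
    one column per parameter) or from :class:`SampleSummary` objects, then
    :meth:`fit` runs one t-test per (marker, parameter) and returns a
    :class:`CohortResultSet`.

    Examples
    --------
    >>> import pandas as pd
    >>> df = pd.DataFrame({"group": ["A"] * 3 + ["B"] * 3,
    ...                    "uniformity_index": [1, 2, 3, 4, 5, 6]})
    >>> res = CohortComparison.from_dataframe(df).fit()
    >>> round(res["uniformity_index"].t, 4)
    -3.6742
    """

    def __init__(self, summaries: Sequence[SampleSummary],
                 parameters: Sequence[str] = PARAMETERS):
        self.summaries = list(summaries)
        self.parameters = tuple(parameters)
        groups: dict[str, None] = {}
        for s in self.summaries:
            groups.setdefault(s.group, None)
        if len(groups) != 2:
            raise ValueError(f"exactly two groups required, got {list(groups)}")
        self.labels = tuple(groups)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str = "group",
                       parameters: Sequence[str] | None = None,
                       marker_col: str | None = None) -> "CohortComparison":
        if parameters is None:
            parameters = [c for c in PARAMETERS if c in df.columns]
            if not parameters:
                parameters = [c for c in df.columns
                              if c != group_col and np.issubdtype(df[c].dtype, np.number)]
        summaries = []
        for i, row in df.reset_index(drop=True).iterrows():
            summaries.append(SampleSummary(
                sample_id=str(row.get("sample_id", i)),
                group=str(row[group_col]),
                marker=str(row[marker_col]) if marker_col else "",
                mean_area_percent=float(row["area_percent"]) if "area_percent" in df.columns else float("nan"),
                mean_uniformity_index=float(row["uniformity_index"]) if "uniformity_index" in df.columns else float("nan"),
                n_fields_used=int(row.get("n_fields_used", 1)),
                n_fields_total=int(row.get("n_fields_total", 1)),
            ))
        model = cls(summaries, parameters=tuple(parameters))
        model._frame = df.copy()
        model._group_col = group_col
        return model

    def fit(self, equal_var: bool = True, alpha: float = 0.05) -> "CohortResultSet":
        results = {}
        frame = getattr(self, "_frame", None)
        for param in self.parameters:
            if frame is not None and param in frame.columns:
                col = frame[param].astype(float)
                ga = col[frame[self._group_col].astype(str) == self.labels[0]].to_numpy()
                gb = col[frame[self._group_col].astype(str) == self.labels[1]].to_numpy()
            else:
                ga = np.array([s.value(param) for s in self.summaries
                               if s.group == self.labels[0]])
                gb = np.array([s.value(param) for s in self.summaries
                               if s.group == self.labels[1]])
            results[param] = compare_groups(ga, gb, parameter=param,
                                            labels=self.labels,
                                            equal_var=equal_var, alpha=alpha)
        return CohortResultSet(results)


@dataclass(frozen=True)
class CohortResultSet:
    """One :class:`CohortResult` per parameter, with tidy export."""

    results: dict[str, CohortResult]

    def __getitem__(self, parameter: str) -> CohortResult:
        return self.results[parameter]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results.values()])

    def summary(self) -> str:
        return "\n\n".join(r.summary() for r in self.results.values())
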