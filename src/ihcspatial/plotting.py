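"""Figures: L(d) envelope panels and per-parameter group bar charts."""

from __future__ import annotations


def plot_l_function(result, ax=None):
    """Plot L(d) = K(d) - K0(d) with dashed 95% envelope bounds.

    The envelopes are drawn as deviations from the null mean, so a curve
    escaping above the upper dashed line indicates clustering and one below
    the lower line indicates avoidance.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.d, result.L, color="black", lw=1.5, label="L(d)")
    ax.plot(result.d, result.env_lo - result.k0_mean, "k--", lw=1, label="95% envelope")
    ax.plot(result.d, result.env_hi - result.k0_mean, "k--", lw=1)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("distance d")
    ax.set_ylabel("L(d) = K(d) − K0(d)")
    ax.set_title(f"n = {result.n_points}, verdict: {result.verdict.label}")
    ax.legend(frameon=False)
    return ax


def plot_group_bars(tidy, parameter: str, ax=None, error: str = "sd"):
    """Bar chart of group means with SD (default) or SEM error bars.

    ``tidy`` is the DataFrame produced by
    :meth:`ihcspatial.cohort.CohortResultSet.to_frame` (one row per
    marker/parameter).
    """
    import matplotlib.pyplot as plt
    import numpy as np

    rows = tidy[tidy["parameter"] == parameter]
    if rows.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    markers = rows["marker"].astype(str).tolist()
    x = np.arange(len(rows))
    width = 0.38
    err_a = rows[f"{error}_a"].to_numpy(float)
    err_b = rows[f"{error}_b"].to_numpy(float)
    ax.bar(x - width / 2, rows["mean_a"], width, yerr=err_a, capsize=3,
           label=rows["group_a"].iloc[0])
    ax.bar(x + width / 2, rows["mean_b"], width, yerr=err_b, capsize=3,
           label=rows["group_b"].iloc[0])
    for xi, (_, row) in zip(x, rows.iterrows()):
        if row["significant"]:
            top = max(row["mean_a"] + err_a[xi], row["mean_b"] + err_b[xi])
            ax.text(xi, top * 1.03, "*", ha="center", fontsize=14)
    ax.set_xticks(x)
    ax.set_xticklabels(markers if any(markers) else [str(i) for i in x])
    ax.set_ylabel(parameter)
    ax.legend(frameon=False)
    return ax
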