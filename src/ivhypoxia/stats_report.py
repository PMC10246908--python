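"""Shared statistics, half-life fitting, and study-level aggregation.

Pearson correlations (two-sided t-based p), Welch's unequal-variance t
test, single-exponential fluorescence-decay fitting, and helpers that
pool per-image tables into the headline correlation report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass
class DecayFit:
    """Fit of intensity(t) = baseline + amplitude * 2**(-t/halflife)."""

    halflife_h: float
    baseline: float
    amplitude: float
    rss: float
    decaying: bool = True


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with two-sided p from the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n)


def welch_t(g1, g2) -> tuple[float, float, float]:
    """Welch's unequal-variance t test.

    Returns
    -------
    (t, df, p) : statistic, Welch-Satterthwaite degrees of freedom,
    two-sided p value.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(g1) == 0 and np.ptp(g2) == 0:
        raise ValueError("both groups constant: t undefined")
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fit_halflife(times_h, intensities) -> DecayFit:
    """Least-squares fit of a single-exponential decay with baseline.

    A non-decaying series (fitted amplitude <= 0 or no curvature) is
    returned flagged with ``decaying=False`` and NaN half-life instead
    of raising.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if np.any(y < 0):
        raise ValueError("intensities must be non-negative")

    span = y.max() - y.min()
    if span == 0 or y[np.argmin(t)] <= y[np.argmax(t)]:
        rss = float(np.sum((y - y.mean()) ** 2))
        return DecayFit(float("nan"), float(y.mean()), 0.0, rss, decaying=False)

    def model(tt, baseline, amplitude, halflife):
        return baseline + amplitude * np.power(2.0, -tt / halflife)

    # Initial guesses: plateau from the tail, decay rate from a
    # log-linear fit of the baseline-subtracted early points.
    b0 = float(y.min())
    a0 = float(span)
    pos = y - b0 > 0.05 * span
    if pos.sum() >= 2:
        slope, _ = np.polyfit(t[pos], np.log2(y[pos] - b0 + 1e-12), 1)
        h0 = -1.0 / slope if slope < 0 else (t.max() - t.min()) / 2
    else:
        h0 = (t.max() - t.min()) / 2
    h0 = float(np.clip(h0, 1e-3, 1e3))
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=[b0, a0, h0],
            bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, 1e6]),
            maxfev=20000,
        )
    except RuntimeError:
        rss = float(np.sum((y - y.mean()) ** 2))
        return DecayFit(float("nan"), float(y.mean()), 0.0, rss, decaying=False)
    baseline, amplitude, halflife = (float(v) for v in popt)
    rss = float(np.sum((y - model(t, *popt)) ** 2))
    if amplitude <= 0:
        return DecayFit(float("nan"), baseline, amplitude, rss, decaying=False)
    return DecayFit(halflife, baseline, amplitude, rss)


def holm_adjust(p_values: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment of a named p-value panel."""
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted: dict[str, float] = {}
    running = 0.0
    for rank, (name, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[name] = running
    return adjusted


def aggregate(
    cell_tables: list[pd.DataFrame],
    roi_metric_tables: list[dict],
    peritumoral_tables: list[pd.DataFrame] | None = None,
    adjust: bool = False,
) -> dict:
    """Pool per-image tables and compute the headline correlation report.

    Parameters
    ----------
    cell_tables : list of per-image cell-sample tables
        Columns gfp_intensity and distance_um.
    roi_metric_tables : list of per-image metric dicts
        Keys vascular_density and gfp_positive_fraction.
    peritumoral_tables : list of per-image moving-ROI tables, optional
        Columns mean_gfp, mean_shg, alignment_score,
        relative_orientation_deg.
    adjust : bool
        Apply Holm adjustment to the correlation panel's p values.

    Returns
    -------
    dict with pooled tables ("cells", "rois", "peritumoral") and a
    "correlations" panel of CorrelationResult entries.
    """
    if not cell_tables and not roi_metric_tables and not peritumoral_tables:
        raise ValueError("no input tables to aggregate")

    out: dict = {"correlations": {}}
    if cell_tables:
        cells = pd.concat(cell_tables, ignore_index=True)
        out["cells"] = cells
        finite = cells[np.isfinite(cells["distance_um"])]
        if len(finite) >= 3 and finite["gfp_intensity"].nunique() > 1:
            out["correlations"]["gfp_vs_distance"] = pearson(
                finite["gfp_intensity"], finite["distance_um"]
            )
    if roi_metric_tables:
        rois = pd.DataFrame(roi_metric_tables)
        out["rois"] = rois
        if (
            len(rois) >= 3
            and rois["vascular_density"].nunique() > 1
            and rois["gfp_positive_fraction"].nunique() > 1
        ):
            out["correlations"]["density_vs_gfp_fraction"] = pearson(
                rois["vascular_density"], rois["gfp_positive_fraction"]
            )
    if peritumoral_tables:
        peri = pd.concat(peritumoral_tables, ignore_index=True)
        out["peritumoral"] = peri
        ok = peri.dropna(subset=["mean_gfp", "mean_shg"])
        for key, col in [
            ("gfp_vs_shg", "mean_shg"),
            ("gfp_vs_alignment", "alignment_score"),
            ("gfp_vs_relative_orientation", "relative_orientation_deg"),
        ]:
            sub = ok.dropna(subset=[col])
            if len(sub) >= 3 and sub[col].nunique() > 1 and sub["mean_gfp"].nunique() > 1:
                out["correlations"][key] = pearson(sub["mean_gfp"], sub[col])
    if adjust and out["correlations"]:
        raw = {k: v.p_value for k, v in out["correlations"].items()}
        out["p_holm"] = holm_adjust(raw)
    return out


def grouped_comparison(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    edges: list[float],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Bin a covariate, then Welch-compare the outcome across the extreme bins.

    Returns a one-row frame with group means and the Welch t/df/p of
    first-vs-last bin, mirroring grouped box-plot comparisons (for
    edge-relative orientation the default grouping is <10, 10-80, >80
    degrees).
    """
    vals = table.dropna(subset=[value_col, group_col])
    binned = pd.cut(vals[group_col], bins=edges, labels=labels, include_lowest=True)
    groups = [vals.loc[binned == cat, value_col].to_numpy() for cat in binned.cat.categories]
    lo, hi = groups[0], groups[-1]
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError("extreme bins need at least 2 observations each")
    t, df, p = welch_t(lo, hi)
    return pd.DataFrame(
        {
            "low_bin_mean": [float(np.mean(lo))],
            "high_bin_mean": [float(np.mean(hi))],
            "t": [t],
            "df": [df],
            "p": [p],
            "n_low": [len(lo)],
            "n_high": [len(hi)],
        }
    )


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write pooled tables as CSV, the correlation panel as JSON, and plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key in ("cells", "rois", "peritumoral"):
        if key in report:
            report[key].to_csv(out_dir / f"{key}.csv", index=False)
    panel = {
        k: {"r": v.r, "p": v.p_value, "n": v.n}
        for k, v in report.get("correlations", {}).items()
    }
    if "p_holm" in report:
        panel["p_holm"] = report["p_holm"]
    (out_dir / "correlations.json").write_text(json.dumps(panel, indent=2))

    if "cells" in report:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        cells = report["cells"]
        finite = cells[np.isfinite(cells["distance_um"])]
        if len(finite):
            fig, ax = plt.subplots(figsize=(5, 4))
            hb = ax.hist2d(
                finite["distance_um"], finite["gfp_intensity"], bins=30, density=True
            )
            fig.colorbar(hb[3], ax=ax, label="probability density")
            ax.set_xlabel("distance to nearest vessel (µm)")
            ax.set_ylabel("reporter intensity (a.u.)")
            fig.tight_layout()
            fig.savefig(out_dir / "bivariate_histogram.png", dpi=120)
            plt.close(fig)
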