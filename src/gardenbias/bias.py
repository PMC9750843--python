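"""Bias statistics: ANOVA F, relativized F, correlation convergence,
group summaries, and the minimum planting-distance recommendation.

The central quantity is the relativized F metric

    F(mu_full - mu_base) / mean_over_draws[ F(mu_base) ]

where F(.) is the one-way ANOVA F statistic over taxonomic groups of the
response in parentheses. The difference mu_full - mu_base isolates the
spatial crowding term, so the metric measures how much apparent
between-group signal neighborhood interactions inject, on the scale of
the genuine (base-model) group differences. It converges to zero as
planting distance grows and the kernel weights vanish.

A second convergence diagnostic is the Pearson correlation between the
full- and base-model predictions across plants, computed with sigma = 0
so that uncertainty propagates only through the mean. The recommended
minimum planting distance is the smallest grid distance at which the
lower percentile-band edge of r exceeds a threshold (default r > .99).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SweepResult

__all__ = [
    "FResult",
    "BiasSummary",
    "DegenerateDesignError",
    "one_way_f",
    "relative_f",
    "correlation_curve",
    "percentile_band",
    "recommend_min_distance",
    "group_summary",
    "summarize_sweep",
    "NO_RECOMMENDATION",
]

#: Sentinel returned when no grid distance satisfies the correlation
#: threshold; distinct from any valid distance.
NO_RECOMMENDATION = None


class DegenerateDesignError(ValueError):
    """Raised when an ANOVA design has fewer than two groups."""


@dataclass(frozen=True)
class FResult:
    """One-way ANOVA F statistic with its degrees of freedom."""

    f_value: float
    df1: int
    df2: int


@dataclass(frozen=True)
class BiasSummary:
    """Per-distance bias statistics pooled over posterior draws."""

    distance: float
    rel_f_samples: np.ndarray
    rel_f_mean: float
    rel_f_band68: tuple[float, float]
    rel_f_band95: tuple[float, float]
    r_samples: np.ndarray | None
    r_mean: float | None
    r_band68: tuple[float, float] | None
    r_band95: tuple[float, float] | None
    group_means: pd.DataFrame


def one_way_f(response: np.ndarray, groups: np.ndarray) -> FResult:
    """Classical one-way ANOVA F = MS_between / MS_within.

    Degrees of freedom are (k - 1, n - k) for k groups and n
    observations. Degenerate responses follow a continuity convention:
    zero between-group sum of squares gives F = 0; nonzero between with
    zero within gives +inf.
    """
    response = np.asarray(response, float)
    groups = np.asarray(groups)
    n = len(response)
    if len(groups) != n:
        raise ValueError("response and groups must have equal length")
    labels, inverse = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise DegenerateDesignError("ANOVA requires at least two groups")
    if n <= k:
        raise DegenerateDesignError("need more observations than groups")

    counts = np.bincount(inverse)
    sums = np.bincount(inverse, weights=response)
    means = sums / counts
    grand = response.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((response - means[inverse]) ** 2))
    df1, df2 = k - 1, n - k
    if ssb == 0.0:
        f = 0.0
    elif ssw == 0.0:
        f = np.inf
    else:
        f = (ssb / df1) / (ssw / df2)
    return FResult(f_value=f, df1=df1, df2=df2)


def relative_f(results: SweepResult) -> np.ndarray:
    """Per-draw relativized F samples at one planting distance.

    For each draw, F(mu_full - mu_base) over groups, divided by the
    across-draw mean of F(mu_base).
    """
    if results.n_distances != 1:
        raise ValueError("relative_f expects results at a single distance")
    groups = results.groups
    diff_f = np.array([
        one_way_f(results.mu_full[0, k] - results.mu_base[0, k], groups).f_value
        for k in range(results.n_draws)
    ])
    base_f = np.array([
        one_way_f(results.mu_base[0, k], groups).f_value
        for k in range(results.n_draws)
    ])
    denom = base_f.mean()
    if denom == 0.0:
        raise ValueError("mean base-model F is zero; relativization undefined")
    return diff_f / denom


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with an explicit convention for degenerate vectors:
    identical vectors give r = 1 even when constant; otherwise a
    constant vector makes r undefined."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.array_equal(x, y):
        return 1.0
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_curve(
    results: SweepResult, band_levels: tuple[float, float] = (0.68, 0.95)
) -> pd.DataFrame:
    """Pearson r between mu_full and mu_base, per distance and draw.

    Intended for sweeps run with ``noise_mode='none'`` (the correlation
    analysis propagates uncertainty only through the mean). Returns one
    row per distance with the sample mean and central percentile bands.
    """
    lo_q = [(1 - lv) / 2 for lv in band_levels]
    rows = []
    r_samples = {}
    for i, d in enumerate(results.distances):
        r = np.array([
            _pearson(results.mu_full[i, k], results.mu_base[i, k])
            for k in range(results.n_draws)
        ])
        r_samples[float(d)] = r
        row = {"distance": float(d), "r_mean": r.mean()}
        for lv, q in zip(band_levels, lo_q):
            lo, hi = percentile_band(r, lv)
            pct = int(round(lv * 100))
            row[f"r_lo{pct}"] = lo
            row[f"r_hi{pct}"] = hi
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("distance", ignore_index=True)
    df.attrs["r_samples"] = r_samples
    return df


def percentile_band(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Central empirical quantile interval covering ``level`` of the mass.

    Linear interpolation between order statistics; e.g. level 0.95 gives
    the (2.5th, 97.5th) percentiles.
    """
    samples = np.asarray(samples, float)
    if samples.size == 0:
        raise ValueError("no samples to summarize")
    if not 0 < level < 1:
        raise ValueError("band level must lie in (0, 1)")
    lo, hi = np.quantile(samples, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def recommend_min_distance(
    curve: pd.DataFrame, r_threshold: float = 0.99, band_level: float = 0.68
) -> float | None:
    """Smallest grid distance whose correlation band lower edge clears
    ``r_threshold``; :data:`NO_RECOMMENDATION` if none qualifies."""
    col = f"r_lo{int(round(band_level * 100))}"
    if col not in curve.columns:
        raise KeyError(f"curve has no {band_level:.0%} band column {col!r}")
    ok = curve[curve[col] > r_threshold]
    if ok.empty:
        return NO_RECOMMENDATION
    return float(ok["distance"].min())


def group_summary(results: SweepResult, group_names=None) -> pd.DataFrame:
    """Per-group mean and SD of full-model predicted growth at one distance.

    The mean pools over plants and draws; the SD is taken across draws
    of the per-draw group means (posterior spread of the group mean).
    Rank 1 is the fastest-growing group.
    """
    if results.n_distances != 1:
        raise ValueError("group_summary expects results at a single distance")
    groups = results.groups
    labels = np.unique(groups)
    per_draw = np.stack([
        np.array([results.mu_full[0, k][groups == g].mean() for g in labels])
        for k in range(results.n_draws)
    ])  # (n_draws, n_groups)
    means = per_draw.mean(axis=0)
    sds = per_draw.std(axis=0, ddof=1) if results.n_draws > 1 else np.zeros_like(means)
    order = np.argsort(-means)
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(labels) + 1)
    df = pd.DataFrame({
        "group": labels,
        "mean_growth": means,
        "sd_growth": sds,
        "rank": rank,
    })
    if group_names is not None:
        df.insert(1, "group_name", [group_names[g] for g in labels])
    return df


def summarize_sweep(
    f_results: SweepResult,
    r_results: SweepResult | None = None,
    band_levels: tuple[float, float] = (0.68, 0.95),
    r_threshold: float = 0.99,
    band_level: float = 0.68,
    group_names=None,
) -> tuple[pd.DataFrame, pd.DataFrame, float | None]:
    """Full bias analysis of a sweep.

    Parameters
    ----------
    f_results:
        Sweep for the relativized-F analysis (normally run with
        independent residual noise).
    r_results:
        Sweep for the correlation analysis (normally run with
        ``noise_mode='none'``); defaults to ``f_results``.

    Returns
    -------
    summary:
        One row per distance: relativized-F mean and bands, r mean and
        bands.
    groups:
        Group means/SD/rank at every distance (long format).
    recommendation:
        Minimum planting distance, or None when no distance qualifies.
    """
    if r_results is None:
        r_results = f_results
    curve = correlation_curve(r_results, band_levels)
    rows = []
    gtabs = []
    for i, d in enumerate(f_results.distances):
        sub = f_results.at_distance(float(d))
        rf = relative_f(sub)
        row = {"distance": float(d), "rel_f_mean": rf.mean()}
        for lv in band_levels:
            lo, hi = percentile_band(rf, lv)
            pct = int(round(lv * 100))
            row[f"rel_f_lo{pct}"] = lo
            row[f"rel_f_hi{pct}"] = hi
        rows.append(row)
        gt = group_summary(sub, group_names)
        gt.insert(0, "distance", float(d))
        gtabs.append(gt)
    summary = pd.DataFrame(rows).merge(curve, on="distance", how="outer")
    summary = summary.sort_values("distance", ignore_index=True)
    groups = pd.concat(gtabs, ignore_index=True)
    rec = recommend_min_distance(curve, r_threshold, band_level)
    return summary, groups, rec
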