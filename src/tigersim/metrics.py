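"""Reductions over replicate runs: population series with t-based confidence
intervals, road-attributed mortality proportions, rank-sum comparisons of
replicate totals, and occupancy maps with near/far-road stratification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .engine import RunRecord

__all__ = ["population_summary", "road_mortality_proportion",
           "total_deaths_comparison", "occupancy", "significance_stars"]

GROUPS = ("adults", "breeding_females", "dependents")


def population_summary(records: list[RunRecord],
                       experiment_only: bool = False) -> pd.DataFrame:
    """Per-step mean and 95% CI across replicates for adults (all tigers
    >= 36 months), breeding (territory-holding) females, and dependent
    offspring.  The CI is mean +/- t_{0.975, n-1} * sd / sqrt(n); with a
    single replicate the CI columns are NaN."""
    if not records:
        raise ValueError("no records")
    frames = [(r.experiment_counts() if experiment_only else r.counts)
              for r in records]
    steps = frames[0]["step"].to_numpy()
    n = len(frames)
    rows = []
    for group in GROUPS:
        data = np.stack([f[group].to_numpy() for f in frames])  # reps x steps
        mean = data.mean(axis=0)
        if n > 1:
            sd = data.std(axis=0, ddof=1)
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = np.full_like(mean, np.nan, dtype=float)
        rows.append(pd.DataFrame({"step": steps, "group": group, "mean": mean,
                                  "ci_low": lo, "ci_high": hi}))
    return pd.concat(rows, ignore_index=True)


def _monthly_proportions(deaths: pd.DataFrame, steps: np.ndarray,
                         road_class: str | None) -> np.ndarray:
    """Proportion of the month's deaths whose territory intersected a road
    (of one class, or any); months without deaths are NaN."""
    out = np.full(len(steps), np.nan)
    if deaths.empty:
        return out
    grouped = deaths.groupby("step")
    for i, s in enumerate(steps):
        if s not in grouped.groups:
            continue
        month = grouped.get_group(s)
        if road_class is None:
            num = (month["road_intersect"] != "none").sum()
        else:
            num = (month["road_intersect"] == road_class).sum()
        out[i] = num / len(month)
    return out


def road_mortality_proportion(records: list[RunRecord]) -> pd.DataFrame:
    """Annual proportions of all mortality attributed to roads.

    For each replicate the monthly proportion of deaths that occurred while
    the (female's) territory intersected a road is averaged within each year
    of the experiment window (zero-death months are excluded); the table
    reports the across-replicate mean and standard error per year, by road
    class and combined."""
    rows = []
    for cls_name, cls in (("primary", "primary"), ("secondary", "secondary"),
                          ("combined", None)):
        annual = []  # reps x years
        for rec in records:
            start = rec.burn_in_steps
            steps = np.arange(start + 1, start + rec.experiment_steps + 1)
            deaths = rec.deaths_df
            deaths = deaths[deaths["step"] > start]
            monthly = _monthly_proportions(deaths, steps, cls)
            n_years = rec.experiment_steps // 12
            yearly = [np.nanmean(monthly[y * 12:(y + 1) * 12])
                      if np.isfinite(monthly[y * 12:(y + 1) * 12]).any() else np.nan
                      for y in range(n_years)]
            annual.append(yearly)
        annual = np.asarray(annual, dtype=float)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(annual, axis=0)
            n_eff = np.isfinite(annual).sum(axis=0)
            se = np.nanstd(annual, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
        for y, (m, s) in enumerate(zip(mean, se), start=1):
            rows.append({"year": y, "road_class": cls_name,
                         "mean_proportion": m, "se": s})
    return pd.DataFrame(rows)


def total_deaths_comparison(values_a, values_b) -> dict:
    """Unpaired two-sample Wilcoxon (Mann-Whitney) rank-sum comparison of
    per-replicate totals.

    Accepts arrays of per-replicate numbers or lists of RunRecords (then the
    summed death counts over the experiment window are compared).  Exact
    two-sided p-values are used when the pooled sample is tie-free, the
    tie-corrected normal approximation otherwise; degenerate all-equal
    samples report p = 1.
    """
    a = _replicate_totals(values_a)
    b = _replicate_totals(values_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 replicates per arm")
    if np.ptp(np.concatenate([a, b])) == 0:
        return {"p_value": 1.0, "statistic": np.nan,
                "median_a": float(np.median(a)), "median_b": float(np.median(b))}
    pooled = np.concatenate([a, b])
    method = "exact" if len(np.unique(pooled)) == len(pooled) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"p_value": float(res.pvalue), "statistic": float(res.statistic),
            "median_a": float(np.median(a)), "median_b": float(np.median(b))}


def _replicate_totals(values) -> np.ndarray:
    if len(values) and isinstance(values[0], RunRecord):
        return np.array([
            (r.deaths_df["step"] > r.burn_in_steps).sum() for r in values
        ], dtype=float)
    return np.asarray(values, dtype=float)


def occupancy(records: list[RunRecord], near_mask: np.ndarray | None = None,
              landscape_mask: np.ndarray | None = None) -> dict:
    """Replicate-mean per-cell occupancy and its near/far-road stratification.

    Occupancy is the proportion of experiment steps in which a cell belonged
    to any breeding female's territory, averaged over replicates.  When a
    near-road mask (within 2 km of a secondary or 5 km of a primary road) is
    given, stratum means over in-landscape cells are reported too.
    """
    maps = np.stack([r.occupancy for r in records])
    mean_map = maps.mean(axis=0)
    out = {"map": mean_map, "mean": float(mean_map.mean())}
    if landscape_mask is None:
        landscape_mask = np.ones(mean_map.shape, dtype=bool)
    out["mean"] = float(mean_map[landscape_mask].mean())
    if near_mask is not None:
        near = near_mask & landscape_mask
        far = ~near_mask & landscape_mask
        out["near_mean"] = float(mean_map[near].mean()) if near.any() else np.nan
        out["far_mean"] = float(mean_map[far].mean()) if far.any() else np.nan
    return out


def plot_population_trajectories(summary: pd.DataFrame, path) -> None:
    """Plot the mean population series with its confidence band per group
    (one panel each) from a :func:`population_summary` table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(dict.fromkeys(summary["group"]))
    fig, axes = plt.subplots(len(groups), 1, figsize=(7, 2.4 * len(groups)),
                             sharex=True, squeeze=False)
    for ax, group in zip(axes.ravel(), groups):
        sub = summary[summary["group"] == group]
        ax.plot(sub["step"], sub["mean"], lw=1.5)
        ax.fill_between(sub["step"], sub["ci_low"], sub["ci_high"],
                        alpha=0.3, lw=0)
        ax.set_ylabel(group.replace("_", " "))
    axes.ravel()[-1].set_xlabel("month")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def significance_stars(p: float) -> str:
    """Significance bands: ns, <=0.05 (*), <=0.01 (**), <=0.001 (***),
    <=0.0001 (****)."""
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p <= thresh:
            return stars
    return "ns"
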