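"""Correlation and depth-profile summaries of sweep and Sobol outputs.

Three correlation analyses link conductivity variation to localization
behaviour, per source:

* deviation-vs-scatter: |sigma_i - center_i| against the distance of
  each reconstruction from the centroid of its localization cloud —
  large conductivity errors of either sign push the reconstruction away
  from the cloud center, hence the absolute deviation;
* sigma-vs-depth: each tissue conductivity against the reconstructed
  source depth;
* rdm-vs-locerror: the topography error of each draw against its
  localization error.

Depth profiles reduce any per-source quantity to binned medians with
lower/upper quartiles over source depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .model import ConductivityPrior
from .scan import SweepResult

__all__ = [
    "CorrelationProfile",
    "corr_deviation_vs_scatter",
    "corr_sigma_vs_depth",
    "corr_rdm_vs_locerror",
    "depth_profile",
    "summarize_sweeps",
    "build_correlation_profile",
]


def _corr(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[float, bool]:
    """Correlation with an explicit undefined flag for zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        return 0.0, True
    if method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
    elif method == "spearman":
        r = float(spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return r, False


def corr_deviation_vs_scatter(
    sweep: SweepResult,
    priors: dict[str, ConductivityPrior],
    center: str = "mean",
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-tissue correlation of |sigma_i - center_i| with the distance
    of each reconstruction from the localization-cloud centroid.

    ``center='mean'`` uses the prior mean (sigma_min + sigma_max)/2;
    ``center='half_range'`` uses (sigma_max - sigma_min)/2 instead (an
    alternative centering that appears in the literature).
    """
    scatter = sweep.scatter
    rows = []
    for t, p in priors.items():
        col = f"sigma_{t}"
        if col not in sweep.draws:
            continue
        if center == "mean":
            c = p.mean
        elif center == "half_range":
            c = p.half_range
        else:
            raise ValueError(f"unknown center {center!r}")
        dev = np.abs(sweep.draws[col].to_numpy() - c)
        r, undef = _corr(dev, scatter, method)
        rows.append((t, r, undef))
    return pd.DataFrame(rows, columns=["tissue", "r", "undefined"])


def corr_sigma_vs_depth(sweep: SweepResult, method: str = "pearson") -> pd.DataFrame:
    """Per-tissue correlation of the drawn conductivity with the
    reconstructed source depth."""
    depth = sweep.draws["reco_depth"].to_numpy()
    rows = []
    for col in sweep.draws.columns:
        if not col.startswith("sigma_"):
            continue
        r, undef = _corr(sweep.draws[col].to_numpy(), depth, method)
        rows.append((col.removeprefix("sigma_"), r, undef))
    return pd.DataFrame(rows, columns=["tissue", "r", "undefined"])


def corr_rdm_vs_locerror(sweep: SweepResult, method: str = "pearson") -> tuple[float, bool]:
    """Correlation of per-draw RDM with per-draw localization error."""
    return _corr(sweep.draws["rdm"].to_numpy(), sweep.draws["loc_error"].to_numpy(), method)


def depth_profile(
    values,
    depths,
    bin_width: float = 2.5,
    depth_range: tuple[float, float] = (0.0, 45.0),
) -> pd.DataFrame:
    """Binned median and quartiles of a per-source quantity over depth.

    Quartiles use linear interpolation between order statistics (the
    numpy default percentile rule).  Empty bins are emitted with count 0
    and NaN statistics; depths outside ``depth_range`` are rejected.
    """
    values = np.asarray(values, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if values.shape != depths.shape:
        raise ValueError("values and depths must align")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = depth_range
    if np.any(depths < lo) or np.any(depths > hi):
        raise ValueError(f"source depth outside the profile range [{lo}, {hi}] mm")
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        inbin = (depths >= a) & (depths < b) if b < edges[-1] else (depths >= a) & (depths <= b)
        v = values[inbin]
        if v.size:
            med, q25, q75 = np.percentile(v, [50, 25, 75])
        else:
            med = q25 = q75 = np.nan
        rows.append((a, b, v.size, med, q25, q75))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "count", "median", "q25", "q75"])


def summarize_sweeps(sweeps: list[SweepResult]) -> pd.DataFrame:
    """Per-source means: localization error, depth-change ratio, RDM."""
    if not sweeps:
        raise ValueError("no sweeps to summarize")
    rows = [
        (
            s.source_id,
            s.depth,
            s.mean_localization_error,
            s.mean_depth_change_ratio,
            s.mean_rdm,
        )
        for s in sweeps
    ]
    return pd.DataFrame(
        rows,
        columns=["source", "depth", "mean_loc_error", "mean_depth_change_ratio", "mean_rdm"],
    )


@dataclass
class CorrelationProfile:
    """Per-source correlations plus their depth-binned profiles."""

    per_source: pd.DataFrame  # one row per (source, analysis, tissue)
    profiles: dict[str, pd.DataFrame]  # analysis/tissue -> depth profile


def build_correlation_profile(
    sweeps: list[SweepResult],
    priors: dict[str, ConductivityPrior],
    center: str = "mean",
    method: str = "pearson",
    bin_width: float = 2.5,
    depth_range: tuple[float, float] = (0.0, 45.0),
) -> CorrelationProfile:
    """All three correlation analyses for a set of sweeps, with
    depth-binned median/quartile profiles per tissue."""
    rows = []
    for s in sweeps:
        for _, rec in corr_deviation_vs_scatter(s, priors, center, method).iterrows():
            rows.append((s.source_id, s.depth, "deviation_vs_scatter", rec.tissue, rec.r, rec.undefined))
        for _, rec in corr_sigma_vs_depth(s, method).iterrows():
            rows.append((s.source_id, s.depth, "sigma_vs_depth", rec.tissue, rec.r, rec.undefined))
        r, undef = corr_rdm_vs_locerror(s, method)
        rows.append((s.source_id, s.depth, "rdm_vs_locerror", "", r, undef))
    per_source = pd.DataFrame(rows, columns=["source", "depth", "analysis", "tissue", "r", "undefined"])
    profiles = {}
    for (analysis, tissue), grp in per_source.groupby(["analysis", "tissue"]):
        key = f"{analysis}:{tissue}" if tissue else analysis
        profiles[key] = depth_profile(grp.r.to_numpy(), grp.depth.to_numpy(), bin_width, depth_range)
    return CorrelationProfile(per_source, profiles)


def plot_depth_profile(profile: pd.DataFrame, ax=None, label: str | None = None, color=None):
    """Median with interquartile band over source depth (one line per call)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mid = 0.5 * (profile.bin_lo + profile.bin_hi)
    ok = profile["count"] > 0
    ax.plot(mid[ok], profile["median"][ok], label=label, color=color)
    ax.fill_between(mid[ok], profile["q25"][ok], profile["q75"][ok], alpha=0.25, color=color)
    ax.set_xlabel("source depth (mm)")
    return ax
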