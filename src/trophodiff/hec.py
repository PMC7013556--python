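"""High-expression-change (HEC) gene selection and temporal clustering.

The HEC threshold is read off the curve of PPE-gene enrichment odds ratios
as a function of the log2 fold-change cutoff: the chosen cutoff is where
the slope of the OR curve increases sharply (operationalised as a forward
difference exceeding ``slope_factor`` times the median positive forward
difference), with an optional manual override (2.5 log2 units in the
original study, ~5.7-fold).  HEC genes are then clustered by the shape of
their log2FC-vs-day-0 trajectories (correlation distance, average linkage)
and clusters are numbered by how early they reach half their maximal
response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .enrichment import fisher_2x2

__all__ = [
    "HECResult",
    "ppe_enrichment_curve",
    "select_hec_threshold",
    "cluster_trajectories",
    "hec_analysis",
]

log = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.1, 4.0 + 1e-9, 0.1), 10)


@dataclass
class HECResult:
    curve: pd.DataFrame               # t, a, b, c, d, odds_ratio, p
    threshold: float                  # chosen t*
    auto_threshold: float | None      # what the slope rule picked (may equal)
    hec_genes: pd.Index
    enrichment_fold: float            # OR at t*
    clusters: pd.Series | None = None         # gene -> "C1"..
    cluster_means: pd.DataFrame | None = None  # cluster × day mean trajectory


def ppe_enrichment_curve(
    max_abs_fc: pd.Series,
    ppe_flags: pd.Series,
    grid=DEFAULT_GRID,
) -> pd.DataFrame:
    """PPE enrichment odds ratio as a function of the |log2FC| cutoff.

    At each grid point t the 2x2 table crosses (max |log2FC| >= t) with the
    PPE flag over the whole universe; odds ratios with an empty margin are
    reported as NaN.
    """
    if len(max_abs_fc) == 0:
        raise ValueError("empty universe")
    ppe = ppe_flags.reindex(max_abs_fc.index).fillna(False).astype(bool).to_numpy()
    fc = max_abs_fc.to_numpy(dtype=float)
    rows = []
    for t in grid:
        above = fc >= t
        a = int((above & ppe).sum())
        b = int((~above & ppe).sum())
        c = int((above & ~ppe).sum())
        d = int((~above & ~ppe).sum())
        # cells as (in-set=above-threshold) x (group=PPE)
        res = fisher_2x2(a, b, c, d)
        rows.append({"t": float(t), "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": res.odds_ratio, "p": res.p})
    return pd.DataFrame(rows)


def select_hec_threshold(
    curve: pd.DataFrame,
    slope_factor: float = 3.0,
    override: float | None = None,
    max_above_fraction: float = 0.95,
) -> float:
    """Pick the fold-change threshold at the OR-curve slope breakpoint.

    The automatic rule looks for the first grid step across which the
    enrichment odds ratio grows by at least ``slope_factor``-fold (a
    relative-slope criterion: OR curves climb geometrically as the
    background stratum thins, so a sudden multiplicative jump — not a large
    absolute increment, which accumulates gradually along the climb — marks
    the breakpoint).  The grid point at the top of the jump is returned.
    A manual ``override`` always wins; the automatic choice is still
    computed and logged for comparison when possible.
    """
    defined = curve.dropna(subset=["odds_ratio"])
    if {"a", "b", "c", "d"} <= set(defined.columns):
        # grid points below the measurement noise floor are degenerate:
        # essentially every gene sits above the cutoff and the OR is not
        # about enrichment; exclude them from the breakpoint search
        counts = defined[["a", "b", "c", "d"]].sum(axis=1)
        above = (defined["a"] + defined["c"]) / counts
        defined = defined[above <= max_above_fraction]
    auto = None
    if len(defined) >= 5:
        t = defined["t"].to_numpy()
        orv = defined["odds_ratio"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = orv[1:] / orv[:-1]
        hits = np.nonzero(ratios >= slope_factor)[0]
        if len(hits):
            auto = float(t[hits[0] + 1])
    if override is not None:
        if auto is not None:
            log.info("HEC threshold override %.3g (automatic rule chose %.3g)",
                     override, auto)
        return float(override)
    if len(defined) < 5:
        raise ValueError("need >= 5 defined grid points to select a threshold")
    if auto is None:
        raise ValueError("no slope breakpoint in the OR curve (no grid step "
                         f"with an OR jump >= {slope_factor}x)")
    return auto


def cluster_trajectories(
    trajectories: pd.DataFrame,
    k: int = 5,
    linkage_method: str = "average",
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster fold-change trajectories by shape into temporal clusters.

    Distance is 1 − Pearson correlation between trajectories (scale-free:
    multiplying a trajectory by a positive constant does not move it),
    linkage is average by default.  The tree is cut into ``k`` clusters
    (reduced with a warning when there are fewer distinct non-constant
    profiles) and clusters are renamed C1..Ck by the time their mean
    |trajectory| first reaches half its maximum — earliest first.
    """
    x = trajectories.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant trajectories excluded "
                      "from correlation clustering")
    keep = trajectories.index[sd > 0]
    xk = trajectories.loc[keep].to_numpy(dtype=float)
    n_distinct = len(np.unique(np.round(xk, 12), axis=0)) if len(keep) else 0
    k_eff = min(k, max(n_distinct, 1))
    if k_eff < k:
        warnings.warn(f"fewer distinct profiles than k; reducing k to {k_eff}")
    if len(keep) == 0:
        raise ValueError("no non-constant trajectories to cluster")
    if len(keep) == 1 or k_eff == 1:
        raw = np.ones(len(keep), dtype=int)
    else:
        d = pdist(xk, metric="correlation")
        link = hierarchy.linkage(np.clip(d, 0, None), method=linkage_method)
        raw = hierarchy.fcluster(link, t=k_eff, criterion="maxclust")
    labels = pd.Series(raw, index=keep)

    # order clusters by time-to-half-maximum of the mean trajectory
    days = trajectories.columns
    order = []
    for c in sorted(labels.unique()):
        mean = trajectories.loc[labels.index[labels == c]].mean(axis=0)
        amax = mean.abs().max()
        t_half = float(days[-1]) + 1.0
        if amax > 0:
            reached = mean.abs() >= amax / 2.0
            t_half = float(days[np.argmax(reached.to_numpy())])
        order.append((t_half, c))
    order.sort()
    rename = {c: f"C{i + 1}" for i, (_, c) in enumerate(order)}
    named = labels.map(rename)
    means = pd.DataFrame(
        {name: trajectories.loc[named.index[named == name]].mean(axis=0)
         for name in sorted(rename.values())}
    ).T
    return named, means


def hec_analysis(
    max_abs_fc: pd.Series,
    ppe_flags: pd.Series,
    trajectories: pd.DataFrame,
    grid=DEFAULT_GRID,
    slope_factor: float = 3.0,
    override: float | None = 2.5,
    k: int = 5,
) -> HECResult:
    """Full HEC stage: enrichment curve, threshold, gene set, clustering."""
    curve = ppe_enrichment_curve(max_abs_fc, ppe_flags, grid=grid)
    auto = None
    try:
        auto = select_hec_threshold(curve, slope_factor=slope_factor)
    except ValueError:
        if override is None:
            raise
    t_star = float(override) if override is not None else auto
    hec_genes = max_abs_fc.index[max_abs_fc >= t_star]
    idx = int(np.argmin(np.abs(curve["t"].to_numpy() - t_star)))
    fold = float(curve["odds_ratio"].iloc[idx])
    clusters, means = None, None
    if len(hec_genes) >= 2:
        traj = trajectories.loc[trajectories.index.intersection(hec_genes)]
        if 0 not in traj.columns:
            # anchor every trajectory at the day-0 baseline (log2FC 0) so
            # flat-after-day-1 shapes still have a defined shape correlation
            traj = traj.copy()
            traj.insert(0, 0, 0.0)
        clusters, means = cluster_trajectories(traj, k=k)
    return HECResult(curve, t_star, auto, hec_genes, fold, clusters, means)
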