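"""Weighted co-expression network modules from day-mean profiles.

Follows the classic weighted gene co-expression workflow: per-gene day-mean
profiles, a soft-thresholded adjacency ``|r|^beta`` (unsigned by default;
a signed variant ``((1+r)/2)^beta`` is available when up- and
down-regulated patterns must be kept apart), the topological overlap
measure (TOM), average-linkage clustering of ``1 - TOM`` with a static
quantile tree cut, size-ordered module labels with the conventional module
colors, and a placental / non-placental module-group classification based
on enrichment of placenta-marker (PPE) genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrichment import module_enrichment

__all__ = [
    "ModuleSet",
    "WGCNA_COLORS",
    "day_mean_profiles",
    "correlation_matrix",
    "adjacency_matrix",
    "scale_free_fit",
    "pick_soft_power",
    "tom_matrix",
    "detect_modules",
    "classify_module_groups",
    "module_trajectories",
]

# conventional module color sequence (largest module first); grey = unassigned
WGCNA_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

UNASSIGNED = "unassigned"


def day_mean_profiles(expr, genes=None) -> pd.DataFrame:
    """Per-gene day-mean log2 expression profiles (genes × days)."""
    return expr.day_means(genes=genes)


def correlation_matrix(profiles: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Pearson correlations between gene profiles.

    Genes with constant profiles have undefined correlations and are
    dropped with a warning.  Returns (corr matrix, kept gene index).
    """
    x = profiles.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} constant-profile genes")
    x = x[keep]
    if x.shape[0] < 2:
        raise ValueError("need >= 2 non-constant profiles")
    r = np.corrcoef(x)
    return np.clip(r, -1.0, 1.0), profiles.index[keep]


def adjacency_matrix(corr: np.ndarray, beta: float, signed: bool = False) -> np.ndarray:
    """Soft-thresholded adjacency with zeroed diagonal."""
    a = ((1.0 + corr) / 2.0) ** beta if signed else np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R² of the log10 p(k) vs log10 k regression over occupied degree bins.

    Returns NaN when fewer than 5 bins are occupied or the fit is degenerate.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 5:
        return np.nan
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() > 0:
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.sum() / len(k)))
    if len(xs) < 5:
        return np.nan
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.allclose(xs, xs[0]) or np.allclose(ys, ys[0]):
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def pick_soft_power(
    profiles: pd.DataFrame,
    powers=range(1, 21),
    target_r2: float = 0.8,
    signed: bool = False,
    fallback: int = 9,
) -> tuple[int, pd.DataFrame]:
    """Smallest soft power whose degree distribution fits a power law.

    For each candidate power the adjacency connectivity ``k_i`` is computed
    and the scale-free model fit R² evaluated; the smallest power reaching
    ``target_r2`` wins.  If none qualifies the conventional fallback power
    is returned with a warning.  Returns (power, scan table).
    """
    corr, _ = correlation_matrix(profiles)
    if corr.shape[0] < 3:
        raise ValueError("need >= 3 profiles to pick a soft power")
    rows = []
    chosen = None
    for b in powers:
        a = adjacency_matrix(corr, b, signed=signed)
        r2 = scale_free_fit(a.sum(axis=1))
        rows.append({"power": b, "r2": r2})
        if chosen is None and np.isfinite(r2) and r2 >= target_r2:
            chosen = b
    scan = pd.DataFrame(rows).set_index("power")
    if chosen is None:
        warnings.warn(
            f"no power reached scale-free R^2 >= {target_r2}; falling back to {fallback}"
        )
        chosen = fallback
    return chosen, scan


def tom_matrix(
    profiles: pd.DataFrame, beta: float, signed: bool = False
) -> tuple[np.ndarray, pd.Index]:
    """Topological overlap matrix of the soft-thresholded network.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with a
    unit diagonal; entries lie in [0, 1].
    """
    corr, genes = correlation_matrix(profiles)
    a = adjacency_matrix(corr, beta, signed=signed)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0), genes


@dataclass
class ModuleSet:
    """Gene → module assignment with the artefacts that produced it."""

    labels: pd.Series                      # gene -> "M1".. or "unassigned"
    colors: dict[str, str]                 # module -> conventional color
    beta: float
    power_scan: pd.DataFrame | None = None
    tom: np.ndarray | None = None
    linkage: np.ndarray | None = None
    cut_height: float = np.nan
    groups: dict[str, str] = field(default_factory=dict)   # module -> group
    ppe_enrichment: pd.DataFrame | None = None

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.colors if m != UNASSIGNED]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_in(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def group_genes(self, group: str) -> pd.Index:
        mods = [m for m, g in self.groups.items() if g == group]
        return self.labels.index[self.labels.isin(mods)]


def detect_modules(
    tom: np.ndarray,
    genes: pd.Index,
    min_size: int = 30,
    cut_quantile: float = 0.99,
    beta: float = np.nan,
    power_scan: pd.DataFrame | None = None,
    keep_tom: bool = False,
) -> ModuleSet:
    """Average-linkage clustering of 1−TOM with a static quantile tree cut.

    Merge heights above the ``cut_quantile`` quantile separate clusters;
    clusters smaller than ``min_size`` become unassigned.  Modules are
    labelled M1..Mk by decreasing size with the conventional color series.
    """
    n = tom.shape[0]
    if n < min_size:
        warnings.warn("fewer genes than min_size; all genes unassigned")
        labels = pd.Series(UNASSIGNED, index=genes)
        return ModuleSet(labels, {UNASSIGNED: "grey"}, beta, power_scan,
                         tom if keep_tom else None)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    heights = link[:, 2]
    cut = float(np.quantile(heights, cut_quantile))
    raw = hierarchy.fcluster(link, t=cut, criterion="distance")
    counts = pd.Series(raw).value_counts()
    big = counts[counts >= min_size].index
    order = sorted(big, key=lambda c: (-counts[c], c))
    mapping = {c: f"M{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([mapping.get(c, UNASSIGNED) for c in raw], index=genes)
    colors = {f"M{i + 1}": WGCNA_COLORS[i % len(WGCNA_COLORS)]
              for i in range(len(order))}
    colors[UNASSIGNED] = "grey"
    return ModuleSet(labels, colors, beta, power_scan,
                     tom if keep_tom else None, link, cut)


def classify_module_groups(
    modules: ModuleSet,
    ppe_flags: pd.Series,
    universe=None,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Label each module placental or non-placental by PPE enrichment.

    A module is placental when its one-sided Fisher enrichment p-value for
    PPE genes is below ``alpha`` with OR > 1.  Stores and returns the
    module → group mapping (unassigned genes get no group).
    """
    assigned = modules.labels[modules.labels != UNASSIGNED]
    flags = ppe_flags.reindex(
        universe if universe is not None else modules.labels.index
    ).fillna(False).astype(bool)
    if not flags.any():
        warnings.warn("no PPE genes in universe; all modules non-placental")
        groups = {m: "non-placental" for m in modules.module_names}
        modules.groups = groups
        return groups
    enr = module_enrichment(assigned, flags,
                            universe=universe if universe is not None
                            else modules.labels.index,
                            sided="greater")
    groups = {}
    for mod in modules.module_names:
        row = enr.loc[mod]
        placental = bool(row["p"] < alpha and row["odds_ratio"] > 1)
        groups[mod] = "placental" if placental else "non-placental"
    modules.groups = groups
    modules.ppe_enrichment = enr
    return groups


def module_trajectories(
    modules: ModuleSet, fc_day0: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean |log2FC vs day 0| per day, per module and per module group.

    The group curve is the plain mean over all member genes, i.e. the
    size-weighted mean of the member module curves.
    """
    mods = {}
    for mod in modules.module_names:
        genes = modules.genes_in(mod)
        if len(genes) == 0:
            raise ValueError(f"module {mod} is empty")
        mods[mod] = fc_day0.loc[genes].abs().mean(axis=0)
    per_module = pd.DataFrame(mods).T
    grp = {}
    for group in sorted(set(modules.groups.values())):
        genes = modules.group_genes(group)
        if len(genes):
            grp[group] = fc_day0.loc[genes].abs().mean(axis=0)
    return per_module, pd.DataFrame(grp).T
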