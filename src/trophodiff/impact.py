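"""Topology-based pathway impact analysis.

Each pathway is a signed directed graph of gene interactions (+1
activation, −1 inhibition).  A gene's perturbation factor PF(g) is its own
measured log2 fold change plus contributions propagated from its upstream
regulators, each weighted by the interaction sign and normalised by the
regulator's number of downstream edges:

    PF(g) = ΔE(g) + Σ_u  β_ug / N_ds(u) · PF(u)

i.e. PF = (I − B)⁻¹ ΔE with B[g, u] = β_ug / N_ds(u).  The pathway-level
accumulation tA = Σ_g (PF(g) − ΔE(g)) is scored against a bootstrap null
(pAcc) and combined with a hypergeometric over-representation p-value
(pORA) into a single pathway p-value pG = c − c·ln c, c = pORA·pAcc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "PathwayGraph",
    "ImpactResult",
    "perturbation_factors",
    "p_ora",
    "p_acc",
    "combine_p",
    "analyze_pathways",
]


@dataclass
class PathwayGraph:
    """Signed directed pathway topology."""

    pathway_id: str
    graph: nx.DiGraph                      # edges carry sign in {+1, -1}

    @classmethod
    def from_edges(cls, pathway_id: str, edges, extra_nodes=()) -> "PathwayGraph":
        g = nx.DiGraph()
        for u, v, sign in edges:
            if sign not in (1, -1):
                raise ValueError(f"edge sign must be +1 or -1, got {sign}")
            g.add_edge(u, v, sign=int(sign))
        g.add_nodes_from(extra_nodes)
        return cls(pathway_id, g)

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    def n_downstream(self, u) -> int:
        return self.graph.out_degree(u)

    def propagation_matrix(self) -> tuple[np.ndarray, list]:
        """B[g, u] = sign(u→g) / N_ds(u), in sorted node order."""
        nodes = self.nodes
        pos = {n: i for i, n in enumerate(nodes)}
        b = np.zeros((len(nodes), len(nodes)))
        for u, v, data in self.graph.edges(data=True):
            b[pos[v], pos[u]] = data["sign"] / self.graph.out_degree(u)
        return b, nodes

    def accumulation_weights(self) -> tuple[np.ndarray, list] | None:
        """Weights w with tA = w·ΔE, i.e. w = 1ᵀ((I−B)⁻¹ − I); None if singular."""
        b, nodes = self.propagation_matrix()
        eye = np.eye(len(nodes))
        m = eye - b
        if np.linalg.cond(m) > 1e12:
            return None
        inv = np.linalg.inv(m)
        return inv.sum(axis=0) - 1.0, nodes


def perturbation_factors(
    pathway: PathwayGraph, delta_e: dict | pd.Series
) -> tuple[pd.Series, pd.Series, float, str]:
    """Propagate fold changes over the topology.

    ``delta_e`` maps gene → log2FC (genes not present count as 0).
    Returns (PF, Acc, tA, status); a singular system marks the pathway
    ``non-evaluable`` with NaN results instead of raising.
    """
    b, nodes = pathway.propagation_matrix()
    de = np.array([float(delta_e.get(n, 0.0)) for n in nodes])
    m = np.eye(len(nodes)) - b
    if np.linalg.cond(m) > 1e12:
        nan = pd.Series(np.nan, index=nodes)
        return nan, nan.copy(), np.nan, "non-evaluable"
    pf = np.linalg.solve(m, de)
    acc = pf - de
    return (pd.Series(pf, index=nodes), pd.Series(acc, index=nodes),
            float(acc.sum()), "ok")


def p_ora(n_de_on_pathway: int, n_pathway: int, n_de_universe: int,
          n_universe: int) -> float:
    """Hypergeometric upper-tail over-representation p-value P(X >= observed)."""
    if n_de_on_pathway > min(n_pathway, n_de_universe):
        raise ValueError("more DE genes on pathway than possible")
    if n_pathway > n_universe or n_de_universe > n_universe:
        raise ValueError("inconsistent counts")
    if n_de_on_pathway == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_de_on_pathway - 1, n_universe,
                                    n_de_universe, n_pathway))


def p_acc(
    pathway: PathwayGraph,
    ta_obs: float,
    delta_e_pool: np.ndarray,
    n_de_on_pathway: int,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap p-value for the accumulated perturbation tA.

    Each round draws ``n_de_on_pathway`` fold changes from the observed DE
    pool, places them on uniformly chosen pathway genes and recomputes tA.
    The null is median-centred; the p-value is two-sided in |tA − median|
    with the +1 count correction.
    """
    if n_boot < 1:
        raise ValueError("need >= 1 bootstrap round")
    pool = np.asarray(delta_e_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty fold-change pool")
    if n_de_on_pathway < 1:
        return 1.0
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    weights_nodes = pathway.accumulation_weights()
    if weights_nodes is None:
        return np.nan
    w, nodes = weights_nodes
    k = min(n_de_on_pathway, len(nodes))
    # vectorised: tA_b = sum over placed genes of w[pos] * delta
    pos = np.array([
        rng.choice(len(nodes), size=k, replace=False) for _ in range(n_boot)
    ])
    draws = rng.choice(pool, size=(n_boot, k), replace=True)
    ta_null = (w[pos] * draws).sum(axis=1)
    med = np.median(ta_null)
    extreme = np.abs(ta_null - med) >= abs(ta_obs - med)
    return float((extreme.sum() + 1) / (n_boot + 1))


def combine_p(p_ora_value: float, p_acc_value: float) -> float:
    """Combine pORA and pAcc: pG = c − c·ln c with c = pORA·pAcc."""
    if not (0 < p_ora_value <= 1 and 0 < p_acc_value <= 1):
        raise ValueError("p-values must lie in (0, 1]")
    c = p_ora_value * p_acc_value
    return float(c - c * np.log(c))


@dataclass
class ImpactResult:
    pathway_id: str
    n_pathway: int
    n_de_on_pathway: int
    ta: float
    p_ora: float
    p_acc: float
    p_g: float
    status: str
    q: float = np.nan
    pf: pd.Series | None = None
    acc: pd.Series | None = None

    def gene_ranking(self) -> pd.DataFrame:
        """Per-gene accumulated perturbation, ranked by |Acc| (bar-plot data)."""
        if self.acc is None:
            return pd.DataFrame(columns=["acc"])
        frame = self.acc.to_frame("acc")
        return frame.reindex(frame["acc"].abs().sort_values(ascending=False).index)


def analyze_pathways(
    pathways: list[PathwayGraph],
    delta_e: pd.Series,
    de_genes,
    universe,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[list[ImpactResult], pd.DataFrame]:
    """Score every pathway: tA, pORA, pAcc, combined pG and BH q.

    ``delta_e`` holds signed log2 fold changes for DE genes (others 0);
    the over-representation universe is the full measured gene set.
    Pathways whose nodes carry no measurements are non-evaluable.
    """
    if not pathways:
        raise ValueError("no pathways supplied")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    universe = pd.Index(universe)
    de_genes = pd.Index(de_genes)
    pool = delta_e.reindex(de_genes).dropna().to_numpy(dtype=float)
    results = []
    for pw in pathways:
        nodes = pd.Index(pw.nodes)
        measured = nodes.intersection(universe)
        n_de_on = len(nodes.intersection(de_genes))
        if len(measured) == 0:
            results.append(ImpactResult(pw.pathway_id, len(nodes), 0, np.nan,
                                        np.nan, np.nan, np.nan, "non-evaluable"))
            continue
        de_map = {g: float(delta_e.get(g, 0.0)) for g in nodes
                  if g in de_genes}
        pf, acc, ta, status = perturbation_factors(pw, de_map)
        if status != "ok":
            results.append(ImpactResult(pw.pathway_id, len(nodes), n_de_on,
                                        np.nan, np.nan, np.nan, np.nan, status))
            continue
        ora = p_ora(n_de_on, len(measured), len(de_genes), len(universe))
        if n_de_on >= 1 and pool.size:
            pacc = p_acc(pw, ta, pool, n_de_on, n_boot=n_boot, seed=rng)
        else:
            pacc = 1.0
        pg = combine_p(ora, pacc) if np.isfinite(pacc) else np.nan
        results.append(ImpactResult(pw.pathway_id, len(nodes), n_de_on, ta,
                                    ora, pacc, pg, "ok", pf=pf, acc=acc))
    ok = [r for r in results if r.status == "ok"]
    if ok:
        qs = bh_adjust([r.p_g for r in ok])
        for r, q in zip(ok, qs):
            r.q = float(q)
    table = pd.DataFrame([
        {"pathway": r.pathway_id, "n": r.n_pathway, "n_de": r.n_de_on_pathway,
         "tA": r.ta, "pORA": r.p_ora, "pAcc": r.p_acc, "pG": r.p_g,
         "q": r.q, "status": r.status}
        for r in results
    ]).set_index("pathway")
    return results, table
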