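"""Transcription-regulator networks and the disease overlay.

Two complementary network constructions:

* a co-expression network connecting each differentially expressed
  transcription-regulatory (TR) gene to every DE gene whose 8-day profile
  correlates with it at |r| >= 0.9 (connectivity = neighbour count), and
* a DNaseI-footprint network: TF -> target edges wherever a motif instance
  labelled with the TF overlaps a footprint and lies inside the target's
  strand-aware promoter window, optionally filtered by expression
  correlation (|r| > 0.6).

The disease overlay classifies TR genes that are DE both in the
differentiation time course and in a second condition (preterm
preeclampsia in the original study) as concordant or discordant by
fold-change sign, and tests whether the discordant set is unusually tight
in co-expression space with a permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CoexpressionNetwork",
    "FootprintEdgeSet",
    "DiseaseOverlay",
    "build_tr_coexpression_network",
    "tr_timing",
    "footprint_edge_map",
    "attach_correlations",
    "module_coverage_report",
    "disease_overlay",
    "discordance_tightness",
]


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph                      # nodes: DE genes; edges carry r
    tr_genes: pd.Index                   # DE TR genes (the network's hubs)
    r_min: float

    def connectivity(self) -> pd.Series:
        """Neighbour count of every DE TR gene."""
        return pd.Series({g: self.graph.degree(g) for g in self.tr_genes},
                         dtype=int).sort_index()

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["r"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "r"])


def build_tr_coexpression_network(
    profiles: pd.DataFrame,
    de_genes,
    tr_flags: pd.Series,
    r_min: float = 0.9,
) -> CoexpressionNetwork:
    """Connect DE TR genes to DE genes with |profile correlation| >= r_min.

    Correlations are Pearson over the day-mean profiles.  TR–TR pairs give
    a single edge.  Genes with constant profiles cannot correlate and are
    skipped.
    """
    de_genes = pd.Index(de_genes)
    missing = de_genes.difference(profiles.index)
    if len(missing):
        raise ValueError(f"profiles missing DE genes: {list(missing[:5])}")
    tr = tr_flags.reindex(de_genes).fillna(False).astype(bool)
    tr_genes = de_genes[tr]
    graph = nx.Graph()
    graph.add_nodes_from(de_genes)
    if len(tr_genes) == 0:
        warnings.warn("no differentially expressed TR genes; empty network")
        return CoexpressionNetwork(graph, tr_genes, r_min)
    x = profiles.loc[de_genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    ok = sd > 0
    xc = (x - x.mean(axis=1, keepdims=True))
    denom = np.where(sd > 0, sd, 1.0) * np.sqrt(x.shape[1])
    xn = xc / denom[:, None]
    tr_pos = np.nonzero(tr.to_numpy())[0]
    corr = xn[tr_pos] @ xn.T                    # TR × all DE genes
    corr = np.clip(corr, -1.0, 1.0)
    for i, ti in enumerate(tr_pos):
        if not ok[ti]:
            continue
        hits = np.nonzero((np.abs(corr[i]) >= r_min) & ok)[0]
        gi = de_genes[ti]
        for j in hits:
            gj = de_genes[j]
            if gi == gj:
                continue
            graph.add_edge(gi, gj, r=float(corr[i, j]))
    return CoexpressionNetwork(graph, tr_genes, r_min)


def tr_timing(de_table, tr_flags: pd.Series) -> dict[str, set]:
    """Split DE TR genes by whether the DE rule first holds on day 1."""
    tr = tr_flags.reindex(de_table.genes).fillna(False).astype(bool)
    first = de_table.first_de_day()
    de_tr = de_table.is_de & tr
    day1 = set(de_table.genes[de_tr & (first == de_table.fc_day0.columns[0])])
    later = set(de_table.genes[de_tr]) - day1
    return {"day1": day1, "later": later}


@dataclass
class FootprintEdgeSet:
    """TF -> target edges supported by motif-in-footprint-in-promoter evidence."""

    edges: pd.DataFrame     # tf, target, motif/footprint intervals, n_support
    n_unmapped_tfs: int = 0
    unmapped_tfs: list = field(default_factory=list)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["target"]))

    def targets_of(self, tf: str) -> set:
        return set(self.edges.loc[self.edges["tf"] == tf, "target"])


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in sorted(iv):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect_tracks(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s, e = max(a[i][0], b[j][0]), min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _footprint_track(frames: list[pd.DataFrame], mode: str) -> dict[str, list]:
    per_file = []
    for bed in frames:
        track: dict[str, list] = {}
        for chrom, grp in bed.groupby("chrom"):
            track[chrom] = _merge_intervals(list(zip(grp["start"], grp["end"])))
        per_file.append(track)
    if mode == "union":
        merged: dict[str, list] = {}
        for track in per_file:
            for chrom, iv in track.items():
                merged.setdefault(chrom, []).extend(iv)
        return {c: _merge_intervals(iv) for c, iv in merged.items()}
    if mode == "intersection":
        base = per_file[0]
        for track in per_file[1:]:
            base = {c: _intersect_tracks(iv, track.get(c, []))
                    for c, iv in base.items()}
        return {c: iv for c, iv in base.items() if iv}
    raise ValueError("mode must be 'union' or 'intersection'")


def promoter_window(tss: int, strand: str, window=(-5000, 1000)) -> tuple[int, int]:
    """Strand-aware promoter interval around a TSS (0-based half-open).

    ``window`` is in transcription-direction coordinates (negative =
    upstream).  For the minus strand the interval is reflected.
    """
    w0, w1 = window
    if strand == "+":
        return tss + w0, tss + w1
    if strand == "-":
        return tss - w1 + 1, tss - w0 + 1
    raise ValueError(f"unknown strand {strand!r}")


def footprint_edge_map(
    footprints,
    motifs: pd.DataFrame,
    tss: pd.DataFrame,
    window: tuple[int, int] = (-5000, 1000),
    mode: str = "union",
) -> FootprintEdgeSet:
    """Derive TF -> target edges from footprint / motif / TSS interval files.

    An edge is created when a motif instance (name field = TF) overlaps a
    footprint by >= 1 bp and lies entirely within the target gene's
    promoter window.  ``footprints`` may be one BED frame or a list of
    them combined by ``mode`` (union or intersection).  Duplicate edges
    collapse with an evidence count.
    """
    if isinstance(footprints, pd.DataFrame):
        footprints = [footprints]
    track = _footprint_track(list(footprints), mode)

    promoters = []
    for _, row in tss.iterrows():
        ws, we = promoter_window(int(row["start"]), row["strand"], window)
        promoters.append((row["chrom"], ws, we, row["name"]))

    found: dict[tuple[str, str], dict] = {}
    for _, m in motifs.iterrows():
        chrom, ms, me, tf = m["chrom"], int(m["start"]), int(m["end"]), m["name"]
        fps = track.get(chrom, [])
        hit_fp = next(((fs, fe) for fs, fe in fps if fs < me and ms < fe), None)
        if hit_fp is None:
            continue
        for pchrom, ws, we, gene in promoters:
            if pchrom == chrom and ms >= ws and me <= we:
                key = (tf, gene)
                if key in found:
                    found[key]["n_support"] += 1
                else:
                    found[key] = {
                        "tf": tf, "target": gene,
                        "motif_chrom": chrom, "motif_start": ms, "motif_end": me,
                        "fp_start": hit_fp[0], "fp_end": hit_fp[1],
                        "n_support": 1,
                    }
    edges = pd.DataFrame(
        sorted(found.values(), key=lambda r: (r["tf"], r["target"])),
        columns=["tf", "target", "motif_chrom", "motif_start", "motif_end",
                 "fp_start", "fp_end", "n_support"],
    )
    return FootprintEdgeSet(edges)


def attach_correlations(
    edge_set: FootprintEdgeSet,
    profiles: pd.DataFrame,
    tf_gene_map: dict[str, str] | None = None,
    min_abs_r: float = 0.6,
) -> FootprintEdgeSet:
    """Annotate footprint edges with TF–target expression correlation.

    TF names map to gene ids through ``tf_gene_map`` (identity for names
    already present among the profiles).  Edges are retained only when
    |r| > min_abs_r (strictly); edges whose TF cannot be mapped to an
    expression profile are dropped from the filtered set but counted.
    """
    edges = edge_set.edges.copy()
    unmapped = []
    rs = []
    keep = []
    for _, row in edges.iterrows():
        tf_gene = (tf_gene_map or {}).get(row["tf"], row["tf"])
        if tf_gene not in profiles.index or row["target"] not in profiles.index:
            unmapped.append(row["tf"])
            rs.append(np.nan)
            keep.append(False)
            continue
        a = profiles.loc[tf_gene].to_numpy(dtype=float)
        b = profiles.loc[row["target"]].to_numpy(dtype=float)
        if a.std() == 0 or b.std() == 0:
            rs.append(np.nan)
            keep.append(False)
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        rs.append(r)
        keep.append(abs(r) > min_abs_r)
    edges["r"] = rs
    filtered = edges[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    return FootprintEdgeSet(filtered, n_unmapped_tfs=len(set(unmapped)),
                            unmapped_tfs=sorted(set(unmapped)))


def module_coverage_report(
    edge_set: FootprintEdgeSet,
    group_genes: dict[str, set],
    thresholds: tuple[float, float, float] = (0.04, 0.05, 0.10),
) -> pd.DataFrame:
    """Per-TF coverage of the placental / non-placental module-group genes.

    Coverage of a group is the fraction of its genes the TF targets.
    Flags report: both groups covered at >= thresholds[0]; each group at
    >= thresholds[1]; each group at >= thresholds[2].
    """
    for grp, genes in group_genes.items():
        if len(genes) == 0:
            raise ValueError(f"empty module group {grp!r}")
    t_both, t_mid, t_high = thresholds
    groups = sorted(group_genes)
    rows = []
    for tf in sorted(set(edge_set.edges["tf"])):
        targets = edge_set.targets_of(tf)
        cov = {g: len(targets & set(group_genes[g])) / len(group_genes[g])
               for g in groups}
        row = {"tf": tf}
        for g in groups:
            row[f"coverage_{g}"] = cov[g]
        row["both_ge_4pct"] = all(cov[g] >= t_both for g in groups)
        for g in groups:
            row[f"{g}_ge_5pct"] = cov[g] >= t_mid
            row[f"{g}_ge_10pct"] = cov[g] >= t_high
        rows.append(row)
    return pd.DataFrame(rows).set_index("tf") if rows else pd.DataFrame()


@dataclass
class DiseaseOverlay:
    table: pd.DataFrame            # per TR gene in both contexts
    discordant: pd.Index
    concordant: pd.Index
    tightness: float = np.nan
    tightness_p: float = np.nan


def disease_overlay(
    de_table,
    tr_flags: pd.Series,
    disease: pd.DataFrame,
    disease_q_threshold: float = 0.1,
    disease_fc_threshold: float = 2.0,
    modules: pd.Series | None = None,
    disease_modules: pd.Series | None = None,
) -> DiseaseOverlay:
    """Overlay a second-condition DE table on the differentiation results.

    TR genes that are DE in the time course and DE in the disease table
    (FDR below ``disease_q_threshold`` and |log2FC| >= log2 of
    ``disease_fc_threshold``) are classified concordant or discordant by
    comparing the sign of the differentiation fold change (taken at the
    day of maximum |log2FC|) with the disease fold change.
    """
    if "fdr" not in disease.columns:
        raise ValueError("disease table lacks an 'fdr' column")
    tr = tr_flags.reindex(de_table.genes).fillna(False).astype(bool)
    de_tr = de_table.genes[de_table.is_de & tr]
    rows = []
    for gene in de_tr:
        if gene not in disease.index:
            continue
        fc_dis = float(disease.at[gene, "log2fc"])
        fdr_dis = float(disease.at[gene, "fdr"])
        de_in_disease = (fdr_dis < disease_q_threshold
                         and abs(fc_dis) >= np.log2(disease_fc_threshold))
        fc_diff = float(de_table.signed_max_log2fc[gene])
        concordance = "not_de_in_disease"
        if de_in_disease:
            concordance = ("discordant" if np.sign(fc_diff) != np.sign(fc_dis)
                           else "concordant")
        rows.append({
            "gene": gene, "log2fc_differentiation": fc_diff,
            "log2fc_disease": fc_dis, "fdr_disease": fdr_dis,
            "de_both": de_in_disease, "concordance": concordance,
            "module": modules.get(gene) if modules is not None else None,
            "disease_module": (disease_modules.get(gene)
                               if disease_modules is not None else None),
        })
    table = pd.DataFrame(
        rows, columns=["gene", "log2fc_differentiation", "log2fc_disease",
                       "fdr_disease", "de_both", "concordance", "module",
                       "disease_module"],
    ).set_index("gene")
    disc = table.index[table["concordance"] == "discordant"]
    conc = table.index[table["concordance"] == "concordant"]
    return DiseaseOverlay(table, disc, conc)


def discordance_tightness(
    profiles: pd.DataFrame,
    discordant: pd.Index,
    de_tr_genes: pd.Index,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation test for co-expression tightness of the discordant set.

    The statistic is the mean pairwise |Pearson r| of the 8-day profiles
    within the set; the null draws same-size subsets of the DE TR genes.
    Returns (statistic, p) with p = (#null >= observed + 1) / (B + 1).
    """
    if n_permutations < 1:
        raise ValueError("need >= 1 permutation")
    discordant = pd.Index(discordant)
    if len(discordant) < 2:
        raise ValueError("discordant set must have >= 2 genes")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    pool = pd.Index(de_tr_genes)
    x = profiles.loc[pool].to_numpy(dtype=float)
    corr = np.corrcoef(x)
    pos = {g: i for i, g in enumerate(pool)}

    def mean_abs_r(idx):
        sub = np.abs(corr[np.ix_(idx, idx)])
        n = len(idx)
        return float((sub.sum() - n) / (n * (n - 1)))

    obs_idx = [pos[g] for g in discordant]
    stat = mean_abs_r(obs_idx)
    count = 0
    for _ in range(n_permutations):
        idx = rng.choice(len(pool), size=len(discordant), replace=False)
        if mean_abs_r(idx) >= stat:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return stat, p
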