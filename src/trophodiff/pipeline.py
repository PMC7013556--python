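"""Configuration and end-to-end orchestration of the analysis workflow.

``run_pipeline`` chains the stages the study performs on the time-course
matrix: differential expression → chromosome/module enrichment →
co-expression modules → HEC threshold + temporal clusters → TR networks →
pathway impact → disease overlay, writing every stage's table plus a
machine-readable JSON summary.  All thresholds default to the study's
values (FC ≥ 2, FDR < 0.1, |r| ≥ 0.9 and > 0.6, HEC override 2.5, k = 5,
GMT q < 0.2), so the zero-configuration path reproduces the published
analysis design.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, hec, io, networks
from .de import build_de_table, group_fc_comparison, summarize_time_course
from .enrichment import chromosome_enrichment, gmt_enrichment, module_enrichment
from .impact import PathwayGraph, analyze_pathways

__all__ = ["PipelineConfig", "InputBundle", "PipelineResult",
           "load_inputs", "run_pipeline", "write_report", "simulate_inputs"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # input paths (None = stage skipped where optional)
    expression: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None           # GMT
    pathways: str | None = None            # signed edge-list TSV
    footprints: tuple[str, ...] = ()       # one or more BED files
    motifs: str | None = None
    tss: str | None = None
    disease: str | None = None
    tf_gene_map: str | None = None         # two-column TSV tf<TAB>gene
    out_dir: str = "results/pipeline"
    # differential expression
    fc_threshold: float = 2.0
    q_threshold: float = 0.1
    constitutive_background: float | None = None
    constitutive_ratio: float = 4.0
    # co-expression modules
    soft_power: int | None = None          # None = scale-free scan
    soft_power_target_r2: float = 0.8
    signed_network: bool = False
    module_min_size: int = 30
    cut_quantile: float = 0.99
    module_group_alpha: float = 0.05
    # HEC stage
    hec_grid_start: float = 0.1
    hec_grid_stop: float = 4.0
    hec_grid_step: float = 0.1
    hec_slope_factor: float = 3.0
    hec_override: float | None = 2.5
    hec_k: int = 5
    hec_universe: str = "all"              # "all" measured genes or "de"
    # networks
    coexpression_r_min: float = 0.9
    footprint_min_abs_r: float = 0.6
    promoter_window: tuple[int, int] = (-5000, 1000)
    footprint_mode: str = "union"
    coverage_thresholds: tuple[float, float, float] = (0.04, 0.05, 0.10)
    # disease overlay
    disease_q_threshold: float = 0.1
    disease_fc_threshold: float = 2.0
    tightness_permutations: int = 1000
    # impact analysis
    impact_n_boot: int = 2000
    # gene-set enrichment
    gmt_q_threshold: float = 0.2
    # misc
    seed: int = 0
    plots: bool = False

    def __post_init__(self):
        if isinstance(self.footprints, str):
            self.footprints = (self.footprints,)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("footprints", "promoter_window", "coverage_thresholds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def hec_grid(self) -> np.ndarray:
        return np.round(np.arange(self.hec_grid_start,
                                  self.hec_grid_stop + 1e-9,
                                  self.hec_grid_step), 10)


@dataclass
class InputBundle:
    expr: "io.ExpressionMatrix"
    annotation: pd.DataFrame
    gene_sets: dict | None = None
    pathways: list[PathwayGraph] | None = None
    footprints: list[pd.DataFrame] = field(default_factory=list)
    motifs: pd.DataFrame | None = None
    tss: pd.DataFrame | None = None
    disease: pd.DataFrame | None = None
    tf_gene_map: dict[str, str] | None = None


def load_inputs(config: PipelineConfig) -> InputBundle:
    """Read and cross-validate all configured input files."""
    if config.expression is None or config.annotation is None:
        raise ValueError("expression and annotation paths are required")
    expr = io.read_expression(config.expression)
    ann = io.read_annotation(config.annotation)
    missing = expr.genes.difference(ann.index)
    if len(missing):
        log.warning("%d expression genes missing from the annotation; "
                    "treated as unflagged", len(missing))
        filler = pd.DataFrame({"chromosome": "chrNA", "is_ppe": False,
                               "is_tr": False}, index=missing)
        ann = pd.concat([ann, filler]).loc[expr.genes.union(ann.index)]
    bundle = InputBundle(expr=expr, annotation=ann)
    if config.gene_sets:
        bundle.gene_sets = io.read_gmt(config.gene_sets)
    if config.pathways:
        frame = io.read_pathways_tsv(config.pathways)
        bundle.pathways = [
            PathwayGraph.from_edges(pid, list(zip(g["source"], g["target"],
                                                  g["sign"])))
            for pid, g in frame.groupby("pathway_id")
        ]
    bundle.footprints = [io.read_bed(p) for p in config.footprints]
    if config.motifs:
        bundle.motifs = io.read_bed(config.motifs)
    if config.tss:
        bundle.tss = io.read_bed(config.tss)
    if config.disease:
        bundle.disease = io.read_disease_table(config.disease)
    if config.tf_gene_map:
        mapping = pd.read_csv(config.tf_gene_map, sep="\t",
                              names=["tf", "gene"], header=None)
        bundle.tf_gene_map = dict(zip(mapping["tf"], mapping["gene"]))
    log.info("loaded %d genes × %d samples; %d PPE, %d TR",
             len(expr.genes), expr.data.shape[1],
             int(ann["is_ppe"].sum()), int(ann["is_tr"].sum()))
    return bundle


@dataclass
class PipelineResult:
    config: PipelineConfig
    de_table: object
    timecourse_counts: pd.DataFrame
    chromosome_enrichment: pd.DataFrame
    modules: coexpression.ModuleSet | None
    module_table: pd.DataFrame | None
    hec: hec.HECResult | None
    coexpression_network: networks.CoexpressionNetwork | None
    footprint_edges: networks.FootprintEdgeSet | None
    coverage: pd.DataFrame | None
    impact_table: pd.DataFrame | None
    overlay: networks.DiseaseOverlay | None
    gene_set_enrichment: pd.DataFrame | None
    summary: dict


def _module_table(modules, ann, de_table) -> pd.DataFrame:
    """Module summary in the layout of the study's module table, plus a Σ row."""
    up = de_table.signed_max_log2fc > 0
    rows = []
    universe = modules.labels.index
    ppe_enr = module_enrichment(modules.labels, ann["is_ppe"], universe=universe)
    tr_enr = module_enrichment(modules.labels, ann["is_tr"], universe=universe)
    for mod in [*modules.module_names, coexpression.UNASSIGNED]:
        genes = modules.genes_in(mod)
        if len(genes) == 0:
            continue
        tr_genes = genes[ann.loc[genes, "is_tr"]]
        rows.append({
            "module": mod, "color": modules.colors.get(mod, "grey"),
            "group": modules.groups.get(mod, ""),
            "n_genes": len(genes),
            "n_ppe": int(ann.loc[genes, "is_ppe"].sum()),
            "ppe_or": (ppe_enr.at[mod, "odds_ratio"]
                       if mod in ppe_enr.index else np.nan),
            "pct_up": 100.0 * float(up.reindex(genes).mean()),
            "n_tr": len(tr_genes),
            "tr_or": (tr_enr.at[mod, "odds_ratio"]
                      if mod in tr_enr.index else np.nan),
            "pct_up_tr": (100.0 * float(up.reindex(tr_genes).mean())
                          if len(tr_genes) else np.nan),
        })
    frame = pd.DataFrame(rows).set_index("module")
    total = {
        "color": "", "group": "", "n_genes": frame["n_genes"].sum(),
        "n_ppe": frame["n_ppe"].sum(), "ppe_or": np.nan,
        "pct_up": 100.0 * float(up.reindex(universe).mean()),
        "n_tr": frame["n_tr"].sum(), "tr_or": np.nan, "pct_up_tr": np.nan,
    }
    frame.loc["total"] = total
    return frame


def run_pipeline(config: PipelineConfig,
                 bundle: InputBundle | None = None) -> PipelineResult:
    """Execute all configured stages and write their outputs to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = load_inputs(config)
    expr, ann = bundle.expr, bundle.annotation
    summary: dict = {"seed": config.seed}

    # --- differential expression -------------------------------------------
    de_table = build_de_table(
        expr, fc_threshold=config.fc_threshold, q_threshold=config.q_threshold,
        background_level=config.constitutive_background,
        constitutive_ratio=config.constitutive_ratio,
    )
    de_table.to_frame().to_csv(out / "de_table.tsv", sep="\t", index_label="gene")
    counts = summarize_time_course(
        de_table.fc_day0, de_table.q_day0, de_table.fc_prev, de_table.q_prev,
        config.fc_threshold, config.q_threshold)
    counts.to_csv(out / "timecourse_counts.tsv", sep="\t", index=False)
    de_genes = de_table.de_genes()
    n_up = int((de_table.is_de & (de_table.signed_max_log2fc > 0)).sum())
    summary["n_de"] = int(de_table.is_de.sum())
    summary["n_up"], summary["n_down"] = n_up, summary["n_de"] - n_up
    if de_table.is_constitutive is not None:
        summary["n_constitutive"] = int(de_table.is_constitutive.sum())

    ppe = ann["is_ppe"]
    if ppe.any() and (~ppe).sum() >= 2 and ppe.sum() >= 2:
        mean_in, mean_out, p_fc = group_fc_comparison(
            de_table.max_abs_log2fc[de_genes], ppe)
        summary["ppe_mean_linear_fc"] = mean_in
        summary["de_mean_linear_fc"] = mean_out
        summary["ppe_vs_de_fc_p"] = p_fc

    # --- chromosome enrichment of PPE genes --------------------------------
    chrom_enr = chromosome_enrichment(
        ann["chromosome"], ann.index[ppe], universe=ann.index)
    chrom_enr.to_csv(out / "chromosome_enrichment.tsv", sep="\t")
    if chrom_enr["odds_ratio"].notna().any():
        top = chrom_enr["odds_ratio"].idxmax()
        summary["top_ppe_chromosome"] = str(top)
        summary["top_ppe_chromosome_or"] = float(chrom_enr.at[top, "odds_ratio"])

    profiles_all = expr.day_means()

    # --- co-expression modules over DE genes -------------------------------
    modules = module_table = None
    if len(de_genes) >= 3:
        profiles = profiles_all.loc[de_genes]
        if config.soft_power is None:
            beta, scan = coexpression.pick_soft_power(
                profiles, target_r2=config.soft_power_target_r2,
                signed=config.signed_network)
        else:
            beta, scan = config.soft_power, None
        tom, kept = coexpression.tom_matrix(profiles, beta,
                                            signed=config.signed_network)
        modules = coexpression.detect_modules(
            tom, kept, min_size=config.module_min_size,
            cut_quantile=config.cut_quantile, beta=beta, power_scan=scan)
        coexpression.classify_module_groups(
            modules, ppe, alpha=config.module_group_alpha)
        pd.DataFrame({
            "module": modules.labels,
            "color": modules.labels.map(modules.colors),
            "group": modules.labels.map(modules.groups).fillna(""),
        }).to_csv(out / "modules.tsv", sep="\t", index_label="gene")
        module_table = _module_table(modules, ann, de_table)
        module_table.to_csv(out / "module_table.tsv", sep="\t")
        per_mod, per_grp = coexpression.module_trajectories(
            modules, de_table.fc_day0)
        per_mod.to_csv(out / "module_trajectories.tsv", sep="\t")
        per_grp.to_csv(out / "group_trajectories.tsv", sep="\t")
        summary["n_modules"] = len(modules.module_names)
        summary["soft_power"] = float(beta)
        summary["placental_modules"] = sorted(
            m for m, g in modules.groups.items() if g == "placental")

    # --- HEC threshold and temporal clusters -------------------------------
    hec_res = None
    hec_universe = de_genes if config.hec_universe == "de" else expr.genes
    if ppe.reindex(hec_universe).fillna(False).any():
        hec_res = hec.hec_analysis(
            de_table.max_abs_log2fc[hec_universe], ppe,
            de_table.fc_day0.loc[de_table.fc_day0.index.intersection(hec_universe)],
            grid=config.hec_grid(), slope_factor=config.hec_slope_factor,
            override=config.hec_override, k=config.hec_k)
        hec_res.curve.to_csv(out / "hec_curve.tsv", sep="\t", index=False)
        hec_frame = pd.DataFrame({
            "max_abs_log2fc": de_table.max_abs_log2fc[hec_res.hec_genes]})
        if hec_res.clusters is not None:
            hec_frame["cluster"] = hec_res.clusters
        hec_frame.to_csv(out / "hec_genes.tsv", sep="\t", index_label="gene")
        if hec_res.cluster_means is not None:
            hec_res.cluster_means.to_csv(out / "hec_cluster_means.tsv", sep="\t")
        summary["hec_threshold"] = hec_res.threshold
        summary["hec_auto_threshold"] = hec_res.auto_threshold
        summary["n_hec"] = len(hec_res.hec_genes)
        summary["hec_ppe_enrichment_or"] = hec_res.enrichment_fold
        if hec_res.clusters is not None:
            summary["hec_cluster_sizes"] = (
                hec_res.clusters.value_counts().sort_index().to_dict())

    # --- TR co-expression network ------------------------------------------
    coex = None
    if len(de_genes):
        coex = networks.build_tr_coexpression_network(
            profiles_all, de_genes, ann["is_tr"],
            r_min=config.coexpression_r_min)
        coex.edge_table().to_csv(out / "coexpression_edges.tsv", sep="\t",
                                 index=False)
        coex.connectivity().to_csv(out / "tr_connectivity.tsv", sep="\t",
                                   index_label="gene", header=["connectivity"])
        timing = networks.tr_timing(de_table, ann["is_tr"])
        summary["n_de_tr"] = len(timing["day1"]) + len(timing["later"])
        summary["n_tr_de_day1"] = len(timing["day1"])

    # --- footprint network --------------------------------------------------
    fp_edges = coverage = None
    if bundle.footprints and bundle.motifs is not None and bundle.tss is not None:
        raw_edges = networks.footprint_edge_map(
            bundle.footprints, bundle.motifs, bundle.tss,
            window=config.promoter_window, mode=config.footprint_mode)
        fp_edges = networks.attach_correlations(
            raw_edges, profiles_all, tf_gene_map=bundle.tf_gene_map,
            min_abs_r=config.footprint_min_abs_r)
        fp_edges.edges.to_csv(out / "footprint_edges.tsv", sep="\t", index=False)
        summary["n_footprint_edges_raw"] = len(raw_edges.edges)
        summary["n_footprint_edges_correlated"] = len(fp_edges.edges)
        if modules is not None and modules.groups:
            group_genes = {g: set(modules.group_genes(g))
                           for g in sorted(set(modules.groups.values()))}
            if all(group_genes.values()):
                coverage = networks.module_coverage_report(
                    fp_edges, group_genes,
                    thresholds=config.coverage_thresholds)
                coverage.to_csv(out / "tf_module_coverage.tsv", sep="\t")

    # --- pathway impact ------------------------------------------------------
    impact_table = None
    if bundle.pathways:
        _, impact_table = analyze_pathways(
            bundle.pathways, de_table.signed_max_log2fc.where(de_table.is_de, 0.0),
            de_genes, expr.genes, n_boot=config.impact_n_boot,
            seed=np.random.default_rng(config.seed))
        impact_table.to_csv(out / "pathway_impact.tsv", sep="\t")
        summary["n_pathways"] = len(impact_table)
        summary["n_pathways_significant"] = int((impact_table["pG"] < 0.05).sum())

    # --- gene-set enrichment of the DE set ----------------------------------
    gse = None
    if bundle.gene_sets and len(de_genes):
        gse = gmt_enrichment(de_genes, expr.genes, bundle.gene_sets,
                             q_threshold=config.gmt_q_threshold)
        gse.to_csv(out / "gene_set_enrichment.tsv", sep="\t")

    # --- disease overlay -----------------------------------------------------
    overlay = None
    if bundle.disease is not None and coex is not None:
        overlay = networks.disease_overlay(
            de_table, ann["is_tr"], bundle.disease,
            disease_q_threshold=config.disease_q_threshold,
            disease_fc_threshold=config.disease_fc_threshold,
            modules=modules.labels if modules is not None else None)
        overlay.table.to_csv(out / "disease_overlay.tsv", sep="\t")
        summary["n_de_both"] = int(overlay.table["de_both"].sum())
        summary["n_discordant"] = len(overlay.discordant)
        summary["discordant_genes"] = sorted(overlay.discordant)
        if len(overlay.discordant) >= 2:
            de_tr = [g for g in de_genes if ann.at[g, "is_tr"]]
            stat, p = networks.discordance_tightness(
                profiles_all, overlay.discordant, pd.Index(de_tr),
                n_permutations=config.tightness_permutations,
                seed=np.random.default_rng(config.seed + 7))
            overlay.tightness, overlay.tightness_p = stat, p
            summary["discordant_tightness"] = stat
            summary["discordant_tightness_p"] = p

    config.to_yaml(out / "resolved_config.yaml")
    io.write_json(summary, out / "summary.json")
    result = PipelineResult(
        config=config, de_table=de_table, timecourse_counts=counts,
        chromosome_enrichment=chrom_enr, modules=modules,
        module_table=module_table, hec=hec_res, coexpression_network=coex,
        footprint_edges=fp_edges, coverage=coverage, impact_table=impact_table,
        overlay=overlay, gene_set_enrichment=gse, summary=summary)
    if config.plots:
        write_report(result, out)
    return result


def write_report(result: PipelineResult, out_dir) -> None:
    """Write diagnostic plots for the main stages (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    fig, ax = plt.subplots(figsize=(5, 4))
    curve = result.hec.curve if result.hec is not None else None
    if curve is not None:
        ax.plot(curve["t"], curve["odds_ratio"], marker="o", ms=2)
        ax.axvline(result.hec.threshold, color="red", ls="--",
                   label=f"t* = {result.hec.threshold}")
        ax.set_xlabel("|log2FC| threshold")
        ax.set_ylabel("PPE enrichment OR")
        ax.legend()
    fig.savefig(out / "hec_curve.png", dpi=100)
    plt.close(fig)

    counts = result.timecourse_counts
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, baseline in zip(axes, ("day0", "prev")):
        sub = counts[counts["baseline"] == baseline]
        ax.bar(sub["day"] - 0.2, sub["n_up"], width=0.4, label="up")
        ax.bar(sub["day"] + 0.2, sub["n_down"], width=0.4, label="down")
        ax.set_title(f"vs {baseline}")
        ax.set_xlabel("day")
    axes[0].set_ylabel("DE genes")
    axes[0].legend()
    fig.savefig(out / "timecourse_counts.png", dpi=100)
    plt.close(fig)

    if result.modules is not None:
        _, per_grp = coexpression.module_trajectories(
            result.modules, result.de_table.fc_day0)
        fig, ax = plt.subplots(figsize=(5, 4))
        for grp, row in per_grp.iterrows():
            ax.plot(row.index, row.values, marker="o", label=grp)
        ax.set_xlabel("day")
        ax.set_ylabel("mean |log2FC| vs day 0")
        ax.legend()
        fig.savefig(out / "group_trajectories.png", dpi=100)
        plt.close(fig)


def simulate_inputs(syn_config, out_dir, write_fixtures: bool = True):
    """Generate a full synthetic input set on disk (plus the ground truth).

    Writes expression.tsv, annotation.tsv, disease.tsv, footprints.bed,
    motifs.bed, tss.bed, pathways.tsv and truth.json under ``out_dir`` and
    returns (paths dict, truth).
    """
    from . import synthetic
    from .de import build_de_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, ann, truth = synthetic.generate_timecourse(syn_config)
    io.write_expression(expr, out / "expression.tsv")
    io.write_annotation(ann, out / "annotation.tsv")
    paths = {"expression": str(out / "expression.tsv"),
             "annotation": str(out / "annotation.tsv")}
    de_table = build_de_table(expr)
    disease = synthetic.generate_disease_table(truth, de_table, syn_config)
    io.write_disease_table(disease, out / "disease.tsv")
    paths["disease"] = str(out / "disease.tsv")
    # gene-set collection: one term per planted module plus random decoys
    rng = np.random.default_rng(syn_config.seed + 5)
    terms = {f"planted_{mod}": set(genes) for mod, genes in
             truth.planted_module_genes().groupby(
                 truth.planted_module_genes()).groups.items()}
    for j in range(5):
        terms[f"random_{j + 1}"] = set(rng.choice(truth.genes, size=50,
                                                  replace=False))
    io.write_gmt(terms, out / "gene_sets.gmt")
    paths["gene_sets"] = str(out / "gene_sets.gmt")
    if write_fixtures:
        fix = synthetic.generate_footprint_fixtures(truth, syn_config)
        io.write_bed(fix.footprints, out / "footprints.bed")
        io.write_bed(fix.motifs, out / "motifs.bed")
        io.write_bed(fix.tss, out / "tss.bed")
        paths.update(footprints=str(out / "footprints.bed"),
                     motifs=str(out / "motifs.bed"), tss=str(out / "tss.bed"))
        pathways = synthetic.generate_pathway_fixture(
            truth.genes, seed=syn_config.seed + 3)
        rows = []
        for pw in pathways:
            for u, v, data in pw.graph.edges(data=True):
                rows.append((pw.pathway_id, u, v, data["sign"]))
        io.write_pathways_tsv(
            pd.DataFrame(rows, columns=["pathway_id", "source", "target",
                                        "sign"]),
            out / "pathways.tsv")
        paths["pathways"] = str(out / "pathways.tsv")
    io.write_json({
        "module_label": truth.module_label.to_dict(),
        "archetype": truth.archetype,
        "is_ppe": truth.is_ppe[truth.is_ppe].index,
        "is_tr": truth.is_tr[truth.is_tr].index,
        "disease_flip": sorted(truth.disease_flip),
    }, out / "truth.json")
    return paths, truth
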