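"""Synthetic trophoblast-differentiation data with known ground truth.

Generates an 8-day × 3-replicate log2 expression matrix with planted
co-expression modules following distinct temporal archetypes, placental
(PPE) and transcription-regulator (TR) gene labels, a chromosome layout
with one PPE-enriched chromosome, a second-condition (disease) DE table
whose discordant genes are planted, footprint/motif/TSS interval fixtures
with planted TF→target edges, and random signed pathway graphs.  Every
generated quantity is recorded in a :class:`SyntheticTruth` so downstream
stages can be scored against the planted answer.

Temporal archetypes (log2FC template f(day), scaled per gene by a
log-normal amplitude and a direction sign):

* ``flat`` — no change;
* ``immediate_transient`` — full response on day 1, halved on day 2, gone
  from day 3 on;
* ``immediate_persistent`` — full response from day 1, held;
* ``slow_persistent`` — linear rise over days 0–5, held.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de import ExpressionMatrix
from .impact import PathwayGraph

__all__ = [
    "ModuleSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "FootprintFixtures",
    "ARCHETYPES",
    "archetype_template",
    "generate_timecourse",
    "generate_disease_table",
    "generate_footprint_fixtures",
    "generate_pathway_fixture",
    "make_chain_pathway",
]

ARCHETYPES = ("flat", "immediate_transient", "immediate_persistent",
              "slow_persistent")


def archetype_template(archetype: str, days: np.ndarray) -> np.ndarray:
    """Unsigned unit-amplitude log2FC template f(day) for an archetype."""
    base = archetype.removesuffix("_up").removesuffix("_down")
    if base not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    days = np.asarray(days, dtype=float)
    if base == "flat":
        f = np.zeros_like(days)
    elif base == "immediate_transient":
        f = np.zeros_like(days)
        f[days == 1] = 1.0
        f[days == 2] = 0.5
    elif base == "immediate_persistent":
        f = (days >= 1).astype(float)
    else:  # slow_persistent
        f = np.minimum(days / 5.0, 1.0)
    sign = -1.0 if archetype.endswith("_down") else 1.0
    return sign * f


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: archetype (with _up/_down suffix), size, amplitudes.

    ``amp_mean``/``amp_sigma`` parameterise the log-normal amplitude
    distribution by its mean (log2 units) and log-scale SD.
    """

    archetype: str
    n_genes: int
    amp_mean: float = 1.5
    amp_sigma: float = 0.5


# default planted design: a dominant immediate down-regulated module and an
# immediate up/transient pair (the fast "non-placental" programme) plus two
# slow modules carrying most placental-marker genes (the "placental"
# programme), over a flat background
DEFAULT_MODULES = (
    ModuleSpec("immediate_persistent_down", 400),
    ModuleSpec("immediate_persistent_up", 200),
    ModuleSpec("immediate_transient_up", 150),
    ModuleSpec("slow_persistent_up", 250),
    ModuleSpec("slow_persistent_down", 100),
)
DEFAULT_PPE_FRACTIONS = (0.02, 0.02, 0.02, 0.20, 0.10)


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 3000
    n_days: int = 8
    n_reps: int = 3
    module_spec: tuple[ModuleSpec, ...] = DEFAULT_MODULES
    ppe_fraction_by_module: tuple[float, ...] = DEFAULT_PPE_FRACTIONS
    ppe_fraction_background: float = 0.005
    ppe_amp_multiplier: float = 2.0
    ppe_breakpoint: float | None = None    # when set, PPE amplitudes start here
    tr_fraction: float = 0.12
    n_chromosomes: int = 23
    ppe_chromosome: int = 19               # 1-based designated chromosome
    ppe_chromosome_bias: float = 4.0
    rep_sigma: float = 0.25
    baseline_range: tuple[float, float] = (6.0, 12.0)
    disease_flip_set_size: int = 7
    disease_concordant_fraction: float = 0.4
    disease_flip_min_amplitude: float = 1.2
    # footprint fixture geometry (0-based half-open toy genome)
    toy_chrom: str = "chrS"
    toy_chrom_length: int = 1_000_000
    promoter_window: tuple[int, int] = (-5000, 1000)
    motif_length: int = 10
    n_planted_tfs: int = 5
    targets_per_tf: int = 4
    n_decoy_motifs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_days <= 0 or self.n_reps <= 0:
            raise ValueError("counts must be positive")
        if sum(m.n_genes for m in self.module_spec) > self.n_genes:
            raise ValueError("module gene counts exceed n_genes")
        if len(self.ppe_fraction_by_module) != len(self.module_spec):
            raise ValueError("need one PPE fraction per module")
        fracs = (*self.ppe_fraction_by_module, self.ppe_fraction_background,
                 self.tr_fraction)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.rep_sigma < 0:
            raise ValueError("rep_sigma must be >= 0")
        for m in self.module_spec:
            archetype_template(m.archetype, np.arange(self.n_days))  # validates

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    module_label: pd.Series          # gene -> "mod1".. / "background"
    archetype: dict[str, str]        # module label -> archetype id
    amplitude: pd.Series             # planted amplitude (log2 units, >= 0)
    is_ppe: pd.Series
    is_tr: pd.Series
    chromosome: pd.Series
    disease_flip: set[str] = field(default_factory=set)
    config: SyntheticConfig | None = None

    @property
    def genes(self) -> pd.Index:
        return self.module_label.index

    def planted_module_genes(self) -> pd.Series:
        """Module labels restricted to non-background genes."""
        return self.module_label[self.module_label != "background"]


def _lognormal_amp(rng, mean: float, sigma: float, size: int) -> np.ndarray:
    mu = np.log(mean) - sigma ** 2 / 2.0
    return rng.lognormal(mu, sigma, size=size)


def generate_timecourse(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate the expression matrix, annotation table and ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene")
    days = np.arange(config.n_days)

    module_label = np.array(["background"] * n, dtype=object)
    archetype = {}
    start = 0
    for i, spec in enumerate(config.module_spec):
        lbl = f"mod{i + 1}"
        module_label[start:start + spec.n_genes] = lbl
        archetype[lbl] = spec.archetype
        start += spec.n_genes
    archetype["background"] = "flat"

    # PPE labels: per-module fractions, low background rate
    is_ppe = np.zeros(n, dtype=bool)
    start = 0
    for spec, frac in zip(config.module_spec, config.ppe_fraction_by_module):
        sel = rng.random(spec.n_genes) < frac
        is_ppe[start:start + spec.n_genes] = sel
        start += spec.n_genes
    is_ppe[start:] = rng.random(n - start) < config.ppe_fraction_background

    # amplitudes: log-normal, PPE genes from a higher-mean distribution.
    # Breakpoint mode is a purpose-built parameter-recovery benchmark:
    # non-boosted amplitudes follow a truncated exponential below the
    # breakpoint (so the enrichment odds grow at a steady geometric rate up
    # to it), while half of the PPE genes carry a slowly decaying boost
    # above it — the enrichment-vs-threshold curve then kinks sharply
    # upward at the planted breakpoint.
    amplitude = np.zeros(n)
    start = 0
    for spec in config.module_spec:
        ppe_here = is_ppe[start:start + spec.n_genes]
        if config.ppe_breakpoint is not None:
            bp, scale = config.ppe_breakpoint, spec.amp_mean
            u = rng.random(spec.n_genes)
            amps = -scale * np.log(1.0 - u * (1.0 - np.exp(-bp / scale)))
            boosted = rng.random(int(ppe_here.sum())) < 0.5
            mix = amps[ppe_here]
            mix[boosted] = bp + rng.exponential(1.0, size=int(boosted.sum()))
            amps[ppe_here] = mix
        else:
            amps = _lognormal_amp(rng, spec.amp_mean, spec.amp_sigma,
                                  spec.n_genes)
            amps[ppe_here] = _lognormal_amp(
                rng, spec.amp_mean * config.ppe_amp_multiplier, spec.amp_sigma,
                int(ppe_here.sum()))
        amplitude[start:start + spec.n_genes] = amps
        start += spec.n_genes

    is_tr = rng.random(n) < config.tr_fraction

    # chromosomes: uniform, except PPE genes biased to the designated one
    chroms = np.array([f"chr{c}" for c in range(1, config.n_chromosomes + 1)])
    designated = min(config.ppe_chromosome, config.n_chromosomes) - 1
    weights = np.ones(config.n_chromosomes)
    weights_ppe = weights.copy()
    weights_ppe[designated] = config.ppe_chromosome_bias
    chromosome = np.empty(n, dtype=object)
    chromosome[~is_ppe] = rng.choice(chroms, size=int((~is_ppe).sum()),
                                     p=weights / weights.sum())
    chromosome[is_ppe] = rng.choice(chroms, size=int(is_ppe.sum()),
                                    p=weights_ppe / weights_ppe.sum())

    # expression values
    baseline = rng.uniform(*config.baseline_range, size=n)
    templates = np.zeros((n, config.n_days))
    for i in range(n):
        templates[i] = archetype_template(archetype[module_label[i]], days)
    signal = baseline[:, None] + amplitude[:, None] * templates
    cols, mat = [], []
    for d in days:
        for r in range(1, config.n_reps + 1):
            cols.append(f"day{d}_rep{r}")
            mat.append(signal[:, d])
    values = np.column_stack(mat)
    if config.rep_sigma > 0:
        values = values + rng.normal(0.0, config.rep_sigma, size=values.shape)
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols))

    # disease flip set: TR genes with a robustly detectable planted change
    eligible = genes[(amplitude >= config.disease_flip_min_amplitude)
                     & is_tr & (module_label != "background")]
    k = min(config.disease_flip_set_size, len(eligible))
    if k < config.disease_flip_set_size:
        warnings.warn(f"only {k} TR genes eligible for the disease flip set")
    flip = set(rng.choice(eligible, size=k, replace=False)) if k else set()

    annotation = pd.DataFrame({
        "chromosome": chromosome, "is_ppe": is_ppe, "is_tr": is_tr,
    }, index=genes)
    truth = SyntheticTruth(
        module_label=pd.Series(module_label, index=genes),
        archetype=archetype,
        amplitude=pd.Series(amplitude, index=genes),
        is_ppe=pd.Series(is_ppe, index=genes),
        is_tr=pd.Series(is_tr, index=genes),
        chromosome=pd.Series(chromosome, index=genes),
        disease_flip=flip,
        config=config,
    )
    return expr, annotation, truth


def generate_disease_table(
    truth: SyntheticTruth,
    de_table,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Second-condition DE table with the planted flip set discordant.

    Genes in ``truth.disease_flip`` receive a disease log2FC of sign
    opposite to their differentiation fold change (at the max-|FC| day) at
    low FDR; a fraction of the other DE TR genes are concordant; everything
    else is reported non-significant.
    """
    config = config or truth.config
    if not truth.disease_flip <= set(truth.genes[truth.is_tr]):
        raise ValueError("disease flip set must be a subset of TR genes")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = {}
    de_tr = [g for g in de_table.genes
             if de_table.is_de[g] and truth.is_tr[g]]
    for gene in de_tr:
        sign_diff = np.sign(de_table.signed_max_log2fc[gene]) or 1.0
        if gene in truth.disease_flip:
            rows[gene] = (-sign_diff * rng.uniform(1.0, 3.0),
                          rng.uniform(1e-4, 0.05))
        elif rng.random() < config.disease_concordant_fraction:
            rows[gene] = (sign_diff * rng.uniform(1.0, 3.0),
                          rng.uniform(1e-4, 0.05))
        else:
            rows[gene] = (rng.normal(0.0, 0.3), rng.uniform(0.2, 0.9))
    missing_flips = truth.disease_flip - set(rows)
    if missing_flips:
        warnings.warn(f"{len(missing_flips)} flip genes are not DE in the "
                      "time course; they cannot appear discordant")
        for gene in sorted(missing_flips):
            rows[gene] = (rng.uniform(1.0, 3.0) * rng.choice([-1.0, 1.0]),
                          rng.uniform(1e-4, 0.05))
    table = pd.DataFrame(
        [(g, fc, fdr) for g, (fc, fdr) in sorted(rows.items())],
        columns=["gene", "log2fc", "fdr"],
    ).set_index("gene")
    return table


@dataclass
class FootprintFixtures:
    footprints: pd.DataFrame
    motifs: pd.DataFrame
    tss: pd.DataFrame
    planted_edges: set[tuple[str, str]]


def generate_footprint_fixtures(
    truth: SyntheticTruth,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> FootprintFixtures:
    """Toy-genome footprint/motif/TSS fixtures with planted TF→gene edges.

    TF names are TR gene ids (so the name→gene mapping is the identity).
    Each planted edge gets a motif inside a footprint inside the target's
    promoter window.  Decoy motifs are emitted both inside promoters
    without footprint support and inside footprints outside any promoter;
    neither may produce an edge.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    w0, w1 = config.promoter_window
    span = w1 - w0
    slot = 3 * span + 2000
    if span >= config.toy_chrom_length:
        raise ValueError("promoter window larger than the toy chromosome")

    tr_genes = list(truth.genes[truth.is_tr])
    n_tfs = min(config.n_planted_tfs, len(tr_genes))
    tfs = sorted(rng.choice(tr_genes, size=n_tfs, replace=False)) if n_tfs else []
    n_targets_needed = n_tfs * config.targets_per_tf
    max_slots = config.toy_chrom_length // slot - 1
    pool = [g for g in truth.genes if g not in tfs]
    targets = sorted(rng.choice(
        pool, size=min(n_targets_needed, len(pool), max_slots), replace=False))

    # lay target TSSs on well-separated slots, alternating strand
    tss_rows, windows = [], {}
    for i, gene in enumerate(targets):
        pos = (i + 1) * slot + span
        strand = "+" if i % 2 == 0 else "-"
        tss_rows.append((config.toy_chrom, pos, pos + 1, gene, ".", strand))
        ws, we = pos + w0, pos + w1
        if strand == "-":
            ws, we = pos - w1 + 1, pos - w0 + 1
        windows[gene] = (ws, we)

    planted: set[tuple[str, str]] = set()
    fp_rows, motif_rows = [], []
    tlist = list(targets)
    for tf in tfs:
        chosen = rng.choice(tlist, size=min(config.targets_per_tf, len(tlist)),
                            replace=False)
        for gene in chosen:
            ws, we = windows[gene]
            s = int(rng.integers(ws + 20, we - config.motif_length - 20))
            motif_rows.append((config.toy_chrom, s, s + config.motif_length,
                               tf, ".", "."))
            fp_rows.append((config.toy_chrom, s - 5,
                            s + config.motif_length + 5, "footprint", ".", "."))
            planted.add((tf, gene))

    # decoys: motifs in promoters without footprints, and motifs in
    # footprints that fall between promoter slots
    occupied = [(r[1], r[2]) for r in fp_rows]
    for j in range(config.n_decoy_motifs):
        tf = tfs[j % len(tfs)] if tfs else f"TFdecoy{j}"
        if j % 2 == 0 and targets:
            gene = tlist[int(rng.integers(len(tlist)))]
            ws, we = windows[gene]
            for _ in range(100):
                s = int(rng.integers(ws, we - config.motif_length))
                e = s + config.motif_length
                if not any(fs < e and s < fe for fs, fe in occupied):
                    motif_rows.append((config.toy_chrom, s, e, tf, ".", "."))
                    break
        else:
            base = int(rng.integers(len(targets) + 1)) * slot if targets else 0
            s = base + 2 * span + int(rng.integers(0, 500))
            e = s + config.motif_length
            in_promoter = any(ws <= s and e <= we for ws, we in windows.values())
            if not in_promoter:
                motif_rows.append((config.toy_chrom, s, e, tf, ".", "."))
                fp_rows.append((config.toy_chrom, s - 5, e + 5,
                                "footprint_decoy", ".", "."))
                occupied.append((s - 5, e + 5))

    cols = ["chrom", "start", "end", "name", "score", "strand"]
    return FootprintFixtures(
        footprints=pd.DataFrame(fp_rows, columns=cols),
        motifs=pd.DataFrame(motif_rows, columns=cols),
        tss=pd.DataFrame(tss_rows, columns=cols),
        planted_edges=planted,
    )


def generate_pathway_fixture(
    gene_universe,
    n_pathways: int = 10,
    n_nodes: tuple[int, int] = (8, 15),
    edge_prob: float = 0.35,
    p_activation: float = 0.7,
    include_cycle: bool = False,
    seed: int = 0,
) -> list[PathwayGraph]:
    """Random signed DAG pathways (optionally with a single feedback cycle).

    Node ids are drawn from ``gene_universe``; edges point from earlier to
    later sampled nodes, so the DAG property holds by construction unless
    ``include_cycle`` adds one back edge.
    """
    if n_nodes[0] < 2:
        raise ValueError("pathways need >= 2 nodes")
    rng = np.random.default_rng(seed)
    universe = list(gene_universe)
    pathways = []
    for p in range(n_pathways):
        size = int(rng.integers(n_nodes[0], n_nodes[1] + 1))
        nodes = list(rng.choice(universe, size=min(size, len(universe)),
                                replace=False))
        edges = []
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if rng.random() < edge_prob:
                    sign = 1 if rng.random() < p_activation else -1
                    edges.append((nodes[i], nodes[j], sign))
        if not edges:
            edges.append((nodes[0], nodes[1], 1))
        if include_cycle and len(nodes) >= 3:
            edges.append((nodes[-1], nodes[0], 1))
        pathways.append(PathwayGraph.from_edges(f"synthetic_pw{p + 1}", edges,
                                                extra_nodes=nodes))
    return pathways


def make_chain_pathway(genes, signs, pathway_id: str = "chain") -> PathwayGraph:
    """Linear cascade g1 → g2 → ... with the given edge signs."""
    genes = list(genes)
    if len(signs) != len(genes) - 1:
        raise ValueError("need one sign per chain edge")
    edges = [(genes[i], genes[i + 1], signs[i]) for i in range(len(signs))]
    return PathwayGraph.from_edges(pathway_id, edges, extra_nodes=genes)
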