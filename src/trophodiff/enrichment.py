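"""2x2 Fisher enrichment machinery.

Covers chromosome enrichment of gene sets, co-expression module enrichment
(placental-marker and transcription-regulator flags), generic GMT gene-set
enrichment with coverage percentages, and the odds ratio conventions used
throughout the pipeline.

The exact test is computed from first principles: with both margins fixed
the table count ``a`` follows a hypergeometric law whose point masses are
ratios of binomial coefficients.  Working with the integer numerators makes
tie comparisons in the two-sided (point-probability) rule exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .de import bh_adjust

__all__ = [
    "FisherResult",
    "EnrichmentRecord",
    "fisher_2x2",
    "odds_ratio",
    "enrichment_from_counts",
    "module_enrichment",
    "chromosome_enrichment",
    "gmt_enrichment",
]


@dataclass
class FisherResult:
    odds_ratio: float
    p: float
    haldane: bool = False  # True when the displayed OR used the +0.5 correction


@dataclass
class EnrichmentRecord:
    """One 2x2 enrichment result.

    Cells follow the convention (a, b, c, d) = (in-set & in-group,
    in-set & out-of-group, out-of-set & in-group, out & out); the odds
    ratio is the raw cross-product a*d / (b*c), reported as NaN when a
    margin is empty and with the Haldane–Anscombe +0.5 correction (flagged)
    when a single cell is zero.
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float = np.nan
    haldane: bool = False
    coverage: float = np.nan


def _check_cells(*cells) -> tuple[int, ...]:
    out = []
    for x in cells:
        if x < 0 or int(x) != x:
            raise ValueError(f"2x2 cells must be non-negative integers, got {x}")
        out.append(int(x))
    return tuple(out)


def odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """Cross-product odds ratio ad/bc.

    Returns (OR, haldane_flag).  With an empty margin the OR is undefined
    (NaN); with a single zero cell the Haldane–Anscombe +0.5 correction is
    applied to every cell and flagged.
    """
    a, b, c, d = _check_cells(a, b, c, d)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return np.nan, False
    if 0 in (a, b, c, d):
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


def fisher_2x2(a: int, b: int, c: int, d: int, sided: str = "two") -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    ``sided`` is ``"two"`` (point-probability rule: sum over all tables with
    the observed margins whose probability does not exceed the observed
    table's), ``"greater"`` (upper tail in ``a``) or ``"less"``.  The odds
    ratio is the raw cross-product; the +0.5 correction is applied for
    display only, never to the p-value.
    """
    a, b, c, d = _check_cells(a, b, c, d)
    or_, haldane = odds_ratio(a, b, c, d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return FisherResult(or_, 1.0, haldane)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    # integer numerators of the hypergeometric pmf; denominator C(n, c1)
    weights = {x: comb(r1, x) * comb(n - r1, c1 - x) for x in range(lo, hi + 1)}
    total = comb(n, c1)
    w_obs = weights[a]
    if sided == "two":
        num = sum(w for w in weights.values() if w <= w_obs)
    elif sided == "greater":
        num = sum(w for x, w in weights.items() if x >= a)
    elif sided == "less":
        num = sum(w for x, w in weights.items() if x <= a)
    else:
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    return FisherResult(or_, min(num / total, 1.0), haldane)


def enrichment_from_counts(
    label: str,
    n_group: int,
    n_flagged_in_group: int,
    n_universe: int,
    n_flagged_universe: int,
    sided: str = "two",
) -> EnrichmentRecord:
    """Enrichment record from group/universe counts (e.g. a module table row)."""
    a = n_flagged_in_group
    b = n_group - a
    c = n_flagged_universe - a
    d = n_universe - n_group - c
    if min(b, c, d) < 0:
        raise ValueError(f"{label}: inconsistent counts")
    res = fisher_2x2(a, b, c, d, sided=sided)
    return EnrichmentRecord(label, a, b, c, d, res.odds_ratio, res.p,
                            haldane=res.haldane)


def _records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([r.__dict__ for r in records]).set_index("label")
    if len(frame):
        frame["q"] = bh_adjust(frame["p"].to_numpy())
        for rec, q in zip(records, frame["q"]):
            rec.q = float(q)
    return frame


def module_enrichment(
    module_labels: pd.Series,
    flags: pd.Series,
    universe=None,
    sided: str = "two",
) -> pd.DataFrame:
    """Per-module 2x2 enrichment of a binary gene flag.

    ``module_labels`` maps gene → module id; the universe defaults to the
    labelled genes (in the study this is the DE gene set).  BH adjustment
    is applied across the modules as one family.
    """
    if universe is None:
        universe = module_labels.index
    universe = pd.Index(universe)
    missing = module_labels.index.difference(universe)
    if len(missing):
        raise ValueError(f"modules contain genes outside the universe: {list(missing[:5])}")
    flags = flags.reindex(universe).fillna(False).astype(bool)
    n_uni, n_flag = len(universe), int(flags.sum())
    records = []
    for mod, genes in module_labels.groupby(module_labels).groups.items():
        a = int(flags.loc[list(genes)].sum())
        records.append(
            enrichment_from_counts(str(mod), len(genes), a, n_uni, n_flag, sided=sided)
        )
    records.sort(key=lambda r: r.label)
    return _records_to_frame(records)


def chromosome_enrichment(
    chromosomes: pd.Series,
    gene_set,
    universe=None,
    sided: str = "two",
) -> pd.DataFrame:
    """Per-chromosome Fisher enrichment of a gene set within a universe."""
    if universe is None:
        universe = chromosomes.index
    universe = pd.Index(universe)
    gene_set = pd.Index(gene_set)
    if len(gene_set.difference(universe)):
        raise ValueError("gene_set is not contained in the universe")
    chrom = chromosomes.reindex(universe)
    in_set = universe.isin(gene_set)
    records = []
    for ch in sorted(chrom.dropna().unique()):
        on = (chrom == ch).to_numpy()
        a = int((on & in_set).sum())
        b = int((~on & in_set).sum())
        c = int((on & ~in_set).sum())
        d = int((~on & ~in_set).sum())
        res = fisher_2x2(a, b, c, d, sided=sided)
        records.append(EnrichmentRecord(str(ch), a, b, c, d, res.odds_ratio,
                                        res.p, haldane=res.haldane))
    return _records_to_frame(records)


def gmt_enrichment(
    gene_set,
    universe,
    collections: dict[str, set],
    sided: str = "greater",
    q_threshold: float = 0.2,
) -> pd.DataFrame:
    """Gene-set (GMT term) enrichment with coverage percentages.

    Terms are intersected with the universe before testing; terms disjoint
    from the universe are dropped with a warning.  Coverage is the fraction
    of the query set annotated to the term (reported as a percentage).  The
    default test is one-sided enrichment; ``q`` marks terms significant at
    the BH ``q_threshold`` via the ``significant`` column.
    """
    universe = pd.Index(universe)
    gene_set = pd.Index(gene_set)
    if len(universe) == 0 or len(gene_set) == 0:
        raise ValueError("universe and gene_set must be non-empty")
    in_set = set(gene_set)
    records = []
    for term, members in collections.items():
        members = set(members) & set(universe)
        if not members:
            warnings.warn(f"term {term!r} has no genes in the universe; dropped")
            continue
        a = len(members & in_set)
        b = len(in_set) - a
        c = len(members) - a
        d = len(universe) - len(in_set) - c
        res = fisher_2x2(a, b, c, d, sided=sided)
        records.append(EnrichmentRecord(
            str(term), a, b, c, d, res.odds_ratio, res.p,
            haldane=res.haldane, coverage=100.0 * a / len(in_set),
        ))
    frame = _records_to_frame(records)
    if len(frame):
        frame["significant"] = frame["q"] < q_threshold
    return frame
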