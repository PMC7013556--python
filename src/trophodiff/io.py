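"""Readers and writers for the pipeline's plain-text formats.

Expression matrices, gene annotations, DE tables and network tables travel
as TSV; genomic intervals (DNaseI footprints, motif instances, TSS) as BED
(0-based, half-open); gene-set collections as GMT; run summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .de import ExpressionMatrix

__all__ = [
    "read_expression", "write_expression",
    "read_annotation", "write_annotation",
    "read_bed", "write_bed",
    "read_gmt", "write_gmt",
    "read_pathways_tsv", "write_pathways_tsv",
    "read_disease_table", "write_disease_table",
    "write_json",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_expression(path) -> ExpressionMatrix:
    """Read a genes × samples log2 expression TSV (columns day{d}_rep{r})."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate gene ids, e.g. {list(dups[:3])}")
    return ExpressionMatrix(frame)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def read_annotation(path) -> pd.DataFrame:
    """Read the gene annotation TSV (gene, chromosome, is_ppe, is_tr, ...)."""
    ann = pd.read_csv(path, sep="\t", index_col=0)
    required = {"chromosome", "is_ppe", "is_tr"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    for col in ("is_ppe", "is_tr"):
        ann[col] = ann[col].astype(bool)
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="gene")


def read_bed(path) -> pd.DataFrame:
    """Parse a BED file (>= 3 columns; name/score/strand optional).

    Intervals are 0-based half-open.  Malformed lines are reported with
    their line number; strands must be '+' or '-' when present.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start},{end})")
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "."
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            rows.append((parts[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, "
                                 "description and >=1 gene")
            terms[parts[0]] = {g for g in parts[2:] if g}
    return terms


def write_gmt(terms: dict[str, set], path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_pathways_tsv(path) -> pd.DataFrame:
    """Read a signed directed pathway edge list: pathway_id, source, target, sign."""
    frame = pd.read_csv(path, sep="\t", dtype={"sign": int})
    required = {"pathway_id", "source", "target", "sign"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing pathway columns {sorted(missing)}")
    bad = ~frame["sign"].isin([1, -1])
    if bad.any():
        raise ValueError(f"{path}: edge signs must be +1 or -1")
    return frame


def write_pathways_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_disease_table(path) -> pd.DataFrame:
    """Read a second-condition DE table: gene, log2fc, fdr."""
    frame = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "fdr"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing disease-table columns {sorted(missing)}")
    if frame["gene"].duplicated().any():
        raise ValueError(f"{path}: duplicate genes in disease table")
    return frame.set_index("gene")


def write_disease_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset, pd.Index)):
            return sorted(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     cls=_NumpyEncoder) + "\n")
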