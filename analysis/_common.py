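"""Shared loading for the numbered analysis drivers."""

import argparse
from pathlib import Path

from trophodiff import io
from trophodiff.de import build_de_table


def standard_args(description, **extra):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--data", type=Path, default=Path("results/data"),
                    help="input directory written by 01_simulate.py")
    ap.add_argument("--out", type=Path, default=None)
    ap.add_argument("--seed", type=int, default=0)
    for name, kw in extra.items():
        ap.add_argument(f"--{name.replace('_', '-')}", **kw)
    return ap


def load_study(data_dir: Path):
    expr = io.read_expression(data_dir / "expression.tsv")
    ann = io.read_annotation(data_dir / "annotation.tsv")
    de = build_de_table(expr)
    return expr, ann, de
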