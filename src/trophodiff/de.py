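"""Time-course differential expression on log2 expression matrices.

The experimental design is a differentiation time course: samples collected
daily (day 0 .. day 7, three replicates per day in the original design).
Fold changes are computed from day-mean log2 intensities against two
baselines — day 0 and the previous day — and tested with an empirical-Bayes
moderated t-statistic.  A gene is called differentially expressed (DE) when
on some day versus day 0 it shows a fold change of at least ``fc_threshold``
(linear scale, default 2) together with a Benjamini–Hochberg adjusted
p-value below ``q_threshold`` (default 0.1) in that same comparison.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ModerationParams",
    "DifferentialExpressionTable",
    "fold_change_table",
    "moderated_t_test",
    "estimate_moderation",
    "bh_adjust",
    "call_de",
    "de_flags",
    "detect_constitutive",
    "summarize_time_course",
    "group_fc_comparison",
    "build_de_table",
]

_SAMPLE_RE = re.compile(r"^day(\d+)_rep(\d+)$")


class ExpressionMatrix:
    """Genes × samples matrix of log2 intensities.

    Columns follow the ``day{d}_rep{r}`` convention.  Day 0 must be present
    and every represented day needs at least one replicate.
    """

    def __init__(self, data: pd.DataFrame):
        days = {}
        for col in data.columns:
            m = _SAMPLE_RE.match(str(col))
            if m is None:
                raise ValueError(
                    f"sample column {col!r} does not match 'day{{d}}_rep{{r}}'"
                )
            days.setdefault(int(m.group(1)), []).append(col)
        if 0 not in days:
            raise ValueError("expression matrix has no day 0 samples")
        if not np.isfinite(data.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        if data.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        self.data = data
        self._day_cols = {d: sorted(cols) for d, cols in days.items()}

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def days(self) -> list[int]:
        return sorted(self._day_cols)

    def day_columns(self, day: int) -> list[str]:
        return self._day_cols[day]

    def day_values(self, day: int) -> np.ndarray:
        """Log2 values on a day, shape (genes, replicates)."""
        return self.data[self._day_cols[day]].to_numpy(dtype=float)

    def day_means(self, genes=None) -> pd.DataFrame:
        """Per-gene mean log2 expression for each day (replicates averaged)."""
        out = {d: self.data[cols].mean(axis=1) for d, cols in self._day_cols.items()}
        means = pd.DataFrame(out).reindex(columns=self.days)
        if genes is not None:
            missing = [g for g in genes if g not in means.index]
            if missing:
                raise KeyError(f"unknown genes: {missing[:5]}")
            means = means.loc[list(genes)]
        return means


@dataclass
class ModerationParams:
    """Empirical-Bayes hyperparameters for the moderated t-statistic.

    ``d0`` is the prior degrees of freedom (``inf`` allowed) and ``s0_sq``
    the prior variance in squared log2 units.
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0 and np.isfinite(self.d0) and self.d0 > 0:
            raise ValueError("s0_sq must be > 0")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Method-of-moments fit of the variance prior on log sample variances.

    Under the hierarchical model s²_g ~ s0² · F(df, d0), the moments of
    log s²_g identify (d0, s0²) through digamma/trigamma functions.  If the
    observed spread of log s² does not exceed its expected sampling spread,
    the prior is degenerate and d0 is reported as infinite.
    """
    s2 = np.asarray(s2, dtype=float)
    z = np.log(np.where(s2 > 0, s2, np.nan))
    z = z[np.isfinite(z)]
    if len(z) < 2:
        return ModerationParams(d0=np.inf, s0_sq=float(np.nanmedian(s2)) or 1e-12)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    var_e = float(np.var(e, ddof=1))
    excess = var_e - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        s0_sq = float(np.exp(np.mean(e)))
        return ModerationParams(d0=np.inf, s0_sq=max(s0_sq, 1e-300))
    d0 = 2.0 * _trigamma_inverse(excess)
    log_s0 = np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    return ModerationParams(d0=d0, s0_sq=float(np.exp(log_s0)))


def moderated_t_test(
    expr: ExpressionMatrix,
    day: int,
    baseline: str = "day0",
    params: ModerationParams | None = None,
) -> tuple[pd.Series, pd.Series, ModerationParams | None]:
    """Moderated two-sample t-test of day-d means versus a baseline day.

    ``baseline`` is ``"day0"`` or ``"prev"``.  Pooled per-gene residual
    variances are shrunk toward the method-of-moments prior; pass ``params``
    to force hyperparameters (d0=0 recovers the ordinary pooled t, d0=inf
    the fixed-denominator normal test).

    Returns (t, p, params); with fewer than two replicates in either group
    the statistics are NaN and a warning is emitted.
    """
    base_day = 0 if baseline == "day0" else day - 1
    if baseline not in ("day0", "prev"):
        raise ValueError("baseline must be 'day0' or 'prev'")
    a = expr.day_values(day)
    b = expr.day_values(base_day)
    n_a, n_b = a.shape[1], b.shape[1]
    genes = expr.genes
    if n_a < 2 or n_b < 2:
        warnings.warn(
            f"day {day} vs {baseline}: <2 replicates in a group; "
            "moderated statistics unavailable (DE calling will use FC only)"
        )
        nan = pd.Series(np.nan, index=genes)
        return nan, nan.copy(), None

    delta = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n_a + n_b - 2
    s2 = ss / df
    if params is None:
        params = estimate_moderation(s2, df)
    d0, s0_sq = params.d0, params.s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    scale = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(scale > 0, delta / np.where(scale > 0, scale, 1.0),
                     np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.Series(t, index=genes), pd.Series(p, index=genes), params


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved).

    NaN entries propagate as NaN and do not count toward the family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def de_flags(
    fc: pd.DataFrame, q: pd.DataFrame, fc_threshold: float = 2.0,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-comparison DE flags: |log2FC| >= log2(fc_threshold) and q < q_threshold.

    When q is entirely NaN for a day (too few replicates) the significance
    condition is waived for that day and the FC criterion alone applies.
    """
    cut = np.log2(fc_threshold)
    flags = fc.abs() >= cut
    for col in fc.columns:
        qc = q[col]
        if qc.notna().any():
            flags[col] &= qc < q_threshold
    return flags


def call_de(
    fc_day0: pd.DataFrame, q_day0: pd.DataFrame,
    fc_threshold: float = 2.0, q_threshold: float = 0.1,
) -> pd.Series:
    """Gene-level DE call: the day-0-baseline rule holds on at least one day."""
    return de_flags(fc_day0, q_day0, fc_threshold, q_threshold).any(axis=1)


def fold_change_table(expr: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 fold changes of day means versus day 0 and versus the previous day.

    Returns (fc_vs_day0, fc_vs_prev), each genes × days (day 0 excluded).
    """
    means = expr.day_means()
    days = [d for d in expr.days if d != 0]
    fc0 = pd.DataFrame({d: means[d] - means[0] for d in days})
    prev = {d: means[d] - means[expr.days[expr.days.index(d) - 1]] for d in days}
    return fc0, pd.DataFrame(prev)


def detect_constitutive(
    expr: ExpressionMatrix, background_level: float, ratio: float = 4.0
) -> pd.Series:
    """Flag genes whose expression stays high on every day.

    A gene is constitutively high when the smallest day-mean linear
    intensity (2^mean-log2) over all days is at least ``ratio`` times the
    ``background_level`` (linear scale).  The boundary is inclusive.
    """
    if background_level <= 0:
        raise ValueError("background_level must be > 0")
    linear_min = np.power(2.0, expr.day_means()).min(axis=1)
    return linear_min >= ratio * background_level


def summarize_time_course(
    fc_day0: pd.DataFrame, q_day0: pd.DataFrame,
    fc_prev: pd.DataFrame, q_prev: pd.DataFrame,
    fc_threshold: float = 2.0, q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-day counts of up/down DE genes for both baselines.

    A gene counts as up or down on a day when the DE rule holds in that
    single comparison; the sign is the sign of that comparison's log2FC.
    """
    rows = []
    for name, fc, q in (("day0", fc_day0, q_day0), ("prev", fc_prev, q_prev)):
        flags = de_flags(fc, q, fc_threshold, q_threshold)
        for d in fc.columns:
            hit = flags[d]
            rows.append({
                "day": d, "baseline": name,
                "n_up": int((hit & (fc[d] > 0)).sum()),
                "n_down": int((hit & (fc[d] < 0)).sum()),
            })
    return pd.DataFrame(rows)


def group_fc_comparison(
    max_abs_log2fc: pd.Series, group_flags: pd.Series
) -> tuple[float, float, float]:
    """Compare mean linear maximum fold change inside vs outside a gene group.

    Returns (mean linear max-FC in group, out of group, Welch-t p on the
    log2 values).  Requires at least two genes on each side.
    """
    flags = group_flags.reindex(max_abs_log2fc.index).fillna(False).astype(bool)
    inside = max_abs_log2fc[flags]
    outside = max_abs_log2fc[~flags]
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError("need >= 2 genes on each side of the comparison")
    p = stats.ttest_ind(inside, outside, equal_var=False).pvalue
    return (
        float(np.power(2.0, inside).mean()),
        float(np.power(2.0, outside).mean()),
        float(p),
    )


@dataclass
class DifferentialExpressionTable:
    """Full per-gene, per-day differential expression results."""

    fc_day0: pd.DataFrame
    fc_prev: pd.DataFrame
    p_day0: pd.DataFrame
    q_day0: pd.DataFrame
    p_prev: pd.DataFrame
    q_prev: pd.DataFrame
    t_day0: pd.DataFrame
    t_prev: pd.DataFrame
    max_abs_log2fc: pd.Series
    max_fc_day: pd.Series
    signed_max_log2fc: pd.Series
    is_de: pd.Series
    is_constitutive: pd.Series | None = None
    moderation: dict = field(default_factory=dict)
    fc_threshold: float = 2.0
    q_threshold: float = 0.1

    @property
    def genes(self) -> pd.Index:
        return self.fc_day0.index

    def de_genes(self) -> pd.Index:
        return self.is_de.index[self.is_de]

    def de_flags_day0(self) -> pd.DataFrame:
        return de_flags(self.fc_day0, self.q_day0, self.fc_threshold, self.q_threshold)

    def first_de_day(self) -> pd.Series:
        """First day on which the day-0-baseline DE rule holds (NaN if never)."""
        flags = self.de_flags_day0()
        first = pd.Series(np.nan, index=self.genes)
        for d in flags.columns:
            hit = flags[d] & first.isna()
            first[hit] = d
        return first

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-gene table (for TSV export)."""
        out = pd.DataFrame(index=self.genes)
        for d in self.fc_day0.columns:
            out[f"log2fc_day{d}_vs_day0"] = self.fc_day0[d]
            out[f"p_day{d}"] = self.p_day0[d]
            out[f"q_day{d}"] = self.q_day0[d]
        out["max_abs_log2fc"] = self.max_abs_log2fc
        out["max_fc_day"] = self.max_fc_day
        out["signed_max_log2fc"] = self.signed_max_log2fc
        out["is_de"] = self.is_de
        if self.is_constitutive is not None:
            out["is_constitutive"] = self.is_constitutive
        return out


def build_de_table(
    expr: ExpressionMatrix,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.1,
    background_level: float | None = None,
    constitutive_ratio: float = 4.0,
    params: ModerationParams | None = None,
) -> DifferentialExpressionTable:
    """Run the complete per-day differential expression analysis.

    Moderated t-tests are run per comparison, BH adjustment is applied
    within each comparison family (one family per day and baseline), and
    gene-level DE / constitutive flags are derived.
    """
    fc0, fcp = fold_change_table(expr)
    days = list(fc0.columns)
    t0, p0, tp_, pp_ = {}, {}, {}, {}
    moderation = {}
    for d in days:
        t, p, mp = moderated_t_test(expr, d, "day0", params=params)
        t0[d], p0[d] = t, p
        moderation[("day0", d)] = mp
        t, p, mp = moderated_t_test(expr, d, "prev", params=params)
        tp_[d], pp_[d] = t, p
        moderation[("prev", d)] = mp
    t0 = pd.DataFrame(t0)
    p0 = pd.DataFrame(p0)
    tp_ = pd.DataFrame(tp_)
    pp_ = pd.DataFrame(pp_)
    q0 = p0.apply(lambda col: pd.Series(bh_adjust(col), index=col.index))
    qp = pp_.apply(lambda col: pd.Series(bh_adjust(col), index=col.index))

    max_abs = fc0.abs().max(axis=1)
    max_day = fc0.abs().idxmax(axis=1)
    signed_max = pd.Series(
        [fc0.at[g, d] for g, d in max_day.items()], index=fc0.index
    )
    is_de = call_de(fc0, q0, fc_threshold, q_threshold)
    const = None
    if background_level is not None:
        const = detect_constitutive(expr, background_level, constitutive_ratio)
    return DifferentialExpressionTable(
        fc_day0=fc0, fc_prev=fcp, p_day0=p0, q_day0=q0, p_prev=pp_, q_prev=qp,
        t_day0=t0, t_prev=tp_, max_abs_log2fc=max_abs, max_fc_day=max_day,
        signed_max_log2fc=signed_max, is_de=is_de, is_constitutive=const,
        moderation=moderation, fc_threshold=fc_threshold, q_threshold=q_threshold,
    )
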