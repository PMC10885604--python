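"""Gene-level association of 3' UTR structure with expression and stability.

Given a gene table carrying the per-transcript average Gini index joined to
expression (RPKM), half-life, and sequence covariates, this module
reproduces the analysis skeleton of the transcriptome-wide comparisons:
decile classification, two-group rank-sum / Kolmogorov-Smirnov comparisons
with ECDF export, Pearson correlation, median-split confounder
stratification, RNA G-quadruplex prediction, and first-order decay fits.
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DecayCurve


def classify_deciles(
    records: pd.DataFrame,
    key: str,
    q: float = 0.10,
    id_col: str = "transcript_id",
    labels: tuple[str, str, str] = ("high", "low", "mid"),
    out_col: Optional[str] = None,
) -> pd.DataFrame:
    """Label the top/bottom ``q`` fraction of records by ``key``.

    Exactly ``floor(q * n)`` records land in each extreme class; ties are
    broken deterministically by ``id_col`` order. Works for the average Gini
    (high/low structure), half-life (long/short), or any numeric column.
    """
    n = len(records)
    if n < 10:
        raise ValueError(f"need >= 10 records to classify deciles, got {n}")
    if records[key].isna().any():
        raise ValueError(f"column {key!r} has missing values; drop them first")
    high_label, low_label, mid_label = labels
    n_class = int(math.floor(q * n))
    order = records.sort_values([key, id_col], kind="mergesort")
    out = records.copy()
    col = out_col or f"{key}_class"
    out[col] = mid_label
    out.loc[order.index[:n_class], col] = low_label
    out.loc[order.index[n - n_class:], col] = high_label
    return out


@dataclass
class GroupCompareResult:
    test: str
    statistic: float
    pvalue: float
    summaries: pd.DataFrame   # per-group n, median, q1, q3
    ecdf: pd.DataFrame        # group, value, ecdf — cumulative-curve table


def group_compare(
    records: pd.DataFrame,
    group_field: str,
    value_field: str,
    test: str = "ranksum",
    groups: tuple[str, str] = ("high", "low"),
) -> GroupCompareResult:
    """Two-sided rank-sum or two-sample KS between two groups of genes."""
    a = records.loc[records[group_field] == groups[0], value_field].dropna().to_numpy()
    b = records.loc[records[group_field] == groups[1], value_field].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group in {group_field} ({groups})")
    if test == "ranksum":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ks":
        stat, p = stats.ks_2samp(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    summaries = pd.DataFrame(
        {
            "group": groups,
            "n": [len(a), len(b)],
            "median": [np.median(a), np.median(b)],
            "q1": [np.quantile(a, 0.25), np.quantile(b, 0.25)],
            "q3": [np.quantile(a, 0.75), np.quantile(b, 0.75)],
        }
    )
    ecdf_rows = []
    for g, x in zip(groups, (a, b)):
        xs = np.sort(x)
        ecdf_rows.append(
            pd.DataFrame(
                {"group": g, "value": xs, "ecdf": np.arange(1, len(xs) + 1) / len(xs)}
            )
        )
    return GroupCompareResult(
        test=test,
        statistic=float(stat),
        pvalue=float(p),
        summaries=summaries,
        ecdf=pd.concat(ecdf_rows, ignore_index=True),
    )


def correlate(
    records: pd.DataFrame,
    x_field: str,
    y_field: str,
    log_y: bool = False,
    eps: float = 1e-6,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of x against (optionally log10) y.

    Returns (R, p, scatter table); R is NaN when either side is degenerate.
    """
    x = records[x_field].to_numpy(dtype=float)
    y = records[y_field].to_numpy(dtype=float)
    if log_y:
        y = np.log10(y + eps)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired finite values, got {len(x)}")
    scatter = pd.DataFrame({x_field: x, y_field + ("_log10" if log_y else ""): y})
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), scatter
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), scatter


def gini_threshold_filter(
    records: pd.DataFrame, min_avg_gini: float = 0.4, col: str = "avg_gini"
) -> pd.DataFrame:
    """Keep genes whose average Gini exceeds the threshold (default 0.4)."""
    return records[records[col] > min_avg_gini].copy()


def stratified_confounder(
    records: pd.DataFrame,
    covariate: str,
    value_field: str = "rpkm",
    group_field: str = "avg_gini_class",
    test: str = "ranksum",
) -> dict[str, Optional[GroupCompareResult]]:
    """Median-split the covariate and re-run the high/low-Gini comparison per stratum.

    Genes at or above the sample median form the 'high' stratum, the rest the
    'low' stratum (>= / < boundary convention). A stratum with fewer than 2
    genes of either class is reported as not evaluable (None).
    """
    med = records[covariate].median()
    out: dict[str, Optional[GroupCompareResult]] = {}
    for name, stratum in (
        ("high", records[records[covariate] >= med]),
        ("low", records[records[covariate] < med]),
    ):
        counts = stratum[group_field].value_counts()
        if counts.get("high", 0) < 2 or counts.get("low", 0) < 2:
            out[name] = None
            continue
        out[name] = group_compare(stratum, group_field, value_field, test=test)
    return out


def gc_content(seq: str) -> float:
    """GC percentage of a sequence; N bases excluded from both counts."""
    s = seq.upper()
    n_total = sum(1 for c in s if c != "N")
    if n_total == 0:
        return float("nan")
    gc = s.count("G") + s.count("C")
    return 100.0 * gc / n_total


_LOOP = "ACGTUN"


def predict_rg4(
    seq: str,
    min_g: int = 3,
    loop_range: tuple[int, int] = (1, 7),
    dna: bool = False,
) -> list[tuple[int, int, str]]:
    """Predict RNA G-quadruplex sites: four G-tracts of >= ``min_g`` Gs
    separated by 1-7 nt loops, matched greedily left to right without overlap
    (the quadparser pattern). Returns (start0, end0, matched_sequence[, strand]).

    RNA mode scans the given strand only; DNA mode also reports C-tract
    matches, i.e. quadruplexes on the reverse complement.
    """
    lo, hi = loop_range
    s = seq.upper()
    pattern = re.compile(
        rf"G{{{min_g},}}(?:[{_LOOP}]{{{lo},{hi}}}G{{{min_g},}}){{3}}"
    )
    hits = [(m.start(), m.end(), m.group(0)) for m in pattern.finditer(s)]
    if not dna:
        return hits
    cpattern = re.compile(
        rf"C{{{min_g},}}(?:[{_LOOP}]{{{lo},{hi}}}C{{{min_g},}}){{3}}"
    )
    plus = [(st, en, sq, "+") for st, en, sq in hits]
    minus = [(m.start(), m.end(), m.group(0), "-") for m in cpattern.finditer(s)]
    return sorted(plus + minus)  # type: ignore[return-value]


@dataclass
class HalfLifeFit:
    k: float            # per hour
    t_half: float       # hours; NaN for non-decaying fits
    intercept: float
    r_squared: float


def fit_half_life(curve: DecayCurve) -> HalfLifeFit:
    """First-order decay fit: least squares on ln(abundance) = -k t + b.

    Needs >= 3 timepoints including t = 0 and strictly positive abundances.
    t1/2 = ln 2 / k; a non-positive k (no decay / growth) yields t1/2 = NaN
    with a warning.
    """
    t = curve.timepoints
    a = curve.relative_abundance
    if len(t) < 3:
        raise ValueError(f"{curve.gene_id}: need >= 3 timepoints, got {len(t)}")
    if not np.any(t == 0):
        raise ValueError(f"{curve.gene_id}: time course must include t = 0")
    if np.any(a <= 0):
        raise ValueError(f"{curve.gene_id}: abundances must be positive")
    res = stats.linregress(t, np.log(a))
    k = -float(res.slope)
    if k <= 0:
        warnings.warn(
            f"{curve.gene_id}: non-decaying fit (k = {k:.4g}); t1/2 undefined",
            stacklevel=2,
        )
        t_half = float("nan")
    else:
        t_half = math.log(2) / k
    return HalfLifeFit(
        k=k,
        t_half=t_half,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def mirna_overlap_summary(
    records: pd.DataFrame,
    group_field: str = "avg_gini_class",
    flag_field: str = "mirna_target",
    groups: tuple[str, str] = ("high", "low"),
) -> dict:
    """Fraction of miRNA-target genes per class plus a two-proportion test.

    The test is Fisher's exact test on the 2x2 (class x target) table.
    """
    table = []
    fractions = {}
    for g in groups:
        sub = records.loc[records[group_field] == g, flag_field].astype(bool)
        k, n = int(sub.sum()), len(sub)
        table.append([k, n - k])
        fractions[g] = k / n if n else float("nan")
    odds, p = stats.fisher_exact(table)
    return {
        "fractions": fractions,
        "counts": {g: row for g, row in zip(groups, table)},
        "odds_ratio": float(odds),
        "pvalue": float(p),
    }


def level_enrichment(
    records: pd.DataFrame,
    level_col: str,
    level_value,
    group_field: str = "avg_gini_class",
) -> float:
    """Fold enrichment of a generating level in the high- vs the low-Gini class:
    P(level | high) / P(level | low), with a 0.5-count continuity correction so
    an empty low-class cell yields a finite fold."""
    high = records[records[group_field] == "high"]
    low = records[records[group_field] == "low"]
    if len(high) == 0 or len(low) == 0:
        return float("nan")
    p_high = ((high[level_col] == level_value).sum() + 0.5) / (len(high) + 1)
    p_low = ((low[level_col] == level_value).sum() + 0.5) / (len(low) + 1)
    return float(p_high / p_low)
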