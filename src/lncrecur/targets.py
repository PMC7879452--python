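"""Cis / trans target-gene prediction and over-representation analysis.

Cis targets are protein-coding genes whose genomic span lies within a
fixed window (default 100 kb, inclusive at the boundary) of a lncRNA's
span, strand-agnostic. Trans targets are protein-coding genes whose
expression on log2(CPM+1) correlates with the lncRNA across all samples
with |Pearson r| strictly above a threshold (default 0.95). Predicted
target sets can be tested for over-representation in user-supplied gene
sets with the upper-tail hypergeometric test, BH-adjusted over sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .de import NormalizedExpression
from .types import TranscriptRecord, ValidationError

__all__ = [
    "cis_targets",
    "trans_targets",
    "correlate_pair",
    "overrepresentation_test",
    "format_pvalue",
]

TARGET_COLUMNS = ["lnc_id", "gene_id", "mode", "distance_bp", "r", "r_pvalue", "passes"]

#: below this, human-readable reports print "<2.2e-16" (R's tail convention)
PVALUE_FLOOR = 2.2e-16


def format_pvalue(p: float) -> str:
    """Human-readable p: tiny values become the conventional "<2.2e-16"."""
    if np.isnan(p):
        return "NA"
    return "<2.2e-16" if p < PVALUE_FLOOR else f"{p:.6g}"


def _span_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two 1-based inclusive spans; 0 when they overlap."""
    if b_start > a_end:
        return b_start - a_end
    if a_start > b_end:
        return a_start - b_end
    return 0


def cis_targets(
    lnc_records: list[TranscriptRecord],
    coding_records: list[TranscriptRecord],
    window_bp: int = 100_000,
) -> pd.DataFrame:
    """Emit every (lncRNA, coding gene) pair within the genomic window.

    A coding gene qualifies iff its span intersects
    [lnc.start - window_bp, lnc.end + window_bp] on the same chromosome
    (i.e. gap distance <= window_bp, boundary inclusive); strand ignored.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    by_id: dict[str, TranscriptRecord] = {}
    for g in coding_records:
        # half-open interval arithmetic local to this query, never serialized
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.transcript_id)
        by_id[g.transcript_id] = g
    rows = []
    for l in lnc_records:
        tree = trees.get(l.chrom)
        if tree is None:
            continue
        lo = max(1, l.start - window_bp)
        hi = l.end + window_bp + 1
        for hit in sorted(tree.overlap(lo, hi), key=lambda iv: iv.data):
            g = by_id[hit.data]
            dist = _span_distance(l.start, l.end, g.start, g.end)
            if dist <= window_bp:
                rows.append(
                    dict(
                        lnc_id=l.transcript_id,
                        gene_id=g.transcript_id,
                        mode="cis",
                        distance_bp=dist,
                        r=np.nan,
                        r_pvalue=np.nan,
                        passes=True,
                    )
                )
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between every row of x and every row of y (zero-var -> NaN)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def _r_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-transform t = r * sqrt((n-2)/(1-r^2))."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, p)


def trans_targets(
    expr: NormalizedExpression,
    lnc_ids: list[str] | set[str],
    coding_ids: list[str] | set[str],
    r_min: float = 0.95,
) -> pd.DataFrame:
    """Emit (lncRNA, coding gene) pairs with |Pearson r| strictly > r_min.

    Correlation is computed across ALL samples (paired and unpaired).
    p-values from the t-transform are reported but never filtered on.
    Zero-variance vectors give r = NaN and are skipped with a warning.
    """
    lnc_ids = sorted(set(lnc_ids) & set(expr.values.index))
    coding_ids = sorted(set(coding_ids) & set(expr.values.index))
    n = expr.values.shape[1]
    if n < 3:
        raise ValidationError("trans correlation needs >= 3 samples")
    x = expr.values.loc[lnc_ids].to_numpy(dtype=float)
    y = expr.values.loc[coding_ids].to_numpy(dtype=float)
    r = _pearson_matrix(x, y)
    if np.isnan(r).any():
        warnings.warn("zero-variance expression vectors: pairs skipped with r = NA")
    p = _r_pvalue(r, n)
    li, gi = np.where(np.abs(r) > r_min)
    rows = [
        dict(
            lnc_id=lnc_ids[i],
            gene_id=coding_ids[j],
            mode="trans",
            distance_bp=np.nan,
            r=r[i, j],
            r_pvalue=p[i, j],
            passes=True,
        )
        for i, j in zip(li, gi)
    ]
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


def correlate_pair(expr: NormalizedExpression, id_a: str, id_b: str) -> tuple[float, float]:
    """Pearson r and two-sided p for one named pair (same estimator as trans)."""
    n = expr.values.shape[1]
    if n < 3:
        raise ValidationError("correlation needs >= 3 samples")
    x = expr.values.loc[[id_a]].to_numpy(dtype=float)
    y = expr.values.loc[[id_b]].to_numpy(dtype=float)
    r = float(_pearson_matrix(x, y)[0, 0])
    p = float(_r_pvalue(np.array([[r]]), n)[0, 0])
    return r, p


def overrepresentation_test(
    selected_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of selected genes.

    For each set: population = universe, successes = set & universe,
    draws = selected, p = P(X >= observed hits). BH over all tested sets.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not set(selected_genes) <= set(universe):
        raise ValidationError("selected genes must be a subset of the universe")
    M = len(universe)
    N = len(selected_genes)
    rows = []
    for set_id in sorted(gene_sets):
        members = gene_sets[set_id] & universe
        K = len(members)
        hits = len(members & selected_genes)
        p = float(stats.hypergeom.sf(hits - 1, M, K, N))
        rows.append(
            dict(
                set_id=set_id,
                set_size=K,
                n_hits=hits,
                universe_size=M,
                n_selected=N,
                p=min(p, 1.0),
            )
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = []
    return out
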