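"""Unreplicated per-pair differential expression via a local pooled error test.

With one tumor and one normal sample per patient there are no replicates,
so the variance of a per-transcript expression difference cannot be
estimated per transcript. The local pooled error (LPE) strategy borrows it
from the data instead: transcripts are stratified by average abundance
into equal-occupancy bins, and within each bin the spread of the
tumor-minus-normal differences — which for the vast majority of (null)
transcripts reflects pure measurement noise — is estimated robustly by
the median absolute deviation (MAD). Each transcript's difference is then
scored against the pooled scale of its own abundance stratum:

    d_i = tumor_i - normal_i            (log2(CPM + 1) scale)
    z_i = (d_i - median_bin(d)) / sigma_bin
    p_i = two-sided normal tail of z_i

Centering on the bin median absorbs pair-level global shifts; the MAD is
robust to the DE minority within a bin; the per-bin scales are smoothed
by a running median of 3 and floored to avoid degenerate bins.
DE calls follow q < 0.05 (Benjamini-Hochberg within pair) and
|log2FC| > 1, both strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import PairedCohort, ValidationError

__all__ = [
    "NormalizedExpression",
    "LpeParams",
    "normalize",
    "lpe_test",
    "call_de",
    "run_paired_de",
    "MAD_CONSTANT",
]

#: scales the MAD to the standard deviation of a normal distribution
MAD_CONSTANT = 1.4826

DE_COLUMNS = ["transcript_id", "pair_id", "log2fc", "z", "p", "q", "direction", "is_de"]


@dataclass
class NormalizedExpression:
    """log2(CPM + pseudocount) matrix with the library sizes used."""

    values: pd.DataFrame
    pseudocount: float
    libsize: pd.Series


@dataclass
class LpeParams:
    """Tunables of the local pooled error test."""

    bins: int = 100
    min_bin: int = 30
    sigma_min: float = 0.05
    mad_constant: float = MAD_CONSTANT
    min_count: int = 1  # expression gate: tested iff >= min_count in >= 1 of the 2 samples


def normalize(cohort: PairedCohort, pseudocount: float = 1.0) -> NormalizedExpression:
    """log2(1e6 * count / library_size + pseudocount), per sample."""
    libsize = cohort.counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValidationError(f"samples with zero total counts: {list(zero.index)}")
    cpm = cohort.counts.div(libsize, axis=1) * 1e6
    values = np.log2(cpm + pseudocount)
    return NormalizedExpression(values=values, pseudocount=pseudocount, libsize=libsize)


def _bin_edges(n: int, bins: int, min_bin: int) -> list[np.ndarray]:
    """Split 0..n-1 (already abundance-ordered) into equal-occupancy bins.

    The bin count is reduced so no bin falls below ``min_bin`` members
    (tail bins merge); at least one bin always remains.
    """
    eff_bins = max(1, min(bins, n // min_bin))
    return np.array_split(np.arange(n), eff_bins)


def lpe_test(
    expr: NormalizedExpression,
    cohort: PairedCohort,
    pair_id: str,
    params: LpeParams | None = None,
) -> pd.DataFrame:
    """Score every tested transcript of one pair; p, z, log2fc filled, q empty.

    Transcripts below the expression gate in BOTH samples of the pair are
    excluded from the test (and hence from the BH denominator).
    """
    params = params or LpeParams()
    tumor, normal = cohort.samples.pair_samples(pair_id)
    t = expr.values[tumor]
    n = expr.values[normal]
    gate = (cohort.counts[tumor] >= params.min_count) | (
        cohort.counts[normal] >= params.min_count
    )
    tested = gate[gate].index
    d = (t - n).loc[tested].to_numpy(dtype=float)
    a = ((t + n) / 2.0).loc[tested].to_numpy(dtype=float)

    order = np.argsort(a, kind="stable")
    z = np.empty_like(d)
    bins_idx = _bin_edges(len(tested), params.bins, params.min_bin)

    med = np.empty(len(bins_idx))
    sigma = np.empty(len(bins_idx))
    for b, members in enumerate(bins_idx):
        db = d[order[members]]
        med[b] = np.median(db)
        sigma[b] = params.mad_constant * np.median(np.abs(db - med[b]))
    # running median of 3 across bins, endpoints kept, then floor
    if len(sigma) >= 3:
        smoothed = sigma.copy()
        smoothed[1:-1] = [
            np.median(sigma[b - 1 : b + 2]) for b in range(1, len(sigma) - 1)
        ]
        sigma = smoothed
    sigma = np.maximum(sigma, params.sigma_min)

    for b, members in enumerate(bins_idx):
        idx = order[members]
        z[idx] = (d[idx] - med[b]) / sigma[b]

    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        dict(
            transcript_id=tested,
            pair_id=pair_id,
            log2fc=d,
            z=z,
            p=p,
            q=np.nan,
            direction=np.where(d < 0, -1, 1),
            is_de=False,
        )
    ).reset_index(drop=True)


def call_de(
    results: pd.DataFrame,
    q_max: float = 0.05,
    lfc_min: float = 1.0,
    *,
    within_pair: bool = True,
) -> pd.DataFrame:
    """Benjamini-Hochberg adjust p within each pair and call DE.

    A transcript is DE in a pair iff q < q_max AND |log2FC| > lfc_min,
    both strict inequalities.
    """
    out = results.copy()
    group = out.groupby("pair_id").groups if within_pair else {"all": out.index}
    for _, idx in group.items():
        p = out.loc[idx, "p"].to_numpy()
        out.loc[idx, "q"] = multipletests(p, method="fdr_bh")[1]
    out["is_de"] = (out["q"] < q_max) & (out["log2fc"].abs() > lfc_min)
    return out


def run_paired_de(
    cohort: PairedCohort,
    *,
    pseudocount: float = 1.0,
    params: LpeParams | None = None,
    q_max: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Normalize, LPE-test every matched pair, and call DE."""
    expr = normalize(cohort, pseudocount)
    frames = [
        lpe_test(expr, cohort, pair_id, params)
        for pair_id in cohort.samples.pair_ids
    ]
    if not frames:
        return pd.DataFrame(columns=DE_COLUMNS)
    return call_de(pd.concat(frames, ignore_index=True), q_max, lfc_min)
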