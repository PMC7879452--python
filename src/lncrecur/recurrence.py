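"""Recurrence and direction-consistency prioritization of per-pair DE calls.

A lncRNA's "occurrence" is the number of matched pairs in which it is
called differentially expressed. Candidates must recur (occurrence above a
threshold, default strictly > 10) and be direction-consistent (every DE
pair shares one sign, with a configurable tolerance for discordant pairs)
before they are ranked by a rank-sum of occurrence and the magnitude of
the median per-pair log2 fold change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CONSISTENCY_CLASSES",
    "compute_occurrence",
    "classify_consistency",
    "rank_candidates",
    "prioritize",
]

CONSISTENCY_CLASSES = ("consistent_up", "consistent_down", "inconsistent", "not_recurrent")

OCCURRENCE_COLUMNS = [
    "transcript_id",
    "n_pairs_tested",
    "occurrence",
    "n_up",
    "n_down",
    "median_log2fc",
    "consistency",
    "rank_score",
    "rank",
]


def compute_occurrence(de_results: pd.DataFrame, lnc_ids: set[str]) -> pd.DataFrame:
    """Per lncRNA: pairs tested, DE occurrence, per-direction counts.

    ``median_log2fc`` is the median log2FC over the pairs where the
    lncRNA was called DE (NaN when occurrence is zero). lncRNAs never
    tested in any pair still appear, with zero counts.
    """
    sub = de_results[de_results["transcript_id"].isin(lnc_ids)]
    rows = []
    grouped = dict(list(sub.groupby("transcript_id")))
    for tid in sorted(lnc_ids):
        grp = grouped.get(tid)
        if grp is None:
            rows.append(
                dict(
                    transcript_id=tid,
                    n_pairs_tested=0,
                    occurrence=0,
                    n_up=0,
                    n_down=0,
                    median_log2fc=np.nan,
                )
            )
            continue
        de = grp[grp["is_de"]]
        n_up = int((de["direction"] > 0).sum())
        n_down = int((de["direction"] < 0).sum())
        rows.append(
            dict(
                transcript_id=tid,
                n_pairs_tested=int(grp["pair_id"].nunique()),
                occurrence=len(de),
                n_up=n_up,
                n_down=n_down,
                median_log2fc=float(de["log2fc"].median()) if len(de) else np.nan,
            )
        )
    return pd.DataFrame(rows)


def classify_consistency(
    summaries: pd.DataFrame,
    min_occurrence: int = 10,
    *,
    occurrence_cmp: str = "gt",
    max_discordant: int = 0,
) -> pd.DataFrame:
    """Label each lncRNA consistent_up/down, inconsistent, or not_recurrent.

    Recurrence uses strict ``occurrence > min_occurrence`` by default
    (``occurrence_cmp="ge"`` switches to >=). A recurrent lncRNA is
    consistent_up when at most ``max_discordant`` of its DE pairs are
    down-regulated (and it has more up than down pairs); symmetrically
    for consistent_down; anything else recurrent is inconsistent.
    """
    if occurrence_cmp not in ("gt", "ge"):
        raise ValueError("occurrence_cmp must be 'gt' or 'ge'")
    out = summaries.copy()
    occ = out["occurrence"]
    recurrent = occ > min_occurrence if occurrence_cmp == "gt" else occ >= min_occurrence
    up = recurrent & (out["n_down"] <= max_discordant) & (out["n_up"] > out["n_down"])
    down = recurrent & (out["n_up"] <= max_discordant) & (out["n_down"] > out["n_up"])
    out["consistency"] = np.select(
        [~recurrent, up, down],
        ["not_recurrent", "consistent_up", "consistent_down"],
        default="inconsistent",
    )
    return out


def rank_candidates(summaries: pd.DataFrame, direction: str = "both") -> pd.DataFrame:
    """Rank consistent candidates by fold change and occurrence.

    rank_score is the mean of the (average-tie) ranks of occurrence and
    |median_log2fc|, higher = better; rank 1 is the top candidate. Exact
    score ties break lexicographically by transcript_id, so the ranking
    is independent of input order. Only consistent_up/consistent_down
    lncRNAs are rankable; ``direction`` restricts to one class.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    wanted = {
        "up": ["consistent_up"],
        "down": ["consistent_down"],
        "both": ["consistent_up", "consistent_down"],
    }[direction]
    out = summaries.copy()
    out["rank_score"] = np.nan
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    mask = out["consistency"].isin(wanted)
    if not mask.any():
        warnings.warn("no rankable (consistent) candidates")
        return out
    sub = out.loc[mask]
    occ_rank = rankdata(sub["occurrence"], method="average")
    fc_rank = rankdata(sub["median_log2fc"].abs(), method="average")
    score = (occ_rank + fc_rank) / 2.0
    out.loc[mask, "rank_score"] = score
    order = sub.assign(_score=score).sort_values(
        by=["_score", "transcript_id"], ascending=[False, True], kind="stable"
    )
    out.loc[order.index, "rank"] = np.arange(1, len(order) + 1)
    return out


def prioritize(
    de_results: pd.DataFrame,
    lnc_ids: set[str],
    *,
    min_occurrence: int = 10,
    occurrence_cmp: str = "gt",
    max_discordant: int = 0,
    direction: str = "both",
) -> pd.DataFrame:
    """occurrence -> consistency -> ranking, in one call."""
    occ = compute_occurrence(de_results, lnc_ids)
    occ = classify_consistency(
        occ,
        min_occurrence,
        occurrence_cmp=occurrence_cmp,
        max_discordant=max_discordant,
    )
    return rank_candidates(occ, direction)[OCCURRENCE_COLUMNS]
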