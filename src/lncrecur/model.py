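"""Model/Results front end over the per-pair DE + recurrence machinery.

`RecurrenceModel` is built from a `PairedCohort` (plus the set of lncRNA
ids to prioritize); `fit()` estimates the local pooled error model in
every matched pair, calls DE, aggregates occurrence and consistency, and
ranks candidates. The returned `RecurrenceResults` carries the per-pair
DE table, the occurrence summaries, and target-prediction helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import de as de_mod
from . import recurrence as rec_mod
from . import targets as tgt_mod
from .types import PairedCohort

__all__ = ["RecurrenceModel", "RecurrenceResults"]


class RecurrenceModel:
    """Recurrence screen for tumor-specific lncRNAs on a matched cohort.

    Parameters
    ----------
    cohort : validated count matrix with pair structure.
    lnc_ids : transcript ids to prioritize (typically the classified
        lncRNA catalog); defaults to every non-protein-coding transcript.
    q_max, lfc_min : per-pair DE thresholds (strict inequalities).
    min_occurrence, occurrence_cmp, max_discordant : recurrence /
        consistency thresholds (strict ``>`` by default).
    """

    def __init__(
        self,
        cohort: PairedCohort,
        lnc_ids: set[str] | None = None,
        *,
        pseudocount: float = 1.0,
        lpe_params: de_mod.LpeParams | None = None,
        q_max: float = 0.05,
        lfc_min: float = 1.0,
        min_occurrence: int = 10,
        occurrence_cmp: str = "gt",
        max_discordant: int = 0,
    ):
        self.cohort = cohort
        if lnc_ids is None:
            lnc_ids = {
                t.transcript_id
                for t in cohort.annotation
                if t.biotype in ("lncRNA_known", "lncRNA_novel_candidate")
            } or {
                t.transcript_id
                for t in cohort.annotation
                if t.biotype != "protein_coding"
            }
        self.lnc_ids = set(lnc_ids)
        self.pseudocount = pseudocount
        self.lpe_params = lpe_params or de_mod.LpeParams()
        self.q_max = q_max
        self.lfc_min = lfc_min
        self.min_occurrence = min_occurrence
        self.occurrence_cmp = occurrence_cmp
        self.max_discordant = max_discordant

    def fit(self, direction: str = "both") -> "RecurrenceResults":
        expr = de_mod.normalize(self.cohort, self.pseudocount)
        frames = [
            de_mod.lpe_test(expr, self.cohort, pair_id, self.lpe_params)
            for pair_id in self.cohort.samples.pair_ids
        ]
        de_table = de_mod.call_de(
            pd.concat(frames, ignore_index=True), self.q_max, self.lfc_min
        )
        occurrence = rec_mod.prioritize(
            de_table,
            self.lnc_ids,
            min_occurrence=self.min_occurrence,
            occurrence_cmp=self.occurrence_cmp,
            max_discordant=self.max_discordant,
            direction=direction,
        )
        return RecurrenceResults(
            model=self, expression=expr, de=de_table, occurrence=occurrence
        )


@dataclass
class RecurrenceResults:
    """Fitted screen: per-pair DE calls, occurrence summaries, ranking."""

    model: RecurrenceModel
    expression: de_mod.NormalizedExpression
    de: pd.DataFrame
    occurrence: pd.DataFrame
    _class_counts: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._class_counts = self.occurrence["consistency"].value_counts()

    @property
    def ranking(self) -> pd.DataFrame:
        """Ranked consistent candidates, best first."""
        ranked = self.occurrence.dropna(subset=["rank"])
        return ranked.sort_values("rank").reset_index(drop=True)

    def top(self, n: int) -> pd.DataFrame:
        return self.ranking.head(n)

    def predict_cis_targets(self, window_bp: int = 100_000, candidates=None) -> pd.DataFrame:
        """Cis targets (genomic window) for ranked candidates (or `candidates`)."""
        ids = set(candidates) if candidates is not None else set(
            self.ranking["transcript_id"]
        )
        lnc = [t for t in self.model.cohort.annotation if t.transcript_id in ids]
        coding = [
            t for t in self.model.cohort.annotation if t.biotype == "protein_coding"
        ]
        return tgt_mod.cis_targets(lnc, coding, window_bp)

    def predict_trans_targets(self, r_min: float = 0.95, candidates=None) -> pd.DataFrame:
        """Trans targets (co-expression) for ranked candidates (or `candidates`)."""
        ids = set(candidates) if candidates is not None else set(
            self.ranking["transcript_id"]
        )
        coding = {
            t.transcript_id
            for t in self.model.cohort.annotation
            if t.biotype == "protein_coding"
        }
        return tgt_mod.trans_targets(self.expression, ids, coding, r_min)

    def summary(self) -> str:
        """Counts funnel of the screen, one line per stage."""
        m = self.model
        n_de_calls = int(self.de["is_de"].sum())
        cc = self._class_counts
        n_cons = int(cc.get("consistent_up", 0) + cc.get("consistent_down", 0))
        cmp_sym = ">" if m.occurrence_cmp == "gt" else ">="
        lines = [
            "Recurrence screen for tumor-specific lncRNAs",
            "=" * 44,
            f"Matched pairs:                {m.cohort.n_pairs}",
            f"Samples:                      {len(m.cohort.samples)}",
            f"Transcripts in cohort:        {len(m.cohort.transcript_ids)}",
            f"lncRNAs prioritized:          {len(m.lnc_ids)}",
            f"Per-pair DE calls (q<{m.q_max:g}, |log2FC|>{m.lfc_min:g}): {n_de_calls}",
            f"Recurrent (occurrence {cmp_sym} {m.min_occurrence}):  "
            f"{int((cc.get('inconsistent', 0)) + n_cons)}",
            f"  consistent up:              {int(cc.get('consistent_up', 0))}",
            f"  consistent down:            {int(cc.get('consistent_down', 0))}",
            f"  inconsistent:               {int(cc.get('inconsistent', 0))}",
        ]
        top = self.top(5)
        if len(top):
            lines.append("Top candidates:")
            for row in top.itertuples():
                lines.append(
                    f"  {int(row.rank):>2}. {row.transcript_id}  "
                    f"occurrence={int(row.occurrence)}  "
                    f"median_log2FC={row.median_log2fc:+.2f}  ({row.consistency})"
                )
        return "\n".join(lines)
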