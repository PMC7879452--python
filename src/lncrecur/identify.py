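"""Classification of assembled transcripts into known / novel lncRNAs.

The rule set mirrors the standard lncRNA discovery funnel: a transcript
must be expressed (raw count >= min_count in at least one sample), and is
then either matched against a known-lncRNA catalog, or — if novel — must
be longer than 200 nt and called non-coding by a consensus of three
external coding-potential callers (unanimity by default, any-k-of-3
configurable). Protein-coding transcripts pass through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PairedCohort, TranscriptRecord, ValidationError

__all__ = [
    "REASON_CODES",
    "ClassificationResult",
    "CatalogSummary",
    "classify_transcripts",
    "summarize_catalog",
    "summarize_counts",
]

#: machine-readable reasons a transcript is rejected from the lncRNA catalog
REASON_CODES = ("too_short", "coding_call", "not_expressed", "no_coding_calls")

MIN_LNC_LENGTH_NT = 200  # exclusive bound: a lncRNA must be strictly longer


@dataclass
class ClassificationResult:
    """Outcome of classify_transcripts: one class per input transcript."""

    table: pd.DataFrame  # transcript_id, assigned_class, reason
    records: list[TranscriptRecord]  # annotation with biotypes updated

    def ids_of(self, assigned_class: str) -> set[str]:
        mask = self.table["assigned_class"] == assigned_class
        return set(self.table.loc[mask, "transcript_id"])

    @property
    def lncrna_ids(self) -> set[str]:
        return self.ids_of("lncRNA_known") | self.ids_of("lncRNA_novel_candidate")


@dataclass
class CatalogSummary:
    """Composition of the identified lncRNA catalog."""

    n_total: int
    n_known: int
    n_novel: int
    pct_known: float  # percent, rounded to 2 decimals; NaN when n_total == 0


def classify_transcripts(
    annotation: list[TranscriptRecord],
    catalog: set[str],
    calls: pd.DataFrame,
    expression: PairedCohort,
    *,
    min_length: int = MIN_LNC_LENGTH_NT,
    consensus_k: int = 3,
    min_count: int = 1,
) -> ClassificationResult:
    """Partition transcripts into lncRNA classes and rejected bins.

    Parameters
    ----------
    catalog : ids of transcripts known to be lncRNAs (may be empty).
    calls : boolean frame indexed by transcript_id, three caller columns,
        True = "predicted coding". Duplicated rows are a validation error;
        transcripts without calls become ``unclassified/no_coding_calls``
        rather than being dropped.
    consensus_k : a novel transcript counts as non-coding when at least
        k of the 3 callers call it non-coding (default 3 = unanimity).

    The expression gate is applied first, then the catalog lookup, then
    the length rule (strictly > ``min_length`` nt), then the coding
    consensus. Every transcript lands in exactly one class.
    """
    if calls.index.duplicated().any():
        raise ValidationError(
            f"duplicate coding-call rows: {calls.index[calls.index.duplicated()].tolist()[:10]}"
        )
    known_ids = {t.transcript_id for t in annotation}
    orphans = [t for t in calls.index if t not in known_ids]
    if orphans:
        warnings.warn(
            f"{len(orphans)} coding-call rows for transcripts absent from the "
            f"annotation were ignored (e.g. {orphans[:5]})"
        )
    expressed = (expression.counts >= min_count).any(axis=1)
    call_values = {t: calls.loc[t].to_numpy() for t in calls.index if t in known_ids}

    rows = []
    new_records = []
    for rec in annotation:
        tid = rec.transcript_id
        if rec.biotype == "protein_coding":
            cls, reason = "protein_coding", None
        elif not bool(expressed.get(tid, False)):
            cls, reason = "unclassified", "not_expressed"
        elif tid in catalog:
            cls, reason = "lncRNA_known", None
        elif rec.length_nt <= min_length:
            cls, reason = "unclassified", "too_short"
        elif tid not in call_values:
            cls, reason = "unclassified", "no_coding_calls"
        elif int(np.sum(~call_values[tid])) >= consensus_k:
            cls, reason = "lncRNA_novel_candidate", None
        else:
            cls, reason = "unclassified", "coding_call"
        rows.append(dict(transcript_id=tid, assigned_class=cls, reason=reason))
        if cls in ("lncRNA_known", "lncRNA_novel_candidate"):
            new_records.append(rec.with_biotype(cls))
        else:
            new_records.append(rec)
    return ClassificationResult(table=pd.DataFrame(rows), records=new_records)


def summarize_catalog(classified: ClassificationResult | pd.DataFrame) -> CatalogSummary:
    """Count known vs novel lncRNAs; percentage rounded to 2 decimals."""
    table = classified.table if isinstance(classified, ClassificationResult) else classified
    n_known = int((table["assigned_class"] == "lncRNA_known").sum())
    n_novel = int((table["assigned_class"] == "lncRNA_novel_candidate").sum())
    return summarize_counts(n_known, n_novel)


def summarize_counts(n_known: int, n_novel: int) -> CatalogSummary:
    """Catalog summary straight from class counts."""
    n_total = n_known + n_novel
    pct = round(100.0 * n_known / n_total, 2) if n_total else float("nan")
    return CatalogSummary(n_total=n_total, n_known=n_known, n_novel=n_novel, pct_known=pct)
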