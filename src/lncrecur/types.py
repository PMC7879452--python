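"""Core in-memory domain types shared by every pipeline stage.

Coordinates are GTF-native throughout: 1-based, inclusive at both ends.
Any half-open arithmetic is local to an operation and never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BIOTYPES",
    "TranscriptRecord",
    "SampleSheet",
    "PairedCohort",
    "ValidationError",
]

#: Recognised transcript biotypes. ``unclassified`` is the entry state for
#: transcripts that have not yet been through lncRNA classification.
BIOTYPES = (
    "protein_coding",
    "lncRNA_known",
    "lncRNA_novel_candidate",
    "unclassified",
)


class ValidationError(ValueError):
    """An input artifact violated a structural contract."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript locus: genomic span, spliced length and biotype.

    ``length_nt`` is the sum of exon lengths when exon structure is known,
    else the genomic span ``end - start + 1``; spliced length may be smaller
    than the span but never larger.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    length_nt: int
    biotype: str = "unclassified"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(
                f"{self.transcript_id}: start must be >= 1 (1-based), got {self.start}"
            )
        if self.end < self.start:
            raise ValidationError(
                f"{self.transcript_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(
                f"{self.transcript_id}: strand must be one of +, -, '.', got {self.strand!r}"
            )
        if self.length_nt < 1:
            raise ValidationError(
                f"{self.transcript_id}: length_nt must be >= 1, got {self.length_nt}"
            )
        if self.length_nt > self.span:
            raise ValidationError(
                f"{self.transcript_id}: spliced length {self.length_nt} exceeds "
                f"genomic span {self.span}"
            )
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.transcript_id}: unknown biotype {self.biotype!r}"
            )

    @property
    def span(self) -> int:
        """Genomic span in bp, inclusive of both ends."""
        return self.end - self.start + 1

    def with_biotype(self, biotype: str) -> "TranscriptRecord":
        return TranscriptRecord(
            self.transcript_id,
            self.gene_id,
            self.chrom,
            self.strand,
            self.start,
            self.end,
            self.length_nt,
            biotype,
        )


class SampleSheet:
    """Sample metadata: condition (tumor/normal) and optional pair membership.

    A pair_id, where present, must occur exactly twice — once per condition.
    Samples without a pair_id are "unpaired" and take part only in
    correlation (trans-target) analysis, never in paired DE.
    """

    CONDITIONS = ("tumor", "normal")

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "condition"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        frame = frame.copy()
        if "pair_id" not in frame.columns:
            frame["pair_id"] = pd.NA
        frame["pair_id"] = frame["pair_id"].astype("string")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_ids: {dups}")
        bad = set(frame["condition"]) - set(self.CONDITIONS)
        if bad:
            raise ValidationError(f"unknown conditions: {sorted(bad)}")
        for pid, grp in frame.dropna(subset=["pair_id"]).groupby("pair_id"):
            if len(grp) != 2 or set(grp["condition"]) != set(self.CONDITIONS):
                raise ValidationError(
                    f"pair {pid!r} must have exactly one tumor and one normal sample, "
                    f"got conditions {grp['condition'].tolist()}"
                )
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def pair_ids(self) -> list[str]:
        return sorted(self.frame["pair_id"].dropna().unique())

    def pair_samples(self, pair_id: str) -> tuple[str, str]:
        """Return (tumor_sample_id, normal_sample_id) for a pair."""
        grp = self.frame[self.frame["pair_id"] == pair_id]
        if grp.empty:
            raise KeyError(f"unknown pair_id {pair_id!r}")
        tumor = grp.loc[grp["condition"] == "tumor", "sample_id"].item()
        normal = grp.loc[grp["condition"] == "normal", "sample_id"].item()
        return tumor, normal

    def condition_of(self, sample_id: str) -> str:
        row = self.frame[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample_id {sample_id!r}")
        return row["condition"].item()

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleSheet) and self.frame.equals(other.frame)


@dataclass
class PairedCohort:
    """A raw count matrix (transcripts x samples) with pair structure.

    Every row id must exist in the annotation; every column id in the
    sample sheet; counts are non-negative integers.
    """

    counts: pd.DataFrame
    samples: SampleSheet
    annotation: list[TranscriptRecord]
    _by_id: dict[str, TranscriptRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [t.transcript_id for t in self.annotation]
        self._by_id = {t.transcript_id: t for t in self.annotation}
        if len(self._by_id) != len(ids):
            raise ValidationError("duplicate transcript_ids in annotation")
        unknown_rows = [i for i in self.counts.index if i not in self._by_id]
        if unknown_rows:
            raise ValidationError(
                f"count rows absent from annotation: {unknown_rows[:10]}"
                + ("..." if len(unknown_rows) > 10 else "")
            )
        unknown_cols = set(self.counts.columns) - set(self.samples.sample_ids)
        if unknown_cols:
            raise ValidationError(
                f"count columns absent from sample sheet: {sorted(unknown_cols)}"
            )
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts contain negative entries")

    def record(self, transcript_id: str) -> TranscriptRecord:
        return self._by_id[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_pairs(self) -> int:
        return len(self.samples.pair_ids)
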