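"""Readers and writers for every external artifact.

All other modules operate on the in-memory types from :mod:`lncrecur.types`;
this module is the only place file formats appear. Formats handled: GTF
(Ensembl dialect, 1-based inclusive), TSV count matrices and sample sheets,
one-ID-per-line catalogs, coding-potential call tables, GMT gene sets, and
generic result tables. "NA" is the sole missing-value token in every TSV;
floats are serialized with 6 significant digits.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .types import PairedCohort, SampleSheet, TranscriptRecord, ValidationError

__all__ = [
    "ParseError",
    "read_gtf",
    "write_gtf",
    "read_sample_sheet",
    "read_counts",
    "read_catalog",
    "read_coding_calls",
    "read_gmt",
    "write_table",
    "read_table",
]

NA_TOKEN = "NA"
FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gtf(path) -> list[TranscriptRecord]:
    """Read transcript records from a GTF file.

    One record per ``transcript`` feature. Transcripts with ``exon``
    children get spliced length (sum of exon lengths); transcripts without
    exon lines fall back to the genomic span. Coordinates are kept 1-based
    inclusive, exactly as written.
    """
    transcripts: dict[str, dict] = {}
    exon_lengths: dict[str, int] = defaultdict(int)
    order: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # malformed line
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if feat.featuretype not in ("transcript", "exon"):
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs or not attrs["transcript_id"]:
                raise ParseError(
                    f"{path}: line {lineno}: missing transcript_id attribute"
                )
            tid = attrs["transcript_id"][0]
            if feat.featuretype == "transcript":
                if "gene_id" not in attrs or not attrs["gene_id"]:
                    raise ParseError(
                        f"{path}: line {lineno}: missing gene_id attribute"
                    )
                if feat.end < feat.start:
                    raise ValidationError(
                        f"{path}: line {lineno}: end {feat.end} < start {feat.start}"
                    )
                if tid in transcripts:
                    raise ParseError(
                        f"{path}: line {lineno}: duplicate transcript_id {tid!r}"
                    )
                biotype = "unclassified"
                for key in ("transcript_biotype", "gene_biotype"):
                    if key in attrs and attrs[key]:
                        if attrs[key][0] == "protein_coding":
                            biotype = "protein_coding"
                        break
                transcripts[tid] = dict(
                    gene_id=attrs["gene_id"][0],
                    chrom=feat.seqid,
                    strand=feat.strand if feat.strand in "+-" else ".",
                    start=feat.start,
                    end=feat.end,
                    biotype=biotype,
                )
                order.append(tid)
            else:  # exon
                exon_lengths[tid] += feat.end - feat.start + 1
    records = []
    for tid in order:
        info = transcripts[tid]
        length = exon_lengths.get(tid) or (info["end"] - info["start"] + 1)
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                start=info["start"],
                end=info["end"],
                length_nt=length,
                biotype=info["biotype"],
            )
        )
    return records


def write_gtf(records: Iterable[TranscriptRecord], path) -> None:
    """Write transcript (and synthesized single-exon) lines, Ensembl dialect.

    Spliced length is preserved by emitting one exon of ``length_nt`` bp
    anchored at the transcript start when the spliced length is shorter
    than the span, else one exon covering the span.
    """
    with open(path, "wt") as fh:
        for rec in records:
            attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}";'
            if rec.biotype == "protein_coding":
                attrs += ' transcript_biotype "protein_coding";'
            base = (
                f"{rec.chrom}\tlncrecur\t{{feat}}\t{{start}}\t{{end}}\t.\t"
                f"{rec.strand}\t.\t{attrs}\n"
            )
            fh.write(base.format(feat="transcript", start=rec.start, end=rec.end))
            exon_end = rec.start + rec.length_nt - 1
            fh.write(base.format(feat="exon", start=rec.start, end=exon_end))


def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(
        path, sep="\t", dtype=str, na_values=[NA_TOKEN], keep_default_na=False
    )
    return SampleSheet(frame)


def read_counts(matrix_path, sheet_path, annotation: list[TranscriptRecord]) -> PairedCohort:
    """Read a count matrix + sample sheet into a validated cohort.

    Rows absent from the annotation are rejected with a named list;
    non-integer or negative counts are validation errors.
    """
    samples = read_sample_sheet(sheet_path)
    raw = pd.read_csv(
        matrix_path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False
    )
    arr = raw.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        try:
            as_float = arr.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{matrix_path}: non-numeric counts") from exc
        if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
            raise ValidationError(f"{matrix_path}: counts must be integers")
        raw = raw.astype(np.int64)
    if (raw.to_numpy() < 0).any():
        raise ValidationError(f"{matrix_path}: counts contain negative values")
    raw.index = raw.index.astype(str)
    return PairedCohort(counts=raw, samples=samples, annotation=annotation)


def read_catalog(path) -> set[str]:
    """Read a known-lncRNA catalog: one transcript id per line."""
    with _open_text(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_coding_calls(path) -> pd.DataFrame:
    """Read coding-potential calls: transcript_id + three boolean columns.

    ``True`` means the caller predicts the transcript to be protein-coding.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN], keep_default_na=False)
    if frame.shape[1] != 4:
        raise ValidationError(
            f"{path}: expected 4 columns (transcript_id + 3 callers), got {frame.shape[1]}"
        )
    if frame.iloc[:, 0].duplicated().any():
        dups = frame.iloc[:, 0][frame.iloc[:, 0].duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate call rows for {dups[:10]}")
    out = frame.rename(columns={frame.columns[0]: "transcript_id"})
    for col in out.columns[1:]:
        vals = out[col].str.lower()
        bad = set(vals) - {"true", "false"}
        if bad:
            raise ValidationError(f"{path}: column {col}: non-boolean values {sorted(bad)}")
        out[col] = vals == "true"
    return out.set_index("transcript_id")


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format: set_id <TAB> description <TAB> genes..."""
    sets: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ParseError(f"{path}: line {lineno}: fewer than 3 fields")
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as TSV: NA for missing, 6 significant digits.

    Round-trips losslessly through :func:`read_table` at that precision;
    an empty table yields a header-only file.
    """
    records.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
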