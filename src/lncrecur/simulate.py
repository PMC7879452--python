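"""Synthetic matched tumor-normal cohorts with planted ground truth.

The generator emulates the study design the pipeline targets: a cohort of
matched tumor-normal pairs (default 19) profiled by bulk RNA-seq, where a
fraction of lncRNAs carries a planted, tumor-specific fold change that is
direction-consistent across all pairs (or deliberately inconsistent in a
subset), each planted lncRNA has protein-coding neighbors placed inside and
beyond the cis window, and trans targets whose expression is coupled to the
lncRNA through a shared per-patient latent factor so that the realized
Pearson correlation on log2(CPM+1) is high.

Counts are negative binomial with a common dispersion (var = mu + a*mu^2)
and per-sample library-size multipliers, so that normalization matters.
All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .types import PairedCohort, SampleSheet, TranscriptRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "GenerationError",
    "simulate_annotation",
    "simulate_counts",
    "simulate_cohort",
    "export_fixture",
    "FIXTURE_FILES",
]

FIXTURE_FILES = (
    "annotation.gtf",
    "counts.tsv",
    "samples.tsv",
    "known_catalog.txt",
    "coding_calls.tsv",
    "truth.tsv",
)


class GenerationError(RuntimeError):
    """The configuration cannot be realized (e.g. chromosome overflow)."""


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with study-scale defaults."""

    n_pairs: int = 19
    n_unpaired_tumor: int = 0
    n_coding_genes: int = 500
    n_lncRNA: int = 300
    frac_de: float = 0.1
    frac_consistent: float = 0.7
    log2fc_mean: float = 2.0
    log2fc_sd: float = 0.5
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.3)
    cis_window_bp: int = 100_000
    n_cis_true: int = 1
    n_trans_true: int = 1
    #: sd of the per-patient latent factor on planted-DE lncRNA log2 means
    #: (uniform, bounded at +/- sd*sqrt(3)); widens the across-patient
    #: dynamic range their targets track.
    pair_latent_sd: float = 3.5
    #: extra per-sample Gaussian noise on coupled-target log2 means; the
    #: knob bounding the planted trans correlation from above.
    trans_latent_sd: float = 0.1
    #: coupled targets track the lncRNA's centered realized log2 signal
    #: clipped to +/- this many log2 units (keeps targets quantifiable).
    coupling_clip: float = 7.0
    #: baseline abundance: log2 mean expression drawn N(mean, sd).
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    #: planted-DE lncRNAs and coupled targets are drawn abundant (the
    #: screen targets quantifiable transcripts); floored at `abundant_floor`.
    de_lnc_log2_mean: float = 7.5
    coupled_log2_mean: float = 8.0
    abundant_log2_sd: float = 1.0
    abundant_floor: float = 6.0
    n_short_decoys: int = 10
    frac_known: float = 0.5
    caller_error_rate: float = 0.0
    chrom_length_bp: int = 100_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        for name in ("frac_de", "frac_consistent", "frac_known", "caller_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_range must be 0 < lo <= hi")
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be positive")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_lncRNA))

    @property
    def n_consistent(self) -> int:
        return int(round(self.frac_consistent * self.n_de))


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of everything the generator planted.

    lnc:        per-lncRNA table (index transcript_id): is_de, consistent,
                planted_log2fc (signed), base_direction.
    directions: lncRNA x pair matrix of {-1, 0, +1}; non-zero only for
                planted-DE lncRNAs.
    cis_true:   planted cis targets with signed distance (bp, + downstream).
    cis_decoys: coding genes planted beyond the window, with distance.
    trans_true: planted trans targets with intended correlation sign.
    """

    lnc: pd.DataFrame
    directions: pd.DataFrame
    cis_true: pd.DataFrame
    cis_decoys: pd.DataFrame
    trans_true: pd.DataFrame
    short_decoys: list[str] = field(default_factory=list)

    @property
    def de_lnc_ids(self) -> list[str]:
        return self.lnc.index[self.lnc["is_de"]].tolist()

    @property
    def consistent_de_lnc_ids(self) -> list[str]:
        mask = self.lnc["is_de"] & self.lnc["consistent"]
        return self.lnc.index[mask].tolist()


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible substreams per stage
    return np.random.default_rng([config.seed % (2**31), stream])


def simulate_annotation(config: SimulationConfig) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Lay out toy chromosomes and decide which lncRNAs carry planted DE.

    Each planted-DE lncRNA owns an isolated block on the DE chromosome
    holding `n_cis_true` coding genes at a uniform distance in
    (0, cis_window_bp] and one decoy coding gene in
    (cis_window_bp, 3*cis_window_bp], with blocks spaced so neighborhoods
    never bleed into each other. All real lncRNAs are > 200 nt; a handful
    of short (< 200 nt) decoy transcripts is added.
    """
    rng = _rng(config, 1)
    W = config.cis_window_bp
    pair_ids = [f"P{i + 1:02d}" for i in range(config.n_pairs)]

    lnc_ids = [f"LNC_{i + 1:04d}" for i in range(config.n_lncRNA)]
    de_ids = list(rng.choice(lnc_ids, size=config.n_de, replace=False))
    consistent_ids = set(de_ids[: config.n_consistent])

    records: list[TranscriptRecord] = []
    cis_rows, decoy_rows, trans_rows = [], [], []

    # --- DE blocks: lncRNA + cis neighbors + beyond-window decoy ---
    block_span = 8 * W
    cursor = 1
    n_pc_used = 0

    def _coding(chrom: str, start: int, span: int) -> TranscriptRecord:
        nonlocal n_pc_used
        n_pc_used += 1
        tid = f"PCT_{n_pc_used:04d}"
        length = int(rng.integers(500, min(span, 15_000) + 1))
        return TranscriptRecord(
            transcript_id=tid,
            gene_id=f"G_{tid}",
            chrom=chrom,
            strand="+" if rng.random() < 0.5 else "-",
            start=start,
            end=start + span - 1,
            length_nt=min(length, span),
            biotype="protein_coding",
        )

    for lnc_id in de_ids:
        if cursor + block_span > config.chrom_length_bp:
            raise GenerationError(
                "chromosome overflow: too many DE blocks for chrom_length_bp"
            )
        lnc_len = int(rng.integers(201, 3001))
        lnc = TranscriptRecord(
            transcript_id=lnc_id,
            gene_id=f"G_{lnc_id}",
            chrom="chrDE",
            strand="+" if rng.random() < 0.5 else "-",
            start=cursor,
            end=cursor + lnc_len - 1,
            length_nt=lnc_len,
        )
        records.append(lnc)
        for _ in range(config.n_cis_true):
            gap = int(rng.integers(1, W + 1))
            span = int(rng.integers(1_000, 20_001))
            gene = _coding("chrDE", lnc.end + gap, span)
            records.append(gene)
            cis_rows.append(
                dict(lnc_id=lnc_id, gene_id=gene.transcript_id, distance_bp=gap)
            )
        gap = int(rng.integers(W + 1, 3 * W + 1))
        span = int(rng.integers(1_000, 20_001))
        decoy = _coding("chrDE", lnc.end + gap, span)
        records.append(decoy)
        decoy_rows.append(
            dict(lnc_id=lnc_id, gene_id=decoy.transcript_id, distance_bp=gap)
        )
        cursor += block_span

    # --- trans targets live on a separate chromosome (never cis) ---
    cursor_t = 1
    for lnc_id in de_ids:
        for _ in range(config.n_trans_true):
            span = int(rng.integers(1_000, 20_001))
            if cursor_t + span + 50_000 > config.chrom_length_bp:
                raise GenerationError("chromosome overflow on trans chromosome")
            gene = _coding("chrTRANS", cursor_t, span)
            records.append(gene)
            sign = 1 if rng.random() < 0.5 else -1
            trans_rows.append(dict(lnc_id=lnc_id, gene_id=gene.transcript_id, sign=sign))
            cursor_t += span + int(rng.integers(10_000, 50_001))

    # --- background: remaining lncRNAs, coding genes, short decoys ---
    cursor_b = 1
    background = [lid for lid in lnc_ids if lid not in set(de_ids)]
    n_bg_coding = config.n_coding_genes - n_pc_used
    if n_bg_coding < 0:
        raise GenerationError(
            "n_coding_genes too small for the requested cis/trans structure"
        )
    short_ids = [f"SHORT_{i + 1:03d}" for i in range(config.n_short_decoys)]
    bg_queue: list[tuple[str, str]] = [("lnc", lid) for lid in background]
    bg_queue += [("coding", f"bg{i}") for i in range(n_bg_coding)]
    bg_queue += [("short", sid) for sid in short_ids]
    for kind, ident in bg_queue:
        if kind == "lnc":
            length = int(rng.integers(201, 3001))
            if cursor_b + length > config.chrom_length_bp:
                raise GenerationError("chromosome overflow on background chromosome")
            records.append(
                TranscriptRecord(
                    transcript_id=ident,
                    gene_id=f"G_{ident}",
                    chrom="chrBG",
                    strand="+" if rng.random() < 0.5 else "-",
                    start=cursor_b,
                    end=cursor_b + length - 1,
                    length_nt=length,
                )
            )
            cursor_b += length
        elif kind == "coding":
            span = int(rng.integers(1_000, 20_001))
            if cursor_b + span > config.chrom_length_bp:
                raise GenerationError("chromosome overflow on background chromosome")
            records.append(_coding("chrBG", cursor_b, span))
            cursor_b += span
        else:
            length = int(rng.integers(50, 200))
            records.append(
                TranscriptRecord(
                    transcript_id=ident,
                    gene_id=f"G_{ident}",
                    chrom="chrBG",
                    strand="+",
                    start=cursor_b,
                    end=cursor_b + length - 1,
                    length_nt=length,
                )
            )
            cursor_b += length
        cursor_b += int(rng.integers(5_000, 30_001))

    # --- planted effects and per-pair directions ---
    fc = rng.normal(config.log2fc_mean, config.log2fc_sd, size=config.n_de)
    fc = np.maximum(np.abs(fc), 1.0 + 1e-9)  # planted effects must clear |log2FC| > 1
    base_dir = np.where(rng.random(config.n_de) < 0.5, 1, -1)
    lnc_table = pd.DataFrame(
        dict(
            is_de=[lid in set(de_ids) for lid in lnc_ids],
            consistent=[lid in consistent_ids for lid in lnc_ids],
            planted_log2fc=0.0,
            base_direction=0,
        ),
        index=pd.Index(lnc_ids, name="transcript_id"),
    )
    directions = pd.DataFrame(
        0, index=pd.Index(lnc_ids, name="transcript_id"), columns=pair_ids, dtype=int
    )
    n_flip = config.n_pairs // 3
    for k, lnc_id in enumerate(de_ids):
        lnc_table.loc[lnc_id, "planted_log2fc"] = base_dir[k] * fc[k]
        lnc_table.loc[lnc_id, "base_direction"] = base_dir[k]
        dirs = np.full(config.n_pairs, base_dir[k], dtype=int)
        if lnc_id not in consistent_ids and n_flip > 0:
            flip = rng.choice(config.n_pairs, size=n_flip, replace=False)
            dirs[flip] *= -1
        directions.loc[lnc_id] = dirs

    truth = SyntheticTruth(
        lnc=lnc_table,
        directions=directions,
        cis_true=pd.DataFrame(cis_rows, columns=["lnc_id", "gene_id", "distance_bp"]),
        cis_decoys=pd.DataFrame(decoy_rows, columns=["lnc_id", "gene_id", "distance_bp"]),
        trans_true=pd.DataFrame(trans_rows, columns=["lnc_id", "gene_id", "sign"]),
        short_decoys=short_ids,
    )
    return records, truth


def simulate_counts(
    annotation: list[TranscriptRecord],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> PairedCohort:
    """Draw the negative-binomial count matrix with the planted structure.

    Planted-DE lncRNAs have tumor means scaled by 2^(direction * log2fc)
    per pair, on top of a per-patient latent factor that widens their
    dynamic range across patients. Coupled targets (planted cis and
    trans) are tied to their lncRNA's *realized* per-sample log
    expression: the target's log2 mean follows the lncRNA's centered
    realized log2 expression (with the intended sign for trans targets)
    plus Gaussian noise of sd ``trans_latent_sd``. Tying to the realized
    signal makes the lncRNA's own counting noise part of the shared
    variation, so the planted Pearson correlation on log2(CPM+1) is
    bounded only by the target-side counting noise.
    """
    rng = _rng(config, 2)
    pair_ids = list(truth.directions.columns)
    sample_rows = []
    for p in pair_ids:
        sample_rows.append(dict(sample_id=f"{p}_T", condition="tumor", pair_id=p))
        sample_rows.append(dict(sample_id=f"{p}_N", condition="normal", pair_id=p))
    for i in range(config.n_unpaired_tumor):
        sample_rows.append(
            dict(sample_id=f"U{i + 1:02d}_T", condition="tumor", pair_id=None)
        )
    sheet = SampleSheet(pd.DataFrame(sample_rows))
    sample_ids = sheet.sample_ids
    tids = [t.transcript_id for t in annotation]
    n_t, n_s = len(tids), len(sample_ids)
    tidx = {t: i for i, t in enumerate(tids)}

    de_ids = truth.de_lnc_ids
    coupled_targets = set(truth.cis_true["gene_id"]) | set(truth.trans_true["gene_id"])

    # baseline log2 means
    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_t)
    for t in de_ids:
        base[tidx[t]] = max(
            config.abundant_floor,
            rng.normal(config.de_lnc_log2_mean, config.abundant_log2_sd),
        )
    for t in sorted(coupled_targets):
        base[tidx[t]] = max(
            config.abundant_floor,
            rng.normal(config.coupled_log2_mean, config.abundant_log2_sd),
        )

    log2_mu = np.tile(base[:, None], (1, n_s))

    # per-sample condition/pair lookup
    cond = np.array([sheet.condition_of(s) == "tumor" for s in sample_ids])
    pair_of = {
        s: sheet.frame.loc[sheet.frame["sample_id"] == s, "pair_id"].item()
        for s in sample_ids
    }

    # coupling map lncRNA -> [(target, sign)]
    targets_of: dict[str, list[tuple[str, int]]] = {t: [] for t in de_ids}
    for row in truth.cis_true.itertuples():
        targets_of[row.lnc_id].append((row.gene_id, 1))
    for row in truth.trans_true.itertuples():
        targets_of[row.lnc_id].append((row.gene_id, row.sign))

    for lnc_id in de_ids:
        fc = abs(truth.lnc.loc[lnc_id, "planted_log2fc"])
        half_width = config.pair_latent_sd * np.sqrt(3.0)
        latent = rng.uniform(-half_width, half_width, size=len(pair_ids))
        latent_by_pair = dict(zip(pair_ids, latent))
        li = tidx[lnc_id]
        for j, s in enumerate(sample_ids):
            p = pair_of[s]
            if p is None or pd.isna(p):
                z = rng.uniform(-half_width, half_width)
                d = int(truth.lnc.loc[lnc_id, "base_direction"])
            else:
                z = latent_by_pair[p]
                d = int(truth.directions.loc[lnc_id, p])
            shift = d * fc if cond[j] else 0.0
            log2_mu[li, j] += z + shift

    lib = rng.uniform(*config.libsize_range, size=n_s)
    shape = 1.0 / config.nb_dispersion
    mu = lib[None, :] * np.exp2(log2_mu)
    counts = rng.negative_binomial(shape, shape / (shape + mu))

    # second pass: coupled targets follow the lncRNA's realized measured
    # signal (log2 CPM against provisional library totals), so the planted
    # correlation survives library-size noise with either coupling sign
    lib_total = counts.sum(axis=0).astype(float)
    lib_rel = lib_total / lib_total.mean()
    for lnc_id in de_ids:
        li = tidx[lnc_id]
        realized = np.log2(counts[li] * (1e6 / lib_total) + 1.0)
        centered = realized - realized.mean()
        centered = np.clip(centered, -config.coupling_clip, config.coupling_clip)
        for gene_id, sign in targets_of[lnc_id]:
            gi = tidx[gene_id]
            log2_mu[gi] = (
                base[gi]
                + sign * centered
                + rng.normal(0.0, config.trans_latent_sd, size=n_s)
            )
            mu_g = lib_rel * np.exp2(log2_mu[gi])
            counts[gi] = rng.negative_binomial(shape, shape / (shape + mu_g))
    frame = pd.DataFrame(
        counts.astype(np.int64), index=pd.Index(tids, name="transcript_id"), columns=sample_ids
    )
    return PairedCohort(counts=frame, samples=sheet, annotation=annotation)


def simulate_cohort(config: SimulationConfig) -> tuple[PairedCohort, SyntheticTruth]:
    """Convenience: annotation + counts in one call."""
    annotation, truth = simulate_annotation(config)
    cohort = simulate_counts(annotation, truth, config)
    return cohort, truth


def _truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    rows = []
    for lnc_id, row in truth.lnc.iterrows():
        rows.append(
            dict(
                kind="lnc",
                lnc_id=lnc_id,
                gene_id=None,
                is_de=bool(row["is_de"]),
                consistent=bool(row["consistent"]),
                planted_log2fc=row["planted_log2fc"] if row["is_de"] else np.nan,
                directions=",".join(str(int(d)) for d in truth.directions.loc[lnc_id]),
                distance_bp=np.nan,
                sign=np.nan,
            )
        )
    for kind, frame in (("cis_true", truth.cis_true), ("cis_decoy", truth.cis_decoys)):
        for r in frame.itertuples():
            rows.append(
                dict(
                    kind=kind,
                    lnc_id=r.lnc_id,
                    gene_id=r.gene_id,
                    is_de=None,
                    consistent=None,
                    planted_log2fc=np.nan,
                    directions=None,
                    distance_bp=float(r.distance_bp),
                    sign=np.nan,
                )
            )
    for r in truth.trans_true.itertuples():
        rows.append(
            dict(
                kind="trans_true",
                lnc_id=r.lnc_id,
                gene_id=r.gene_id,
                is_de=None,
                consistent=None,
                planted_log2fc=np.nan,
                directions=None,
                distance_bp=np.nan,
                sign=float(r.sign),
            )
        )
    for sid in truth.short_decoys:
        rows.append(
            dict(
                kind="short_decoy",
                lnc_id=sid,
                gene_id=None,
                is_de=None,
                consistent=None,
                planted_log2fc=np.nan,
                directions=None,
                distance_bp=np.nan,
                sign=np.nan,
            )
        )
    return pd.DataFrame(rows)


def export_fixture(
    cohort: PairedCohort,
    truth: SyntheticTruth,
    directory,
    config: SimulationConfig,
) -> dict[str, Path]:
    """Write the six-file fixture directory readable by :mod:`lncrecur.io`.

    known_catalog.txt flags a random `frac_known` subset of the true
    lncRNAs as "known"; coding_calls.tsv calls every true lncRNA (and
    short decoy) non-coding and every coding gene coding, then corrupts
    a `caller_error_rate` fraction of rows with one flipped caller.
    """
    rng = _rng(config, 3)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / name for name in FIXTURE_FILES}

    lio.write_gtf(cohort.annotation, paths["annotation.gtf"])
    cohort.counts.rename_axis("transcript_id").to_csv(paths["counts.tsv"], sep="\t")
    cohort.samples.frame.to_csv(
        paths["samples.tsv"], sep="\t", index=False, na_rep=lio.NA_TOKEN
    )

    lnc_ids = sorted(truth.lnc.index)
    n_known = int(round(config.frac_known * len(lnc_ids)))
    known = sorted(rng.choice(lnc_ids, size=n_known, replace=False))
    paths["known_catalog.txt"].write_text("".join(f"{t}\n" for t in known))

    call_rows = []
    for rec in cohort.annotation:
        coding = rec.biotype == "protein_coding"
        calls = [coding, coding, coding]
        if rng.random() < config.caller_error_rate:
            k = int(rng.integers(0, 3))
            calls[k] = not calls[k]
        call_rows.append(
            dict(
                transcript_id=rec.transcript_id,
                caller_1=str(calls[0]).lower(),
                caller_2=str(calls[1]).lower(),
                caller_3=str(calls[2]).lower(),
            )
        )
    pd.DataFrame(call_rows).to_csv(paths["coding_calls.tsv"], sep="\t", index=False)

    lio.write_table(_truth_frame(truth), paths["truth.tsv"])
    return paths
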