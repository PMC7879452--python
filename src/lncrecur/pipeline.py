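"""End-to-end orchestration: simulate -> identify -> de -> prioritize -> targets.

A run is driven by a single namespaced config (dict or YAML), writes each
stage's TSV into a run directory together with a manifest recording the
resolved config, seed and per-stage row counts, and is byte-identical
when repeated with the same config and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import de as de_mod
from . import identify as id_mod
from . import io as lio
from . import recurrence as rec_mod
from . import simulate as sim_mod
from . import targets as tgt_mod
from .types import ValidationError

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_all"]

log = logging.getLogger("lncrecur")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {f.name: None for f in sim_mod.SimulationConfig.__dataclass_fields__.values()},
    "identify": {"min_length": 200, "consensus_k": 3, "min_count": 1},
    "de": {
        "pseudocount": 1.0,
        "q_max": 0.05,
        "lfc_min": 1.0,
        "bins": 100,
        "min_bin": 30,
        "sigma_min": 0.05,
        "min_count": 1,
    },
    "prioritize": {
        "min_occurrence": 10,
        "occurrence_cmp": "gt",
        "max_discordant": 0,
        "direction": "both",
    },
    "targets": {"window_bp": 100_000, "r_min": 0.95},
    "enrich": {"gmt": None},
    "paths": {"input_dir": None, "out_dir": "run"},
}


def resolve_config(user: dict) -> dict:
    """Merge a user config over the defaults; unknown keys are rejected."""
    resolved = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, value in user.items():
        if section not in resolved:
            raise ValidationError(f"unknown config section {section!r}")
        if isinstance(resolved[section], dict):
            if not isinstance(value, dict):
                raise ValidationError(f"config section {section!r} must be a mapping")
            for key, v in value.items():
                if key not in resolved[section]:
                    raise ValidationError(f"unknown config key {section}.{key}")
                resolved[section][key] = v
        else:
            resolved[section] = value
    return resolved


def _sim_config(resolved: dict) -> sim_mod.SimulationConfig:
    kwargs = {k: v for k, v in resolved["simulate"].items() if v is not None}
    kwargs.setdefault("seed", resolved["seed"])
    if isinstance(kwargs.get("libsize_range"), list):
        kwargs["libsize_range"] = tuple(kwargs["libsize_range"])
    return sim_mod.SimulationConfig(**kwargs)


def run_all(config: dict, out_dir: str | Path | None = None) -> Path:
    """Execute every stage in order; returns the run directory.

    Inputs either come from ``paths.input_dir`` (a fixture directory laid
    out as by :func:`lncrecur.simulate.export_fixture`) or are simulated
    from the ``simulate.*`` parameters. A failing stage halts the run;
    outputs of completed stages are retained.
    """
    resolved = resolve_config(config)
    out = Path(out_dir or resolved["paths"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "lncrecur",
        "version": __version__,
        "seed": resolved["seed"],
        "config": resolved,
        "stages": {},
    }

    def _done(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    # --- stage 1: inputs (simulate or load) ---
    if resolved["paths"]["input_dir"]:
        d = Path(resolved["paths"]["input_dir"])
        annotation = lio.read_gtf(d / "annotation.gtf")
        cohort = lio.read_counts(d / "counts.tsv", d / "samples.tsv", annotation)
        catalog = lio.read_catalog(d / "known_catalog.txt")
        calls = lio.read_coding_calls(d / "coding_calls.tsv")
    else:
        sim_cfg = _sim_config(resolved)
        cohort, truth = sim_mod.simulate_cohort(sim_cfg)
        sim_mod.export_fixture(cohort, truth, out / "fixture", sim_cfg)
        d = out / "fixture"
        annotation = lio.read_gtf(d / "annotation.gtf")
        cohort = lio.read_counts(d / "counts.tsv", d / "samples.tsv", annotation)
        catalog = lio.read_catalog(d / "known_catalog.txt")
        calls = lio.read_coding_calls(d / "coding_calls.tsv")
    _done(
        "input",
        transcripts=len(annotation),
        samples=len(cohort.samples),
        pairs=cohort.n_pairs,
    )

    # --- stage 2: identify ---
    icfg = resolved["identify"]
    classified = id_mod.classify_transcripts(
        annotation,
        catalog,
        calls,
        cohort,
        min_length=icfg["min_length"],
        consensus_k=icfg["consensus_k"],
        min_count=icfg["min_count"],
    )
    lio.write_table(classified.table, out / "classified.tsv")
    summary = id_mod.summarize_catalog(classified)
    _done(
        "identify",
        rows=len(classified.table),
        n_known=summary.n_known,
        n_novel=summary.n_novel,
    )

    # --- stage 3: paired DE ---
    dcfg = resolved["de"]
    params = de_mod.LpeParams(
        bins=dcfg["bins"],
        min_bin=dcfg["min_bin"],
        sigma_min=dcfg["sigma_min"],
        min_count=dcfg["min_count"],
    )
    de_table = de_mod.run_paired_de(
        cohort,
        pseudocount=dcfg["pseudocount"],
        params=params,
        q_max=dcfg["q_max"],
        lfc_min=dcfg["lfc_min"],
    )
    lio.write_table(de_table, out / "de_results.tsv")
    _done("de", rows=len(de_table), de_calls=int(de_table["is_de"].sum()))

    # --- stage 4: prioritize ---
    pcfg = resolved["prioritize"]
    occ = rec_mod.prioritize(
        de_table,
        classified.lncrna_ids,
        min_occurrence=pcfg["min_occurrence"],
        occurrence_cmp=pcfg["occurrence_cmp"],
        max_discordant=pcfg["max_discordant"],
        direction=pcfg["direction"],
    )
    lio.write_table(occ, out / "occurrence.tsv")
    n_consistent = int(occ["consistency"].str.startswith("consistent").sum())
    _done("prioritize", rows=len(occ), consistent=n_consistent)

    # --- stage 5: targets ---
    tcfg = resolved["targets"]
    candidate_ids = set(occ.dropna(subset=["rank"])["transcript_id"])
    lnc_recs = [r for r in classified.records if r.transcript_id in candidate_ids]
    coding_recs = [r for r in classified.records if r.biotype == "protein_coding"]
    cis = tgt_mod.cis_targets(lnc_recs, coding_recs, tcfg["window_bp"])
    expr = de_mod.normalize(cohort, dcfg["pseudocount"])
    trans = tgt_mod.trans_targets(
        expr, candidate_ids, {r.transcript_id for r in coding_recs}, tcfg["r_min"]
    )
    target_table = pd.concat([cis, trans], ignore_index=True)
    lio.write_table(target_table, out / "targets.tsv")
    _done("targets", cis=len(cis), trans=len(trans))

    # --- stage 6: enrichment (only when gene sets are supplied) ---
    if resolved["enrich"]["gmt"]:
        gene_sets = lio.read_gmt(resolved["enrich"]["gmt"])
        universe = {r.transcript_id for r in coding_recs}
        selected = set(target_table["gene_id"]) & universe
        enrichment = tgt_mod.overrepresentation_test(selected, gene_sets, universe)
        lio.write_table(enrichment, out / "enrichment.tsv")
        _done("enrich", sets=len(enrichment))

    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
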