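"""End-to-end pipeline orchestration from one YAML configuration.

Stage order: simulate -> build-db -> map-peptides -> fit-kloss -> assemble
-> correlate -> enrich -> call-switches.  Every stage writes its TSV
outputs plus a manifest entry (parameters, row counts, output hashes); a
rerun with identical config and seed reproduces identical outputs and can
resume from the manifest.  A single global seed is fanned out to per-stage
seeds by a fixed derivation so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import db_builder, enrichment, io_formats, matrix_assembly
from . import peptide_mapping, sim, stats_correlation, switch_events, turnover

log = logging.getLogger("pulsekin")

STAGES = [
    "simulate",
    "build_db",
    "map_peptides",
    "fit_kloss",
    "assemble",
    "correlate",
    "enrich",
    "call_switches",
]


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    db: db_builder.DbFilterConfig = field(default_factory=db_builder.DbFilterConfig)
    digest: peptide_mapping.DigestConfig = field(
        default_factory=peptide_mapping.DigestConfig
    )
    turnover: turnover.TurnoverConfig = field(default_factory=turnover.TurnoverConfig)
    assembly: matrix_assembly.AssemblyConfig = field(
        default_factory=matrix_assembly.AssemblyConfig
    )
    switch: switch_events.SwitchConfig = field(
        default_factory=switch_events.SwitchConfig
    )
    annotations_path: Path | None = None
    kloss_method: str = "RIA"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "out_dir" not in raw:
            raise ValueError("pipeline config requires 'out_dir'")
        kwargs: dict = {
            "out_dir": Path(raw["out_dir"]),
            "seed": int(raw.get("seed", 0)),
            "log_level": raw.get("log_level", "INFO"),
            "kloss_method": raw.get("kloss_method", "RIA"),
        }
        if raw.get("annotations_path"):
            kwargs["annotations_path"] = Path(raw["annotations_path"])
        blocks = {
            "sim": sim.SimConfig,
            "db": db_builder.DbFilterConfig,
            "digest": peptide_mapping.DigestConfig,
            "turnover": turnover.TurnoverConfig,
            "assembly": matrix_assembly.AssemblyConfig,
            "switch": switch_events.SwitchConfig,
        }
        for name, klass in blocks.items():
            block = dict(raw.get(name, {}))
            if name == "sim":
                block.setdefault("seed", kwargs["seed"])
                if "isoform_count_distribution" in block:
                    dist = block["isoform_count_distribution"]
                    pairs = dist.items() if hasattr(dist, "items") else dist
                    block["isoform_count_distribution"] = tuple(
                        sorted((int(k), float(v)) for k, v in pairs)
                    )
                for key in ("time_points_h", "kloss_range"):
                    if key in block:
                        block[key] = tuple(block[key])
            if name == "turnover" and "k_bounds" in block:
                block["k_bounds"] = tuple(block["k_bounds"])
            kwargs[name] = klass(**block)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out: dict = {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "log_level": self.log_level,
            "kloss_method": self.kloss_method,
            "annotations_path": str(self.annotations_path)
            if self.annotations_path
            else None,
        }
        for name in ("sim", "db", "digest", "turnover", "assembly", "switch"):
            out[name] = dataclasses.asdict(getattr(self, name))
        return out


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.entries: dict[str, dict] = {}
        if path.exists():
            self.entries = json.loads(path.read_text())

    def done(self, stage: str, params_hash: str) -> bool:
        e = self.entries.get(stage)
        if not e or e.get("params_hash") != params_hash:
            return False
        return all(Path(p).exists() for p in e.get("outputs", {}))

    def record(self, stage: str, params_hash: str, outputs: dict[str, Path],
               counts: dict[str, int]) -> None:
        self.entries[stage] = {
            "params_hash": params_hash,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs.values()},
            "row_counts": counts,
        }
        self.path.write_text(json.dumps(self.entries, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the manifest entries.

    A stage failure aborts with the failing stage named in the raised error.
    """
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out / "manifest.json")
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()

    state: dict = {}
    for stage in STAGES:
        try:
            _run_stage(stage, config, out, manifest, cfg_hash, state)
        except Exception as exc:  # add stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest.entries


def _resume_stage(stage: str, out: Path, state: dict) -> None:
    """Reload a completed stage's state from its outputs."""
    if stage == "simulate":
        state["transcripts"] = io_formats.read_transcripts(out / "transcripts.tsv")
        state["expression"] = io_formats.read_expression_matrix(out / "expression.tsv")
        state["precursors"] = io_formats.read_precursor_table(out / "psilac.tsv")
        meta = io_formats.read_table(out / "sim_samples.tsv", dtype=str)
        samples = tuple(meta["sample"])
        condition_of = dict(zip(meta["sample"], meta["condition"]))
        buf = io_formats.read_table(out / "sim_buffered.tsv", dtype=str)
        state["truth"] = sim.SimTruth(
            transcripts=state["transcripts"],
            fpkm=pd.DataFrame(),
            gene_kloss=pd.DataFrame(),
            samples=samples,
            condition_of=condition_of,
            buffered_genes=frozenset(buf["gene_id"]),
        )
    elif stage == "build_db":
        state["db"] = io_formats.read_fasta(out / "db.fasta")
    elif stage == "map_peptides":
        adf = io_formats.read_table(out / "peptide_assignments.tsv", dtype=str)
        state["assignments"] = {
            r["peptide"]: peptide_mapping.PeptideAssignment(
                r["peptide"],
                frozenset(r["transcript_ids"].split(";")),
                frozenset(r["gene_ids"].split(";")),
                r["class"],
            )
            for r in adf.to_dict("records")
        }
        gdf = io_formats.read_table(out / "as_groups.tsv", dtype=str)
        state["groups"] = [
            peptide_mapping.ASGroup(
                r["group_id"],
                r["gene_id"],
                frozenset(r["member_transcripts"].split(";")),
                r["class"],
                r["representative_transcript"],
                frozenset(str(r["peptides"]).split(";"))
                if pd.notna(r["peptides"]) else frozenset(),
            )
            for r in gdf.to_dict("records")
        ]
    elif stage == "fit_kloss":
        group = io_formats.read_table(out / "kloss_group.tsv", index_col=0)
        state["kloss"] = {"group": group}
    elif stage == "assemble":
        mats = {
            name: io_formats.read_table(out / f"matrix_{name}.tsv", index_col=0)
            for name in ("protein", "kloss", "mrna", "meta")
        }
        state["omics"] = matrix_assembly.OmicsMatrix(
            protein=mats["protein"], kloss=mats["kloss"],
            mrna=mats["mrna"], meta=mats["meta"],
        )
    elif stage == "correlate":
        state["correlations"] = io_formats.read_table(
            out / "correlation_per_group.tsv", index_col=0
        )


def _run_stage(stage, config: PipelineConfig, out: Path, manifest: Manifest,
               cfg_hash: str, state: dict) -> None:
    seed = stage_seed(config.seed, stage)
    write = io_formats.write_table

    if manifest.done(stage, cfg_hash):
        log.info("%s: up to date, resuming from manifest", stage)
        _resume_stage(stage, out, state)
        return

    if stage == "simulate":
        sim_cfg = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "sim"))
        transcripts, expression, precursors, truth = sim.simulate_dataset(sim_cfg)
        state.update(
            transcripts=transcripts, expression=expression,
            precursors=precursors, truth=truth,
        )
        io_formats.write_transcripts(transcripts, out / "transcripts.tsv",
                                     "simulate", seed)
        io_formats.write_expression_matrix(expression, out / "expression.tsv",
                                           "simulate", seed)
        io_formats.write_precursor_table(precursors, out / "psilac.tsv",
                                         "simulate", seed)
        samples_df = pd.DataFrame(
            {"sample": list(truth.samples),
             "condition": [truth.condition_of[s] for s in truth.samples]}
        )
        write(samples_df, out / "sim_samples.tsv", "simulate", seed)
        write(pd.DataFrame({"gene_id": sorted(truth.buffered_genes)}),
              out / "sim_buffered.tsv", "simulate", seed)
        manifest.record(stage, cfg_hash, {
            "transcripts": out / "transcripts.tsv",
            "expression": out / "expression.tsv",
            "psilac": out / "psilac.tsv",
            "samples": out / "sim_samples.tsv",
            "buffered": out / "sim_buffered.tsv",
        }, {"transcripts": len(transcripts), "precursor_rows": len(precursors)})
        log.info("simulate: %d transcripts, %d precursor rows",
                 len(transcripts), len(precursors))

    elif stage == "build_db":
        included, report = db_builder.build_filtered_db(
            state["transcripts"], state["expression"], config.db
        )
        state["db"] = included
        io_formats.write_fasta(included, out / "db.fasta")
        write(report, out / "db_report.tsv", "build-db", seed)
        n_exc = int((~report["included"]).sum())
        log.info("build_db: %d included, %d excluded", len(included), n_exc)
        manifest.record(stage, cfg_hash,
                        {"fasta": out / "db.fasta", "report": out / "db_report.tsv"},
                        {"included": len(included), "excluded": n_exc})

    elif stage == "map_peptides":
        pep_map = peptide_mapping.build_peptide_map(state["db"], config.digest)
        assignments = peptide_mapping.classify_peptides(pep_map, state["transcripts"])
        groups = peptide_mapping.assemble_as_groups(assignments, state["expression"])
        state["assignments"] = assignments
        state["groups"] = groups
        adf = peptide_mapping.assignments_frame(assignments)
        gdf = peptide_mapping.groups_frame(groups)
        write(adf, out / "peptide_assignments.tsv", "map-peptides", seed)
        write(gdf, out / "as_groups.tsv", "map-peptides", seed)
        n_multi = int((adf["class"] == "multi_gene").sum())
        log.info("map_peptides: %d peptides (%d multi-gene excluded), %d groups",
                 len(adf), n_multi, len(gdf))
        manifest.record(stage, cfg_hash,
                        {"assignments": out / "peptide_assignments.tsv",
                         "groups": out / "as_groups.tsv"},
                        {"peptides": len(adf), "groups": len(gdf)})

    elif stage == "fit_kloss":
        if config.kloss_method == "NLI":
            est, excl = turnover.fit_kloss_nli(state["precursors"], config.turnover)
        else:
            est, excl = turnover.fit_kloss_ria_table(
                state["precursors"], config.turnover
            )
        agg = turnover.aggregate_kloss(
            est, state["assignments"], state["groups"], config.turnover,
            samples=list(state["truth"].samples),
        )
        state["kloss"] = agg
        write(est, out / "kloss_precursor.tsv", "fit-kloss", seed)
        write(excl, out / "kloss_exclusions.tsv", "fit-kloss", seed)
        write(agg["group"].reset_index(), out / "kloss_group.tsv", "fit-kloss", seed)
        for reason, n in excl["reason"].value_counts().items():
            log.info("fit_kloss: excluded %d profiles (%s)", n, reason)
        for rule, n in agg["log"].items():
            log.info("fit_kloss: %s = %d", rule, n)
        manifest.record(stage, cfg_hash,
                        {"precursor": out / "kloss_precursor.tsv",
                         "exclusions": out / "kloss_exclusions.tsv",
                         "group": out / "kloss_group.tsv"},
                        {"precursor_fits": len(est), "groups": len(agg["group"])})

    elif stage == "assemble":
        pep_int = matrix_assembly.peptide_intensity_from_psilac(state["precursors"])
        protein, plog = matrix_assembly.assemble_protein_matrix(
            pep_int, state["assignments"], state["groups"], config.assembly
        )
        om = matrix_assembly.join_omics(
            protein, state["kloss"]["group"], state["expression"], state["groups"],
            config.assembly,
        )
        state["omics"] = om
        for rule, n in plog.items():
            log.info("assemble: %s = %d", rule, n)
        write(om.protein.reset_index(), out / "matrix_protein.tsv", "assemble", seed)
        write(om.kloss.reset_index(), out / "matrix_kloss.tsv", "assemble", seed)
        write(om.mrna.reset_index(), out / "matrix_mrna.tsv", "assemble", seed)
        write(om.meta.reset_index(), out / "matrix_meta.tsv", "assemble", seed)
        manifest.record(stage, cfg_hash,
                        {"protein": out / "matrix_protein.tsv",
                         "kloss": out / "matrix_kloss.tsv",
                         "mrna": out / "matrix_mrna.tsv",
                         "meta": out / "matrix_meta.tsv"},
                        {"groups": len(om.protein)})

    elif stage == "correlate":
        om = state["omics"]
        cond = state["truth"].condition_of
        rows = []
        for pair in stats_correlation.PAIRS:
            try:
                rho, p, n = stats_correlation.absolute_correlation(om, pair)
                rows.append(("absolute", pair, rho, p, n))
                rho, p, n = stats_correlation.relative_correlation(om, cond, pair)
                rows.append(("relative", pair, rho, p, n))
            except ValueError as exc:
                log.warning("correlate: %s skipped (%s)", pair, exc)
        summary = pd.DataFrame(rows, columns=["kind", "pair", "rho", "p", "n"])
        per_group = stats_correlation.per_group_correlation(om, "mRNA_kloss")
        state["correlations"] = per_group
        write(summary, out / "correlation_summary.tsv", "correlate", seed)
        write(per_group.reset_index(), out / "correlation_per_group.tsv",
              "correlate", seed)
        manifest.record(stage, cfg_hash,
                        {"summary": out / "correlation_summary.tsv",
                         "per_group": out / "correlation_per_group.tsv"},
                        {"per_group": len(per_group)})

    elif stage == "enrich":
        per_group = state["correlations"]
        if config.annotations_path:
            annotations = enrichment.read_annotations(config.annotations_path)
        else:
            # default annotation: buffered-gene membership from the simulation
            truth = state["truth"]
            meta = state["omics"].meta
            annotations = {
                "buffered": set(meta.index[meta["gene_id"].isin(truth.buffered_genes)])
            }
        res = enrichment.enrich_1d(per_group["rho"], annotations, min_members=5)
        write(res.reset_index(), out / "enrichment_1d.tsv", "enrich", seed)
        manifest.record(stage, cfg_hash,
                        {"enrichment": out / "enrichment_1d.tsv"},
                        {"terms": len(res)})

    elif stage == "call_switches":
        truth = state["truth"]
        events = switch_events.call_switches(
            state["expression"], state["transcripts"], truth.condition_of,
            config.switch,
        )
        edf = switch_events.events_frame(events)
        write(edf, out / "switch_events.tsv", "call-switches", seed)
        log.info("call_switches: %d events", len(edf))
        manifest.record(stage, cfg_hash,
                        {"events": out / "switch_events.tsv"},
                        {"events": len(edf)})
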