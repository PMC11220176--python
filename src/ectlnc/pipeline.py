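"""Pipeline orchestration: sim -> catalog -> screen -> conserve -> triplex -> clusters.

One YAML config drives all stages; every output is a TSV/JSON file written
deterministically (sorted keys, fixed column orders, no timestamps), so a
re-run with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import clusters as clusters_mod
from . import conservation, screen as screen_mod, triplex as triplex_mod
from .catalog import CatalogParams, build_catalog, regulation_mode, write_catalog
from .simulate import (
    SimParams,
    SpeciesData,
    SyntheticDataset,
    generate_ect_dataset,
    load_species,
    write_dataset,
)

logger = logging.getLogger("ectlnc.pipeline")

ALL_STAGES = ("sim", "catalog", "screen", "conserve", "triplex", "clusters")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    sim: SimParams | None = None
    species_paths: list[dict[str, str]] = field(default_factory=list)
    catalog_params: CatalogParams = field(default_factory=CatalogParams)
    screen_params: screen_mod.ScreenParams = field(default_factory=screen_mod.ScreenParams)
    triplex_params: triplex_mod.TriplexParams = field(default_factory=triplex_mod.TriplexParams)
    cluster_max_gap: int = 250_000
    cluster_min_members: int = 2
    log_level: str = "INFO"


def load_config(path: str | Path, outdir: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    cfg_seed = seed if seed is not None else int(raw.get("seed", 0))
    sim_block = raw.get("sim")
    sim = None
    if sim_block is not None:
        sim_block = dict(sim_block)
        sim_block.setdefault("rng_seed", cfg_seed)
        if seed is not None:
            sim_block["rng_seed"] = cfg_seed
        sim = SimParams(**sim_block)
    clusters_block = raw.get("clusters", {})
    tri_block = dict(raw.get("triplex", {}))
    if "motifs" in tri_block:
        tri_block["motifs"] = frozenset(tri_block["motifs"])
    return PipelineConfig(
        outdir=Path(outdir if outdir is not None else raw.get("out", "ect_out")),
        seed=cfg_seed,
        sim=sim,
        species_paths=list(raw.get("species", [])),
        catalog_params=CatalogParams(**raw.get("catalog", {})),
        screen_params=screen_mod.ScreenParams(**raw.get("screen", {})),
        triplex_params=triplex_mod.TriplexParams(**tri_block),
        cluster_max_gap=int(clusters_block.get("max_gap", 250_000)),
        cluster_min_members=int(clusters_block.get("min_members", 2)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _load_inputs(config: PipelineConfig) -> list[SpeciesData]:
    if config.sim is not None:
        dataset: SyntheticDataset = generate_ect_dataset(config.sim)
        simdir = config.outdir / "sim"
        write_dataset(dataset, simdir)
        logger.info("sim: wrote %d species to %s", len(dataset.species), simdir)
        return dataset.species
    if not config.species_paths:
        raise PipelineError("config provides neither 'sim' nor 'species' inputs")
    species = []
    for entry in config.species_paths:
        species.append(
            load_species(entry["fasta"], entry["gff3"], entry.get("name", Path(entry["fasta"]).stem))
        )
    return species


def _count_trans(lncrnas, targets, params: CatalogParams) -> int:
    n = 0
    for lnc_model, _ in lncrnas:
        if all(
            regulation_mode(lnc_model, t_model, params) == "trans"
            for t_model, _ in targets
        ):
            n += 1
    return n


def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> dict[str, Any]:
    """Run the requested stages (default: all) and write the report bundle.

    On stage failure, partial outputs are retained and MANIFEST.json records
    which stages completed before the error is re-raised.
    """
    stages = tuple(stages) if stages is not None else ALL_STAGES
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    report: dict[str, Any] = {"seed": config.seed}
    try:
        species = _load_inputs(config)
        if config.sim is not None and "sim" in stages:
            completed.append("sim")
        primary = species[0]
        others = species[1:]
        lncrnas = primary.lncrnas()
        targets = primary.mrnas()

        if "catalog" in stages:
            catalog = build_catalog(
                primary.transcripts("lncRNA") + primary.transcripts("coding")
                + primary.transcripts("unclassified"),
                config.catalog_params,
            )
            write_catalog(catalog, outdir / "catalog.tsv")
            logger.info("catalog: %d transcripts", len(catalog))
            completed.append("catalog")

        pairs: list[screen_mod.ECTPair] = []
        if "screen" in stages:
            pairs = screen_mod.screen_pairs(
                lncrnas, targets, config.screen_params, config.catalog_params
            )
            screen_mod.write_pairs(pairs, outdir / "pairs.tsv")
            n_trans = _count_trans(lncrnas, targets, config.catalog_params)
            summary = screen_mod.summarize_screen(pairs, len(lncrnas), n_trans)
            report["screen"] = dataclasses.asdict(summary)
            (outdir / "summary.json").write_text(
                json.dumps(report["screen"] | {"seed": config.seed}, indent=2, sort_keys=True)
            )
            logger.info(
                "screen: %d lncRNAs x %d targets -> %d pairs (%d trans-NAT)",
                len(lncrnas), len(targets), summary.n_pairs, summary.nat_count,
            )
            completed.append("screen")

        if "conserve" in stages:
            seed_cdnas = {m.transcript_id: c for m, c in lncrnas}
            species_data = {sp.name: (sp.lncrnas(), sp.mrnas()) for sp in others}
            rows, conserved = conservation.build_conservation_table(
                pairs, seed_cdnas, species_data,
                config.screen_params, config.catalog_params,
            )
            df = conservation.table_to_dataframe(rows, conserved)
            conservation.write_conservation_table(df, outdir / "conservation_table.tsv")
            report["conserve"] = {
                "n_rows": len(rows),
                "n_conserved_seeds": sum(conserved.values()),
            }
            logger.info("conserve: %d rows, %d conserved seeds", len(rows), sum(conserved.values()))
            completed.append("conserve")

        if "triplex" in stages:
            frames = []
            model_index = primary.model_index()
            for pair in pairs:
                lnc_cdna = seed_cdnas_lookup(lncrnas, pair.alignment.lnc_id)
                tgt_model = model_index[pair.alignment.target_id]
                locus = tgt_model.locus
                dna = primary.genome[locus.chrom][locus.start : locus.end]
                sites = triplex_mod.match_triplex(lnc_cdna, dna, config.triplex_params)
                frames.append(
                    triplex_mod.sites_to_dataframe(
                        sites, pair.alignment.lnc_id, pair.alignment.target_id
                    )
                )
            frames = [f for f in frames if not f.empty]
            df = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=triplex_mod.SITE_COLUMNS)
            )
            triplex_mod.write_sites(df, outdir / "triplex_sites.tsv")
            report["triplex"] = {"n_sites": len(df)}
            logger.info("triplex: %d sites", len(df))
            completed.append("triplex")

        if "clusters" in stages:
            genes = [
                (m.gene_id, m.family_label, m.locus)
                for m in primary.models
                if m.family_label
            ]
            found, singles = clusters_mod.detect_clusters(
                genes, config.cluster_max_gap, config.cluster_min_members
            )
            clusters_mod.clusters_to_dataframe(found, singles).to_csv(
                outdir / "clusters.tsv", sep="\t", index=False
            )
            adjacency = clusters_mod.adjacency_report(
                pairs, found + singles, primary.model_index()
            )
            adjacency.to_csv(outdir / "adjacency.tsv", sep="\t", index=False)
            report["clusters"] = {"n_clusters": len(found), "n_singletons": len(singles)}
            logger.info("clusters: %d clusters, %d singletons", len(found), len(singles))
            completed.append("clusters")
    finally:
        (outdir / "MANIFEST.json").write_text(
            json.dumps({"completed_stages": completed, "seed": config.seed},
                       indent=2, sort_keys=True)
        )
    report["completed_stages"] = completed
    return report


def seed_cdnas_lookup(lncrnas, lnc_id: str) -> str:
    for model, cdna in lncrnas:
        if model.transcript_id == lnc_id:
            return cdna.seq
    raise KeyError(lnc_id)


# --- printed-table fixtures ------------------------------------------------

def fixture_path(name: str) -> Path:
    """Path to a packaged fixture TSV (table1_fixture.tsv / table2_fixture.tsv)."""
    return Path(resources.files("ectlnc.data") / name)


def load_table_fixture(path: str | Path) -> list[tuple[float, float, str]]:
    """Load a transcribed pair table as (overlap, global, flag) records.

    Rows whose identity columns are null ('.') are skipped (the published
    table contains ortholog hits with no qualifying target).  Malformed rows
    raise with their line number; an empty file is malformed.
    """
    path = Path(path)
    lines = path.read_text().rstrip("\n").split("\n")
    if len(lines) < 2 or not lines[0].strip():
        raise ValueError(f"{path}: fixture is empty")
    header = lines[0].split("\t")
    try:
        i_overlap = header.index("overlap_identity_pct")
        i_global = header.index("global_identity_pct")
        i_flag = header.index("consistency_flag")
    except ValueError as exc:
        raise ValueError(f"{path}: missing required column ({exc})") from exc
    records: list[tuple[float, float, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
        overlap, global_, flag = fields[i_overlap], fields[i_global], fields[i_flag]
        if overlap == "." and global_ == "." and flag == ".":
            continue
        if flag not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: bad consistency flag {flag!r}")
        try:
            records.append((float(overlap), float(global_), flag))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric identity") from exc
    return records
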