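"""End-to-end workflow: read -> filter -> map -> cluster -> summarize -> render.

The pipeline is configured from a YAML file (see :class:`PipelineConfig`)
and is deterministic given (inputs, config, seed); reruns are
byte-identical except for the manifest timestamp.  Each stage logs one
structured line with its record counts in/out.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml
from Bio import SeqIO

from . import __version__
from .clustering import DEFAULT_MIN_CORE_OVERLAP, Cluster, build_clusters
from .errors import ConfigError, MappkitError
from .heatmap_render import HeatmapStyle, render_heatmap
from .identification_filter import FilterConfig, apply_filters, compute_qvalues
from .mapped_io import write_mapped_table
from .panel_summary import PanelSummary, panel_report, write_report_bundle
from .peptide_mapping import MappedPeptide, map_records
from .psm_io import PSMRecord, read_psm_table
from .sequence_model import TherapeuticMolecule, load_therapeutic
from .synthetic_data import SimulatedPanel, SimulationConfig, simulate_panel

logger = logging.getLogger("mappkit.pipeline")


@dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 0
    therapeutic_fasta: Path | None = None
    regions: Path | None = None
    background_fasta: Path | None = None
    psm_tables: list[Path] = field(default_factory=list)
    simulation: SimulationConfig | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_core_overlap: int = DEFAULT_MIN_CORE_OVERLAP
    match_mode: str = "exact"
    style: HeatmapStyle = field(default_factory=HeatmapStyle)

    def __post_init__(self):
        if self.simulation is None:
            if self.therapeutic_fasta is None or self.regions is None:
                raise ConfigError(
                    "therapeutic_fasta and regions are required unless a "
                    "simulation section is given"
                )
            for path in [self.therapeutic_fasta, self.regions, self.background_fasta,
                         *self.psm_tables]:
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"input path does not exist: {path}")
            if not self.psm_tables:
                raise ConfigError("no PSM tables configured")
        if self.match_mode not in ("exact", "il_equivalent"):
            raise ConfigError(f"unknown match_mode {self.match_mode!r}")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Parse the YAML pipeline configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a mapping")
    base = path.parent

    def _path(key: str) -> Path | None:
        value = raw.get(key)
        return None if value is None else (base / value)

    sim = None
    if "simulation" in raw:
        sim_raw = dict(raw["simulation"] or {})
        sim_raw.setdefault("seed", raw.get("seed", 0))
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_raw) - known
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        for tuple_key in ("analysts", "days", "hc_cdrs", "lc_cdrs", "core_positions"):
            if tuple_key in sim_raw and sim_raw[tuple_key] is not None:
                sim_raw[tuple_key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in sim_raw[tuple_key]
                )
        sim = SimulationConfig(**sim_raw)

    filter_cfg = FilterConfig(**(raw.get("filter") or {}))
    style_raw = raw.get("style") or {}
    known_style = {f.name for f in dataclasses.fields(HeatmapStyle)}
    unknown_style = set(style_raw) - known_style
    if unknown_style:
        raise ConfigError(f"unknown style keys: {sorted(unknown_style)}")
    style = HeatmapStyle(**style_raw)

    clustering_raw = raw.get("clustering") or {}
    psm_tables = [base / p for p in raw.get("psm_tables") or []]
    if raw.get("output_dir") is None:
        raise ConfigError("output_dir is required")

    try:
        return PipelineConfig(
            output_dir=base / raw["output_dir"],
            seed=int(raw.get("seed", 0)),
            therapeutic_fasta=_path("therapeutic_fasta"),
            regions=_path("regions"),
            background_fasta=_path("background_fasta"),
            psm_tables=psm_tables,
            simulation=sim,
            filter=filter_cfg,
            min_core_overlap=int(clustering_raw.get("min_core_overlap", DEFAULT_MIN_CORE_OVERLAP)),
            match_mode=raw.get("match_mode", "exact"),
            style=style,
        )
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def read_background_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class RunResult:
    molecule: TherapeuticMolecule
    accepted: list[PSMRecord]
    mapped: list[MappedPeptide]
    clusters: list[Cluster]
    summary: PanelSummary
    output_paths: dict[str, Path]
    panel: SimulatedPanel | None = None


def _config_hash(config: PipelineConfig) -> str:
    def _default(obj: Any):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, Path):
            return str(obj)
        return str(obj)

    payload = json.dumps(dataclasses.asdict(config), default=_default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _file_checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full workflow and write the report bundle + heat maps."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- stage: read ------------------------------------------------------
    panel: SimulatedPanel | None = None
    if config.simulation is not None:
        panel = simulate_panel(config.simulation)
        molecule = panel.molecule
        background = panel.background_proteome
        tables = {sid: panel.samples[sid] for sid in sorted(panel.samples)}
    else:
        molecule = load_therapeutic(config.therapeutic_fasta, config.regions)
        background = (
            read_background_fasta(config.background_fasta)
            if config.background_fasta
            else {}
        )
        tables = {}
        for table_path in config.psm_tables:
            records = read_psm_table(table_path)
            for rec in records:
                tables.setdefault(rec.sample_id, []).append(rec)
    n_raw = sum(len(v) for v in tables.values())
    logger.info("stage=read samples=%d records_in=%d", len(tables), n_raw)

    # --- stage: filter (q-values estimated per sample/run) ---------------
    accepted: list[PSMRecord] = []
    for sid in sorted(tables):
        records = tables[sid]
        qvalues = compute_qvalues(records)
        accepted.extend(apply_filters(records, config.filter, qvalues))
    logger.info("stage=filter records_in=%d records_out=%d", n_raw, len(accepted))

    # --- stage: map -------------------------------------------------------
    mapped = map_records(accepted, molecule, background, config.match_mode)
    paths["mapped"] = outdir / "mapped.tsv"
    write_mapped_table(mapped, paths["mapped"])
    logger.info("stage=map records_in=%d placements_out=%d", len(accepted), len(mapped))

    # --- stage: cluster ---------------------------------------------------
    clusters = build_clusters(mapped, config.min_core_overlap)
    logger.info("stage=cluster placements_in=%d clusters_out=%d", len(mapped), len(clusters))

    # --- stage: summarize -------------------------------------------------
    summary = panel_report(
        molecule.name, accepted, mapped, clusters,
        min_core_overlap=config.min_core_overlap,
    )
    paths.update(write_report_bundle(summary, outdir))
    logger.info("stage=summarize samples=%d clusters=%d", len(summary.samples), len(clusters))

    # --- stage: render ----------------------------------------------------
    by_sample: dict[str, list[MappedPeptide]] = {}
    for mp in mapped:
        by_sample.setdefault(mp.sample_id, []).append(mp)
    svg_dir = outdir / "heatmaps"
    svg_dir.mkdir(exist_ok=True)
    for sid in sorted(by_sample):
        svg = render_heatmap(molecule, {sid: by_sample[sid]}, config.style)
        svg_path = svg_dir / f"{sid}.svg"
        svg_path.write_text(svg)
        paths[f"heatmap:{sid}"] = svg_path
    logger.info("stage=render heatmaps_out=%d", len(by_sample))

    # --- manifest ---------------------------------------------------------
    input_checksums = {}
    if config.simulation is None:
        for p in [config.therapeutic_fasta, config.regions, config.background_fasta,
                  *config.psm_tables]:
            if p is not None:
                input_checksums[str(p)] = _file_checksum(Path(p))
    manifest = {
        "version": __version__,
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "input_checksums": input_checksums,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunResult(
        molecule=molecule,
        accepted=accepted,
        mapped=mapped,
        clusters=clusters,
        summary=summary,
        output_paths=paths,
        panel=panel,
    )
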