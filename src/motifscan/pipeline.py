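"""Configuration-driven orchestration of the scan stages.

The config is a strict YAML document (unknown keys rejected, all problems
reported at once) holding the paths, spans and the numeric parameters of
the analysis: the 5.0 Å model-contact cutoff, the 4.5 Å MD cutoff, the
fragment tiling (initial length 5, step 5), and the hotspot rule. Stages
run in dependency order (fragments -> manifest -> contacts -> consensus)
and every table is written with a provenance header echoing the full
configuration hash, package version and seed, so reruns with an unchanged
config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consensus import (
    accumulate_runs,
    consensus_to_long_frame,
    detect_hotspots,
    hotspots_to_frame,
)
from .errors import ConfigError, RunError
from .fragment_scan import (
    BaitDomain,
    RunEntry,
    ScanConfig,
    build_manifest,
    enumerate_fragments,
    manifest_to_frame,
    read_manifest,
)
from .model_contacts import (
    contacts_to_frame,
    interchain_contacts,
    load_structure,
    remap_contacts,
    select_top_model,
)
from .sequences import Span, locate_unique_residue, parse_fasta

logger = logging.getLogger(__name__)

STAGES = ("fragments", "manifest", "contacts", "consensus")

_SCHEMA = {
    "sequences": str,
    "prey_id": str,
    "bait_id": str,
    "tail_span": list,
    "bait_domains": dict,
    "scan": dict,
    "cutoffs": dict,
    "hotspot": dict,
    "run_dirs": str,
    "output": str,
    "bait_chain": str,
    "prey_chain": str,
    "seed": int,
}
_SCAN_KEYS = {"init_len", "step", "anchors"}
_CUTOFF_KEYS = {"model_contact", "md_contact", "hbond_distance", "hbond_angle"}
_HOTSPOT_KEYS = {"threshold", "min_size"}


@dataclass
class PipelineConfig:
    """Validated pipeline parameters."""

    sequences: Path
    prey_id: str
    tail_span: Span
    bait_domains: list[BaitDomain]
    run_dirs: Path
    output: Path
    bait_id: str | None = None
    init_len: int = 5
    step: int = 5
    anchors: tuple = ("start", "middle", "end")
    model_contact_cutoff: float = 5.0
    md_contact_cutoff: float = 4.5
    hbond_distance: float = 3.5
    hbond_angle: float = 150.0
    hotspot_threshold: float = 0.5
    hotspot_min_size: int = 3
    bait_chain: str = "A"
    prey_chain: str = "B"
    seed: int = 0

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            tail_span=self.tail_span,
            init_len=self.init_len,
            step=self.step,
            anchors=tuple(self.anchors),
        )

    def digest(self) -> str:
        payload = {k: str(v) for k, v in sorted(vars(self).items())}
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML pipeline config, listing all failures."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    problems: list[str] = []
    for key in raw:
        if key not in _SCHEMA:
            problems.append(f"unknown key {key!r}")
    for key in ("sequences", "prey_id", "tail_span", "bait_domains", "run_dirs", "output"):
        if key not in raw:
            problems.append(f"missing required key {key!r}")
    for sub, allowed in (("scan", _SCAN_KEYS), ("cutoffs", _CUTOFF_KEYS), ("hotspot", _HOTSPOT_KEYS)):
        for key in raw.get(sub, {}) or {}:
            if key not in allowed:
                problems.append(f"unknown key {sub}.{key}")
    cutoffs = raw.get("cutoffs", {}) or {}
    for key, value in cutoffs.items():
        if not isinstance(value, (int, float)) or value <= 0:
            problems.append(f"cutoffs.{key} must be a positive number")
    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))

    scan = raw.get("scan", {}) or {}
    hotspot = raw.get("hotspot", {}) or {}
    base = path.parent
    config = PipelineConfig(
        sequences=(base / raw["sequences"]).resolve(),
        prey_id=raw["prey_id"],
        bait_id=raw.get("bait_id"),
        tail_span=Span(*raw["tail_span"]),
        bait_domains=[
            BaitDomain(name, Span(*span)) for name, span in raw["bait_domains"].items()
        ],
        run_dirs=(base / raw["run_dirs"]).resolve(),
        output=(base / raw["output"]).resolve(),
        init_len=int(scan.get("init_len", 5)),
        step=int(scan.get("step", 5)),
        anchors=tuple(scan.get("anchors", ("start", "middle", "end"))),
        model_contact_cutoff=float(cutoffs.get("model_contact", 5.0)),
        md_contact_cutoff=float(cutoffs.get("md_contact", 4.5)),
        hbond_distance=float(cutoffs.get("hbond_distance", 3.5)),
        hbond_angle=float(cutoffs.get("hbond_angle", 150.0)),
        hotspot_threshold=float(hotspot.get("threshold", 0.5)),
        hotspot_min_size=int(hotspot.get("min_size", 3)),
        bait_chain=raw.get("bait_chain", "A"),
        prey_chain=raw.get("prey_chain", "B"),
        seed=int(raw.get("seed", 0)),
    )
    # spans must fit the named sequences
    records = {r.id: r for r in parse_fasta(config.sequences)}
    if config.prey_id not in records:
        raise ConfigError(f"prey sequence {config.prey_id!r} not in {config.sequences}")
    if not records[config.prey_id].span.contains_span(config.tail_span):
        raise ConfigError("tail_span outside the prey sequence")
    if config.bait_id is not None:
        if config.bait_id not in records:
            raise ConfigError(f"bait sequence {config.bait_id!r} not in {config.sequences}")
        for dom in config.bait_domains:
            if not records[config.bait_id].span.contains_span(dom.span):
                raise ConfigError(f"bait domain {dom.name} outside the bait sequence")
    return config


def provenance_header(config: PipelineConfig) -> str:
    return (
        f"# motifscan {__version__}\n"
        f"# config_digest: {config.digest()}\n"
        f"# seed: {config.seed}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, stages: tuple = STAGES) -> dict[str, Path]:
    """Run the requested stages in dependency order; returns artifacts."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    out = config.output
    artifacts: dict[str, Path] = {}
    manifest: list[RunEntry] | None = None

    def timed(stage):
        logger.info("stage %s starting", stage)
        return time.perf_counter()

    if "fragments" in stages or "manifest" in stages:
        t0 = timed("fragments")
        fragments = enumerate_fragments(config.scan_config())
        logger.info("fragments: %d in %.2fs", len(fragments), time.perf_counter() - t0)

    if "manifest" in stages:
        t0 = timed("manifest")
        manifest = build_manifest(fragments, config.bait_domains)
        path = out / "manifest.tsv"
        _write_table(manifest_to_frame(manifest), path, config)
        artifacts["manifest"] = path
        logger.info("manifest: %d runs in %.2fs", len(manifest), time.perf_counter() - t0)

    if "contacts" in stages:
        t0 = timed("contacts")
        if manifest is None:
            mpath = out / "manifest.tsv"
            if not mpath.exists():
                raise RunError("contacts stage needs a manifest; run the manifest stage first")
            manifest = read_manifest(mpath, tail_start=config.tail_span.start)
        if not config.run_dirs.exists() or not any(config.run_dirs.iterdir()):
            raise RunError(f"no prediction runs found under {config.run_dirs}")
        rows = []
        self_contacts = []
        for entry in manifest:
            run_dir = config.run_dirs / entry.run_id
            if not run_dir.exists():
                raise RunError(f"run directory missing for {entry.run_id}")
            model = load_structure(
                select_top_model(run_dir), config.bait_chain, config.prey_chain
            )
            local = interchain_contacts(model, cutoff=config.model_contact_cutoff)
            self_contacts.append((entry, remap_contacts(local, entry.fragment, entry.bait)))
            rows.append((entry.run_id, local))
        path = out / "contacts.tsv"
        _write_table(contacts_to_frame(rows), path, config)
        artifacts["contacts"] = path
        artifacts["_contact_sets"] = self_contacts  # in-memory handoff
        logger.info("contacts: %d runs in %.2fs", len(manifest), time.perf_counter() - t0)

    if "consensus" in stages:
        t0 = timed("consensus")
        contact_sets = artifacts.get("_contact_sets")
        if contact_sets is None:
            raise RunError("consensus stage needs contacts; run the contacts stage first")
        matrices = accumulate_runs(contact_sets)
        hotspot_frames = []
        for bait_name, matrix in sorted(matrices.items()):
            path = out / f"consensus_{bait_name}.tsv"
            _write_table(consensus_to_long_frame(matrix), path, config)
            artifacts[f"consensus_{bait_name}"] = path
            hotspot_frames.append(
                hotspots_to_frame(
                    detect_hotspots(
                        matrix,
                        freq_threshold=config.hotspot_threshold,
                        min_size=config.hotspot_min_size,
                    )
                )
            )
        path = out / "hotspots.tsv"
        non_empty = [f for f in hotspot_frames if not f.empty]
        merged = (
            pd.concat(non_empty, ignore_index=True) if non_empty else hotspot_frames[0]
        )
        _write_table(merged, path, config)
        artifacts["hotspots"] = path
        logger.info("consensus: %d matrices in %.2fs", len(matrices), time.perf_counter() - t0)

    artifacts.pop("_contact_sets", None)
    return artifacts


def locate_motif_residue(config: PipelineConfig, letter: str = "W") -> int:
    """Global index of the unique motif residue in the configured tail."""
    records = {r.id: r for r in parse_fasta(config.sequences)}
    return locate_unique_residue(records[config.prey_id], config.tail_span, letter)
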