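"""End-to-end pipeline driver: simulate → register → basecall → identify →
analytics, with a reproducibility manifest.

The run manifest echoes the full configuration, the flow schedule, reference
checksums and per-stage record counts — enough to reproduce a run
bit-exactly from the same package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analytics import accuracy_report, extension_traces, stop_pause_stats
from .basecall import assign_spots, call_reads, filter_reads
from .chemistry import ReferenceSet
from .identify import ScoringScheme, default_byproduct_reference, flag_byproducts, identify_reads
from .io import read_fasta, write_fasta, write_fastq, write_spots
from .register import anchors_from_spots, correct_run
from .simulate import RunConfig, make_barcode_library, simulate_run

logger = logging.getLogger("smsbs")

__all__ = ["RunManifest", "load_config", "run_pipeline"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    schedule: dict
    reference_checksum: str
    record_counts: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _checksum(refs: ReferenceSet) -> str:
    h = hashlib.md5()
    for name, seq in refs.items():
        h.update(f">{name}\n{seq}\n".encode())
    return h.hexdigest()


DEFAULT_CONFIG: dict = {
    "run": {},  # RunConfig fields
    "references": {"n": 30, "length": 25, "seed": 1, "min_pairwise_hamming": 8},
    "register": {"window_px": 8, "marker_fraction": 0.10},
    "basecall": {"tolerance_px": 1, "min_len": 5, "cleave_fail_quads": 1},
    "identify": {"threshold": 0.01, "flag_byproducts": False},
}


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration, merged over defaults.

    Unknown sections or keys fail fast with a precise message.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: top level must be a mapping")
    config = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in raw.items():
        if section not in config:
            raise ValueError(
                f"config {path}: unknown section {section!r} "
                f"(expected one of {sorted(config)})"
            )
        if not isinstance(values, dict):
            raise ValueError(f"config {path}: section {section!r} must be a mapping")
        known = (
            set(RunConfig.__dataclass_fields__)
            if section == "run"
            else set(DEFAULT_CONFIG[section])
        )
        for key in values:
            if key not in known:
                raise ValueError(
                    f"config {path}: unknown key {section}.{key} "
                    f"(expected one of {sorted(known)})"
                )
        config[section].update(values)
    return config


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> RunManifest:
    """Run the full pipeline per ``config``, writing outputs under ``out_dir``.

    Outputs: references.fasta, spots.tsv, corrected_spots.tsv, drift.tsv,
    reads.fastq (kept reads), counts.tsv, report.json, manifest.json.
    Fixed seed ⇒ bit-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_cfg = dict(config.get("run", {}))
    if seed is not None:
        run_cfg["seed"] = int(seed)
    rc = RunConfig.from_dict(run_cfg)

    ref_cfg = config.get("references", DEFAULT_CONFIG["references"])
    if "fasta" in ref_cfg:
        refs = read_fasta(ref_cfg["fasta"])
    else:
        refs = make_barcode_library(
            n=ref_cfg.get("n", 30),
            length=ref_cfg.get("length", 25),
            seed=ref_cfg.get("seed", 1),
            min_pairwise_hamming=ref_cfg.get("min_pairwise_hamming", 8),
        )
    write_fasta(refs, out / "references.fasta")

    logger.info("simulating run: %d FOVs x %d molecules", rc.n_fovs, rc.density)
    sim = simulate_run(rc, refs)
    write_spots(sim.spots, out / "spots.tsv")

    logger.info("drift correction (%d spots)", len(sim.spots))
    reg_cfg = config.get("register", DEFAULT_CONFIG["register"])
    anchors = anchors_from_spots(sim.spots)
    corrected, drift = correct_run(
        sim.spots,
        anchors,
        window_px=reg_cfg.get("window_px", 8),
        marker_fraction=reg_cfg.get("marker_fraction", 0.10),
    )
    write_spots(corrected, out / "corrected_spots.tsv")
    drift.to_csv(out / "drift.tsv", sep="\t", index=False)

    bc_cfg = config.get("basecall", DEFAULT_CONFIG["basecall"])
    assignments = assign_spots(corrected, anchors, bc_cfg.get("tolerance_px", 1))
    reads = call_reads(
        assignments, rc.schedule, anchors, bc_cfg.get("cleave_fail_quads", 1)
    )
    id_cfg = config.get("identify", DEFAULT_CONFIG["identify"])
    byp = (
        flag_byproducts(reads, default_byproduct_reference(), id_cfg.get("threshold", 0.01))
        if id_cfg.get("flag_byproducts", False)
        else None
    )
    kept, removed = filter_reads(reads, bc_cfg.get("min_len", 5), byp)
    write_fastq(kept, out / "reads.fastq")

    logger.info("identifying %d reads against %d references", len(kept), len(refs))
    results, counts = identify_reads(kept, refs, id_cfg.get("threshold", 0.01))
    counts.to_csv(out / "counts.tsv", sep="\t")

    traces = extension_traces(reads, rc.n_quads)
    sps = stop_pause_stats(traces)
    identified = [r for r in results if r.best_ref_id != "UNIDENTIFIED"]
    lengths = [r.length for r in kept]
    report = {
        "n_molecules": len(sim.molecules),
        "n_anchors": len(anchors),
        "n_reads": len(reads),
        "n_kept": len(kept),
        "n_removed": len(removed),
        "mean_read_length": float(np.mean(lengths)) if lengths else 0.0,
        "sd_read_length": float(np.std(lengths)) if lengths else 0.0,
        "n_identified": len(identified),
        "identification_efficiency": len(identified) / len(kept) if kept else 0.0,
        "stop_histogram": sps.stop_histogram.tolist(),
        "reached_last_fraction": sps.reached_last_fraction,
        "pause_frequency": sps.pause_frequency,
        "counts_per_fov_barcode": {
            str(fov): {str(b): int(c) for b, c in row.items() if c > 0}
            for fov, row in counts.iterrows()
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    manifest = RunManifest(
        config={**config, "run": rc.to_dict()},
        seed=rc.seed,
        schedule=rc.schedule.to_dict(),
        reference_checksum=_checksum(refs),
        record_counts={
            "references": len(refs),
            "spots": len(sim.spots),
            "anchors": len(anchors),
            "reads": len(reads),
            "kept_reads": len(kept),
            "identified_reads": len(identified),
        },
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
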