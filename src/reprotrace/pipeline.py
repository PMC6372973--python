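"""End-to-end pipeline: simulate every input, run every analysis stage.

The pipeline config is a nested mapping with one block per stage; unknown
keys anywhere are rejected before execution. A run writes all stage outputs
plus a manifest recording the config hash, seeds, package version and
per-output checksums, so identical (config, seed) pairs reproduce identical
checksums for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

from . import __version__, evaluation, io
from .errors import ConfigurationError, ReprotraceError
from .expression import transient_met_genes, venn_partition, enrich_terms
from .flow import detect_bimodality, mfi, positive_gate, quadrant_proportions
from .indels import calibrate, classify_frames, compare_populations, decompose
from .rng import spawn_seeds
from .screen import call_hits, control_stats, flag_sgrnas, hits_table
from .simulate import (
    ExpressionSimConfig,
    FlowSimConfig,
    ScreenSimConfig,
    TraceSimConfig,
    WellSimConfig,
    gen_annotation,
    gen_expression,
    gen_flow_events,
    gen_screen_dataset,
    gen_traces,
    gen_well_image,
)

log = logging.getLogger("reprotrace")

DEFAULT_CONFIG: dict[str, Any] = {
    "expression": {"n_genes": 2000, "noise_sd": 0.0, "enrichment_p_cutoff": 1.0e-3},
    "wells": {"noise_sd": 5.0},
    "flow": {"n_events": 10000},
    "screen": {"min_consistent": None},
    "traces": {"spectrum_day8": {0: 0.3, -1: 0.3, 1: 0.2, -3: 0.2},
               "spectrum_day18": {0: 0.1, -1: 0.45, 1: 0.3, -3: 0.15},
               "window": 10},
    "logging_level": "INFO",
}


def merge_config(user: Mapping[str, Any] | None) -> dict[str, Any]:
    """Overlay a user config on the defaults, rejecting unknown keys."""

    def merge(defaults: Mapping[str, Any], overlay: Mapping[str, Any], path: str) -> dict:
        out = dict(defaults)
        for key, val in overlay.items():
            if key not in defaults:
                raise ConfigurationError(f"unknown config key: {path}{key}")
            if isinstance(defaults[key], Mapping) and isinstance(val, Mapping) and key != "spectrum_day8" and key != "spectrum_day18":
                out[key] = merge(defaults[key], val, f"{path}{key}.")
            else:
                out[key] = val
        return out

    return merge(DEFAULT_CONFIG, user or {}, "")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: Mapping[str, Any] | None, seed: int, out_dir: str | Path) -> dict:
    """Execute simulate → analyze for every stage; return the run manifest."""
    cfg = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(["expression", "wells", "flow", "screen", "traces"], spawn_seeds(seed, 5)))
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        # --- expression ---------------------------------------------------
        stage = "expression"
        log.info("stage %s (seed %d)", stage, seeds[stage])
        ecfg = ExpressionSimConfig(
            n_genes=int(cfg["expression"]["n_genes"]),
            noise_sd=float(cfg["expression"]["noise_sd"]),
            seed=seeds[stage],
        )
        matrix, truth = gen_expression(ecfg)
        io.write_expression(matrix, out / "expression.tsv")
        hk, ker, esc = evaluation.derive_gene_sets(matrix)
        part = venn_partition(hk, ker, esc)
        transient = transient_met_genes(part, matrix)
        io.write_geneset(transient, out / "transient_met_genes.txt")
        ann = gen_annotation(truth, seed=seeds[stage])
        io.write_gmt(ann, out / "annotation.gmt")
        enr = enrich_terms(
            transient, matrix.genes, ann, p_cutoff=float(cfg["expression"]["enrichment_p_cutoff"])
        )
        io.write_results(
            {
                "venn_counts": part.counts,
                "n_transient": len(transient),
                "enriched_terms": enr[enr["reported"]]["term"].tolist(),
            },
            out / "gene_sets.json",
        )
        outputs["expression"] = out / "gene_sets.json"

        # --- wells --------------------------------------------------------
        stage = "wells"
        log.info("stage %s (seed %d)", stage, seeds[stage])
        wcfg = WellSimConfig(noise_sd=float(cfg["wells"]["noise_sd"]), seed=seeds[stage])
        images, _ = gen_well_image(wcfg)
        for ch, img in images.items():
            io.write_image(img, out / f"well_{ch}.tif")
        _, counts, _ = evaluation.quantify_simulated_well(wcfg)
        io.write_results({"colony_counts": counts}, out / "colony_counts.json")
        outputs["wells"] = out / "colony_counts.json"

        # --- flow ---------------------------------------------------------
        stage = "flow"
        log.info("stage %s (seed %d)", stage, seeds[stage])
        from .simulate import LogNormalComponent  # local alias for brevity
        import numpy as np

        fcfg = FlowSimConfig(
            channels={
                "TROP2": (
                    LogNormalComponent(np.log(150.0), 0.45, 0.5),
                    LogNormalComponent(np.log(4000.0), 0.45, 0.5),
                ),
                "SSEA1": (
                    LogNormalComponent(np.log(120.0), 0.45, 0.7),
                    LogNormalComponent(np.log(3000.0), 0.45, 0.3),
                ),
            },
            n_events=int(cfg["flow"]["n_events"]),
            seed=seeds[stage],
        )
        events, _ = gen_flow_events(fcfg)
        io.write_events(events, out / "events.csv")
        ctrl_cfg = FlowSimConfig(
            channels={
                "TROP2": (LogNormalComponent(np.log(150.0), 0.45, 1.0),),
                "SSEA1": (LogNormalComponent(np.log(120.0), 0.45, 1.0),),
            },
            n_events=int(cfg["flow"]["n_events"]),
            seed=seeds[stage] + 1,
        )
        control_events, _ = gen_flow_events(ctrl_cfg)
        gate_x = positive_gate(control_events, "TROP2")
        gate_y = positive_gate(control_events, "SSEA1")
        quad = quadrant_proportions(events, gate_x, gate_y)
        bim, valley = detect_bimodality(events, "TROP2")
        io.write_results(
            {
                "mfi_TROP2": mfi(events, "TROP2"),
                "quadrants": quad.as_dict(),
                "TROP2_bimodal": bool(bim),
                "TROP2_valley": valley,
            },
            out / "flow.json",
        )
        outputs["flow"] = out / "flow.json"

        # --- screen -------------------------------------------------------
        stage = "screen"
        log.info("stage %s (seed %d)", stage, seeds[stage])
        scfg = ScreenSimConfig(seed=seeds[stage])
        dataset = gen_screen_dataset(scfg)
        io.write_screen(dataset, out / "screen.csv")
        stats = control_stats(dataset)
        calls = call_hits(flag_sgrnas(dataset, stats), cfg["screen"]["min_consistent"])
        hits_table(calls).to_csv(out / "screen_calls.csv", index=False)
        outputs["screen"] = out / "screen_calls.csv"

        # --- traces -------------------------------------------------------
        stage = "traces"
        log.info("stage %s (seed %d)", stage, seeds[stage])
        window = int(cfg["traces"]["window"])
        summaries = {}
        for label in ("day8", "day18"):
            spectrum = {int(k): float(v) for k, v in cfg["traces"][f"spectrum_{label}"].items()}
            tcfg = TraceSimConfig(spectrum=spectrum, window=window, seed=seeds[stage])
            control, edited = gen_traces(tcfg)
            io.write_trace(control, out / f"trace_control_{label}.csv")
            io.write_trace(edited, out / f"trace_edited_{label}.csv")
            cal = calibrate(control, edited)
            spec = decompose(control, edited, window=window, calibration=cal)
            summaries[label] = classify_frames(spec)
        comp = compare_populations(summaries["day8"], summaries["day18"])
        io.write_results(
            {
                "frame_fractions_day8": summaries["day8"].fractions,
                "frame_fractions_day18": summaries["day18"].fractions,
                "enrichment_ratio_day18_over_day8": comp.ratios,
            },
            out / "indels.json",
        )
        outputs["traces"] = out / "indels.json"
    except ReprotraceError as exc:
        raise ReprotraceError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": seeds,
        "config_hash": _config_hash(cfg),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "checksums": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    io.write_results(manifest, out / "manifest.json")
    return manifest
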