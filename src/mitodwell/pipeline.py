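"""Configuration-driven pipeline stages behind the command-line interface.

Each stage reads and writes plain interchange formats (CSV tables, TIFF
stacks, YAML configs) so stages can be rerun and diffed independently; every
run writes a machine-readable JSON log recording the parameters, the seed and
the record counts in and out of each stage, which together make the run
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .enrichment import compare_constructs, enrichment_score, segment_masks
from .kinetics import (
    build_survival,
    extract_dwells,
    fit_biexponential,
    summarize_conditions,
    summarize_replicate,
)
from .localization import DetectionParams, localize_stack
from .spikein import compute_scaling, normalize_counts
from .synthetic_data import (
    CellImageConfig,
    KineticConfig,
    MovieConfig,
    SpikeInSimConfig,
    simulate_cell_image,
    simulate_dwell_times,
    simulate_movie,
    simulate_spikein_counts,
)
from .tracking import TrackingParams, link, tracks_to_dataframe

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def check_keys(block: dict, allowed: set[str], context: str) -> None:
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise ConfigError(f"unknown config keys in {context}: {unknown}")


def write_run_log(out_dir: Path, stage: str, params: dict, counts: dict) -> None:
    log = {"stage": stage, "parameters": params, "counts": counts}
    path = out_dir / f"run_log_{stage}.json"
    path.write_text(json.dumps(log, indent=2, default=str))


# ---------------------------------------------------------------------------


def run_simulate(cfg: dict, out_dir: Path, seed: int) -> dict:
    """Generate the synthetic inputs named in the ``simulate`` config block."""
    check_keys(cfg, {"dwells", "movie", "cells", "spikein"}, "simulate")
    counts: dict = {}
    rng = np.random.default_rng(seed)

    for name, block in (cfg.get("dwells") or {}).items():
        check_keys(block, {"frac_fast", "k_fast", "k_slow", "k_bleach", "frame_interval",
                           "n_frames", "n"}, f"simulate.dwells.{name}")
        n = int(block.pop("n", 5000))
        kin = KineticConfig(seed=int(rng.integers(2**31)), **block)
        dwells = simulate_dwell_times(kin, n)
        dwells.to_csv(out_dir / f"dwells_{name}.csv", index=False)
        counts[f"dwells_{name}"] = len(dwells)

    if "movie" in cfg and cfg["movie"] is not None:
        block = dict(cfg["movie"])
        kin_block = block.pop("kinetic", {})
        check_keys(block, {"width", "height", "pixel_size", "psf_sigma", "background_mean",
                           "background_sd", "spot_amplitude", "diffusion_free",
                           "p_detect_free", "n_free", "edge_margin"}, "simulate.movie")
        kin = KineticConfig(seed=int(rng.integers(2**31)), **kin_block)
        mov = MovieConfig(kinetic=kin, **block)
        stack, truth = simulate_movie(mov)
        mio.write_stack(out_dir / "movie.tif", stack)
        mio.write_ground_truth(out_dir / "ground_truth.csv", truth)
        truth.intervals.to_csv(out_dir / "ground_truth_intervals.csv", index=False)
        counts["movie_frames"] = stack.shape[0]
        counts["movie_molecules"] = len(truth.intervals)

    if "cells" in cfg and cfg["cells"] is not None:
        rows = []
        for i, block in enumerate(cfg["cells"]):
            block = dict(block)
            check_keys(block, {"ratio", "construct", "replicate", "n_cells", "noise_sd"},
                       f"simulate.cells[{i}]")
            for c in range(int(block.get("n_cells", 1))):
                img_cfg = CellImageConfig(
                    chromatin_to_cell_ratio=float(block["ratio"]),
                    noise_sd=float(block.get("noise_sd", 10.0)),
                    seed=int(rng.integers(2**31)),
                )
                image, _, true_score = simulate_cell_image(img_cfg)
                path = out_dir / f"cell_{block.get('construct', 'c')}_{block.get('replicate', 'r')}_{c}.tif"
                mio.write_stack(path, image)
                rows.append({"path": path.name, "construct": block.get("construct", "c"),
                             "replicate_id": str(block.get("replicate", "r")),
                             "cell_id": f"cell{c}", "true_score": true_score})
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out_dir / "cells_manifest.csv", index=False)
        counts["cells"] = len(manifest)

    if "spikein" in cfg and cfg["spikein"] is not None:
        block = dict(cfg["spikein"])
        check_keys(block, {"samples", "total_reads", "constant", "deterministic"},
                   "simulate.spikein")
        samples = tuple((s["name"], s["condition"], float(s["fly_fraction"]))
                        for s in block.pop("samples"))
        sim = SpikeInSimConfig(samples=samples, seed=int(rng.integers(2**31)), **block)
        table = simulate_spikein_counts(sim)
        table.to_csv(out_dir / "spikein_counts.csv", index=False)
        counts["spikein_samples"] = len(table)

    write_run_log(out_dir, "simulate", {"seed": seed, "config": cfg}, counts)
    return counts


def run_localize(movie_path: Path, out_dir: Path, params: dict | None = None,
                 calibration: dict | None = None) -> pd.DataFrame:
    params = params or {}
    check_keys(params, {"loc_error", "psf_sigma", "deflation_loops", "window"}, "localize")
    calibration = calibration or {}
    check_keys(calibration, {"frame_interval", "pixel_size", "exposure"}, "calibration")
    stack = mio.read_stack(movie_path, **calibration)
    det = DetectionParams(**params)
    loc = localize_stack(stack, det)
    loc.to_csv(out_dir / "localizations.csv", index=False)
    write_run_log(out_dir, "localize",
                  {"movie": str(movie_path), **asdict(det), **calibration},
                  {"frames": stack.n_frames, "localizations": len(loc)})
    return loc


def run_track(loc: pd.DataFrame, out_dir: Path, params: dict | None = None,
              frame_interval: float = 0.2) -> pd.DataFrame:
    params = params or {}
    check_keys(params, {"d_max", "max_gaps", "max_competitors", "radius_factor"}, "track")
    trk = TrackingParams(**params)
    tracks = link(loc, trk, frame_interval)
    df = tracks_to_dataframe(tracks)
    df.to_csv(out_dir / "tracks.csv", index=False)
    write_run_log(out_dir, "track", {**asdict(trk), "frame_interval": frame_interval},
                  {"localizations": len(loc), "tracks": len(tracks)})
    return df


def run_kinetics(cfg: dict, out_dir: Path, in_dir: Path) -> pd.DataFrame:
    """Survival → two-exponential fit → bleach correction from dwell CSVs.

    Expects ``dwells_<condition>_<replicate>.csv`` and
    ``dwells_h2b_<replicate>.csv`` style inputs named in the config:
    ``replicates`` maps replicate ids to {condition: csv, ...} plus an
    ``h2b`` entry per replicate.
    """
    check_keys(cfg, {"replicates", "min_dwells"}, "kinetics")
    summaries = []
    curve_rows = []
    for rep, files in cfg["replicates"].items():
        check_keys(files, {"interphase", "mitosis", "h2b"}, f"kinetics.replicates.{rep}")
        h2b_durations = pd.read_csv(in_dir / files["h2b"])["duration"].to_numpy()
        h2b_fit = fit_biexponential(build_survival(h2b_durations))
        for condition in ("interphase", "mitosis"):
            if condition not in files:
                continue
            durations = pd.read_csv(in_dir / files[condition])["duration"].to_numpy()
            summary = summarize_replicate(durations, h2b_fit, replicate_id=str(rep),
                                          condition=condition)
            summaries.append(summary)
            curve = build_survival(durations)
            for t, s in zip(curve.times, curve.survival):
                curve_rows.append({"replicate_id": rep, "condition": condition,
                                   "time_s": t, "survival": s})
    df = pd.DataFrame([asdict(s) for s in summaries])
    df.to_csv(out_dir / "kinetic_summaries.csv", index=False)
    pd.DataFrame(curve_rows).to_csv(out_dir / "survival_curves.csv", index=False)
    if {"interphase", "mitosis"} <= set(df["condition"]):
        comp = summarize_conditions(summaries)
        comp.table.to_csv(out_dir / "condition_comparison.csv")
        extra = {"ratio_residence": comp.ratio_residence, "ratio_t1pct": comp.ratio_t1pct,
                 "p_value": comp.p_value}
        (out_dir / "condition_ratios.json").write_text(json.dumps(extra, indent=2))
    write_run_log(out_dir, "kinetics", cfg, {"replicate_summaries": len(df)})
    return df


def run_enrich(manifest: pd.DataFrame, out_dir: Path, in_dir: Path,
               background=None) -> pd.DataFrame:
    """Score every cell image listed in a manifest CSV (path, construct,
    replicate_id, cell_id); two-channel TIFFs with channel 0 = H2B."""
    rows = []
    for _, rec in manifest.iterrows():
        image = mio.read_stack(in_dir / rec["path"]).frames
        h2b, halo = image[0], image[1]
        masks = segment_masks(h2b, halo)
        score = enrichment_score(halo, masks, background=background,
                                 cell_id=str(rec.get("cell_id", "")),
                                 construct=str(rec.get("construct", "")),
                                 replicate_id=str(rec.get("replicate_id", "")))
        rows.append(asdict(score))
    scores = pd.DataFrame(rows)
    scores.to_csv(out_dir / "enrichment_scores.csv", index=False)
    if scores["construct"].nunique() >= 2:
        comparison = compare_constructs(scores)
        comparison["summary"].to_csv(out_dir / "enrichment_summary.csv")
        comparison["replicate_means"].to_csv(out_dir / "enrichment_replicate_means.csv",
                                             index=False)
    write_run_log(out_dir, "enrich", {"background": background}, {"cells": len(scores)})
    return scores


def run_spikein(counts: pd.DataFrame, out_dir: Path, constant: int = 100_000,
                reference: str | None = None,
                site_counts: pd.DataFrame | None = None) -> pd.DataFrame:
    table = compute_scaling(counts, constant=constant, reference=reference)
    table.to_csv(out_dir / "spikein_scaling.csv", index=False)
    counts_out = {"samples": len(table)}
    if site_counts is not None:
        normalized = normalize_counts(site_counts, table)
        normalized.to_csv(out_dir / "normalized_counts.csv", index=False)
        counts_out["sites"] = len(normalized)
    write_run_log(out_dir, "spikein", {"constant": constant, "reference": reference}, counts_out)
    return table


DEFAULT_ALL_CONFIG: dict = {
    "simulate": {
        "dwells": {
            "interphase_r1": {"k_slow": 0.059, "k_bleach": 0.05, "n": 3000},
            "mitosis_r1": {"k_slow": 0.138, "k_bleach": 0.05, "n": 3000},
            "h2b_r1": {"frac_fast": 0.3, "k_slow": 1e-4, "k_bleach": 0.05, "n": 3000},
        },
        "cells": [
            {"ratio": 2.0, "construct": "coating", "replicate": "r1", "n_cells": 2},
            {"ratio": 0.7, "construct": "excluded", "replicate": "r1", "n_cells": 2},
        ],
        "spikein": {
            "samples": [
                {"name": "async", "condition": "asynchronous", "fly_fraction": 0.01},
                {"name": "mitotic", "condition": "mitotic", "fly_fraction": 0.005},
            ],
        },
    },
    "kinetics": {
        "replicates": {
            "r1": {"interphase": "dwells_interphase_r1.csv",
                   "mitosis": "dwells_mitosis_r1.csv",
                   "h2b": "dwells_h2b_r1.csv"},
        },
    },
}


def run_all(cfg: dict | None, out_dir: Path, seed: int) -> None:
    """Small end-to-end synthetic run emitting every CSV artifact."""
    cfg = cfg or DEFAULT_ALL_CONFIG
    check_keys(cfg, {"simulate", "kinetics", "enrich", "spikein"}, "all")
    out_dir.mkdir(parents=True, exist_ok=True)
    run_simulate(cfg.get("simulate", {}), out_dir, seed)
    if "kinetics" in cfg:
        run_kinetics(cfg["kinetics"], out_dir, out_dir)
    manifest_path = out_dir / "cells_manifest.csv"
    if manifest_path.exists():
        run_enrich(pd.read_csv(manifest_path), out_dir, out_dir)
    counts_path = out_dir / "spikein_counts.csv"
    if counts_path.exists():
        run_spikein(pd.read_csv(counts_path), out_dir,
                    constant=int((cfg.get("simulate", {}).get("spikein") or {})
                                 .get("constant", 100_000)))
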