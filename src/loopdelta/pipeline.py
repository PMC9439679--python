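"""End-to-end orchestration: simulate -> balance -> compartments -> domains
-> loops -> integrate, with a run manifest and reproducible outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compartments import classify_switches, compartment_track, reference_from_peaks
from .domains import aggregate_tad, call_boundaries, insulation_score, tads_from_boundaries
from .errors import ConfigError
from .integrate import (
    annotate_promoter_loops,
    classify_genes,
    pileup_dots,
    promoter_peak_overlap,
)
from .loopcall import (
    LoopCallConfig,
    add_qvalues,
    call_loops,
    classify_differential,
    fit_distance_prior,
    loop_pvalues,
)
from .matrixio import balance, coarsen, read_genes, read_matrix, read_narrowpeak, write_bedgraph, write_bedpe
from .simulate import SimConfig, simulate_truth, write_truth

log = logging.getLogger("loopdelta")

STAGES = ("simulate", "balance", "compartments", "domains", "loops", "integrate")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "loopdelta_run",
    "stages": list(STAGES),
    "simulate": {},  # SimConfig overrides
    "balance": {"max_iter": 200, "tol": 1e-5, "mad_max": 5.0},
    "compartments": {"resolution_bp": 100_000, "delta_threshold": 1.5},
    "domains": {"window_bp": 100_000, "min_prominence": 0.2},
    "loops": {
        "resolution_bp": 10_000,
        "min_distance_bp": 30_000,
        "max_distance_bp": 5_000_000,
        "q_call": 0.01,
        "q_loose": 0.1,
    },
    "integrate": {
        "promoter_window_bp": 2_000,
        "fdr": 0.05,
        "logfc": 0.58,
        "stable_logfc": 0.38,
        "pad_bins": 10,
        "n_shifts": 10,
    },
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge YAML config over the defaults profile; unknown keys rejected."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        user = {**user, **overrides}
    for key, value in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown configuration key: {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            known = set(cfg[key]) if key != "simulate" else {
                f.name for f in dataclasses.fields(SimConfig)
            }
            unknown = set(value) - known
            if unknown:
                raise ConfigError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    enabled = list(config["stages"])
    for stage in enabled:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage: {stage!r}")
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: config[k] for k in STAGES if k in config},
        "stages": {},
        "files": {},
    }

    sim_cfg = SimConfig(**{**config["simulate"], "seed": seed})
    truth = None
    matrices: dict[str, object] = {}
    state: dict = {}

    def record(stage: str, outputs: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "status": "completed",
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        for key, p in outputs.items():
            manifest["files"][str(p)] = _sha256(Path(p))
        log.info("stage %s completed (%d outputs)", stage, len(outputs))

    try:
        if "simulate" in enabled:
            log.info("stage simulate: planting truth (seed=%d)", seed)
            truth = simulate_truth(sim_cfg)
            paths = write_truth(truth, sim_cfg, outdir / "sim")
            record("simulate", paths)
            for cond in ("A", "B"):
                matrices[cond] = read_matrix(
                    paths[f"bins_{cond}"], paths[f"matrix_{cond}"]
                )
            state["genes_path"] = paths["genes"]
            state["peaks_path"] = paths["peaks"]

        if "balance" in enabled:
            bcfg = config["balance"]
            outputs = {}
            for cond, mat in matrices.items():
                matrices[cond] = balance(
                    mat,
                    max_iter=int(bcfg["max_iter"]),
                    tol=float(bcfg["tol"]),
                    mad_max=float(bcfg["mad_max"]),
                )
                wpath = outdir / f"weights_{cond}.tsv"
                pd.DataFrame({"bin_id": np.arange(len(matrices[cond].weights)),
                              "weight": matrices[cond].weights}).to_csv(
                    wpath, sep="\t", index=False, float_format="%.8g")
                outputs[f"weights_{cond}"] = wpath
            record("balance", outputs)

        if "compartments" in enabled:
            ccfg = config["compartments"]
            factor = int(ccfg["resolution_bp"]) // matrices["A"].resolution_bp
            peaks = read_narrowpeak(state["peaks_path"])
            tracks = {}
            for cond in ("A", "B"):
                coarse = balance(coarsen(matrices[cond], factor))
                ref = reference_from_peaks(coarse.bins, peaks)
                tracks[cond] = compartment_track(coarse, ref)
            switches = classify_switches(
                tracks["A"], tracks["B"], float(ccfg["delta_threshold"])
            )
            spath = outdir / "switches.tsv"
            switches.to_csv(spath, sep="\t", index=False, float_format="%.6g")
            outputs = {"switches": spath}
            for cond in ("A", "B"):
                evp = outdir / f"ev1_{cond}.bedgraph"
                write_bedgraph(tracks[cond].to_bedgraph_frame(), evp)
                outputs[f"ev1_{cond}"] = evp
            record("compartments", outputs)
            state["switches"] = switches

        if "domains" in enabled:
            dcfg = config["domains"]
            outputs = {}
            for cond in ("A", "B"):
                track = insulation_score(matrices[cond], int(dcfg["window_bp"]))
                ipath = outdir / f"insulation_{cond}.bedgraph"
                write_bedgraph(track.to_bedgraph_frame(), ipath)
                outputs[f"insulation_{cond}"] = ipath
                bnds = call_boundaries(track, float(dcfg["min_prominence"]))
                tset = tads_from_boundaries(bnds, track.bins)
                tpath = outdir / f"tads_{cond}.bed"
                tset.intervals.to_csv(tpath, sep="\t", header=False, index=False)
                outputs[f"tads_{cond}"] = tpath
                state[f"tads_{cond}"] = tset
                if len(tset):
                    grid, _ = aggregate_tad(matrices[cond], tset)
                    gpath = outdir / f"aggregate_tad_{cond}.tsv"
                    np.savetxt(gpath, grid, delimiter="\t", fmt="%.6g")
                    outputs[f"aggregate_tad_{cond}"] = gpath
                    try:
                        from .plots import save_heatmap

                        save_heatmap(
                            grid, outdir / f"aggregate_tad_{cond}.png",
                            f"aggregate TAD ({cond})",
                        )
                    except Exception:  # plots never block headless runs
                        log.warning("aggregate-TAD plot failed", exc_info=True)
            record("domains", outputs)

        if "loops" in enabled:
            lcfg = LoopCallConfig(
                resolution_bp=int(config["loops"]["resolution_bp"]),
                min_distance_bp=int(config["loops"]["min_distance_bp"]),
                max_distance_bp=int(config["loops"]["max_distance_bp"]),
                q_call=float(config["loops"]["q_call"]),
                q_loose=float(config["loops"]["q_loose"]),
            )
            tables = {}
            outputs = {}
            for cond in ("A", "B"):
                prior = fit_distance_prior(matrices[cond], lcfg)
                tables[cond] = add_qvalues(loop_pvalues(matrices[cond], prior, lcfg))
                loops = call_loops(tables[cond], matrices[cond], lcfg.q_call)
                lpath = outdir / f"loops_{cond}.bedpe"
                write_bedpe(loops, lpath)
                outputs[f"loops_{cond}"] = lpath
                state[f"called_{cond}"] = loops
            classified = classify_differential(
                tables["A"], tables["B"], lcfg,
                matrices["A"].bins, matrices["B"].bins,
            )
            cpath = outdir / "loops_classified.tsv"
            classified.to_csv(cpath, sep="\t", index=False, float_format="%.6g")
            outputs["classified"] = cpath
            record("loops", outputs)
            state["classified"] = classified

        if "integrate" in enabled:
            icfg = config["integrate"]
            genes = classify_genes(
                read_genes(state["genes_path"]),
                fdr=float(icfg["fdr"]),
                logfc=float(icfg["logfc"]),
                stable_logfc=float(icfg["stable_logfc"]),
            )
            peaks = read_narrowpeak(state["peaks_path"])
            genes, occupancy = promoter_peak_overlap(
                genes, peaks, int(icfg["promoter_window_bp"])
            )
            outputs = {}
            gpath = outdir / "genes_classified.tsv"
            genes.to_csv(gpath, sep="\t", index=False, float_format="%.6g")
            outputs["genes"] = gpath
            opath = outdir / "promoter_occupancy.tsv"
            occupancy.to_csv(opath, sep="\t", index=False, float_format="%.6g")
            outputs["occupancy"] = opath
            for cond in ("A", "B"):
                called = state.get(f"called_{cond}", [])
                ann = annotate_promoter_loops(
                    called, genes, int(icfg["promoter_window_bp"])
                )
                apath = outdir / f"promoter_loops_{cond}.tsv"
                ann.to_csv(apath, sep="\t", index=False, float_format="%.6g")
                outputs[f"promoter_loops_{cond}"] = apath
                if called and cond in matrices:
                    try:
                        res = pileup_dots(
                            matrices[cond], called,
                            pad_bins=int(icfg["pad_bins"]),
                            n_shifts=int(icfg["n_shifts"]),
                            seed=seed,
                        )
                        ppath = outdir / f"pileup_loops_{cond}.tsv"
                        np.savetxt(ppath, res.mean_map, delimiter="\t", fmt="%.6g")
                        outputs[f"pileup_loops_{cond}"] = ppath
                        from .plots import save_pileup

                        save_pileup(
                            res, outdir / f"pileup_loops_{cond}.png",
                            f"called loops ({cond})",
                        )
                    except Exception:  # plots never block headless runs
                        log.warning("loop pile-up failed", exc_info=True)
            record("integrate", outputs)

    except Exception:
        # abort downstream stages; flag everything not completed as stale
        for stage in enabled:
            if stage not in manifest["stages"]:
                manifest["stages"][stage] = {"status": "failed-or-skipped"}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
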