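"""End-to-end pipelines: configuration, logging and orchestration.

Two pipelines mirror the two experiments:

* confocal: simulate (or load) an ALEX photon stream -> background ->
  DCBS burst search -> E/S + stoichiometry filter -> same-molecule curve ->
  RASP kinetic fit (and optionally BVA) -> kinetics report.
* TIRF: simulate (or read) traces -> QC -> HMM segmentation -> dwell lists ->
  photobleach distribution -> corrected length regression -> rate report.

Both are deterministic given the seed in the configuration; every report
embeds a hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional

import numpy as np
import yaml

from . import bursts as bc
from . import bva as bva_mod
from . import dwells as dw
from . import rasp as rp
from . import synthetic as syn
from . import tirf as tf

__all__ = [
    "PipelineConfig",
    "run_confocal_pipeline",
    "run_tirf_pipeline",
    "config_hash",
]

log = logging.getLogger("plugdyn")


DEFAULTS = {
    "seed": 0,
    "out_dir": None,
    "input": None,                  # photon-HDF5 path or traces TSV; None -> simulate
    "model": {},                    # TwoStateModel overrides
    "confocal": {},                 # ConfocalSimConfig overrides
    "tirf": {},                     # TirfSimConfig overrides
    "burst_search": {"m": 10, "F": 6.0, "background_window_s": 10.0},
    "filter": {"s_min": 0.25, "s_max": 0.75, "min_size": 30},
    "rasp": {"e1_range": [0.0, 0.25], "t_lo": 5e-4, "t_hi": 0.08,
             "n_intervals": 8, "eps": 1.0, "n_boot": 200},
    "bva": {"enabled": False, "n_photons": 5, "alpha": 0.001},
    "qc": {"s_window": [0.25, 0.75], "anticorr_threshold": -0.3},
    "dwell_fit": {"pb_truncation_s": 10.0, "resolution_frames": 2},
    "metadata": {},                 # ATP, temperature, SecB, substrate length
}


class PipelineConfig(dict):
    """Validated pipeline configuration (mapping with defaults filled in)."""

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.resolve(yaml.safe_load(fh) or {})

    @classmethod
    def resolve(cls, user: Optional[dict] = None) -> "PipelineConfig":
        cfg = json.loads(json.dumps(DEFAULTS))
        for key, val in (user or {}).items():
            if key not in cfg:
                raise KeyError(f"unknown configuration field: {key}")
            if isinstance(cfg[key], dict) and isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
        if cfg["seed"] is None:
            raise ValueError("every pipeline run needs an explicit seed")
        return cls(cfg)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self), fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _maybe_write(obj, path):
    if path is None:
        return
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    if hasattr(obj, "to_tsv"):
        obj.to_tsv(path)
    elif hasattr(obj, "to_csv"):
        obj.to_csv(path, sep="\t", index=False)


def run_confocal_pipeline(cfg: PipelineConfig) -> dict:
    """Confocal pipeline: photon stream -> bursts -> RASP (+ optional BVA)."""
    cfg = PipelineConfig.resolve(cfg)
    seed = int(cfg["seed"])
    out = cfg["out_dir"]
    log.info("confocal pipeline: config %s", config_hash(cfg))
    if cfg["input"]:
        if not os.path.exists(cfg["input"]):
            raise FileNotFoundError(f"input: no such file {cfg['input']}")
        stream = bc.read_photon_stream(cfg["input"])
    else:
        model = syn.TwoStateModel(**cfg["model"])
        sim = syn.ConfocalSimConfig(seed=seed, **cfg["confocal"])
        log.info("simulating %.0f s photon stream", sim.duration)
        stream = syn.simulate_confocal_photons(model, sim)
    bg = bc.estimate_background(stream, cfg["burst_search"]["background_window_s"])
    burst_set = bc.search_bursts_dcbs(stream, bg, m=cfg["burst_search"]["m"],
                                      F=cfg["burst_search"]["F"])
    burst_set = bc.compute_burst_es(burst_set)
    burst_set = bc.filter_bursts(burst_set, **cfg["filter"])
    log.info("%d bursts after filtering", len(burst_set))
    if out:
        _maybe_write(burst_set, os.path.join(out, "bursts.tsv"))
    curve = rp.burst_autocorrelation(burst_set)
    r = cfg["rasp"]
    intervals = rp.log_intervals(r["t_lo"], r["t_hi"], r["n_intervals"])
    fit = rp.fit_recurrence_kinetics(
        burst_set, tuple(r["e1_range"]), intervals, curve,
        eps=r["eps"], background=bg, n_boot=r["n_boot"], seed=seed + 1)
    report = {
        "config_hash": config_hash(cfg),
        "n_bursts": len(burst_set),
        "p_same_80ms": float(curve.p_same_at(0.08)),
        "lambda_per_s": fit.lam,
        "rho_open_eq": fit.rho_a_eq,
        "tau_open_ms": fit.tau_open_s * 1e3,
        "tau_close_ms": fit.tau_close_s * 1e3,
        "ci": {k: list(v) for k, v in fit.ci.items()},
        "flags": fit.flags,
    }
    if cfg["bva"]["enabled"]:
        part = bva_mod.subdivide_bursts(burst_set, cfg["bva"]["n_photons"])
        bcfg = bva_mod.BVAConfig(n_photons=cfg["bva"]["n_photons"],
                                 alpha=cfg["bva"]["alpha"], seed=seed + 2)
        res = bva_mod.mc_confidence(part, bcfg)
        report["bva_dynamic_bins"] = int(res.per_bin["dynamic"].sum())
    if out:
        os.makedirs(out, exist_ok=True)
        with open(os.path.join(out, "rasp.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def run_tirf_pipeline(cfg: PipelineConfig) -> dict:
    """TIRF pipeline: traces -> QC -> segmentation -> corrected rate fit."""
    cfg = PipelineConfig.resolve(cfg)
    seed = int(cfg["seed"])
    out = cfg["out_dir"]
    log.info("tirf pipeline: config %s", config_hash(cfg))
    if cfg["input"]:
        if not os.path.exists(cfg["input"]):
            raise FileNotFoundError(f"input: no such file {cfg['input']}")
        traces = tf.read_traces(cfg["input"])
    else:
        sim = syn.TirfSimConfig(seed=seed, **cfg["tirf"])
        log.info("simulating %d traces x %d lengths", sim.n_traces,
                 len(sim.lengths))
        frames, _ = syn.simulate_tirf_traces(sim)
        traces = tf.TirfTraceSet(frames)
    qc = tf.qc_traces(traces, s_window=tuple(cfg["qc"]["s_window"]),
                      anticorr_threshold=cfg["qc"]["anticorr_threshold"])
    log.info("%d traces pass QC (%d excluded)", len(qc.kept), len(qc.excluded))
    segs = [tf.segment_states_hmm(tr) for tr in qc.kept]
    dwell_df = tf.extract_dwells(segs)
    responsive = sum(1 for s in segs if s.responsive)
    report = {"config_hash": config_hash(cfg),
              "n_traces_qc": len(qc.kept),
              "n_responsive": responsive}
    if responsive == 0 or len(dwell_df) == 0:
        report["error"] = "no responsive traces"
        report["exit_code"] = 1
        return report
    bleach_times = np.array(
        [tr.time_s[tr.bleach_frame] for tr in qc.kept
         if tr.bleach_frame is not None])
    censoring = np.array([tr.time_s[-1] for tr in qc.kept
                          if tr.bleach_frame is None])
    dcfg = cfg["dwell_fit"]
    pb = (dw.photobleach_pdf(bleach_times, censoring_times=censoring,
                             truncation_s=dcfg["pb_truncation_s"])
          if len(bleach_times) >= 1 else None)
    open_dwells = dwell_df[dwell_df["state"] == "open"]
    closed_dwells = dwell_df[(dwell_df["state"] == "closed")
                             & (~dwell_df["censored"].astype(bool))]["duration_s"]
    frame = float(np.median(np.diff(
        traces.frames[traces.frames["trace_id"] == traces.trace_ids[0]]["time_s"])))
    if out:
        _maybe_write(dwell_df, os.path.join(out, "dwells.tsv"))
    fit = dw.fit_length_dependence(
        open_dwells, pb, closed_dwells=closed_dwells,
        resolution_s=dcfg["resolution_frames"] * frame)
    report.update({
        "n_open_dwells": int(len(open_dwells)),
        "photobleach_mean_s": None if pb is None else pb.mean_s,
        "slope_s_per_aa": fit.slope_s_per_aa,
        "slope_se": fit.slope_se,
        "intercept_s": fit.intercept_s,
        "intercept_se": fit.intercept_se,
        "rate_aa_per_s": fit.rate_aa_per_s,
        "rate_se": fit.rate_se,
        "n_per_length": {str(k): int(v) for k, v in fit.n_per_length.items()},
        "exit_code": 0,
    })
    if out:
        os.makedirs(out, exist_ok=True)
        with open(os.path.join(out, "rate.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    return report
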