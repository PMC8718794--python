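"""End-to-end orchestration: synthesize -> simulate/fit/analyze -> report.

A :class:`PipelineConfig` selects stages and carries per-stage parameter
blocks plus a master seed; each stage derives its own seed by hashing the
master seed with the stage name, so adding or removing stages never
perturbs the randomness of the others. Every produced file is recorded in
a manifest (path, SHA-256, stage seed); identical configs reproduce
identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crusim, dge, kinetics, synth, traces
from .exceptions import InvalidParameterError

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "ALL_STAGES"]

log = logging.getLogger("alternans.pipeline")

ALL_STAGES = ("titration", "stopped_flow", "transients", "counts", "simulation")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, stable across stage sets."""
    digest = zlib.crc32(f"{master_seed}:{stage}".encode())
    return int(digest & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    """Stage selection plus per-stage parameter overrides."""

    stages: tuple = ALL_STAGES
    master_seed: int = 0
    out_dir: str = "pipeline_out"
    titration: dict = field(default_factory=dict)  # kwargs to gen_titration per construct
    stopped_flow: dict = field(default_factory=dict)
    transients: dict = field(default_factory=dict)  # kwargs to gen_transient_train
    counts: dict = field(default_factory=dict)  # kwargs to gen_counts
    simulation: dict = field(default_factory=dict)  # pcl_grid, n_seeds, scale
    deg_alpha: float = 0.05
    fractions: tuple = (0.30, 0.80)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise InvalidParameterError(f"unknown stages: {sorted(unknown)}")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["fractions"] = list(d["fractions"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest: dict, stage: str, path: Path) -> None:
    manifest["files"][str(path.name)] = {
        "stage": stage,
        "sha256": _sha256(path),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected stages and return the JSON-ready manifest.

    Stage failures halt their dependents but the manifest collected so far
    is still written (and returned) with the error recorded.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": config.master_seed,
        "stages": list(config.stages),
        "stage_seeds": {s: stage_seed(config.master_seed, s) for s in config.stages},
        "files": {},
        "errors": {},
    }

    for stage in config.stages:
        seed = stage_seed(config.master_seed, stage)
        log.info("stage %s (seed %d)", stage, seed)
        try:
            if stage == "titration":
                _stage_titration(config, seed, out, manifest)
            elif stage == "stopped_flow":
                _stage_stopped_flow(config, seed, out, manifest)
            elif stage == "transients":
                _stage_transients(config, seed, out, manifest)
            elif stage == "counts":
                _stage_counts(config, seed, out, manifest)
            elif stage == "simulation":
                _stage_simulation(config, seed, out, manifest)
        except Exception as exc:  # halt dependents, keep partial manifest
            log.exception("stage %s failed", stage)
            manifest["errors"][stage] = f"{type(exc).__name__}: {exc}"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_titration(cfg, seed, out, manifest):
    kw = dict(cfg.titration)
    kd_wt = kw.pop("kd_wt", 3.4)
    kd_variant = kw.pop("kd_variant", kd_wt / 1.7)
    fits = {}
    for i, (label, kd) in enumerate((("WT", kd_wt), ("variant", kd_variant))):
        data = synth.gen_titration(true_kd=kd, seed=seed + i, construct_label=label, **kw)
        path = out / f"titration_{label}.csv"
        data.to_csv(path)
        _record(manifest, "titration", path)
        fits[label] = kinetics.fit_hill(data)
    comp = kinetics.compare_parameters(
        fits["WT"].per_replicate_kd, fits["variant"].per_replicate_kd
    )
    report = {
        label: {"kd": f.kd, "kd_sem": f.kd_sem, "n": len(f.per_replicate_kd)}
        for label, f in fits.items()
    }
    report["comparison"] = dataclasses.asdict(comp)
    path = out / "titration_fits.json"
    path.write_text(json.dumps(report, indent=1))
    _record(manifest, "titration", path)


def _stage_stopped_flow(cfg, seed, out, manifest):
    kw = dict(cfg.stopped_flow)
    koff_wt = kw.pop("koff_wt", 120.0)
    koff_variant = kw.pop("koff_variant", koff_wt / 1.2)
    n_wt = kw.pop("n_traces_wt", 9)
    n_var = kw.pop("n_traces_variant", 11)
    fits = {}
    for i, (label, k, n) in enumerate(
        (("WT", koff_wt, n_wt), ("variant", koff_variant, n_var))
    ):
        data = synth.gen_stopped_flow(
            true_koff=k, n_traces=n, seed=seed + i, construct_label=label, **kw
        )
        path = out / f"stopped_flow_{label}.csv"
        data.to_csv(path)
        _record(manifest, "stopped_flow", path)
        fits[label] = kinetics.fit_exp_decay(data, average_first=False)
    report = {
        label: {"koff": f.koff, "koff_sem": f.koff_sem, "n": f.n_fits}
        for label, f in fits.items()
    }
    report["ratio_wt_over_variant"] = fits["WT"].koff / fits["variant"].koff
    path = out / "stopped_flow_fits.json"
    path.write_text(json.dumps(report, indent=1))
    _record(manifest, "stopped_flow", path)


def _stage_transients(cfg, seed, out, manifest):
    kw = dict(cfg.transients)
    rates = kw.pop("rates_bpm", (55, 65, 75, 100))
    rows = []
    for i, rate in enumerate(rates):
        trace = synth.gen_transient_train(rate=rate, seed=seed + i, **kw)
        path = out / f"transients_{rate}bpm.csv"
        trace.to_csv(path)
        _record(manifest, "transients", path)
        _record(manifest, "transients", path.with_suffix(".stim.csv"))
        norm = traces.normalize_dff(trace)
        table = traces.beat_metrics_table(norm, fractions=cfg.fractions)
        table["rate_bpm"] = rate
        rows.append(table)
        report = traces.entrainment_check(norm, "calcium")
        rpath = out / f"rhythm_{rate}bpm.json"
        rpath.write_text(json.dumps(dataclasses.asdict(report), indent=1))
        _record(manifest, "transients", rpath)
    metrics = pd.concat(rows)
    path = out / "beat_metrics.csv"
    metrics.to_csv(path)
    _record(manifest, "transients", path)


def _stage_counts(cfg, seed, out, manifest):
    kw = dict(cfg.counts)
    matrix = synth.gen_counts(seed=seed, **kw)
    path = out / "counts.csv"
    matrix.to_csv(path)
    _record(manifest, "counts", path)
    normalized = dge.normalize_counts(matrix)
    table = dge.call_degs(normalized, matrix.groups, alpha=cfg.deg_alpha)
    tpath = out / "deg_table.csv"
    table.to_csv(tpath)
    _record(manifest, "counts", tpath)
    spath = out / "deg_summary.json"
    spath.write_text(json.dumps(dge.deg_summary(table), indent=1))
    _record(manifest, "counts", spath)


def _stage_simulation(cfg, seed, out, manifest):
    kw = dict(cfg.simulation)
    pcl_grid = kw.pop("pcl_grid", list(crusim.DEFAULT_PCL_GRID))
    n_seeds = int(kw.pop("n_seeds", 5))
    scale = kw.pop("scale", "test")
    seeds = [seed + i for i in range(n_seeds)]
    rows = []
    for variant in ("control", "reduced_koff"):
        params = crusim.make_default_params(variant, scale=scale)
        result = crusim.scan_pcl(params, pcl_grid, seeds=seeds)
        for pcl, (p1, p2), flag in zip(
            result.pcl_values, result.peaks, result.alternans_flags
        ):
            rows.append(
                {
                    "variant": variant,
                    "pcl_ms": pcl,
                    "peak_1": p1,
                    "peak_2": p2,
                    "alternans": bool(flag),
                }
            )
    path = out / "bifurcation.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    _record(manifest, "simulation", path)
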