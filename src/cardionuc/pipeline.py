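"""End-to-end pipeline orchestration: simulate -> analyze -> fit -> report.

A run is described by a ``RunConfig`` (stage list + per-stage parameter
blocks + one global seed).  Each stage derives its own seed from the global
one by a stable hash, so stages are independently reproducible, and every
output file is recorded in a manifest with its SHA-256 hash.  Reports are
per-figure-style summary tables (CSV/Markdown) built from the manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling, io, morpho, regression
from ._util import derive_seed
from .cohort import CohortSpec, generate_cohort
from .errors import ConfigError
from .presets import generate_image_cohort, trace_preset
from .traces import generate_traces

log = logging.getLogger("cardionuc.pipeline")

KNOWN_STAGES = ("simulate_traces", "coupling", "simulate_cohort", "biphasic",
                "simulate_images", "morphometrics", "mech_scenarios")


@dataclass
class RunConfig:
    stages: list
    out_dir: str
    seed: int = 0
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text())
        return cls(stages=raw["stages"], out_dir=raw.get("out_dir", "pipeline_out"),
                   seed=int(raw.get("seed", 0)), params=raw.get("params", {}),
                   log_level=raw.get("log_level", "INFO"))

    def validate(self):
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ConfigError(f"unknown pipeline stages: {unknown}")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigError("duplicate stages in config")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Deterministic stages are bit-identical on rerun with the same config.
    A stage failure aborts the run (the partial manifest is still written
    with ``status: failed``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest = {"seed": config.seed, "stages": {}, "status": "ok"}

    try:
        for stage in config.stages:
            seed = derive_seed(config.seed, stage)
            params = config.params.get(stage, {})
            log.info("stage=%s seed=%d params=%s", stage, seed, params)
            files = _run_stage(stage, seed, params, out, manifest)
            manifest["stages"][stage] = {
                "seed": seed, "params": params,
                "files": {name: _sha256(p) for name, p in files.items()},
                "paths": {name: str(p) for name, p in files.items()},
            }
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        io.write_json(manifest, out / "manifest.json")
        raise

    manifest.pop("_images", None)
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _run_stage(stage, seed, params, out: Path, manifest):
    if stage == "simulate_traces":
        genotypes = params.get("genotypes", ["WT_mouse", "N195K"])
        n_cells = params.get("n_cells", 10)
        noise = params.get("noise_sd", 0.01)
        traces = []
        for g in genotypes:
            p = trace_preset(g, noise_sd=noise, seed=derive_seed(seed, g))
            traces.extend(generate_traces(p, n_cells))
        path = out / "traces.csv"
        io.write_traces_csv(traces, path)
        return {"traces": path}

    if stage == "coupling":
        traces = io.read_traces_csv(out / "traces.csv")
        results = [coupling.analyze_trace(t) for t in traces]
        metrics = coupling.results_frame(results)
        summary = coupling.summarize_group(results)
        p1 = out / "coupling_metrics.csv"
        p2 = out / "coupling_summary.csv"
        metrics.to_csv(p1, index=False, float_format="%.9g")
        summary.to_csv(p2, index=False, float_format="%.9g")
        return {"metrics": p1, "summary": p2}

    if stage == "simulate_cohort":
        spec = CohortSpec(seed=seed, **params)
        path = out / "cohort.csv"
        generate_cohort(spec).to_csv(path, index=False, float_format="%.9g")
        return {"cohort": path}

    if stage == "biphasic":
        df = pd.read_csv(out / "cohort.csv")
        fit = regression.piecewise_linear_fit(df, with_loess=True,
                                              span=params.get("span", 0.75))
        p1 = out / "biphasic_fit.json"
        io.write_json({
            "breakpoint": fit.breakpoint, "slope_below": fit.slope_below,
            "slope_above": fit.slope_above, "slope_p_below": fit.slope_p_below,
            "slope_p_above": fit.slope_p_above, "flat_above": fit.flat_above,
            "residual_sd": fit.residual_sd, "n_points": fit.n_points}, p1)
        p2 = out / "biphasic_curve.csv"
        pd.DataFrame({"x": fit.loess_curve.x, "loess": fit.loess_curve.fitted,
                      "loess_se": fit.loess_curve.se,
                      "piecewise": fit.predict(fit.loess_curve.x)}).to_csv(
            p2, index=False, float_format="%.9g")
        return {"fit": p1, "curve": p2}

    if stage == "simulate_images":
        preset = params.get("preset", "N195K")
        n = params.get("n_images", 20)
        rows = []
        for i, (channels, truth) in enumerate(
                generate_image_cohort(preset, n, seed=seed)):
            rows.append({"image_id": i, **truth.to_dict()})
        path = out / "image_truth.csv"
        pd.DataFrame(rows).drop(columns=["foci_centers"]).to_csv(
            path, index=False, float_format="%.9g")
        manifest.setdefault("_images", {})[preset] = (n, seed)
        return {"truth": path}

    if stage == "morphometrics":
        preset = params.get("preset", "N195K")
        n, seed_img = manifest.get("_images", {}).get(
            preset, (params.get("n_images", 20), derive_seed(seed, "images")))
        images = generate_image_cohort(preset, n, seed=seed_img)
        table, summary = morpho.score_cohort(
            images, mode=params.get("mode", "protrusion"), seed=seed)
        p1 = out / "morpho_table.csv"
        p2 = out / "morpho_summary.json"
        table.to_csv(p1, index=False, float_format="%.9g")
        io.write_json(summary, p2)
        return {"table": p1, "summary": p2}

    if stage == "mech_scenarios":
        from .mech import SCENARIOS, probe_stresses, run_scenario
        names = params.get("scenarios", list(SCENARIOS))
        rows = []
        for name in names:
            sol = run_scenario(name)
            rows.append({"scenario": name,
                         "aspect_ratio": sol.nuclear_aspect_ratio,
                         "volume_change_pct": sol.nuclear_volume_change,
                         **probe_stresses(sol)})
        path = out / "mech_summary.csv"
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
        return {"summary": path}

    raise ConfigError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------

REPORT_SECTIONS = {
    "strain_coupling": ("coupling", "coupling_summary.csv"),
    "biphasic_fit": ("biphasic", "biphasic_fit.json"),
    "morphometrics": ("morphometrics", "morpho_summary.json"),
    "mechanics": ("mech_scenarios", "mech_summary.csv"),
}


def report(manifest: dict, out_dir=None) -> str:
    """Markdown report with one summary table per completed analysis stage.

    Missing stages are listed as absent, not fatal.  Rerunning on the same
    manifest produces identical bytes.
    """
    lines = ["# Pipeline report", ""]
    for section, (stage, fname) in REPORT_SECTIONS.items():
        lines.append(f"## {section}")
        info = manifest["stages"].get(stage)
        if info is None:
            lines.append("_stage not run; section omitted_")
            lines.append("")
            continue
        path = None
        for p in info["paths"].values():
            if Path(p).name == fname:
                path = Path(p)
        if path is None or not path.exists():
            lines.append("_output missing_")
            lines.append("")
            continue
        if path.suffix == ".json":
            data = json.loads(path.read_text())
            lines.append("| key | value |")
            lines.append("|---|---|")
            for k in sorted(data):
                v = data[k]
                if isinstance(v, float):
                    v = f"{v:.6g}"
                lines.append(f"| {k} | {v} |")
        else:
            df = pd.read_csv(path)
            lines.append("| " + " | ".join(df.columns) + " |")
            lines.append("|" + "---|" * len(df.columns))
            for _, row in df.iterrows():
                cells = [f"{v:.6g}" if isinstance(v, float) else str(v)
                         for v in row]
                lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    text = "\n".join(lines)
    if out_dir is not None:
        (Path(out_dir) / "report.md").write_text(text)
    return text
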