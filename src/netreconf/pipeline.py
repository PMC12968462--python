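"""File-level pipeline orchestration with a JSON config and a manifest.

The pipeline is a pure function of (config, inputs): every run writes the
resolved config next to its outputs, stage outputs carry sha256 checksums in
``manifest.json``, and identical config + inputs give identical bytes.
Stages can be re-run individually from their predecessors' files via the
CLI subcommands.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netreconf.io import (
    AtlasLabels,
    read_atlas,
    read_coverage,
    read_phenotypes,
    read_series,
    write_atlas,
    write_series,
    write_table,
)
from netreconf.metrics import METRIC_NAMES
from netreconf.model import ReconfigurationModel
from netreconf.nulls import SurrogateSpec
from netreconf.windows import WindowSpec

log = logging.getLogger("netreconf")


@dataclass
class PipelineConfig:
    """Resolved run configuration; round-trips losslessly through JSON."""

    input_dir: str = ""
    output_dir: str = ""
    tr_seconds: float = 1.0
    window_seconds: float = 60.0
    step_seconds: float = 10.0
    n_communities: int = 8
    max_iterations: int = 1000
    promiscuity_denominator: int | None = None
    coverage_threshold: float = 0.30
    subject_fraction: float = 0.10
    null_runs: int = 0            # 0 disables the surrogate null stage
    null_mode: str = "average_series"
    phase_mode: str = "multivariate_common_phase"
    family_size: int | None = None
    seed: int = 0

    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_seconds, self.step_seconds)

    def null_spec(self) -> SurrogateSpec | None:
        if self.null_runs < 1:
            return None
        return SurrogateSpec(self.null_runs, self.null_mode, self.phase_mode, seed=self.seed)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_dir(cohort, out_dir, seed: int, params: dict | None = None) -> None:
    """Write a complete simulated input directory: series, atlas, coverage,
    phenotypes, ground-truth assignments, and a manifest with the seed."""
    os.makedirs(os.path.join(out_dir, "series"), exist_ok=True)
    for sid, s in cohort.series.items():
        write_series(s, os.path.join(out_dir, "series", f"{sid}.tsv"))
    write_atlas(cohort.atlas, os.path.join(out_dir, "atlas.tsv"))
    write_table(cohort.phenotypes, os.path.join(out_dir, "phenotypes.tsv"))
    region_ids = list(cohort.atlas.mapping)
    coverage = pd.DataFrame(1.0, index=list(cohort.series) or ["none"], columns=region_ids)
    coverage.index.name = "subject_id"
    write_table(coverage, os.path.join(out_dir, "coverage.tsv"))
    truth = {sid: {"labels": t.assignments.labels.tolist(),
                   "coupling": t.coupling, "seed": t.seed,
                   "events": [dataclasses.asdict(e) for e in t.events]}
             for sid, t in cohort.truths.items()}
    with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth, fh)
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump({"seed": seed, "n_subjects": len(cohort.series),
                   "params": params or {}}, fh, indent=2)


def load_inputs(config: PipelineConfig):
    d = config.input_dir
    series_dir = os.path.join(d, "series")
    if not os.path.isdir(series_dir):
        raise ValueError(f"missing series directory: {series_dir}")
    series = {}
    for name in sorted(os.listdir(series_dir)):
        if name.endswith(".tsv"):
            s = read_series(os.path.join(series_dir, name), config.tr_seconds)
            series[s.subject_id] = s
    atlas = read_atlas(os.path.join(d, "atlas.tsv"))
    cov_path = os.path.join(d, "coverage.tsv")
    coverage = read_coverage(cov_path) if os.path.exists(cov_path) else None
    ph_path = os.path.join(d, "phenotypes.tsv")
    phenotypes = read_phenotypes(ph_path) if os.path.exists(ph_path) else None
    return series, atlas, coverage, phenotypes


def run_pipeline(config: PipelineConfig):
    """Run every stage end-to-end and write all outputs under ``output_dir``."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    logging.basicConfig(filename=os.path.join(out, "pipeline.log"),
                        level=logging.INFO, force=True,
                        format="%(asctime)s %(levelname)s %(message)s")
    config.to_json(os.path.join(out, "config.json"))

    series, atlas, coverage, phenotypes = load_inputs(config)
    log.info("loaded %d subjects", len(series))
    model = ReconfigurationModel(
        series, atlas, phenotypes=phenotypes, coverage=coverage,
        window_spec=config.window_spec(), n_communities=config.n_communities,
        max_iterations=config.max_iterations,
        promiscuity_denominator=config.promiscuity_denominator,
        coverage_threshold=config.coverage_threshold,
        subject_fraction=config.subject_fraction)
    results = model.fit(null_spec=config.null_spec(), family_size=config.family_size)

    written = []
    adir = os.path.join(out, "assignments")
    mdir = os.path.join(out, "metrics")
    os.makedirs(adir, exist_ok=True)
    os.makedirs(mdir, exist_ok=True)
    for sid, am in results.assignments.items():
        p = os.path.join(adir, f"{sid}.tsv")
        write_table(am.to_dataframe(), p, subject=sid,
                    legend=am.label_legend(am.n_communities))
        written.append(p)
        trace = results.traces[sid]
        log.info("subject %s: iterations per window %s; converged %s", sid,
                 [t.n_iterations for t in trace], [t.converged for t in trace])
    tpath = os.path.join(out, "detection_traces.jsonl")
    with open(tpath, "w", encoding="utf-8") as fh:
        for sid, trace in results.traces.items():
            for w, t in enumerate(trace):
                fh.write(json.dumps({
                    "subject": sid, "window": w, "iterations": t.n_iterations,
                    "converged": t.converged, "stop_reason": t.stop_reason,
                    "steps": [[int(r), int(a), int(b), float(q)]
                              for r, a, b, q in t.steps]}) + "\n")
    written.append(tpath)
    for sid, rm in results.metrics.items():
        p = os.path.join(mdir, f"{sid}.tsv")
        write_table(rm.node, p, subject=sid)
        written.append(p)
    p = os.path.join(out, "summaries.tsv")
    write_table(results.summaries, p)
    written.append(p)
    if results.null_summaries is not None:
        p = os.path.join(out, "null_summaries.tsv")
        write_table(results.null_summaries.add_prefix("null_"), p,
                    null_mode=config.null_mode, null_runs=config.null_runs,
                    phase_mode=config.phase_mode)
        written.append(p)
    if results.correlations is not None:
        p = os.path.join(out, "correlations.tsv")
        write_table(results.correlations, p)
        written.append(p)
    if results.ancova is not None:
        p = os.path.join(out, "ancova.tsv")
        write_table(results.ancova, p)
        written.append(p)
    if results.null_adjusted is not None:
        p = os.path.join(out, "ancova_null_adjusted.tsv")
        write_table(results.null_adjusted, p)
        written.append(p)
    with open(os.path.join(out, "summary.txt"), "w", encoding="utf-8") as fh:
        fh.write(results.summary() + "\n")
    written.append(os.path.join(out, "summary.txt"))

    manifest = {os.path.relpath(p, out): _sha256(p) for p in written}
    with open(os.path.join(out, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("wrote %d outputs", len(written))
    return results
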