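"""File formats, run configuration and end-to-end orchestration.

Formats
-------
* recording: long-format CSV (``time_s, roi_id, roi_type, value`` with
  ``roi_type`` in {cell, background}) plus a JSON sidecar carrying the
  sampling interval, stimulus events, subject labels and simulator metadata;
* responses: TSV, one row per cell x stimulus with calibrated values;
* contrast results: JSON holding both levels (per-pair y, v and the pooled
  estimate, se, tau2, Q, z, p, k);
* DEG tables: TSV (``gene_id, log2fc, padj``, header required); gene sets:
  one gene id per line.

:func:`run_end_to_end` ties simulator -> trace processing -> twin-contrast
tests into one reproducible run that writes a manifest with a configuration
hash and per-file checksums; identical (config, seed) gives identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deg_overlap import DEGRecord, GeneSet
from .errors import ParseError
from .response_stats import OutlierConfig, TwinContrastResult, twin_contrast_test
from .synthetic_data import CohortDesign, TraceSimConfig, simulate_twin_cohort
from .trace_processing import (
    DenoiseConfig,
    ImagingRecording,
    ResponseWindows,
    StimulusEvent,
    process_recording,
)

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = ["subject_id", "pair_id", "role", "treatment", "roi_id",
                    "is_neuron", "agent", "dF_star", "iono_calibrated", "final"]


# ---------------------------------------------------------------------------
# recordings

def write_recording(rec: ImagingRecording, csv_path, json_path) -> None:
    """Write one recording as long-format CSV plus a JSON event/metadata sidecar."""
    t = rec.times()
    frames = []
    for roi_id, trace in rec.cell_traces.items():
        frames.append(pd.DataFrame({"time_s": t, "roi_id": roi_id,
                                    "roi_type": "cell", "value": trace}))
    for i, trace in enumerate(rec.background_traces):
        frames.append(pd.DataFrame({"time_s": t, "roi_id": f"bg_{i:02d}",
                                    "roi_type": "background", "value": trace}))
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    sidecar = {
        "sampling_interval": rec.sampling_interval,
        "subject_id": rec.subject_id,
        "pair_id": rec.pair_id,
        "role": rec.role,
        "treatment": rec.treatment,
        "events": [dataclasses.asdict(e) for e in rec.events],
        "cell_rois": list(rec.cell_traces.keys()),
        "background_rois": [f"bg_{i:02d}" for i in range(len(rec.background_traces))],
        "metadata": rec.metadata,
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=1))


def read_recording(csv_path, json_path) -> ImagingRecording:
    """Read a recording written by :func:`write_recording` (or a real export
    with the same columns). Round-trips the in-memory structure exactly."""
    try:
        sidecar = json.loads(Path(json_path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{json_path}: malformed event JSON: {exc}") from exc
    for key in ("sampling_interval", "events", "cell_rois", "background_rois"):
        if key not in sidecar:
            raise ParseError(f"{json_path}: sidecar missing required key {key!r}")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = {"time_s", "roi_id", "roi_type", "value"} - set(df.columns)
    if missing:
        raise ParseError(f"{csv_path}: missing required column(s) {sorted(missing)}")
    bad = set(df["roi_type"].unique()) - {"cell", "background"}
    if bad:
        raise ParseError(f"{csv_path}: unknown roi_type value(s) {sorted(bad)}; "
                         "expected 'cell' or 'background'")
    if not (df["roi_type"] == "background").any():
        raise ParseError(f"{csv_path}: no background ROI rows present")
    by_roi = {roi: grp.sort_values("time_s")["value"].to_numpy()
              for roi, grp in df.groupby("roi_id", sort=False)}
    try:
        cells = {roi: by_roi[roi] for roi in sidecar["cell_rois"]}
        backgrounds = [by_roi[roi] for roi in sidecar["background_rois"]]
    except KeyError as exc:
        raise ParseError(f"{csv_path}: sidecar names ROI {exc} absent from the CSV") from exc
    events = [StimulusEvent(**e) for e in sidecar["events"]]
    return ImagingRecording(
        sampling_interval=float(sidecar["sampling_interval"]),
        cell_traces=cells, background_traces=backgrounds, events=events,
        subject_id=sidecar.get("subject_id", ""), pair_id=sidecar.get("pair_id", ""),
        role=sidecar.get("role", ""), treatment=sidecar.get("treatment", ""),
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# responses and results

def write_responses(responses: pd.DataFrame, path) -> None:
    responses.to_csv(path, sep="\t", index=False)


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: responses table missing column(s) {sorted(missing)}")
    return df


def result_to_dict(res: TwinContrastResult) -> dict:
    return {
        "agent": res.agent,
        "treatment": res.treatment,
        "pairs": [{"pair_id": p.pair_id, "y": p.y, "v": p.v} for p in res.pairs],
        "pooled": {"estimate": res.pooled.pooled, "se": res.pooled.se,
                   "tau2": res.pooled.tau2, "Q": res.pooled.Q,
                   "z": res.pooled.z, "p": res.pooled.p, "k": res.pooled.k},
        "n_cells_used": res.n_cells_used,
        "n_outliers_removed": res.n_outliers_removed,
    }


def write_result(res: TwinContrastResult, path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(res), indent=1))


# ---------------------------------------------------------------------------
# DEG fixtures

def write_deg_table(records, path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, sep="\t", index=False)


def read_deg_table(path) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"gene_id", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: DEG table missing column(s) {sorted(missing)}")
    return [DEGRecord(gene_id=str(r.gene_id), log2fc=float(r.log2fc),
                      padj=float(r.padj)) for r in df.itertuples(index=False)]


def write_gene_set(gs: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gs.genes)) + "\n")


def read_gene_set(path, name: str | None = None) -> GeneSet:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return GeneSet.from_iterable(name or Path(path).stem, lines)


# ---------------------------------------------------------------------------
# run configuration and orchestration

@dataclass
class RunConfig:
    """Everything one end-to-end run depends on, nested per stage."""

    seed: int = 0
    design: CohortDesign = field(default_factory=CohortDesign)
    trace: TraceSimConfig = field(default_factory=TraceSimConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    windows: ResponseWindows = field(default_factory=ResponseWindows)
    outlier: OutlierConfig = field(default_factory=OutlierConfig)
    min_neuron_ratio: float = 0.1
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trace"]["stimulus_amplitudes"] = dict(d["trace"]["stimulus_amplitudes"])
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(json.dumps(self.to_dict())),
                              sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        design = dict(d.pop("design", {}))
        for key in ("treatment_labels", "effect_treatments"):
            if key in design:
                design[key] = tuple(design[key])
        trace = dict(d.pop("trace", {}))
        return cls(
            design=CohortDesign(**design),
            trace=TraceSimConfig(**trace),
            denoise=DenoiseConfig(**d.pop("denoise", {})),
            windows=ResponseWindows(**d.pop("windows", {})),
            outlier=OutlierConfig(**d.pop("outlier", {})),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ParseError(f"{path}: malformed YAML: {exc}") from exc
        return cls.from_dict(data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(cfg: RunConfig, out_dir) -> dict:
    """Simulate a twin cohort, process traces, test contrasts, write a manifest.

    Writes under ``out_dir``: ``recordings/`` (CSV + JSON per subject x
    treatment), ``responses.tsv``, ``results/<agent>_<treatment>.json`` for the
    target agonist in every treatment condition, and ``manifest.json`` with the
    configuration hash, seed, package version and per-file SHA-256 checksums.
    Returns the manifest.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    (out / "results").mkdir(parents=True, exist_ok=True)

    logger.info("simulating cohort: %d pairs x %d cells, seed %d",
                cfg.design.n_pairs, cfg.design.cells_per_subject, cfg.seed)
    cohort = simulate_twin_cohort(cfg.design, cfg.trace, cfg.seed)
    files: list[Path] = []
    tables = []
    for rec in cohort.recordings:
        stem = f"{rec.subject_id}_{rec.treatment}"
        csv_path = out / "recordings" / f"{stem}.csv"
        json_path = out / "recordings" / f"{stem}.json"
        write_recording(rec, csv_path, json_path)
        files += [csv_path, json_path]
        loaded = read_recording(csv_path, json_path)  # process what was written
        tables.append(process_recording(loaded, cfg.denoise, cfg.windows,
                                        cfg.min_neuron_ratio))
    responses = pd.concat(tables, ignore_index=True)
    resp_path = out / "responses.tsv"
    write_responses(responses, resp_path)
    files.append(resp_path)

    results = {}
    for treatment in cfg.design.treatment_labels:
        res = twin_contrast_test(responses, cfg.design.target_agent, treatment,
                                 outlier_cfg=cfg.outlier)
        logger.info("%s/%s: pooled=%.4f se=%.4f tau2=%.4g z=%.3f p=%.4g (k=%d)",
                    res.agent, treatment, res.pooled.pooled, res.pooled.se,
                    res.pooled.tau2, res.pooled.z, res.pooled.p, res.pooled.k)
        res_path = out / "results" / f"{cfg.design.target_agent}_{treatment}.json"
        write_result(res, res_path)
        files.append(res_path)
        results[treatment] = result_to_dict(res)

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "true_pair_effects": cohort.pair_effects,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        "results": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
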