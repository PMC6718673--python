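"""Synthetic calcium-imaging cohorts and DEG tables with known ground truth.

Raw recordings from discordant-twin iPSC studies are rarely public, so every
downstream stage here is exercised on simulated data whose generating truth is
stored alongside. Three generators:

* :func:`simulate_recording` — one subject/condition recording: per-ROI
  fluorescence with stimulus-locked transients (difference-of-exponentials
  kernel) on a noisy baseline, plus cell-free background ROIs. Non-neuronal
  cells respond to the ionomycin calibrator but not to KCl or the agonists.
* :func:`simulate_twin_cohort` / :func:`simulate_response_cohort` — a cohort of
  discordant monozygotic pairs in which the affected twin's expected calibrated
  response to a target agonist is shifted by a pair-level effect
  ``delta_i ~ Normal(delta, between_pair_sd^2)``, with independent cell-level
  noise. The trace-level variant embeds those responses into full recordings;
  the response-level variant emits the calibrated per-cell responses directly
  and is the tool for large Monte-Carlo studies (type-I error, bias, coverage).
* :func:`simulate_deg_tables` — a differential-expression table plus a
  sex-specific gene set and universe constructed so that exactly the configured
  numbers of genes pass the DEG filter and overlap the sex-specific set.

All generators are pure functions of (config, seed); no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .deg_overlap import DEGRecord, GeneSet
from .errors import ConfigError, SchedulingError
from .trace_processing import (
    AGENTS,
    CALIBRATED_AGENTS,
    ImagingRecording,
    ResponseWindows,
    StimulusEvent,
)


def _default_amplitudes() -> dict[str, float]:
    # Plausible raw dF* scale: the ionomycin transient dominates, KCl is a
    # strong depolarization, agonist responses are a fraction of KCl.
    return {"KCl": 1.0, "GABA": 0.5, "GluGlyNoMg": 0.6, "ionomycin": 2.0}


@dataclass(frozen=True)
class TraceSimConfig:
    """Parameters of one simulated recording.

    Units: seconds for times, arbitrary fluorescence units (a.u.) for levels
    and amplitudes. The default 0.5 s sampling interval (2 Hz) is a generic
    imaging rate, not a measured one. ``stimulus_amplitudes`` are the peak
    transient heights added at each event onset for responsive (neuronal)
    cells; ``outlier_fraction`` of cells get their agonist amplitudes
    multiplied by ``outlier_scale`` to emulate aberrant responders for the
    MAD filter to catch.
    """

    sampling_interval: float = 0.5
    duration: float = 400.0
    baseline_level: float = 1.0
    noise_sd: float = 0.02
    background_level: float = 0.2
    n_background_rois: int = 3
    transient_rise: float = 1.0
    transient_decay: float = 8.0
    stimulus_amplitudes: Mapping[str, float] = field(default_factory=_default_amplitudes)
    neuron_fraction: float = 0.8
    outlier_fraction: float = 0.0
    outlier_scale: float = 5.0
    n_cells: int = 50

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ConfigError("duration and sampling_interval must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for name in ("neuron_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if any(a < 0 for a in self.stimulus_amplitudes.values()):
            raise ConfigError("stimulus amplitudes must be >= 0")
        if not 0 < self.transient_rise < self.transient_decay:
            raise ConfigError("need 0 < transient_rise < transient_decay")
        if self.n_background_rois < 1 or self.n_cells < 1:
            raise ConfigError("need >= 1 background ROI and >= 1 cell")


@dataclass(frozen=True)
class CohortDesign:
    """Twin-cohort ground truth for the two-level random-effects model.

    ``true_pair_effect`` (delta) is the mean affected-minus-unaffected
    difference in the final calibrated response to ``target_agent``;
    ``between_pair_sd`` is the SD of the pair-level effects around delta
    (sqrt(tau^2)); ``within_subject_cell_sd`` the cell-level response SD.
    The effect is applied in the treatments listed in ``effect_treatments``
    (default: before treatment only, mirroring a drug that abolishes the
    difference).
    """

    n_pairs: int = 5
    cells_per_subject: int = 50
    true_pair_effect: float = 0.3
    between_pair_sd: float = 0.1
    within_subject_cell_sd: float = 0.15
    baseline_response: float = 0.5
    target_agent: str = "GABA"
    treatment_labels: tuple[str, ...] = ("pre", "post")
    effect_treatments: tuple[str, ...] = ("pre",)
    group_label: str = "TRS"

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if self.cells_per_subject < 2:
            raise ConfigError("cells_per_subject must be >= 2")
        if self.between_pair_sd < 0 or self.within_subject_cell_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.target_agent not in CALIBRATED_AGENTS:
            raise ConfigError(f"target_agent must be one of {CALIBRATED_AGENTS}")
        if not set(self.effect_treatments) <= set(self.treatment_labels):
            raise ConfigError("effect_treatments must be a subset of treatment_labels")


@dataclass(frozen=True)
class DEGSimConfig:
    """Construction parameters for a synthetic DEG table and gene sets.

    Defaults mirror the scale of a transcriptome-wide comparison: ~19.5k
    detectable genes, ~12% sex-specific, a 41-gene illness DEG list of which
    61% is sex-specific. ``effect_size_log2`` are (loc, scale) of the extra
    absolute log2 fold change beyond the filter cutoff for genes that pass.
    """

    n_genes: int = 19462
    frac_sex_specific: float = 2327 / 19462
    n_illness_degs: int = 41
    frac_overlap: float = 25 / 41
    effect_size_log2: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_illness_degs > self.n_genes:
            raise ConfigError("n_illness_degs cannot exceed n_genes")
        for name in ("frac_sex_specific", "frac_overlap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


def default_event_schedule() -> list[StimulusEvent]:
    """The standard application order on the default 400 s recording.

    GABA, then NMDA-preferring glutamate + glycine (Mg-free), then the KCl
    excitability test, then the ionomycin calibrator at the end; each applied
    for 2 s, spaced so every event has a full 50 s baseline window and 20 s
    response window.
    """
    return [
        StimulusEvent("GABA", onset=60.0, concentration_label="100 uM"),
        StimulusEvent("GluGlyNoMg", onset=150.0, concentration_label="100 uM + 10 uM glycine"),
        StimulusEvent("KCl", onset=240.0, concentration_label="30 mM"),
        StimulusEvent("ionomycin", onset=330.0, concentration_label="10 uM"),
    ]


def _validate_schedule(cfg: TraceSimConfig, events: Sequence[StimulusEvent],
                       windows: ResponseWindows) -> None:
    t_last = (round(cfg.duration / cfg.sampling_interval) - 1) * cfg.sampling_interval
    for ev in events:
        if ev.onset - windows.pre_window < 0:
            raise SchedulingError(
                f"{ev.agent} at {ev.onset:g}s: needs {windows.pre_window:g}s pre-window"
            )
        if ev.onset + windows.post_window > t_last:
            raise SchedulingError(
                f"{ev.agent} at {ev.onset:g}s: needs {windows.post_window:g}s post-window "
                f"inside the {t_last:g}s recording"
            )


def transient_kernel(t: np.ndarray, onset: float, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak on ``t``.

    The kernel is zero before ``onset`` and
    ``exp(-(t-onset)/decay) - exp(-(t-onset)/rise)`` after it, divided by its
    maximum over the supplied sample grid so that the sampled peak equals
    exactly 1 (hence an amplitude-A transient has sampled peak exactly A,
    giving a closed-form dF* on noiseless traces).
    """
    s = np.asarray(t, dtype=float) - onset
    g = np.where(s >= 0, np.exp(-np.clip(s, 0, None) / decay)
                 - np.exp(-np.clip(s, 0, None) / rise), 0.0)
    peak = g.max()
    if peak <= 0:
        return np.zeros_like(g)
    return g / peak


def simulate_recording(
    cfg: TraceSimConfig,
    events: Sequence[StimulusEvent] | None = None,
    seed: int | np.random.SeedSequence = 0,
    cell_amplitudes: Sequence[Mapping[str, float]] | None = None,
    windows: ResponseWindows | None = None,
    subject_id: str = "",
    pair_id: str = "",
    role: str = "",
    treatment: str = "",
) -> ImagingRecording:
    """Simulate one recording: cell traces + background ROIs + events.

    Cell traces are ``baseline_level + background_level`` plus one transient
    per event plus white Gaussian noise; background traces are
    ``background_level`` plus noise. Neuronal cells respond with
    ``cfg.stimulus_amplitudes``; non-neuronal cells respond only to ionomycin.
    ``cell_amplitudes`` optionally overrides individual agents per cell
    (entries may be ``None`` to keep defaults); the non-neuron zeroing takes
    precedence over overrides. Identical (config, events, seed) yields
    identical output.
    """
    events = list(events) if events is not None else default_event_schedule()
    windows = windows or ResponseWindows()
    _validate_schedule(cfg, events, windows)
    rng = np.random.default_rng(seed)
    n_frames = round(cfg.duration / cfg.sampling_interval)
    t = np.arange(n_frames) * cfg.sampling_interval

    n = cfg.n_cells
    n_neurons = round(cfg.neuron_fraction * n)
    is_neuron = np.zeros(n, dtype=bool)
    is_neuron[rng.permutation(n)[:n_neurons]] = True

    amplitudes: list[dict[str, float]] = []
    for i in range(n):
        amp = {a: float(v) for a, v in cfg.stimulus_amplitudes.items()}
        if cell_amplitudes is not None and cell_amplitudes[i]:
            amp.update({a: float(v) for a, v in cell_amplitudes[i].items()})
        if not is_neuron[i]:
            # non-neuronal cells lack voltage-gated/receptor responses but keep
            # the receptor-independent ionomycin transient
            amp = {a: (v if a == "ionomycin" else 0.0) for a, v in amp.items()}
        amplitudes.append(amp)

    n_outliers = round(cfg.outlier_fraction * n)
    outlier_idx = sorted(rng.permutation(n)[:n_outliers].tolist()) if n_outliers else []
    for i in outlier_idx:
        for a in CALIBRATED_AGENTS:
            if a in amplitudes[i]:
                amplitudes[i][a] *= cfg.outlier_scale

    kernels = {ev.agent: transient_kernel(t, ev.onset, cfg.transient_rise, cfg.transient_decay)
               for ev in events}
    base = cfg.baseline_level + cfg.background_level
    cell_traces: dict[str, np.ndarray] = {}
    for i in range(n):
        trace = np.full(n_frames, base)
        for ev in events:
            a = amplitudes[i].get(ev.agent, 0.0)
            if a:
                trace = trace + a * kernels[ev.agent]
        if cfg.noise_sd:
            trace = trace + rng.normal(0.0, cfg.noise_sd, n_frames)
        cell_traces[f"cell_{i:03d}"] = trace
    backgrounds = [
        cfg.background_level + (rng.normal(0.0, cfg.noise_sd, n_frames) if cfg.noise_sd
                                else np.zeros(n_frames))
        for _ in range(cfg.n_background_rois)
    ]
    metadata = {
        "is_neuron": is_neuron.tolist(),
        "amplitudes": amplitudes,
        "outlier_cells": [f"cell_{i:03d}" for i in outlier_idx],
    }
    return ImagingRecording(
        sampling_interval=cfg.sampling_interval, cell_traces=cell_traces,
        background_traces=backgrounds, events=events, subject_id=subject_id,
        pair_id=pair_id, role=role, treatment=treatment, metadata=metadata,
    )


def _pair_effects(design: CohortDesign, rng: np.random.Generator) -> dict[str, float]:
    """One pair-level effect delta_i ~ Normal(delta, between_pair_sd^2) per pair."""
    return {
        f"pair{i + 1:02d}": float(rng.normal(design.true_pair_effect, design.between_pair_sd))
        for i in range(design.n_pairs)
    }


def expected_response(design: CohortDesign, role: str, treatment: str,
                      pair_effect: float) -> float:
    """Noise-free expected calibrated response for one subject/condition."""
    mu = design.baseline_response
    if role == "ST" and treatment in design.effect_treatments:
        mu += pair_effect
    return mu


def simulate_response_cohort(
    design: CohortDesign,
    seed: int | np.random.SeedSequence = 0,
    outlier_fraction: float = 0.0,
    outlier_scale: float = 5.0,
):
    """Draw calibrated per-cell responses for a twin cohort, skipping traces.

    Returns ``(responses, truth)`` where ``responses`` is a tidy DataFrame with
    the same columns the trace pipeline emits (``pair_id, subject_id, role,
    treatment, roi_id, is_neuron, agent, final``) and ``truth`` maps pair ids
    to their realized pair-level effects. This is the generator of record for
    Monte-Carlo studies of the statistical model, where simulating and
    denoising full traces would add nothing but runtime.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    effects = _pair_effects(design, rng)
    rows = []
    for pair_id, delta_i in effects.items():
        for role in ("ST", "HT"):
            subject_id = f"{pair_id}_{role}"
            for treatment in design.treatment_labels:
                mu = expected_response(design, role, treatment, delta_i)
                values = rng.normal(mu, design.within_subject_cell_sd,
                                    design.cells_per_subject)
                if outlier_fraction:
                    n_out = round(outlier_fraction * design.cells_per_subject)
                    idx = rng.permutation(design.cells_per_subject)[:n_out]
                    values[idx] *= outlier_scale
                for c, v in enumerate(values):
                    rows.append({
                        "pair_id": pair_id, "subject_id": subject_id, "role": role,
                        "treatment": treatment, "roi_id": f"cell_{c:03d}",
                        "is_neuron": True, "agent": design.target_agent,
                        "final": float(v),
                    })
    truth = {"delta": design.true_pair_effect, "pair_effects": effects}
    return pd.DataFrame(rows), truth


@dataclass
class TwinCohort:
    """A simulated trace-level cohort with its generating ground truth."""

    recordings: list[ImagingRecording]
    pair_effects: dict[str, float]
    design: CohortDesign


def simulate_twin_cohort(
    design: CohortDesign,
    trace_cfg: TraceSimConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> TwinCohort:
    """Simulate full recordings for every subject x treatment in a twin cohort.

    Per-cell target-agent responses are drawn exactly as in
    :func:`simulate_response_cohort` and embedded as transient amplitudes
    (``amplitude = response * KCl amplitude``, so that the final
    KCl-calibrated response recovers the drawn value); negative draws are
    clamped to zero amplitude. Each recording's metadata records the pair
    effect and expected response used, so ground truth can be regenerated
    noise-free.
    """
    trace_cfg = trace_cfg or TraceSimConfig()
    if trace_cfg.n_cells != design.cells_per_subject:
        trace_cfg = TraceSimConfig(**{**trace_cfg.__dict__,
                                      "n_cells": design.cells_per_subject})
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    top_rng = np.random.default_rng(ss.spawn(1)[0])
    effects = _pair_effects(design, top_rng)
    kcl_amp = trace_cfg.stimulus_amplitudes.get("KCl", 1.0)
    if kcl_amp <= 0:
        raise ConfigError("trace_cfg must give neurons a positive KCl amplitude")

    recordings = []
    n_rec = design.n_pairs * 2 * len(design.treatment_labels)
    child_seeds = ss.spawn(n_rec)
    i_rec = 0
    for pair_id, delta_i in effects.items():
        for role in ("ST", "HT"):
            subject_id = f"{pair_id}_{role}"
            for treatment in design.treatment_labels:
                child = child_seeds[i_rec]
                i_rec += 1
                rng = np.random.default_rng(child)
                mu = expected_response(design, role, treatment, delta_i)
                responses = rng.normal(mu, design.within_subject_cell_sd,
                                       design.cells_per_subject)
                overrides = [
                    {design.target_agent: max(float(r), 0.0) * kcl_amp}
                    for r in responses
                ]
                rec = simulate_recording(
                    trace_cfg, default_event_schedule(), seed=child,
                    cell_amplitudes=overrides, subject_id=subject_id,
                    pair_id=pair_id, role=role, treatment=treatment,
                )
                rec.metadata.update({
                    "pair_effect": delta_i if treatment in design.effect_treatments else 0.0,
                    "expected_response": mu,
                    "target_agent": design.target_agent,
                    "group_label": design.group_label,
                })
                recordings.append(rec)
    return TwinCohort(recordings=recordings, pair_effects=effects, design=design)


def simulate_deg_tables(cfg: DEGSimConfig):
    """Construct a DEG table plus sex-specific and universe gene sets.

    Exactly ``round(frac_sex_specific * n_genes)`` genes are sex-specific;
    exactly ``n_illness_degs`` genes pass the standard DEG filter (adjusted
    p < 0.05 and |log2FC| >= 1); exactly ``round(frac_overlap *
    n_illness_degs)`` of those are drawn from the sex-specific set. Returns
    ``(records, sex_specific, universe)``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    n_sex = round(cfg.frac_sex_specific * n)
    n_deg = cfg.n_illness_degs
    n_olap = round(cfg.frac_overlap * n_deg)
    if n_olap > n_sex:
        raise ConfigError(f"cannot draw {n_olap} overlapping DEGs from "
                          f"{n_sex} sex-specific genes")
    if n_deg - n_olap > n - n_sex:
        raise ConfigError(f"cannot draw {n_deg - n_olap} non-overlapping DEGs from "
                          f"{n - n_sex} non-sex-specific genes")

    ids = np.array([f"G{i:06d}" for i in range(n)])
    perm = rng.permutation(n)
    sex_idx = set(perm[:n_sex].tolist())
    deg_idx = set(perm[:n_olap].tolist()) | set(perm[n_sex:n_sex + (n_deg - n_olap)].tolist())

    loc, scale = cfg.effect_size_log2
    records = []
    for i in range(n):
        if i in deg_idx:
            lfc = float(rng.choice([-1.0, 1.0]) * (1.0 + abs(rng.normal(loc, scale))))
            padj = float(rng.uniform(1e-8, 0.05 * (1 - 1e-9)))
        else:
            lfc = float(rng.normal(0.0, 0.4))
            if abs(lfc) >= 1.0:
                padj = float(rng.uniform(0.05, 1.0))
            else:
                padj = float(rng.uniform(1e-4, 1.0))
        records.append(DEGRecord(gene_id=str(ids[i]), log2fc=lfc, padj=padj))
    sex_specific = GeneSet.from_iterable("sex_specific", ids[sorted(sex_idx)])
    universe = GeneSet.from_iterable("universe", ids)
    return records, sex_specific, universe
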