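"""Quantification of stimulus-evoked calcium responses from ROI fluorescence traces.

The processing chain turns raw per-ROI fluorescence time series into calibrated,
dimensionless per-cell responses:

1. subtract the background signal (mean of the cell-free background ROIs) from
   every cell trace;
2. denoise each background-subtracted trace with a stationary (maximal-overlap)
   Haar wavelet transform, soft-thresholding the detail coefficients at the
   Donoho-Johnstone universal threshold with level-dependent noise rescaling;
3. quantify each stimulus response as ``dF* = (f - f0) / f0`` where ``f`` is the
   maximum of the denoised trace in a 20 s window after stimulus onset and
   ``f0`` the minimum in a 50 s window before it;
4. classify cells as neurons by their KCl depolarization response relative to
   the receptor-independent ionomycin transient;
5. calibrate agonist responses first by the ionomycin dF*, then by the
   (ionomycin-calibrated) KCl response.

Denoising makes the min/max extrema in step 3 usable without excessive noise
sensitivity, which is the reason the pipeline denoises before quantifying.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pywt

from .errors import (
    CalibrationError,
    ConfigError,
    DegenerateBaselineError,
    IncompleteProtocolError,
    SchedulingError,
    StructuralError,
    TraceInputError,
)

#: Stimulus agents used in the imaging protocol. ``GluGlyNoMg`` is glutamate +
#: glycine in magnesium-free solution (NMDA-receptor preferring); ``GluGly``
#: the same agonists with magnesium present.
AGENTS = ("KCl", "GABA", "GluGlyNoMg", "GluGly", "ionomycin")

#: Agents whose responses are reported on the final, KCl-calibrated scale.
CALIBRATED_AGENTS = ("GABA", "GluGlyNoMg", "GluGly")

_MAD_GAUSS = 0.6745  # median(|N(0,1)|): MAD-to-sigma consistency factor


@dataclass(frozen=True)
class StimulusEvent:
    """A single agonist application.

    Parameters
    ----------
    agent : str
        One of :data:`AGENTS`.
    onset : float
        Application start time in seconds from the beginning of the recording.
    duration : float
        Application duration in seconds (2 s in the standard protocol).
    concentration_label : str
        Free-text metadata, e.g. ``"30 mM"``.
    """

    agent: str
    onset: float
    duration: float = 2.0
    concentration_label: str = ""

    def __post_init__(self) -> None:
        if self.agent not in AGENTS:
            raise ConfigError(f"unknown stimulus agent {self.agent!r}; expected one of {AGENTS}")
        if self.onset < 0:
            raise ConfigError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ConfigError(f"event duration must be > 0, got {self.duration}")


@dataclass
class ImagingRecording:
    """One subject x condition recording: ROI traces plus the stimulus schedule.

    ``cell_traces`` maps ROI identifiers to fluorescence series (arbitrary
    units); ``background_traces`` are the cell-free ROIs whose mean is the
    background signal. All series share one sampling grid.
    """

    sampling_interval: float
    cell_traces: dict[str, np.ndarray]
    background_traces: list[np.ndarray]
    events: list[StimulusEvent]
    subject_id: str = ""
    pair_id: str = ""
    role: str = ""  # "ST" (affected), "HT" (unaffected co-twin) or "control"
    treatment: str = ""  # "pre" or "post" (clozapine)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be > 0")
        if not self.background_traces:
            raise StructuralError("recording has no background ROI traces")
        self.cell_traces = {k: np.asarray(v, dtype=float) for k, v in self.cell_traces.items()}
        self.background_traces = [np.asarray(v, dtype=float) for v in self.background_traces]
        lengths = {len(v) for v in self.cell_traces.values()}
        lengths |= {len(v) for v in self.background_traces}
        if len(lengths) != 1:
            raise StructuralError(f"traces have unequal lengths: {sorted(lengths)}")
        self.events = sorted(self.events, key=lambda e: e.onset)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.background_traces)))

    @property
    def duration(self) -> float:
        return self.n_frames * self.sampling_interval

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.sampling_interval


@dataclass(frozen=True)
class DenoiseConfig:
    """Stationary-wavelet denoising parameters.

    ``rescaling="per-level"`` estimates the noise scale separately from each
    level's detail coefficients (level-dependent rescaling); ``"single-level"``
    estimates it once from the finest level and reuses it at all levels.
    ``threshold_scale`` multiplies every threshold; 0 disables shrinkage
    entirely, which must reproduce the input (perfect reconstruction).
    """

    wavelet: str = "haar"
    level: int = 3
    threshold_mode: str = "soft"
    rescaling: str = "per-level"
    threshold_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ConfigError("decomposition level must be >= 1")
        if self.rescaling not in ("per-level", "single-level"):
            raise ConfigError(f"unknown rescaling mode {self.rescaling!r}")
        if self.threshold_mode not in ("soft", "hard"):
            raise ConfigError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.threshold_scale < 0:
            raise ConfigError("threshold_scale must be >= 0")


@dataclass(frozen=True)
class ResponseWindows:
    """Extrema windows around each stimulus onset, in seconds.

    ``f`` is taken as the maximum over the half-open post-stimulus window
    ``(onset, onset + post_window]``; ``f0`` as the minimum over the closed
    pre-stimulus window ``[onset - pre_window, onset]``.
    """

    post_window: float = 20.0
    pre_window: float = 50.0

    def __post_init__(self) -> None:
        if self.post_window <= 0 or self.pre_window <= 0:
            raise ConfigError("response windows must be > 0")


@dataclass(frozen=True)
class ResponseMeasure:
    """A single cell's raw response to one stimulus: dF* = (f - f0) / f0."""

    agent: str
    dF_star: float
    f: float
    f0: float


@dataclass
class CellSummary:
    """Raw and calibrated responses for one cell.

    ``iono_calibrated[a] = raw[a] / raw['ionomycin']`` and, for agonists,
    ``final[a] = iono_calibrated[a] / iono_calibrated['KCl']`` — algebraically
    equal to ``raw[a] / raw['KCl']`` since the ionomycin divisor cancels.
    """

    roi_id: str
    is_neuron: bool
    raw: dict[str, float]
    iono_calibrated: dict[str, float]
    final: dict[str, float]


def subtract_background(recording: ImagingRecording) -> ImagingRecording:
    """Subtract the across-background mean, pointwise, from every cell trace.

    Background traces are retained unchanged on the returned recording so the
    subtraction stays auditable.
    """
    bg = np.mean(np.vstack(recording.background_traces), axis=0)
    corrected = {k: v - bg for k, v in recording.cell_traces.items()}
    return replace(recording, cell_traces=corrected,
                   background_traces=[b.copy() for b in recording.background_traces])


def _pad_symmetric(x: np.ndarray, block: int) -> tuple[np.ndarray, int]:
    """Reflect-pad at the end to the next multiple of ``block``."""
    pad = (-len(x)) % block
    if pad == 0:
        return x, 0
    if pad >= len(x):  # pywt symmetric padding cannot exceed the signal length
        reps = int(np.ceil(pad / len(x)))
        tail = np.concatenate([x[::-1] if i % 2 == 0 else x for i in range(reps)])[:pad]
        return np.concatenate([x, tail]), pad
    return np.pad(x, (0, pad), mode="symmetric"), pad


def denoise(series: Sequence[float], cfg: DenoiseConfig | None = None) -> np.ndarray:
    """Wavelet-denoise one fluorescence series.

    Stationary (undecimated) wavelet decomposition to ``cfg.level`` with the
    configured mother wavelet; for each detail level ``j`` the noise scale is
    estimated as ``sigma_j = median(|d_j|) / 0.6745`` and the universal
    threshold ``lambda_j = sigma_j * sqrt(2 ln N)`` applied by soft (or hard)
    thresholding; the approximation coefficients are left untouched. ``N`` is
    the padded series length. The output has the same length as the input.
    """
    cfg = cfg or DenoiseConfig()
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise TraceInputError("series contains non-finite values")
    block = 2 ** cfg.level
    xp, pad = _pad_symmetric(x, block)
    n = len(xp)
    # coeffs = [cA_L, cD_L, cD_{L-1}, ..., cD_1] (coarsest detail first)
    coeffs = pywt.swt(xp, cfg.wavelet, level=cfg.level, trim_approx=True, norm=True)
    details = coeffs[1:]
    if cfg.rescaling == "single-level":
        sigma = np.median(np.abs(details[-1])) / _MAD_GAUSS
        sigmas = [sigma] * len(details)
    else:
        sigmas = [np.median(np.abs(d)) / _MAD_GAUSS for d in details]
    lam = math.sqrt(2.0 * math.log(n)) * cfg.threshold_scale
    shrunk = [coeffs[0]]
    for d, s in zip(details, sigmas):
        thr = lam * s
        # a zero threshold is a no-op (and pywt's soft rule would 0/0 on
        # exactly-zero coefficients)
        shrunk.append(pywt.threshold(d, thr, mode=cfg.threshold_mode) if thr > 0 else d)
    y = pywt.iswt(shrunk, cfg.wavelet, norm=True)
    return np.asarray(y[: len(x)])


def compute_response(
    series: Sequence[float],
    event: StimulusEvent,
    windows: ResponseWindows | None = None,
    sampling_interval: float = 1.0,
) -> ResponseMeasure:
    """Quantify one stimulus response as dF* = (f - f0) / f0.

    ``f`` is the maximum of ``series`` over ``(onset, onset + post_window]``
    and ``f0`` the minimum over ``[onset - pre_window, onset]``. The series is
    expected to be denoised and background-subtracted, so ``f0 > 0``.
    """
    windows = windows or ResponseWindows()
    x = np.asarray(series, dtype=float)
    t = np.arange(len(x)) * sampling_interval
    eps = sampling_interval * 1e-9
    lo, hi = event.onset - windows.pre_window, event.onset + windows.post_window
    if lo < -eps or hi > t[-1] + eps:
        raise SchedulingError(
            f"{event.agent} at {event.onset:g}s: window [{lo:g}, {hi:g}]s falls "
            f"outside the recording [0, {t[-1]:g}]s"
        )
    pre = (t >= lo - eps) & (t <= event.onset + eps)
    post = (t > event.onset + eps) & (t <= hi + eps)
    if not pre.any() or not post.any():
        raise SchedulingError(f"{event.agent} at {event.onset:g}s: empty analysis window")
    f = float(np.max(x[post]))
    f0 = float(np.min(x[pre]))
    if f0 <= 0:
        raise DegenerateBaselineError(
            f"baseline f0 = {f0:g} <= 0 for {event.agent} at {event.onset:g}s; "
            "background subtraction left no positive baseline"
        )
    return ResponseMeasure(agent=event.agent, dF_star=(f - f0) / f0, f=f, f0=f0)


def classify_neuron(
    kcl_response: ResponseMeasure,
    iono_response: ResponseMeasure,
    min_ratio: float = 0.1,
) -> bool:
    """KCl-excitability test: neuron iff dF*(KCl) / dF*(ionomycin) >= min_ratio.

    KCl depolarization activates voltage-gated calcium entry only in excitable
    cells, while the ionomycin transient is receptor-independent and provides
    the per-cell scale.
    """
    if iono_response.dF_star <= 0:
        raise CalibrationError(
            f"ionomycin dF* = {iono_response.dF_star:g} <= 0; cannot classify"
        )
    return kcl_response.dF_star / iono_response.dF_star >= min_ratio


def calibrate_cell(
    raw: Mapping[str, float],
    roi_id: str = "",
    is_neuron: bool = True,
) -> CellSummary:
    """Two-stage calibration of a cell's raw dF* responses.

    First every response is divided by the ionomycin dF*; then the agonist
    responses (GABA, glutamate + glycine) are further divided by the
    ionomycin-calibrated KCl response. Requires positive ionomycin and KCl
    responses.
    """
    if "ionomycin" not in raw or "KCl" not in raw:
        missing = {"ionomycin", "KCl"} - set(raw)
        raise IncompleteProtocolError(f"missing required stimulus response(s): {sorted(missing)}")
    iono = raw["ionomycin"]
    if iono <= 0:
        raise CalibrationError(f"ionomycin dF* = {iono:g} <= 0")
    iono_cal = {a: v / iono for a, v in raw.items()}
    kcl = iono_cal["KCl"]
    if kcl <= 0:
        raise CalibrationError(f"calibrated KCl response = {kcl:g} <= 0")
    final = {a: iono_cal[a] / kcl for a in raw if a in CALIBRATED_AGENTS}
    return CellSummary(roi_id=roi_id, is_neuron=is_neuron, raw=dict(raw),
                       iono_calibrated=iono_cal, final=final)


def process_recording(
    recording: ImagingRecording,
    denoise_cfg: DenoiseConfig | None = None,
    windows: ResponseWindows | None = None,
    min_neuron_ratio: float = 0.1,
):
    """Run the full per-recording chain and return a tidy response table.

    Returns a :class:`pandas.DataFrame` with one row per cell x stimulus:
    columns ``subject_id, pair_id, role, treatment, roi_id, is_neuron, agent,
    dF_star, iono_calibrated, final``. ``final`` is defined only for agonist
    responses of neurons (NaN otherwise). Cells with a nonpositive ionomycin
    transient cannot be calibrated and are dropped.
    """
    import pandas as pd

    windows = windows or ResponseWindows()
    corrected = subtract_background(recording)
    rows = []
    for roi_id, trace in corrected.cell_traces.items():
        den = denoise(trace, denoise_cfg)
        raw: dict[str, float] = {}
        try:
            for ev in corrected.events:
                raw[ev.agent] = compute_response(
                    den, ev, windows, recording.sampling_interval
                ).dF_star
        except DegenerateBaselineError:
            continue
        if raw.get("ionomycin", 0.0) <= 0:
            continue  # no calibrator transient: cell is unusable
        iono = raw["ionomycin"]
        iono_cal = {a: v / iono for a, v in raw.items()}
        is_neuron = "KCl" in raw and iono_cal["KCl"] >= min_neuron_ratio
        finals: dict[str, float] = {}
        if is_neuron and iono_cal.get("KCl", 0.0) > 0:
            finals = {a: iono_cal[a] / iono_cal["KCl"]
                      for a in raw if a in CALIBRATED_AGENTS}
        for agent, val in raw.items():
            rows.append({
                "subject_id": recording.subject_id,
                "pair_id": recording.pair_id,
                "role": recording.role,
                "treatment": recording.treatment,
                "roi_id": roi_id,
                "is_neuron": is_neuron,
                "agent": agent,
                "dF_star": val,
                "iono_calibrated": iono_cal[agent],
                "final": finals.get(agent, float("nan")),
            })
    return pd.DataFrame(
        rows,
        columns=["subject_id", "pair_id", "role", "treatment", "roi_id",
                 "is_neuron", "agent", "dF_star", "iono_calibrated", "final"],
    )
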