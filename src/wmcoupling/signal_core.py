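"""Band-limited phase/amplitude extraction and analysis-window selection.

This module holds the raw-data containers (:class:`Recording`, :class:`Band`,
:class:`AnalysisWindowSet`, :class:`PhaseAmpSeries`) and the two low-level
signal operations every cross-frequency-coupling computation rests on:

1. zero-phase band-pass filtering followed by the analytic (Hilbert) signal,
   giving instantaneous phase of a low band and instantaneous amplitude of a
   high band;
2. selection of per-trial analysis windows (from the response prompt plus an
   offset up to the second button click) and concatenation of the filtered
   samples inside them.

Filtering is always applied to the *continuous* recording before any window
is cut out, so concatenation joins never create artificial phase jumps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("wmcoupling")

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """A frequency band in Hz, ``0 < low_hz < high_hz``."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(f"invalid band: {self.low_hz}-{self.high_hz} Hz")

    def validate_for_fs(self, fs_hz: float) -> None:
        if self.high_hz >= fs_hz / 2.0:
            raise ValueError(
                f"band edge {self.high_hz} Hz at or above Nyquist ({fs_hz / 2} Hz)"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)


THETA = Band(4.0, 8.0)
GAMMA = Band(40.0, 80.0)


@dataclass
class Recording:
    """Continuous multichannel recording.

    signal        : (n_channels, n_samples) array, microvolts
    fs_hz         : sampling rate
    channel_names : one unique name per signal row
    annotations   : list of (label, time_s) event markers
    """

    signal: np.ndarray
    fs_hz: float
    channel_names: list[str]
    annotations: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match signal rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        dur = self.duration_s
        for label, t in self.annotations:
            if not (0.0 <= t <= dur):
                raise ValueError(f"annotation {label!r} at {t} s outside [0, {dur}] s")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs_hz

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def channel(self, name: str) -> np.ndarray:
        return self.signal[self.channel_index(name)]

    def annotation_times(self, label: str) -> np.ndarray:
        return np.array([t for lab, t in self.annotations if lab == label])


@dataclass(frozen=True)
class TrialWindow:
    """Half-open analysis interval for one trial, with optional motor masks.

    Motor masks are half-open sub-intervals (clipped to the window) covering
    +/-200 ms around each button click; samples inside them can be excluded
    (non-motor analysis) or exclusively kept (motor analysis).
    """

    start_s: float
    end_s: float
    motor_masks: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"empty window [{self.start_s}, {self.end_s})")


@dataclass
class AnalysisWindowSet:
    """Per-trial analysis windows, in trial order."""

    windows: list[TrialWindow]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def total_duration_s(self) -> float:
        return float(sum(w.end_s - w.start_s for w in self.windows))


@dataclass
class PhaseAmpSeries:
    """Paired instantaneous phase (rad, in [-pi, pi)) and amplitude series."""

    phase_rad: np.ndarray
    amplitude: np.ndarray
    fs_hz: float
    phase_channel: str = ""
    amp_channel: str = ""
    phase_band: Band | None = None
    amp_band: Band | None = None

    def __post_init__(self) -> None:
        self.phase_rad = np.asarray(self.phase_rad, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase_rad.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude must have equal length")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be nonnegative")

    def __len__(self) -> int:
        return self.phase_rad.size


# ---------------------------------------------------------------------------
# Filtering and analytic signal
# ---------------------------------------------------------------------------

def _fir_bandpass_taps(band: Band, fs_hz: float) -> np.ndarray:
    """Hamming-window FIR band-pass; transition width 25% of the lower edge."""
    band.validate_for_fs(fs_hz)
    trans_hz = 0.25 * band.low_hz
    # Hamming window: ~3.3 / normalized transition width taps.
    numtaps = int(np.ceil(3.3 * fs_hz / trans_hz))
    numtaps += (numtaps + 1) % 2  # force odd -> type-I linear phase
    return sps.firwin(
        numtaps,
        [band.low_hz, band.high_hz],
        pass_zero=False,
        window="hamming",
        fs=fs_hz,
    )


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap angles into [-pi, pi); +pi maps to -pi."""
    return np.mod(np.asarray(phase) + np.pi, TWO_PI) - np.pi


def bandpass_filter(x: np.ndarray, band: Band, fs_hz: float) -> tuple[np.ndarray, int]:
    """Zero-phase (forward-backward) FIR band-pass of a 1-D signal.

    Returns the filtered signal and the number of edge samples (one filter
    length) at each end that should be excluded from phase/amplitude use.
    """
    taps = _fir_bandpass_taps(band, fs_hz)
    if x.size <= 3 * taps.size:
        raise ValueError(
            f"signal too short ({x.size} samples) for filter of {taps.size} taps"
        )
    y = sps.filtfilt(taps, 1.0, x)
    return y, taps.size


def bandpass_phase(recording: Recording, channel: str, band: Band) -> tuple[np.ndarray, int]:
    """Instantaneous phase of a channel in a band: filter -> Hilbert -> angle.

    Returns (phase series in [-pi, pi), n_edge samples to exclude per end).
    Phase 0 corresponds to the peak of the band-passed oscillation (cosine
    convention).
    """
    y, n_edge = bandpass_filter(recording.channel(channel), band, recording.fs_hz)
    phase = wrap_phase(np.angle(sps.hilbert(y)))
    return phase, n_edge


def bandpass_amplitude(recording: Recording, channel: str, band: Band) -> tuple[np.ndarray, int]:
    """Instantaneous amplitude envelope of a channel in a band (Hilbert magnitude)."""
    y, n_edge = bandpass_filter(recording.channel(channel), band, recording.fs_hz)
    return np.abs(sps.hilbert(y)), n_edge


def phase_amp_series(
    recording: Recording,
    phase_channel: str,
    amp_channel: str,
    phase_band: Band = THETA,
    amp_band: Band = GAMMA,
) -> tuple[PhaseAmpSeries, int]:
    """Full-length paired phase/amplitude series for a channel pair.

    Returns the series plus the larger of the two per-end edge exclusions.
    """
    phase, e1 = bandpass_phase(recording, phase_channel, phase_band)
    amp, e2 = bandpass_amplitude(recording, amp_channel, amp_band)
    series = PhaseAmpSeries(
        phase_rad=phase,
        amplitude=amp,
        fs_hz=recording.fs_hz,
        phase_channel=phase_channel,
        amp_channel=amp_channel,
        phase_band=phase_band,
        amp_band=amp_band,
    )
    return series, max(e1, e2)


# ---------------------------------------------------------------------------
# Analysis windows
# ---------------------------------------------------------------------------

def _group_trials(
    recording: Recording, prompt_label: str, click_labels: tuple[str, ...]
) -> list[dict]:
    """Group annotations into trials keyed by successive prompt markers."""
    events = sorted(recording.annotations, key=lambda e: e[1])
    prompts = [t for lab, t in events if lab == prompt_label]
    trials: list[dict] = []
    for i, pt in enumerate(prompts):
        t_next = prompts[i + 1] if i + 1 < len(prompts) else np.inf
        trial = {"prompt": pt, "clicks": {}}
        for lab, t in events:
            if lab in click_labels and pt <= t < t_next:
                trial["clicks"].setdefault(lab, t)
        trials.append(trial)
    return trials


def extract_windows(
    recording: Recording,
    prompt_label: str = "prompt",
    click_labels: tuple[str, ...] = ("click1", "click2", "click3"),
    offset_s: float = 0.5,
    motor_mask_halfwidth_s: float | None = None,
) -> AnalysisWindowSet:
    """Per-trial analysis windows [prompt + offset, second click).

    The window starts ``offset_s`` (default 500 ms, excluding sensory
    processing of the prompt) after each prompt marker and ends at the second
    click of the trial. Trials missing the required markers, or whose second
    click falls at or before the window start, are dropped with a warning.

    If ``motor_mask_halfwidth_s`` is given (conventionally 0.2 s), every click
    in the trial contributes a mask interval of +/- that half-width, clipped
    to the window.
    """
    trials = _group_trials(recording, prompt_label, click_labels)
    if len(click_labels) < 2:
        raise ValueError("need at least two click labels")
    second_click = click_labels[1]
    windows: list[TrialWindow] = []
    n_dropped = 0
    for k, trial in enumerate(trials):
        clicks = trial["clicks"]
        if second_click not in clicks:
            warnings.warn(f"trial {k}: missing {second_click!r}, skipped")
            n_dropped += 1
            continue
        start = trial["prompt"] + offset_s
        end = clicks[second_click]
        if end <= start:
            warnings.warn(f"trial {k}: second click at {end} s precedes window start, dropped")
            n_dropped += 1
            continue
        masks: list[tuple[float, float]] = []
        if motor_mask_halfwidth_s is not None:
            for lab in click_labels:
                if lab in clicks:
                    lo = max(start, clicks[lab] - motor_mask_halfwidth_s)
                    hi = min(end, clicks[lab] + motor_mask_halfwidth_s)
                    if lo < hi:
                        masks.append((lo, hi))
        windows.append(TrialWindow(start, end, tuple(masks)))
    if not windows:
        raise ValueError("no usable trials: every trial lacked a valid analysis window")
    logger.info("extract_windows: %d windows, %d trials dropped", len(windows), n_dropped)
    return AnalysisWindowSet(windows, n_dropped)


def whole_recording_windows(recording: Recording, edge_samples: int = 0) -> AnalysisWindowSet:
    """A single window covering the recording minus ``edge_samples`` per end."""
    fs = recording.fs_hz
    start = edge_samples / fs
    end = (recording.n_samples - edge_samples) / fs
    return AnalysisWindowSet([TrialWindow(start, end)])


def window_sample_mask(
    windows: AnalysisWindowSet,
    n_samples: int,
    fs_hz: float,
    motor: bool | None = None,
) -> np.ndarray:
    """Boolean sample mask for a window set over a series of ``n_samples``.

    motor=None  -> all samples inside windows
    motor=False -> window samples outside every motor mask
    motor=True  -> window samples inside a motor mask
    Sample index convention: index = floor(t * fs); intervals half-open.
    """
    inside = np.zeros(n_samples, dtype=bool)
    in_motor = np.zeros(n_samples, dtype=bool)
    for w in windows:
        i0 = max(0, int(np.floor(w.start_s * fs_hz)))
        i1 = min(n_samples, int(np.floor(w.end_s * fs_hz)))
        inside[i0:i1] = True
        for lo, hi in w.motor_masks:
            j0 = max(0, int(np.floor(lo * fs_hz)))
            j1 = min(n_samples, int(np.floor(hi * fs_hz)))
            in_motor[j0:j1] = True
    if motor is None:
        return inside
    if motor:
        return inside & in_motor
    return inside & ~in_motor


def concatenate_windows(
    series: PhaseAmpSeries,
    windows: AnalysisWindowSet,
    motor: bool | None = None,
) -> PhaseAmpSeries:
    """Concatenate the samples falling inside the analysis windows.

    The phase/amplitude series must have been computed on the continuous
    recording, so selection here introduces no new filter edges. Samples are
    taken in trial order; with ``motor`` set, the motor masks additionally
    include (True) or exclude (False) the +/-200 ms click epochs.
    """
    if len(windows) == 0:
        raise ValueError("empty window set")
    mask = window_sample_mask(windows, len(series), series.fs_hz, motor=motor)
    if not mask.any():
        raise ValueError("window selection produced zero samples")
    return PhaseAmpSeries(
        phase_rad=series.phase_rad[mask],
        amplitude=series.amplitude[mask],
        fs_hz=series.fs_hz,
        phase_channel=series.phase_channel,
        amp_channel=series.amp_channel,
        phase_band=series.phase_band,
        amp_band=series.amp_band,
    )
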