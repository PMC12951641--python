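"""Phase-amplitude coupling strength: the Kullback-Leibler modulation index.

The modulation index (MI) measures how far the distribution of high-frequency
amplitude over low-frequency phase bins departs from uniformity:

    P(j) = <A>_j / sum_k <A>_k           (mean amplitude per phase bin, normalized)
    MI   = D_KL(P, U) / log N = (log N - H(P)) / log N

with N phase bins (18 by default), H the Shannon entropy and U the uniform
distribution. MI is 0 exactly when P is uniform (no coupling) and 1 when all
amplitude concentrates in one bin. Natural logarithms throughout; the log N
normalization makes the index scale-free.

Built on top of the index are the composite estimators used in the analyses:
within- and cross-electrode MI over trial windows, time-binned MI indicators
for latent-variable modeling, the phase x amplitude comodulogram with a
permutation null, and the motor-window control contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signal_core import (
    GAMMA,
    THETA,
    AnalysisWindowSet,
    Band,
    PhaseAmpSeries,
    Recording,
    concatenate_windows,
    phase_amp_series,
    whole_recording_windows,
)

logger = logging.getLogger("wmcoupling")

DEFAULT_N_BINS = 18


@dataclass
class PhaseAmpDistribution:
    """Mean amplitude per phase bin and its normalized distribution P(j)."""

    n_bins: int
    mean_amp_per_bin: np.ndarray
    p: np.ndarray
    bin_edges: np.ndarray
    n_samples: int
    n_empty_bins: int = 0


@dataclass
class MIResult:
    """Scalar modulation index with provenance."""

    mi: float
    n_samples: int
    n_bins: int = DEFAULT_N_BINS
    phase_band: Band | None = None
    amp_band: Band | None = None
    phase_channel: str = ""
    amp_channel: str = ""


def phase_bin_indices(phase_rad: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Assign each phase (in [-pi, pi)) to one of ``n_bins`` equal bins.

    Bins are left-closed right-open over [-pi, pi); the boundary value +pi
    wraps to the first bin.
    """
    idx = np.floor((np.asarray(phase_rad) + np.pi) / (2 * np.pi) * n_bins).astype(np.intp)
    idx[idx == n_bins] = 0  # phase exactly +pi wraps to -pi
    return idx


def bin_by_phase(
    series: PhaseAmpSeries | tuple[np.ndarray, np.ndarray],
    n_bins: int = DEFAULT_N_BINS,
) -> PhaseAmpDistribution:
    """Discretize amplitudes into phase bins and normalize to P(j).

    Accepts a :class:`PhaseAmpSeries` or a raw ``(phase, amplitude)`` pair.
    Bins that receive no samples get mean amplitude 0 (and hence p = 0), with
    a warning — usually a sign of too few samples.
    """
    if isinstance(series, PhaseAmpSeries):
        phase, amp = series.phase_rad, series.amplitude
    else:
        phase, amp = np.asarray(series[0]), np.asarray(series[1])
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if phase.size == 0:
        raise ValueError("empty phase/amplitude series")
    idx = phase_bin_indices(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    mean_amp = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    n_empty = int((counts == 0).sum())
    if n_empty:
        warnings.warn(f"{n_empty} of {n_bins} phase bins received no samples")
    total = mean_amp.sum()
    if total <= 0:
        raise ValueError("degenerate input: zero total amplitude across bins")
    return PhaseAmpDistribution(
        n_bins=n_bins,
        mean_amp_per_bin=mean_amp,
        p=mean_amp / total,
        bin_edges=np.linspace(-np.pi, np.pi, n_bins + 1),
        n_samples=int(phase.size),
        n_empty_bins=n_empty,
    )


def modulation_index(dist: PhaseAmpDistribution) -> MIResult:
    """MI = (log N - H(P)) / log N with the convention 0 * log 0 = 0."""
    p = dist.p
    if dist.n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    log_n = np.log(dist.n_bins)
    mi = (log_n - entropy) / log_n
    # clip tiny negative rounding error; MI is mathematically in [0, 1]
    mi = float(min(max(mi, 0.0), 1.0))
    return MIResult(mi=mi, n_samples=dist.n_samples, n_bins=dist.n_bins)


def mi_from_series(
    series: PhaseAmpSeries | tuple[np.ndarray, np.ndarray],
    n_bins: int = DEFAULT_N_BINS,
) -> MIResult:
    """Convenience composition: bin by phase then compute the MI."""
    res = modulation_index(bin_by_phase(series, n_bins))
    if isinstance(series, PhaseAmpSeries):
        res.phase_band = series.phase_band
        res.amp_band = series.amp_band
        res.phase_channel = series.phase_channel
        res.amp_channel = series.amp_channel
    return res


# ---------------------------------------------------------------------------
# Recording-level MI
# ---------------------------------------------------------------------------

def _windowed_series(
    recording: Recording,
    phase_channel: str,
    amp_channel: str,
    phase_band: Band,
    amp_band: Band,
    windows: AnalysisWindowSet | None,
    motor: bool | None = None,
) -> PhaseAmpSeries:
    series, n_edge = phase_amp_series(
        recording, phase_channel, amp_channel, phase_band, amp_band
    )
    if windows is None:
        windows = whole_recording_windows(recording, n_edge)
    return concatenate_windows(series, windows, motor=motor)


def mi_within(
    recording: Recording,
    channel: str,
    phase_band: Band = THETA,
    amp_band: Band = GAMMA,
    windows: AnalysisWindowSet | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> MIResult:
    """Within-electrode MI: phase and amplitude from the same channel.

    The continuous channel is filtered in both bands, trial windows are cut
    out and concatenated, and the MI of the pooled samples is returned.
    ``windows=None`` uses the whole recording minus filter edges.
    """
    return mi_from_series(
        _windowed_series(recording, channel, channel, phase_band, amp_band, windows),
        n_bins,
    )


def mi_cross(
    recording: Recording,
    phase_channel: str,
    amp_channel: str,
    phase_band: Band = THETA,
    amp_band: Band = GAMMA,
    windows: AnalysisWindowSet | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> MIResult:
    """Cross-electrode MI: low-band phase of one channel modulating the
    high-band amplitude of another; direction recorded as phase -> amplitude."""
    return mi_from_series(
        _windowed_series(
            recording, phase_channel, amp_channel, phase_band, amp_band, windows
        ),
        n_bins,
    )


def mi_time_binned(
    series: PhaseAmpSeries,
    segment_count: int = 3,
    bin_s: float = 5.0,
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Per-segment MI indicators for latent-variable modeling.

    The concatenated series is split into ``segment_count`` contiguous
    equal-length segments (by samples). Within each segment the MI is
    computed over consecutive full ``bin_s``-second bins and averaged; a
    trailing partial bin is discarded. A segment with no full bin yields NaN
    (flagged with a warning).
    """
    n = len(series)
    if segment_count < 1:
        raise ValueError("segment_count must be >= 1")
    seg_len = n // segment_count
    if seg_len == 0:
        raise ValueError("series too short for the requested segment count")
    bin_len = int(round(bin_s * series.fs_hz))
    out = np.full(segment_count, np.nan)
    for s in range(segment_count):
        lo = s * seg_len
        seg_phase = series.phase_rad[lo : lo + seg_len]
        seg_amp = series.amplitude[lo : lo + seg_len]
        n_full = seg_len // bin_len
        if n_full == 0:
            warnings.warn(f"segment {s}: shorter than one {bin_s}-s bin, indicator undefined")
            continue
        mis = []
        for b in range(n_full):
            sl = slice(b * bin_len, (b + 1) * bin_len)
            mis.append(mi_from_series((seg_phase[sl], seg_amp[sl]), n_bins).mi)
        out[s] = float(np.mean(mis))
    return out


# ---------------------------------------------------------------------------
# Comodulogram with permutation null
# ---------------------------------------------------------------------------

def default_phase_grid() -> list[Band]:
    """3-10 Hz in 1-Hz-wide bands."""
    return [Band(lo, lo + 1.0) for lo in np.arange(3.0, 10.0)]


def default_amp_grid() -> list[Band]:
    """30-80 Hz in 10-Hz-wide bands."""
    return [Band(lo, lo + 10.0) for lo in np.arange(30.0, 80.0, 10.0)]


@dataclass
class Comodulogram:
    """MI over a grid of (phase band, amplitude band) pairs plus its null.

    The null reference is built by permuting the MI values across the cells
    of the matrix (within participants), pooling the permuted group-average
    matrices, and thresholding the observed group average at
    ``null_mean + 3 * null_sd``.
    """

    phase_bands: list[Band]
    amp_bands: list[Band]
    mi_grid: np.ndarray  # |phase| x |amp|
    null_mean: float = np.nan
    null_sd: float = np.nan
    significance_mask: np.ndarray | None = None

    @property
    def phase_centers_hz(self) -> np.ndarray:
        return np.array([b.center_hz for b in self.phase_bands])

    @property
    def amp_centers_hz(self) -> np.ndarray:
        return np.array([b.center_hz for b in self.amp_bands])


def mi_grid(
    recording: Recording,
    channel: str,
    phase_bands: list[Band] | None = None,
    amp_bands: list[Band] | None = None,
    windows: AnalysisWindowSet | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Raw MI matrix over all (phase band, amplitude band) pairs for one channel."""
    phase_bands = phase_bands or default_phase_grid()
    amp_bands = amp_bands or default_amp_grid()
    grid = np.empty((len(phase_bands), len(amp_bands)))
    for i, pb in enumerate(phase_bands):
        for j, ab in enumerate(amp_bands):
            grid[i, j] = mi_within(
                recording, channel, pb, ab, windows=windows, n_bins=n_bins
            ).mi
    return grid


def comodulogram_null(
    grids: list[np.ndarray], n_perm: int = 1000, seed: int = 0
) -> tuple[float, float, np.ndarray]:
    """Permutation null for a cohort of MI grids.

    Each permutation shuffles every participant's cell values uniformly over
    the matrix, then the group-average matrix is formed; the null mean and SD
    are computed over all permuted group-average cells. Returns
    (null_mean, null_sd, observed group-average grid).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; null statistics will be noisy")
    rng = np.random.default_rng(seed)
    stack = np.stack(grids)  # participants x phase x amp
    shape = stack.shape[1:]
    n_cells = shape[0] * shape[1]
    flat = stack.reshape(len(grids), n_cells)
    null_cells = np.empty((n_perm, n_cells))
    for p in range(n_perm):
        perm = np.stack([flat[k, rng.permutation(n_cells)] for k in range(len(grids))])
        null_cells[p] = perm.mean(axis=0)
    observed = stack.mean(axis=0)
    return float(null_cells.mean()), float(null_cells.std()), observed


def comodulogram(
    recording: Recording,
    channel: str,
    phase_bands: list[Band] | None = None,
    amp_bands: list[Band] | None = None,
    windows: AnalysisWindowSet | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
) -> Comodulogram:
    """Single-recording comodulogram: MI grid, permutation null, significance mask."""
    phase_bands = phase_bands or default_phase_grid()
    amp_bands = amp_bands or default_amp_grid()
    grid = mi_grid(recording, channel, phase_bands, amp_bands, windows, n_bins)
    mean, sd, observed = comodulogram_null([grid], n_perm=n_perm, seed=seed)
    return Comodulogram(
        phase_bands=phase_bands,
        amp_bands=amp_bands,
        mi_grid=observed,
        null_mean=mean,
        null_sd=sd,
        significance_mask=observed > mean + 3.0 * sd,
    )


def comodulogram_group(
    grids: list[np.ndarray],
    phase_bands: list[Band] | None = None,
    amp_bands: list[Band] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> Comodulogram:
    """Group comodulogram from per-participant MI grids (null mean + 3 SD mask)."""
    phase_bands = phase_bands or default_phase_grid()
    amp_bands = amp_bands or default_amp_grid()
    mean, sd, observed = comodulogram_null(grids, n_perm=n_perm, seed=seed)
    return Comodulogram(
        phase_bands=phase_bands,
        amp_bands=amp_bands,
        mi_grid=observed,
        null_mean=mean,
        null_sd=sd,
        significance_mask=observed > mean + 3.0 * sd,
    )


# ---------------------------------------------------------------------------
# Motor-window control
# ---------------------------------------------------------------------------

def motor_nonmotor_mi(
    recording: Recording,
    channel: str,
    windows: AnalysisWindowSet,
    phase_band: Band = THETA,
    amp_band: Band = GAMMA,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[float, float]:
    """(MI over motor samples, MI over non-motor samples) for one recording.

    Motor samples are those inside the +/-200 ms click masks of the window
    set; the two masks partition each analysis window. Raises if either side
    is empty.
    """
    if not any(w.motor_masks for w in windows):
        raise ValueError("window set carries no motor masks")
    series, _ = phase_amp_series(recording, channel, channel, phase_band, amp_band)
    motor = concatenate_windows(series, windows, motor=True)
    nonmotor = concatenate_windows(series, windows, motor=False)
    return mi_from_series(motor, n_bins).mi, mi_from_series(nonmotor, n_bins).mi


@dataclass
class MotorContrastResult:
    mi_motor: np.ndarray
    mi_nonmotor: np.ndarray
    t: float
    p: float
    df: int


def motor_window_contrast(
    recordings: list[Recording],
    channel: str,
    window_sets: list[AnalysisWindowSet],
    phase_band: Band = THETA,
    amp_band: Band = GAMMA,
) -> MotorContrastResult:
    """Group paired t-test of motor vs non-motor MI across participants."""
    if len(recordings) != len(window_sets):
        raise ValueError("one window set per recording required")
    if len(recordings) < 3:
        raise ValueError("need at least 3 participants for the paired test")
    pairs = [
        motor_nonmotor_mi(rec, channel, ws, phase_band, amp_band)
        for rec, ws in zip(recordings, window_sets)
    ]
    mi_motor = np.array([a for a, _ in pairs])
    mi_nonmotor = np.array([b for _, b in pairs])
    t, p = stats.ttest_rel(mi_motor, mi_nonmotor)
    return MotorContrastResult(
        mi_motor=mi_motor,
        mi_nonmotor=mi_nonmotor,
        t=float(t),
        p=float(p),
        df=len(recordings) - 1,
    )
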