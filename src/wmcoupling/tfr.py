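"""Phase-aligned time-frequency visualization of theta-gamma coupling.

Each 1-second epoch is transformed with an analytic generalized Morse
wavelet (symmetry gamma = 3, time-bandwidth product P = beta * gamma = 60,
hence beta = 20); the CWT magnitude is the epoch's time-frequency
representation (TFR). To visualize how low-frequency phase modulates
high-frequency amplitude, per-epoch TFRs are circularly shifted in time
according to the epoch's theta phase — epochs with earlier phase move
rightward, later phase leftward — and then averaged, so the gamma-band
magnitude lines up on a common theta cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import Band, PhaseAmpSeries, Recording, bandpass_phase, THETA


@dataclass
class TimeFreqMap:
    """Magnitude time-frequency map over a fixed epoch support."""

    freqs_hz: np.ndarray
    times_s: np.ndarray
    magnitude: np.ndarray  # freqs x times, >= 0

    def __post_init__(self) -> None:
        if self.magnitude.shape != (self.freqs_hz.size, self.times_s.size):
            raise ValueError("magnitude shape must be (n_freqs, n_times)")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be nonnegative")

    def band_mean(self, band: Band) -> np.ndarray:
        """Mean magnitude over the rows whose frequency falls inside a band."""
        sel = (self.freqs_hz >= band.low_hz) & (self.freqs_hz <= band.high_hz)
        return self.magnitude[sel].mean(axis=0)


def morse_wavelet_ft(omega: np.ndarray, gamma: float = 3.0, beta: float = 20.0) -> np.ndarray:
    """Frequency-domain generalized Morse wavelet, peak-normalized to 2.

    Psi(w) = H(w) * a * w^beta * exp(-w^gamma) with the peak (at
    w = (beta/gamma)^(1/gamma)) scaled to 2, the usual analytic-wavelet
    normalization. Defined for angular frequency in radians/sample.
    """
    omega = np.asarray(omega, dtype=float)
    peak = (beta / gamma) ** (1.0 / gamma)
    log_a = np.log(2.0) - beta * np.log(peak) + peak**gamma
    out = np.zeros_like(omega)
    pos = omega > 0
    out[pos] = np.exp(log_a + beta * np.log(omega[pos]) - omega[pos] ** gamma)
    return out


def morse_peak_omega(gamma: float = 3.0, beta: float = 20.0) -> float:
    return (beta / gamma) ** (1.0 / gamma)


def cwt_magnitude(
    epoch: np.ndarray,
    fs_hz: float,
    gamma: float = 3.0,
    time_bandwidth: float = 60.0,
    freq_min_hz: float = 2.0,
    freq_max_hz: float = 90.0,
    voices_per_octave: int = 12,
) -> TimeFreqMap:
    """Morse-wavelet CWT magnitude of one 1-second epoch.

    Frequencies are geometrically spaced (``voices_per_octave`` per octave)
    from ``freq_min_hz`` to ``freq_max_hz``. The transform is evaluated in
    the frequency domain: for each center frequency the wavelet is sampled
    at the scaled DFT frequencies and multiplied with the epoch spectrum.
    """
    epoch = np.asarray(epoch, dtype=float)
    n_expected = int(round(fs_hz))
    if epoch.size < n_expected:
        raise ValueError(f"epoch must be >= 1 s ({n_expected} samples), got {epoch.size}")
    beta = time_bandwidth / gamma
    n = epoch.size
    n_octaves = np.log2(freq_max_hz / freq_min_hz)
    n_freqs = int(np.floor(n_octaves * voices_per_octave)) + 1
    freqs = freq_min_hz * 2.0 ** (np.arange(n_freqs) / voices_per_octave)
    omega_k = 2.0 * np.pi * np.fft.fftfreq(n)  # rad/sample
    x_ft = np.fft.fft(epoch)
    peak = morse_peak_omega(gamma, beta)
    mag = np.empty((n_freqs, n))
    for i, f in enumerate(freqs):
        scale = peak / (2.0 * np.pi * f / fs_hz)
        psi = morse_wavelet_ft(scale * omega_k, gamma, beta)
        mag[i] = np.abs(np.fft.ifft(x_ft * np.conj(psi)))
    return TimeFreqMap(freqs_hz=freqs, times_s=np.arange(n) / fs_hz, magnitude=mag)


def phase_align_average(
    maps: list[TimeFreqMap],
    phases_rad: np.ndarray,
    f_low_hz: float,
    fs_hz: float,
) -> TimeFreqMap:
    """Average per-epoch TFRs after aligning them on the low-frequency phase.

    Each map is circularly shifted along time by ``-(phi / 2pi) / f_low``
    seconds (rounded to the nearest sample): an epoch whose reference theta
    phase is earlier (more negative) moves rightward, a later phase moves
    leftward, so after averaging the gamma amplitude sits at a fixed
    position within the common theta cycle.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 epochs to average")
    phases_rad = np.asarray(phases_rad, dtype=float)
    if phases_rad.size != len(maps):
        raise ValueError("one reference phase per epoch required")
    shape = maps[0].magnitude.shape
    for m in maps[1:]:
        if m.magnitude.shape != shape:
            raise ValueError("inconsistent epoch TFR shapes")
    acc = np.zeros(shape)
    for m, phi in zip(maps, phases_rad):
        shift_s = -(phi / (2.0 * np.pi)) / f_low_hz
        shift_samples = int(np.round(shift_s * fs_hz))
        acc += np.roll(m.magnitude, shift_samples, axis=1)
    acc /= len(maps)
    return TimeFreqMap(freqs_hz=maps[0].freqs_hz, times_s=maps[0].times_s, magnitude=acc)


def epoch_recording(
    recording: Recording,
    channel: str,
    epoch_s: float = 1.0,
    phase_band: Band = THETA,
    start_s: float = 0.0,
    end_s: float | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Tile a channel into non-overlapping epochs with midpoint theta phase.

    Returns (list of epoch signals, reference phase per epoch). The trailing
    partial epoch is dropped. The reference phase is the theta phase at the
    epoch midpoint, taken from the continuous-recording extraction.
    """
    fs = recording.fs_hz
    x = recording.channel(channel)
    phase, n_edge = bandpass_phase(recording, channel, phase_band)
    i0 = max(int(np.floor(start_s * fs)), n_edge)
    i1 = min(
        int(np.floor((end_s if end_s is not None else recording.duration_s) * fs)),
        x.size - n_edge,
    )
    ep_len = int(round(epoch_s * fs))
    epochs, phis = [], []
    for lo in range(i0, i1 - ep_len + 1, ep_len):
        epochs.append(x[lo : lo + ep_len])
        phis.append(phase[lo + ep_len // 2])
    if not epochs:
        raise ValueError("no full epochs inside the requested span")
    return epochs, np.array(phis)


def aligned_tfr(
    recording: Recording,
    channel: str,
    phase_band: Band = THETA,
    epoch_s: float = 1.0,
    **cwt_kwargs,
) -> TimeFreqMap:
    """End-to-end descriptive CFC map: epoch -> CWT -> phase-align -> average."""
    epochs, phis = epoch_recording(recording, channel, epoch_s, phase_band)
    maps = [cwt_magnitude(e, recording.fs_hz, **cwt_kwargs) for e in epochs]
    return phase_align_average(maps, phis, phase_band.center_hz, recording.fs_hz)


def modulation_depth(tfmap: TimeFreqMap, band: Band) -> float:
    """Peak-to-trough relative depth of the band-mean magnitude over time.

    A descriptive statistic for aligned maps: (max - min) / mean of the mean
    magnitude in the band; near 0 when the band amplitude is flat over the
    aligned theta cycle.
    """
    trace = tfmap.band_mean(band)
    m = trace.mean()
    if m <= 0:
        return 0.0
    return float((trace.max() - trace.min()) / m)


def save_tfr(tfmap: TimeFreqMap, path_prefix: str) -> None:
    """Write the map as matrix + axis sidecars (TSV) and a PNG figure."""
    np.savetxt(path_prefix + "_magnitude.tsv", tfmap.magnitude, delimiter="\t")
    np.savetxt(path_prefix + "_freqs_hz.tsv", tfmap.freqs_hz, delimiter="\t")
    np.savetxt(path_prefix + "_times_s.tsv", tfmap.times_s, delimiter="\t")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.pcolormesh(tfmap.times_s, tfmap.freqs_hz, tfmap.magnitude, shading="auto")
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.savefig(path_prefix + ".png", dpi=120)
    plt.close(fig)
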