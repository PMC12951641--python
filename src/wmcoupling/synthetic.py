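"""Synthetic EEG-like recordings and behavioral tables with known ground truth.

Two generators:

* :func:`generate_recording` builds multichannel recordings in which the phase
  of a theta-band oscillation on a *source* channel modulates the gamma-band
  amplitude on a *target* channel with a configurable coupling strength
  ``chi`` in [0, 1] — the standard amplitude-modulation construction for
  simulated phase-amplitude coupling. ``chi = 0`` gives an unmodulated
  carrier, ``chi = 1`` full modulation depth.

* :func:`generate_behavior` draws per-trial response times from a
  two-correlated-latent-factor model (one factor per task), so the true
  factor structure behind every behavioral table is known exactly.

Both are fully reproducible: a given spec plus seed yields bit-identical
output, with all randomness flowing from one ``numpy`` Generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_core import Recording, TWO_PI

# Standard 32-channel 10-20 montage (reference electrode excluded).
MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT9", "FC5", "FC1", "FC2", "FC6", "FT10",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

CENTRAL_PARIETAL: tuple[str, ...] = ("CP1", "CP2", "Pz", "Cz")


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth phase-amplitude coupling between two channels.

    The low-frequency oscillation lives on ``source_channel``; its phase
    theta(t) modulates the envelope of a high-frequency carrier on
    ``target_channel`` as ``(1 + strength_chi * cos(theta - preferred_phase)) / 2``.
    """

    source_channel: str
    target_channel: str
    phase_freq_hz: float = 6.0
    amp_freq_hz: float = 60.0
    strength_chi: float = 1.0
    preferred_phase_rad: float = 0.0
    noise_sd: float = 1.0
    phase_amp_uv: float = 10.0
    carrier_amp_uv: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength_chi <= 1.0:
            raise ValueError("strength_chi must lie in [0, 1]")
        if not self.phase_freq_hz < self.amp_freq_hz:
            raise ValueError("phase frequency must be below amplitude frequency")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-amplitude Gaussian noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]  # avoid division by zero at DC
    spec /= np.sqrt(freqs)
    pink = np.fft.irfft(spec, n)
    return pink / pink.std()


def generate_recording(
    montage: list[str] | tuple[str, ...] = MONTAGE_32,
    duration_s: float = 60.0,
    fs_hz: float = 250.0,
    couplings: list[CouplingSpec] | None = None,
    seed: int = 0,
    background_sd: float = 1.0,
    noise_color: str = "white",
) -> Recording:
    """Simulate a multichannel recording with planted phase-amplitude coupling.

    Every channel receives independent background noise (Gaussian white by
    default, ``noise_color="pink"`` for 1/f). For each coupling spec the
    source channel additionally carries a low-frequency oscillation and the
    target channel a high-frequency carrier whose envelope follows
    ``(1 + chi * cos(theta(t) - phi0)) / 2``, plus per-coupling Gaussian noise
    on the target.

    Raises if ``fs_hz`` is below four times the fastest amplitude frequency
    (comfortably above Nyquist) or a coupling names an unknown channel.
    """
    montage = list(montage)
    couplings = list(couplings or [])
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    for c in couplings:
        if c.source_channel not in montage:
            raise KeyError(f"unknown source channel {c.source_channel!r}")
        if c.target_channel not in montage:
            raise KeyError(f"unknown target channel {c.target_channel!r}")
        if fs_hz < 4.0 * c.amp_freq_hz:
            raise ValueError(
                f"fs {fs_hz} Hz below 4x amplitude frequency {c.amp_freq_hz} Hz"
            )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    sig = np.empty((len(montage), n))
    for i in range(len(montage)):
        noise = (
            _pink_noise(rng, n) if noise_color == "pink" else rng.standard_normal(n)
        )
        sig[i] = background_sd * noise
    for c in couplings:
        i_src = montage.index(c.source_channel)
        i_tgt = montage.index(c.target_channel)
        theta0 = rng.uniform(0.0, TWO_PI)
        theta = TWO_PI * c.phase_freq_hz * t + theta0
        slow = c.phase_amp_uv * np.cos(theta)
        envelope = (1.0 + c.strength_chi * np.cos(theta - c.preferred_phase_rad)) / 2.0
        carrier_phase0 = rng.uniform(0.0, TWO_PI)
        fast = c.carrier_amp_uv * envelope * np.cos(
            TWO_PI * c.amp_freq_hz * t + carrier_phase0
        )
        sig[i_src] += slow
        sig[i_tgt] += fast
        if c.noise_sd > 0:
            sig[i_tgt] += c.noise_sd * rng.standard_normal(n)
    return Recording(signal=sig, fs_hz=fs_hz, channel_names=montage)


# ---------------------------------------------------------------------------
# Trial events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialLayout:
    """Timing template of one trial: three images, a prompt, three clicks.

    Images are shown sequentially (1 s each, 1.5 s inter-stimulus interval),
    then a 1-s order prompt, then the response frame in which the three
    clicks occur; feedback and the inter-trial interval close the trial.
    Click latencies are drawn from a lognormal response-time distribution.
    """

    image_duration_s: float = 1.0
    isi_s: float = 1.5
    prompt_duration_s: float = 1.0
    feedback_s: float = 1.0
    iti_s: float = 1.0
    rt_log_mean: float = 0.9    # lognormal params for click2 - prompt (~2.5 s median)
    rt_log_sd: float = 0.25
    click_gap_s: float = 0.8    # mean gap between successive clicks

    def stimulus_span_s(self) -> float:
        return 3 * self.image_duration_s + 2 * self.isi_s + self.prompt_duration_s


def generate_events(
    recording: Recording,
    n_trials: int = 40,
    layout: TrialLayout = TrialLayout(),
    seed: int = 0,
    start_s: float = 2.0,
) -> Recording:
    """Attach per-trial annotations (image/prompt/click markers) to a recording.

    Returns the same Recording object with its annotation list populated:
    per trial ``image1..3``, ``prompt``, ``click1..3``, strictly increasing.
    ``n_trials = 0`` yields an empty annotation set. Raises if the trials do
    not fit within the recording duration.
    """
    rng = np.random.default_rng(seed)
    events: list[tuple[str, float]] = []
    t = start_s
    for _ in range(n_trials):
        for k in range(3):
            events.append((f"image{k + 1}", t))
            t += layout.image_duration_s
            if k < 2:
                t += layout.isi_s
        events.append(("prompt", t))
        rt2 = rng.lognormal(layout.rt_log_mean, layout.rt_log_sd)
        gap1 = rng.uniform(0.4, 1.2) * layout.click_gap_s
        gap3 = rng.uniform(0.4, 1.2) * layout.click_gap_s
        t_click2 = t + layout.prompt_duration_s + rt2
        t_click1 = max(t + layout.prompt_duration_s + 0.05, t_click2 - gap1)
        t_click3 = t_click2 + gap3
        events.append(("click1", t_click1))
        events.append(("click2", t_click2))
        events.append(("click3", t_click3))
        t = t_click3 + layout.feedback_s + layout.iti_s
    if t > recording.duration_s:
        raise ValueError(
            f"{n_trials} trials need {t:.1f} s but recording lasts "
            f"{recording.duration_s:.1f} s"
        )
    recording.annotations = events
    return recording


# ---------------------------------------------------------------------------
# Behavioral tables from a two-latent-factor model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorGenSpec:
    """Ground truth for response-time tables: one latent factor per task.

    Per participant, factor scores (eta1, eta2) come from a standard bivariate
    normal with correlation ``inter_factor_r``. A trial in partition k of task
    j has RT = task mean + loading_jk * eta_j + N(0, unique_sd). Four
    partitions per task, ``trials_per_partition`` trials each.
    """

    n_participants: int = 64
    loadings_task1: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)
    loadings_task2: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5)
    inter_factor_r: float = 0.65
    unique_sd: float = 0.4
    mean_rt_task1: float = 2.0
    mean_rt_task2: float = 3.3
    trials_per_partition: int = 10
    accuracy_task1: float = 0.93
    accuracy_task2: float = 0.90
    task_names: tuple[str, str] = ("maintenance", "manipulation")
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.inter_factor_r) > 1:
            raise ValueError("|inter_factor_r| must be <= 1")
        if self.unique_sd < 0:
            raise ValueError("unique_sd must be nonnegative")
        if self.trials_per_partition < 1:
            raise ValueError("trials_per_partition must be >= 1")
        if not all(np.isfinite(self.loadings_task1 + self.loadings_task2)):
            raise ValueError("loadings must be finite")


def generate_behavior(spec: BehaviorGenSpec = BehaviorGenSpec()) -> pd.DataFrame:
    """Draw a trial-level behavioral table from the two-factor RT model.

    Returns a DataFrame with columns participant_id, task, trial, rt_s,
    correct — the same layout the real-task tables use. RTs are floored at
    50 ms so the table never contains non-positive times.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.inter_factor_r
    cov = np.array([[1.0, r], [r, 1.0]])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    n = spec.n_participants
    n_per_task = 4 * spec.trials_per_partition
    eta = (chol @ rng.standard_normal((2, n))).T  # participants x factors
    task_params = (
        (spec.task_names[0], spec.mean_rt_task1, spec.loadings_task1, spec.accuracy_task1),
        (spec.task_names[1], spec.mean_rt_task2, spec.loadings_task2, spec.accuracy_task2),
    )
    pids = np.array([f"P{p + 1:03d}" for p in range(n)])
    trial_loading_idx = np.arange(n_per_task) // spec.trials_per_partition
    frames = []
    for j, (task, mean_rt, loadings, acc) in enumerate(task_params):
        lam = np.asarray(loadings, dtype=float)[trial_loading_idx]  # per trial
        rt = (
            mean_rt
            + eta[:, j : j + 1] * lam[None, :]
            + rng.normal(0.0, spec.unique_sd, size=(n, n_per_task))
        )
        rt = np.maximum(rt, 0.05)
        correct = rng.random((n, n_per_task)) < acc
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pids, n_per_task),
                    "task": task,
                    "trial": np.tile(np.arange(1, n_per_task + 1), n),
                    "rt_s": rt.ravel(),
                    "correct": correct.ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    # interleave back to participant-major order across both tasks
    return (
        out.sort_values(["participant_id", "task", "trial"], kind="stable")
        .reset_index(drop=True)
    )


def simulate_cohort_matrices(
    n_participants: int,
    n_channels: int = 8,
    mi_sd: float = 0.01,
    mi_mean: float = 0.02,
    planted: dict[tuple[int, int], float] | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Directly simulate per-participant cross-electrode MI matrices.

    A cheap stand-in for full signal simulation when calibrating the network
    statistics: each matrix entry is an independent truncated-at-zero
    Gaussian MI value; ``planted`` adds a fixed offset to chosen (source,
    target) entries. Under ``planted=None`` the directed contrast
    MI(A->B) - MI(B->A) has exactly zero mean for every pair (a fully null
    cohort).
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_participants):
        m = rng.normal(mi_mean, mi_sd, size=(n_channels, n_channels))
        if planted:
            for (i, j), delta in planted.items():
                m[i, j] += delta
        out.append(np.clip(m, 0.0, 1.0))
    return out
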