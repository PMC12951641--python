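"""Directed cross-electrode coupling networks with family-wise statistics.

A directed connection from electrode A to electrode B is the cross-electrode
modulation index: low-band (theta) phase at A modulating high-band (gamma)
amplitude at B. Per participant this yields a full channels x channels MI
matrix (the diagonal is within-electrode MI). The directed contrast

    dMI(A, B) = MI(A->B) - MI(B->A)

is antisymmetric by construction and is stored per unordered pair. Group
inference is a two-sided one-sample t-test of dMI against zero per pair,
with step-down Holm-Bonferroni control of the family-wise error rate over
all C(n, 2) pairs; surviving pairs become directed edges oriented by the
sign of the mean contrast, weighted by its magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .cfc import DEFAULT_N_BINS, mi_from_series, phase_bin_indices
from .signal_core import (
    GAMMA,
    THETA,
    AnalysisWindowSet,
    Band,
    Recording,
    bandpass_amplitude,
    bandpass_phase,
    whole_recording_windows,
    window_sample_mask,
)


@dataclass
class MIMatrix:
    """Per-participant cross-electrode MI matrix (source row -> target column)."""

    matrix: np.ndarray
    channel_names: list[str]
    participant: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        n = len(self.channel_names)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match channel count")
        if np.any((self.matrix < 0) | (self.matrix > 1)):
            raise ValueError("MI entries must lie in [0, 1]")


def mi_matrix(
    recording: Recording,
    phase_band: Band = THETA,
    amp_band: Band = GAMMA,
    windows: AnalysisWindowSet | None = None,
    n_bins: int = DEFAULT_N_BINS,
    participant: str = "",
    task: str = "",
) -> MIMatrix:
    """All ordered channel pairs' MI (diagonal = within-electrode).

    Phase and amplitude series are extracted once per channel on the
    continuous recording, windowed, and pre-binned; each of the n^2 entries
    then reduces to a weighted bin count, keeping the full-montage matrix
    cheap.
    """
    names = recording.channel_names
    n_ch = len(names)
    n_samp = recording.n_samples
    phases, amps, edges = [], [], []
    for name in names:
        ph, e1 = bandpass_phase(recording, name, phase_band)
        am, e2 = bandpass_amplitude(recording, name, amp_band)
        phases.append(ph)
        amps.append(am)
        edges.append(max(e1, e2))
    if windows is None:
        windows = whole_recording_windows(recording, max(edges))
    mask = window_sample_mask(windows, n_samp, recording.fs_hz)
    if not mask.any():
        raise ValueError("window selection produced zero samples")
    bin_idx = [phase_bin_indices(ph[mask], n_bins) for ph in phases]
    amp_w = [am[mask] for am in amps]
    mat = np.empty((n_ch, n_ch))
    log_n = np.log(n_bins)
    for i in range(n_ch):
        counts = np.bincount(bin_idx[i], minlength=n_bins).astype(float)
        for j in range(n_ch):
            sums = np.bincount(bin_idx[i], weights=amp_w[j], minlength=n_bins)
            mean_amp = np.divide(
                sums, counts, out=np.zeros(n_bins), where=counts > 0
            )
            p = mean_amp / mean_amp.sum()
            nz = p[p > 0]
            mi = (log_n + float(np.sum(nz * np.log(nz)))) / log_n
            mat[i, j] = min(max(mi, 0.0), 1.0)
    return MIMatrix(matrix=mat, channel_names=list(names), participant=participant, task=task)


# ---------------------------------------------------------------------------
# Holm-Bonferroni
# ---------------------------------------------------------------------------

def holm_bonferroni(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm-Bonferroni adjustment.

    Sorted ascending, p_(i) is compared against alpha / (m - i); adjusted
    p-values are (m - i) * p_(i) made monotone nondecreasing and capped at 1.
    NaN p-values (untestable pairs) never reject and adjust to NaN. Returns
    (adjusted p, reject mask).
    """
    p = np.asarray(pvals, dtype=float)
    m_valid = int(np.sum(~np.isnan(p)))
    adj = np.full_like(p, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if m_valid == 0:
        return adj, reject
    order = np.argsort(np.where(np.isnan(p), np.inf, p))
    running = 0.0
    still_rejecting = True
    for rank, idx in enumerate(order[:m_valid]):
        factor = m_valid - rank
        running = max(running, min(1.0, factor * p[idx]))
        adj[idx] = running
        if still_rejecting and p[idx] <= alpha / factor:
            reject[idx] = True
        else:
            still_rejecting = False
    return adj, reject


# ---------------------------------------------------------------------------
# Directionality inference
# ---------------------------------------------------------------------------

@dataclass
class DirectedEdge:
    source: str
    target: str
    mean_delta_mi: float
    t: float
    p_raw: float
    p_adj: float


@dataclass
class DirectionalityResult:
    """Group directionality statistics over all unordered channel pairs."""

    channel_names: list[str]
    pairs: list[tuple[int, int]]          # (i, j) with i < j
    delta_mi: np.ndarray                  # participants x pairs, dMI = MI(i->j) - MI(j->i)
    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    reject: np.ndarray
    edges: list[DirectedEdge]
    alpha: float
    task: str = ""

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def significant_pairs(self) -> set[tuple[int, int]]:
        return {pair for pair, rej in zip(self.pairs, self.reject) if rej}


def pair_delta_mi(matrices: list[MIMatrix]) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Per-participant directed contrasts for every unordered pair (i < j)."""
    if not matrices:
        raise ValueError("no matrices given")
    names = matrices[0].channel_names
    for m in matrices:
        if m.channel_names != names:
            raise ValueError("all matrices must share the montage order")
    pairs = list(combinations(range(len(names)), 2))
    delta = np.empty((len(matrices), len(pairs)))
    for k, m in enumerate(matrices):
        for q, (i, j) in enumerate(pairs):
            delta[k, q] = m.matrix[i, j] - m.matrix[j, i]
    return pairs, delta


def directionality(
    matrices: list[MIMatrix], alpha: float = 0.05, task: str = ""
) -> DirectionalityResult:
    """Holm-filtered directed network from per-participant MI matrices.

    Per unordered pair, the directed contrast dMI across participants is
    tested against zero (two-sided one-sample t-test); p-values are
    Holm-Bonferroni corrected over all pairs. Pairs with zero variance
    across participants are flagged (p = NaN) and never rejected.
    """
    if len(matrices) < 3:
        raise ValueError("need at least 3 participants")
    names = matrices[0].channel_names
    pairs, delta = pair_delta_mi(matrices)
    sd = delta.std(axis=0, ddof=1)
    t_vals = np.full(len(pairs), np.nan)
    p_vals = np.full(len(pairs), np.nan)
    ok = sd > 0
    if ok.any():
        res = stats.ttest_1samp(delta[:, ok], 0.0, axis=0)
        t_vals[ok] = res.statistic
        p_vals[ok] = res.pvalue
    n_flagged = int((~ok).sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} pairs had zero dMI variance; p undefined")
    p_adj, reject = holm_bonferroni(p_vals, alpha)
    mean_delta = delta.mean(axis=0)
    edges = []
    for q, (i, j) in enumerate(pairs):
        if not reject[q]:
            continue
        if mean_delta[q] > 0:
            src, tgt = names[i], names[j]
        else:
            src, tgt = names[j], names[i]
        edges.append(
            DirectedEdge(
                source=src,
                target=tgt,
                mean_delta_mi=float(abs(mean_delta[q])),
                t=float(t_vals[q]),
                p_raw=float(p_vals[q]),
                p_adj=float(p_adj[q]),
            )
        )
    return DirectionalityResult(
        channel_names=names,
        pairs=pairs,
        delta_mi=delta,
        t=t_vals,
        p_raw=p_vals,
        p_adj=p_adj,
        reject=reject,
        edges=edges,
        alpha=alpha,
        task=task,
    )


@dataclass
class TaskContrastResult:
    """Paired comparison of directionality between two tasks."""

    channel_names: list[str]
    pairs: list[tuple[int, int]]
    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    reject: np.ndarray
    directionality_task1: DirectionalityResult
    directionality_task2: DirectionalityResult
    exclusive_task1: list[DirectedEdge]
    exclusive_task2: list[DirectedEdge]


def task_contrast(
    matrices_task1: list[MIMatrix],
    matrices_task2: list[MIMatrix],
    alpha: float = 0.05,
) -> TaskContrastResult:
    """Pairwise paired t-tests of directionality between tasks + exclusive edges.

    Per unordered pair, the per-participant dMI values of the two tasks are
    compared with a paired t-test, Holm-Bonferroni corrected. Exclusive
    edges are those significant in one task's Holm-filtered directionality
    network whose unordered pair is not significant in the other's.
    """
    if len(matrices_task1) != len(matrices_task2):
        raise ValueError("paired design requires equal cohort sizes")
    pairs1, d1 = pair_delta_mi(matrices_task1)
    pairs2, d2 = pair_delta_mi(matrices_task2)
    if pairs1 != pairs2:
        raise ValueError("montages differ between tasks")
    diff = d1 - d2
    sd = diff.std(axis=0, ddof=1)
    t_vals = np.full(len(pairs1), np.nan)
    p_vals = np.full(len(pairs1), np.nan)
    ok = sd > 0
    if ok.any():
        res = stats.ttest_rel(d1[:, ok], d2[:, ok], axis=0)
        t_vals[ok] = res.statistic
        p_vals[ok] = res.pvalue
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} pairs had zero dMI variance; p undefined")
    p_adj, reject = holm_bonferroni(p_vals, alpha)
    dir1 = directionality(matrices_task1, alpha, task="task1")
    dir2 = directionality(matrices_task2, alpha, task="task2")
    sig1, sig2 = dir1.significant_pairs(), dir2.significant_pairs()
    name_to_pair = {}
    for e_list, d_res in ((dir1.edges, dir1), (dir2.edges, dir2)):
        for e in e_list:
            i = d_res.channel_names.index(e.source)
            j = d_res.channel_names.index(e.target)
            name_to_pair[(e.source, e.target)] = (min(i, j), max(i, j))
    excl1 = [e for e in dir1.edges if name_to_pair[(e.source, e.target)] not in sig2]
    excl2 = [e for e in dir2.edges if name_to_pair[(e.source, e.target)] not in sig1]
    return TaskContrastResult(
        channel_names=matrices_task1[0].channel_names,
        pairs=pairs1,
        t=t_vals,
        p_raw=p_vals,
        p_adj=p_adj,
        reject=reject,
        directionality_task1=dir1,
        directionality_task2=dir2,
        exclusive_task1=excl1,
        exclusive_task2=excl2,
    )


def strongest_modulators(
    matrices: list[MIMatrix], target_channel: str, k: int = 3
) -> list[tuple[str, float]]:
    """Top-k source channels by group-mean MI(source -> target).

    The target itself is excluded; ties break deterministically by montage
    order (earlier channel wins).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    names = matrices[0].channel_names
    tgt = names.index(target_channel) if target_channel in names else None
    if tgt is None:
        raise KeyError(f"unknown channel {target_channel!r}")
    group = np.mean([m.matrix for m in matrices], axis=0)
    col = group[:, tgt]
    order = sorted(
        (i for i in range(len(names)) if i != tgt), key=lambda i: (-col[i], i)
    )
    return [(names[i], float(col[i])) for i in order[:k]]


def to_digraph(result: DirectionalityResult):
    """Directed significance network as a networkx DiGraph (GraphML-exportable)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(result.channel_names)
    for e in result.edges:
        g.add_edge(
            e.source,
            e.target,
            weight=e.mean_delta_mi,
            t=e.t,
            p_raw=e.p_raw,
            p_adj=e.p_adj,
        )
    return g
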