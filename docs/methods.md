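# Methods

## The measurement problem

Working memory is usually decomposed into *maintenance* (retaining content
over seconds) and *manipulation* (actively transforming it). The package
operationalizes two complementary probes of that distinction:

1. a **neural** probe — theta–gamma phase-amplitude coupling (PAC), within
   and across electrodes, summarized by a modulation index and by directed
   coupling networks; and
2. a **psychometric** probe — whether response-time (or per-segment MI)
   indicators from the two task types are better described by one latent
   factor or by two correlated factors.

Everything is exercised against synthetic data whose coupling strength,
directionality and latent structure are known exactly.

## Modulation index

For a phase series φ(t) (theta band, 4–8 Hz) and an amplitude series A(t)
(gamma band, 40–80 Hz), amplitudes are binned by phase into N = 18 equal
bins over [−π, π) (left-closed, +π wrapping to −π). With mean amplitude
⟨A⟩ⱼ per bin and P(j) = ⟨A⟩ⱼ / Σₖ⟨A⟩ₖ,

    MI = (log N − H(P)) / log N,   H(P) = −Σⱼ P(j) log P(j),

with natural logarithms and the convention 0·log 0 = 0. MI ∈ [0, 1]; it is
invariant to amplitude rescaling and equals 0 iff P is uniform. An empty
bin contributes 0 to the entropy (the continuity limit) and is logged,
since it signals too little data.

Phase and amplitude come from zero-phase (forward–backward) FIR band-pass
filters — Hamming design, transition width 25% of the lower band edge —
followed by the analytic signal. Filtering is always applied to the
*continuous* recording; trial windows are cut out afterwards, so
concatenation joins cannot create artificial phase jumps, and one filter
length at each recording edge is excluded. Phase uses the cosine
convention (0 = oscillation peak), half-open intervals in seconds map to
sample indices via floor(t·fs).

Analysis windows run from 500 ms after the response prompt (excluding
sensory processing of the prompt) to the second button click; trials whose
second click precedes the window start are dropped with a warning. For the
per-segment indicators used in factor models, the concatenated series is
split into three contiguous equal-length segments, each segment's MI is the
mean over its full 5-second bins, and a trailing partial bin is discarded.
Contiguous thirds (rather than trial-block thirds) were chosen because the
concatenated series is the object the MI is defined on; the alternative
makes no difference for stationary couplings.

## Synthetic recordings

`generate_recording` plants couplings of the standard amplitude-modulation
form: the source channel carries a theta oscillation (default 6 Hz, 10 µV)
whose phase θ(t) drives the target channel's gamma carrier (default 60 Hz,
4 µV) through the envelope

    (1 + χ·cos(θ(t) − φ₀)) / 2,    χ ∈ [0, 1],

plus independent Gaussian white channel noise (1 µV by default; 1/f "pink"
noise is available but white keeps analytic expectations simple). χ = 0
yields a constant-envelope carrier and MI at the noise floor; the MI
response is continuous and monotone in χ. Within-electrode coupling is the
source = target special case. The default montage is the standard
32-channel 10–20 set. A sampling rate of at least 4× the carrier frequency
is enforced (default 250 Hz, matching common down-sampled EEG). Event
generation lays out the task's trial timeline (three 1-s images with 1.5-s
inter-stimulus intervals, a 1-s prompt, three clicks with lognormal
response times, feedback and inter-trial gaps); 40 trials per task is the
reference session length.

What the generator does *not* emulate: volume conduction and channel
covariance, 1/f background (by default), non-stationarity, ocular/muscle
artifacts, or biophysically realistic sources. Passing recovery tests on
these signals therefore demonstrates correctness of the estimators, not
robustness to real-world EEG artifacts — artifact handling is assumed to
have happened upstream.

## Comodulogram and permutation null

MI is recomputed over a grid of phase bands (3–10 Hz, 1 Hz wide) ×
amplitude bands (30–80 Hz, 10 Hz wide). The null reference shuffles each
participant's 35 cell values uniformly over the matrix (1000 permutations
by default), pools the permuted group-average cells, and masks observed
group-average cells above null mean + 3 SD.

**Known limitation.** The cell-shuffle null assumes the 35 cells are
exchangeable under no coupling. They are not, quite: the KL-MI estimator
has a positive small-sample bias that grows as the phase frequency falls
(a 3–4 Hz band completes ~2.7× fewer cycles than a 9–10 Hz band in the
same window, so its bin means are noisier), producing a systematic bias
relief across the grid. Empirically the bias ratio between the lowest and
highest phase rows is ~9 and is invariant to recording duration, so under
χ = 0 the mask flags the most-biased (3–5 Hz phase) cell in most
single-participant maps — about 2.5–3% of cells, i.e. roughly one cell per
7×5 map, where perfect calibration would flag ~0. Group averaging makes
this *worse* (≈14%), because it shrinks noise but not the systematic bias.
One stray cell is already 1/35 ≈ 2.9%, so coverage criteria below that
granularity cannot be met by this null scheme; the corresponding
acceptance check is left failing rather than altering the prescribed
procedure. Peak localization is unaffected: with genuine coupling the
planted (6 Hz, 60 Hz) neighborhood dominates the mask.

## Directed networks

Entry (i, j) of a participant's 32×32 matrix is MI(channel i phase →
channel j amplitude); the diagonal is within-electrode MI. For each of the
496 unordered pairs the directed contrast ΔMI = MI(A→B) − MI(B→A)
(antisymmetric by construction) is tested against zero with a two-sided
one-sample t-test across participants; p-values are corrected by
step-down Holm–Bonferroni (implemented from definition, cross-checked
against statsmodels), requiring at least 3 participants. Significant pairs
become directed edges oriented by the sign of the mean contrast and
weighted by its magnitude. Zero-variance pairs are flagged and never
rejected. Task comparisons use paired t-tests on the per-pair contrasts,
again Holm-corrected; "exclusive" edges are significant in one task's
network and not the other's. Family-wise error calibration on fully null
cohorts uses directly simulated MI matrices (i.i.d. truncated-Gaussian
entries), which is exact for the statistic — it operates on matrices —
and cheap enough for 500 replicate cohorts.

## Phase-aligned time-frequency maps

Each 1-s epoch is transformed with an analytic generalized Morse wavelet,
symmetry γ = 3 and time–bandwidth product P = βγ = 60 (β = 20), evaluated
in the frequency domain over geometrically spaced frequencies (12 voices
per octave, 2 to ≥ 90 Hz). Epoch maps are circularly shifted along time by
−(φ/2π)/f_low seconds — earlier theta phase moves rightward — using the
theta phase at the epoch midpoint as the reference (the reference sample
is otherwise arbitrary; the midpoint minimizes edge sensitivity), rounded
to the nearest sample, then averaged. Circular shifting preserves map
energy and never touches the frequency axis. Analysis windows are tiled
into non-overlapping 1-s epochs with any trailing partial epoch dropped.

## Factor models

Indicators are per-participant medians: median RT of each of four
10-trial partitions per task (by trial order), or median RT per memory set
size (3–7) for the complex-span task, or the three per-segment MI values.
Participants are excluded when accuracy falls below 80% in *both*
working-memory tasks (failing one is retained) or when mean RT deviates
more than 4 SD from the group mean; RTs are used untransformed.

The confirmatory model is fit by maximum likelihood on the sample
covariance matrix S (ddof = 1), minimizing

    F(θ) = log|Σ(θ)| + tr(S Σ(θ)⁻¹) − log|S| − p,
    Σ(θ) = Λ Φ Λᵀ + Ψ,

with simple-structure loadings Λ, diagonal uniquenesses Ψ ≥ 0, and factor
variances fixed at 1 so inter-factor correlations in Φ are free — the
identification that yields df = 19 (two-factor) and df = 20 (one-factor)
for 8 indicators. χ² = (n − 1)·F at the optimum. Optimization is L-BFGS-B
with numerical gradients from three starting points (one analytic —
loadings at half the indicator SD — plus two jittered). The inter-factor
correlation is bounded in [−1, 1] *inclusive*: the one-factor model is the
φ = 1 boundary of the two-factor space, and an open bound would break the
nesting that the χ² difference test requires (this surfaced as spurious
negative differences before the bound was widened). Uniquenesses pinned at
zero are flagged as Heywood cases; non-converged fits carry no χ². Under a
true single factor the difference statistic sits on that boundary, so its
null is a ½·0 + ½·χ²(1) mixture and the nominal α = 0.05 test realizes a
type-I rate near 0.025 — inside the accepted [0.02, 0.09] calibration
band. Split-half consistency uses deterministic participant splits
(odd/even by sorted position, or first/second half); trial-level splits
(e.g. by MI magnitude) go through a within-participant median split with
ties to the low half.

Exploratory factor analysis, fit indices beyond χ²/df, and multi-construct
structural models are out of scope; established SEM tooling should be used
for those.

## Simulation sizes used by the acceptance checks

Chosen to keep the whole suite within a desktop compute budget while
leaving comfortable statistical margins: coupling recovery uses 10 seeds ×
60-s single-channel recordings per χ ∈ {0, 0.5, 1}; directionality
recovery uses 20 participants × 40-s full-montage recordings with a
planted FT9→Cz coupling, and 500 directly simulated 8-channel null cohorts
for the family-wise error rate; factor-structure checks use n = 200
participants with 100 replicates (power at inter-factor r = 0.65) and 500
replicates (type-I at r = 1); the motor-window control uses cohorts of 8
participants each completing the full 40-trial session (~540 s), where
motor (~24 s) and non-motor (~100 s) segments are long enough that both MI
estimates share the same small-sample bias — with sessions much shorter
than the task's 40 trials the motor estimate is bias-inflated and the
nominally null comparison over-rejects.
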