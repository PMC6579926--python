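# Methods

`dfcstates` implements a dynamic functional connectivity (DFC) pipeline for
multichannel electrophysiological ROI time series: band decomposition →
window-wise dominant-coupling-mode graphs → topological filtering →
Laplacian spectra → vector-quantized microstates → Markov-chain
chronnectomics → reconstruction-error classification.  This note records
the models, the numerical choices, and what the synthetic benchmarks do and
do not demonstrate.

## Band decomposition and windows

Broadband signals are split into eight rhythms — δ (1–4 Hz), θ (4–8),
α₁ (8–10), α₂ (10–13), β₁ (13–20), β₂ (20–30), γ₁ (30–49), γ₂ (51–90) —
with zero-phase (forward–backward) Butterworth band-pass filters of
one-directional order 4.  Phase fidelity is the design goal: forward–
backward filtering has no group delay, and the phase of a pure tone is
invariant to amplitude scaling.  Instantaneous phase and amplitude come
from the analytic signal (Hilbert transform).

One full cycle of the slowest band's low edge (1 s at the 1 Hz δ edge) is
flagged as an *edge margin* at both ends of every recording; filter startup
and Hilbert edge artifacts corrupt the phase there, so the sliding-window
grid is laid out on the trimmed interior only.

Windows default to the 1 s width / 50 ms step of the underlying method.
At a 250 Hz sampling rate 50 ms is 12.5 samples; start positions are
computed as `floor(i·step·fs)` so that the grid advances at the nominal
rate on average and the closed-form window count
`floor((n − width·fs)/(step·fs)) + 1` holds at any sampling rate (a fixed
integer-sample step would drift by 4% here).

## Coupling modes and the iPLV

For every ROI pair and window, 36 potential coupling modes are evaluated:
8 within-band phase couplings and 28 phase-to-amplitude couplings, one per
unordered band pair with the lower band as modulator.  The estimator is
the imaginary part of the phase-locking value,

    iPLV = | Im( (1/T) Σ_t exp(i(φ_a(t) − φ_b(t))) ) |,

which is insensitive to zero-lag synchronization by construction.  For
phase-to-amplitude coupling, the high band's amplitude envelope is
band-passed inside the low band and its analytic phase enters the iPLV
against the other ROI's low-band phase.  Envelope phases are extracted
once per recording rather than per window, confining filter transients to
the recording edges that the margin already excludes.  A cross-frequency
mode does not fix which ROI supplies the phase and which the envelope, so
both direction assignments are computed and the larger value is used,
keeping the connectivity matrices symmetric and detecting a modulation
planted in either direction.

### Surrogate filtering and the dominant mode

The null for each pair is built by circularly time-shifting every series
belonging to the second ROI by a random offset of at least one window
width.  Shifts act on the margin-trimmed interior, and a surrogate value
whose window spans the circular seam (where the shifted series is
discontinuous) is excluded from the null: seam-spanning windows mix two
unrelated stretches, deflate the null, and measurably inflate the
false-positive rate.  P-values follow the exact permutation convention
p = (r+1)/(n_valid+1), with family-wise control across the 36 modes by the
max-statistic: each surrogate contributes its maximum across modes, and a
mode is significant when p ≤ α (α = 0.05 by default; 99 surrogates at desk
scale, configurable to 10⁴).  The dominant mode of a pair/window is the
significant mode of largest iPLV, ties resolved to the lower mode index,
and mode 0 (strength 0) when nothing is significant.  The p ≤ α
convention (rather than strict <) lets the minimal attainable p of
1/(n+1) count as significant for small surrogate counts; the realized
family-wise rate stays at or below α because the comparison is exact.

The engine computes, per pair and mode, sin(φ_a − φ_b) from float32
sin/cos tables; window sums accumulate in float64 via `reduceat` (disjoint
grids) or a cumulative sum (overlapping grids).  Per-window values are
exact window means, so evaluating any subset of the window grid is
bit-identical to the batch run, and the full 4-D mode × window × ROI × ROI
tensor is never materialized.

## Topological filtering (OMST) and Laplacian spectra

Each snapshot's significant-coupling matrix is sparsified with orthogonal
minimal spanning trees: successive edge-disjoint MSTs on the distance
transform d = 1/w are unioned round by round, and the round count
maximizing the global cost efficiency GCE(m) = GE(m) − Cost(m) is kept
(GE: mean inverse shortest-path distance over ordered pairs; Cost:
selected fraction of total weight).  Weights are normalized to unit
maximum before the distance transform; without this the GE term scales
with the weights while Cost does not, and the selection would depend on an
arbitrary global scale.  All rounds up to N−1 (or edge exhaustion) are
evaluated; an early-stop heuristic (`patience`) exists but is off by
default because the exhaustive sweep is cheap at these graph sizes and is
what the brute-force test oracle checks.  Disconnected inputs are filtered
per component (spanning forests) with a warning.

Each filtered graph is summarized by the ascending eigenvalues of
L_sym = D^{−1/2}(D − A)D^{−1/2}; isolated nodes have their row/column set
to zero and contribute eigenvalue 0, so zero-multiplicity equals the
number of connected components.  Eigenvalues are sorted ascending (the
sort direction is not dictated by the method; ascending is this package's
convention).  Stacking columns over windows yields the N × W eigenvalue
time series fed to the microstate model.

## Microstates, classification, chronnectomics

Group codebooks of k prototype spectra (k = 3 by default) are trained with
the neural-gas algorithm on the column-wise concatenation of the group's
eigenvalue series: for every sample, prototype r moves by
ε·exp(−rank_r/λ)·(x − w_r), with λ: k/2 → 0.01 and ε: 0.5 → 0.005 decayed
exponentially over 50 epochs; 5 random restarts keep the best final mean
squared quantization error.  Eigenvalues are used raw — they are already
scale-bounded in [0, 2] — with no per-subject normalization.  Encoding
assigns each window to its nearest prototype (Euclidean; ties to the
lower index), and an unlabeled subject is assigned to the group whose
codebook rebuilds its eigenvalue series with the smaller mean squared
error (exact ties are flagged indeterminate rather than guessed).

From the symbolic sequence: transition counts row-normalized to P (the
row-stochastic convention; the alternative global normalization
contradicts row sums of one), fractional occupancy, mean dwell time over
maximal runs (reported in segments and seconds since the unit is
convention), flexibility FI (fraction of consecutive windows that switch),
and a complexity index CI defined here as the number of distinct words of
lengths 1..L (overlapping windows, L = 4 by default) divided by the mean
richness of label-shuffled surrogates.  Shuffle surrogates (uniform
permutations) give p = (r+1)/(n+1) per measure; occupancy is permutation-
invariant, so its surrogate p is identically 1 — the implementation
exposes this degeneracy rather than hiding it.  The significant-transition
digraph keeps entries with p < α without renormalizing.

## The synthetic generator

Each ROI carries at most one oscillator per band.  An oscillator is a
frequency-modulated carrier: band carriers are spread deterministically
over the central 60% of the band and assigned to ROIs at random, and every
carrier wobbles as a smoothed Gaussian frequency modulation (0.4 Hz RMS
deviation, 2 Hz modulation bandwidth).  Both choices are what make the
surrogate test meaningful at 1 s windows:

* two independent same-band oscillators closer than ≈0.3 Hz are
  indistinguishable from a locked pair within a single window (the phase
  difference barely rotates), so regional peak-frequency dispersion — a
  robust property of real rhythms — is required for the null to be
  informative;
* a pure drifting tone stays coherent with any time-shifted copy of
  itself over windows much shorter than its inverse linewidth, so the
  carrier must wobble on sub-window timescales.

Both parameters keep ≥ 80% of each oscillator's band power within ±1 Hz
of its carrier.  Oscillators are expressed only where the state repertoire
engages them (`active_bands="auto"`; `"all"` restores blanket tones), over
an always-present −30 dB white background that keeps every band's
analytic phase defined and carries no coupling.  Narrow bands (δ, α₁, α₂)
cannot host many frequency-separated oscillators — a 2 Hz band has no room
for ten carriers spaced 0.3 Hz apart without bleeding into its neighbors —
so dense network states belong in the wide bands.

A hidden Markov schedule switches the active state once per one-second
segment.  Intra-frequency couplings share a latent phase process: the
couplings of a band form a forest per state (each ROI/band may be the
target of at most one coupling; cycles are rejected), every member
inherits the root oscillator's phase minus its accumulated lag (π/2 by
default, where the iPLV is maximal), and partial strength s mixes shared
and private oscillators with amplitude weights (s, √(1−s²)).
Phase-to-amplitude couplings multiply the target's high-band signal by
(1 + s·cos(φ_low − lag))/√(1+s²/2).  White noise is added at a
configurable SNR on each ROI's total signal variance (20 dB default).
The ground-truth record carries the schedule, realized carriers, and per
state both the *expected adjacency* (pairwise |sin Δlag|-weighted
couplings an ideal detector would report) and its OMST-filtered Laplacian
eigen-profile.

What the generator does **not** emulate: 1/f broadband spectra, volume
conduction and field spread, nonstationary amplitude dynamics, and
inter-subject anatomical variability.  Passing benchmarks therefore
demonstrate the pipeline's internal consistency and statistical
calibration on its own generative model, not clinical performance.

## Reference studies and problem sizes

Two studies (module `dfcstates.experiments`) exercise everything
end to end; sizes were fixed once so a full run stays within minutes on a
single CPU:

* **Planted-coupling benchmark**: 10 ROIs, 30 s, noiseless, one constant
  state planting θ–θ, α₁–α₁ and θ→γ₁ couplings at strength 1; 99
  surrogates, windows 1 s / 0.25 s.  Sensitivity is the fraction of
  (planted pair, window) cells whose dominant mode equals the planted
  mode; the false-positive rate is the fraction of non-zero dominant
  modes on the 42 uncoupled pairs.
* **Two-group study**: two repertoires of three network states each, all
  spanning trees over the 10 ROIs chosen for pairwise-distinct Laplacian
  spectra (star, double stars, path, star chain, spider), both groups
  sharing the schedule transition matrix (0.6 stay / 0.2 switch).  10
  training and 10 blind subjects per group, 58 one-second segments per
  subject at 20 dB SNR, window step = width = 1 s so each symbol aligns
  with one generator segment.  Outputs: blind accuracy (reconstruction-
  error classification of the 20 blind subjects), the pooled
  transition-matrix estimate against the generating one (after matching
  learned prototypes to ground-truth profiles by minimal assignment), and
  the prototype matching error relative to the mean inter-profile
  distance.

State graphs are spanning trees deliberately: a weak spurious edge on a
connected graph perturbs the spectrum continuously, whereas an edge
bridging two components jumps a zero eigenvalue, and OMST returns a
spanning tree unchanged, making the expected eigen-profiles exact.  Their
edges live in the wide bands (β₁ and up): a hard coupling switch at a
segment boundary excites the band-pass filters, and the ring-out lasts a
substantial fraction of a window in θ but well under 0.1 s from β₁
upward, so wide-band edges keep their observed iPLV near the ceiling even
in windows adjacent to a state switch.

## Known limitations

* The surrogate test's power depends on the generator's frequency
  dispersion; two genuinely identical-frequency uncoupled oscillators
  cannot be separated from a locked pair within one window by any
  time-shift surrogate.
* The complexity index is one reasonable instantiation of "word richness
  up to length L"; other definitions exist and are not interchangeable.
* Dwell-time units, eigenvalue sort direction, the raw-versus-normalized
  eigenvalue question and the PAC direction convention are method
  conventions chosen and documented here, not forced by the mathematics.
* `k = 3` microstates is a configuration default, not a model-selection
  result; no claim is made about how many states real data support.
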