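# Methods

## The branching cellular automaton

The generative model is a network of `n = grid_rows × grid_cols` automata
(default 10×10, matching a 96/100-channel microelectrode array). Each site
cycles through 11 states: 0 quiescent, 1 active, 2–10 refractory, advancing
deterministically `x → (x+1) mod 11` once non-quiescent. Each site sends
`k = 16` connections to distinct, randomly chosen other sites (no
self-connections, drawn once per run). A quiescent site fires at `t+1` if at
least one active pre-synaptic neighbour transmits at `t`, each connection an
independent Bernoulli with probability `P`; the default `P = 1/k` makes the
expected first-generation offspring of an isolated active site exactly 1
(critical branching). Because every row of the transmission matrix sums to
exactly `k·P = 1`, the linearized dynamics have spectral radius 1 regardless
of the particular wiring draw. The model time step is 2 ms, so the 9
refractory states impose an 18 ms silent period after each activation.

Baseline activity seeds a single random site in a fully quiescent network and
propagates the cascade to extinction; the next initiation waits a random
quiescent interval *and* full network quiescence (deferred initiation), which
preserves the separation of time scales that makes the cluster definition
unambiguous. The default quiescent-interval model is lognormal with median
40 ms and log-scale σ = 1 (mean ≈ 66 ms). This is a synthetic stand-in for an
empirical inter-avalanche-interval distribution: the median is chosen so the
array-wide event rate (≈ 85 events/s, fixed Δt ≈ 12 ms) sits in the range
reported for primate arrays (Δt of order 5–10 ms), and the lognormal shape
gives the right-skewed interval distribution typical of such data. An
empirical sample of intervals can be supplied instead
(`quiescent_model=("empirical", samples)`).

### Drive regimes

Trial-locked rate transients (trial span −0.8…0.4 s, drive window
−0.35…−0.05 s, symmetric triangular ramp with the break at the window
midpoint) come in three flavors:

- **input_driven** — independent per-site Poisson inputs at rate h(t)
  (peak `h_max`, default strong level 6.5 s⁻¹) that activate quiescent sites
  and so trigger or join cascades. Inputs landing on refractory or active
  sites are discarded, consistent with the automaton's transition rule.
- **supercritical** — the transmission probability is multiplied by a
  modifier ramping 1 → peak → 1 (strong level 2.5); the config validator
  rejects `modifier × P > 1`.
- **poisson_noise** — per-site Poisson events at the input-driven rates
  (strong level 35 s⁻¹) that are appended to the event log but never touch
  the network. Noise draws use an RNG stream independent of the network's,
  so switching the noise on or off leaves the network trajectory bit-for-bit
  unchanged under a shared seed (a tested invariant).

Ground-truth avalanche labels follow causal ancestry of the seed; cascades
merged by drive inputs share a label (union-find over parent labels). Labels
exist only so tests can compare pipeline output with known cluster
membership; the analysis never uses them.

Event times on the 2 ms grid are optionally jittered by ±1 ms (half a step,
uniform) before binning, which de-discretises the event stream so adaptive
Δt below the model step does not artificially split cascades.

### Finite-size behaviour of the exponent

The size distribution of seeded cascades in the 10×10 network follows a
power law with a sharp cutoff at `s0 ≈ 55` (max observed size ≈ 90 < n). The
maximum-likelihood exponent at this scale is α ≈ 1.28–1.30, below the
ideal branching value 3/2, and this is a genuine property of the desk-scale
model, not of the estimator: (i) the same fit applied to exact critical
Galton–Watson samples (Otter–Dwass probabilities) truncated at s = 96 yields
α ≈ 1.32, because the head of a branching-process law deviates from a pure
power law at s ≤ 3 while the support ends before the asymptotic regime is
reached; (ii) the estimator recovers α = 1.498–1.500 on genuine sharp-cutoff
power-law samples over the same support; (iii) the fitted exponent climbs
toward 3/2 as the network grows (≈ 1.34, 1.37, 1.41 at 14², 20², 30² sites
with k = 16). Mechanistically, once ~10 sites are active per step the 9-step
refractory pool blocks most of the 100-site network, so cascades that free
branching would carry beyond s ≈ 50 die at s ≈ 15–45; that redistributed
tail mass flattens the maximum-likelihood slope. Analyses that quote the
model's exponent should therefore expect ≈ −1.3 at 100 sites, approaching
−1.5 only in larger networks.

## LFP synthesis

Background noise is white Gaussian filtered to 1–100 Hz (second-order
Butterworth, forward-backward) and normalised to unit SD per channel;
injected nLFP-like deflections are negative half-cosines (default width
20 ms — chosen so each deflection has a unique minimum for peak-time
extraction) with amplitudes drawn uniformly in −4.5…−2.5 SD so events
straddle a −2 SD detection threshold realistically. Deflection times are
inhomogeneous Poisson via thinning; candidates closer than the template
width to the previous event on a channel are dropped (warned and counted).
What the synthesizer does **not** emulate: 1/f spectral shape beyond the
band limit, line noise and artifacts, non-Gaussian heavy tails, and
cross-channel correlation of the background. Consequently a −2 SD threshold
on the synthetic background fires at the Gaussian-tail rate (~7 events/s per
channel); detection tests therefore validate recall against ground truth and
rate *ratios*, and passing them shows the detector's logic is correct — not
that false-positive rates on real, non-Gaussian LFP will be this benign.

The coupled-oscillation generator mixes a common band-limited component into
independent per-channel components with weight `coupling` (linear weights,
so coupling 1 ⇒ identical channels ⇒ Kuramoto R = 1). A profile variant
varies the weight smoothly over time for epoch-contrast fixtures without
signal discontinuities.

## Detection

Fixed thresholding: per channel, threshold = mean − `thr_sd`·SD with both
moments over the whole recording (including task epochs); each maximal
contiguous sub-threshold excursion yields one event at its most negative
sample; amplitudes are stored mean-subtracted (and are therefore strictly
below the negative threshold — a tested invariant). Adaptive thresholding
recomputes mean/SD in consecutive non-overlapping 100 ms windows (trailing
partial window uses its own statistics); the per-sample threshold is the
window step function, and an excursion spanning a boundary is assigned to
the window containing its minimum. No refractory period is imposed between
events: the contiguous-excursion rule already yields one event per crossing.
Zero-variance channels are skipped with a warning.

## Binning and clustering

Fixed Δt = analyzed time / array-wide event count. Adaptive Δt is computed
per (trial, epoch): epoch duration / event count in that cell; cells with no
events have no Δt and contribute no avalanches (counted and warned).
Clusters are maximal runs of consecutive occupied bins; under fixed binning
over full trials, bins anchor at the trial start and clusters may span epoch
boundaries (epoch label = epoch of the first event; an `anchor="epoch"`
flag re-anchors per epoch instead); under adaptive binning each epoch is
clustered independently — with different Δt on each side of a boundary a
spanning cluster would be ill-defined. Avalanche duration is (occupied-bin
span)·Δt. Event conservation (Σ sizes = event count, any Δt), the Δt → 0 and
Δt → ∞ limits, monotonicity of cluster count in Δt, and equivalence with a
brute-force bin-scanning oracle on 1000 random rasters are all enforced by
tests.

## Shuffle statistics and controls

Rate/size time courses use a 100 ms window sliding in 50 ms steps (matching
the PSTH convention and epoch granularity; the choice is ours — only the
epoch lengths are prescribed). Each time point is compared two-sided against
100 shuffle sets — sizes permuted across avalanches (times kept) for the
size null, times redrawn uniformly within the trial for the rate null —
with p = (1 + #shuffles-as-extreme)/(1 + 100), which cannot reach zero.
The shift predictor permutes the trial order independently per electrode,
preserving every electrode's trial-averaged rate profile exactly while
destroying within-trial cross-electrode correlations. Rate splits use the
median of per-trial epoch event counts with deterministic (count, trial-id)
ordering for ties. Per-trial mean-size differences between two epochs are
compared across binning modes with a two-sample Kolmogorov–Smirnov test at
p ≤ 0.05; trials lacking avalanches in either epoch are excluded and
counted.

## Size-distribution inference

All likelihoods are discrete on integer support `[s_min, s_max]`, default
`s_min = 1` and `s_max` = observed maximum. The sharp-cutoff power law
`p(s) = C·s^(−α)·exp[−(s/s0)^γ]` is fitted by bounded L-BFGS-B over
(α ∈ [0.5, 3], s0 ∈ [2, 2·s_max] log-parameterised, γ ∈ [0.1, 10]
log-parameterised) from a 27-point coarse grid of starts; the fit is
deterministic given the sample. The normalization identity
Σ p(s) = 1 (±10⁻¹⁰) is asserted for every fit. The exponential null
`p(s) ∝ e^(−λs)` uses bounded scalar minimisation.

The likelihood-ratio statistic is reported as D = −2[ln L_pl − ln L_alt].
Its p-value is the upper chi-squared tail of the *signed* statistic
2(ln L_pl − ln L_alt): p < 10⁻⁵ means the power law is strongly favored,
1 − p < 10⁻⁵ means the alternative is (the tail of a negative argument is
exactly 1). Degrees of freedom default to the free-parameter difference
(3 − 1 = 2 for power law vs exponential; 3 for cross-distribution
comparisons) and are exposed as a parameter since the convention is not
uniquely determined. For comparing a sample against a *reference* power-law
fit, the statistic 2(ln L_own − ln L_ref) ≥ 0 is referred to the chi-squared
*lower* tail, reproducing the source convention in which p ≤ 0.05 flags the
distributions as significantly **similar** (the reference explains the
sample nearly as well as its own MLE); this inverted reading is preserved
deliberately rather than reinterpreted.

Bootstrap confidence bands resample the original number of avalanches with
replacement (default B = 1000) and take per-size 2.5/97.5 percentiles of the
density. Normalized curves multiply the density by `s^α_ref`; the tail area
for s > 20 (trapezoidal) quantifies excess or deficit of large avalanches,
with its SD from the same bootstrap.

## Spike statistics

PSTH: 250 ms windows in 50 ms steps, trial-averaged rate in Hz. Surrogates
permute inter-spike intervals within each (unit, trial), with the interval
from the trial start to the first spike in the pool, conserving spike count
and final spike time exactly; windows in the top/bottom 2.5 % of the
surrogate rate distribution are flagged (default 1000 surrogates; the count
is a free choice). Units with fewer than 3 spikes per trial on average are
skipped. The Fano factor per 100 ms window (40 ms steps) is the OLS slope of
across-trial count variance on mean, one point per unit, free intercept by
default (a zero-intercept flag exists); the 95 % CI comes from the slope's
standard error. Mean-matching greedily removes the unit with the largest
absolute rate difference between the two compared periods until a paired
two-tailed t-test across units exceeds p = 0.05 — an explicit, swappable
approximation of distribution-matching procedures; it only ever removes
units and reports the surviving fraction.

## Synchrony

Channels are band-passed (default 50–100 Hz, second-order Butterworth,
forward-backward so zero phase lag), phases taken from the Hilbert analytic
signal. r(t) is the Kuramoto order parameter; R is its mean over a segment
of L = duration × fs samples (0.4 s at 2 kHz ⇒ L = 800). Phases are computed
once over the whole recording and sliced into trial epochs, avoiding
per-epoch filter transients; segments reaching within 10 cycles of the band's
low edge of a recording boundary are trimmed with a warning. Epoch contrasts
use two-tailed paired t-tests across trials.

## Orchestration and problem sizes

`pipeline.run_pipeline` composes the stages without computing anything
itself; one global seed expands into independent per-stage generators via
`SeedSequence.spawn`. The default analysis sizes — 5×10⁴–10⁵ cascades for
exponent estimates, ~10⁴ avalanches per binning for the three-regime
contrast (250–650 trials per regime), 20–25 units × 50–60 trials for Fano
calibration, B = 500–1000 bootstrap — were chosen so each analysis estimates
its quantity well inside its sampling error at desk scale.

## Known limitations

- The automaton's exponent at 100 sites is ≈ 1.3, not 3/2 (see above);
  conclusions about exponent *values* need larger networks, while contrasts
  between regimes and binning modes are robust at desk scale.
- The LFP background is Gaussian; false-positive behaviour of −2 SD
  thresholds on real recordings will differ.
- Mean-matching implements one reasonable greedy criterion, not the exact
  histogram-matching algorithm used in the spike-variability literature.
- Adaptive-threshold windows are non-overlapping consecutive, the plain
  reading of a windowed procedure; overlapping windows would smooth the
  threshold step function.
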