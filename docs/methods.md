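# Methods

This note records the models, parameter choices and numerical conventions
behind `sleeptmr`, and what the synthetic-data validation does and does
not establish about real recordings.

## Data model and conventions

Time is measured in seconds from recording start; sample indices are
0-based; intervals are half-open `[start, end)`. Signals are in µV
(readers rescale from the header unit). Sleep stages follow the AASM
five-class convention (W, N1, N2, N3, REM) in 30-s epochs; numeric
stagings 0–4 and legacy labels (S1…S4, Wake, R) are normalized on read.

Stimulation intervals are reconstructed from the cue table: consecutive
same-condition cues with gaps ≤ 10 s (twice the 5-s ISI, tolerating one
dropped cue) form one interval running from the first onset to the last
onset plus one ISI — the protocol does not define the edge beyond the
final cue, so extending by one ISI is this package's convention. NREM2-3
time outside any stimulation interval is rest. Per-kind totals in
minutes are the denominators of all density features, and stimulation +
rest time equals total NREM2-3 time by construction.

## Slow-wave detection

The detection band-pass is a windowed-sinc (firwin) FIR with passband
0.3–2 Hz and 0.2 Hz transition width, placing the half-amplitude (−6 dB)
points at 0.2 and 2.1 Hz. Taps are symmetric and odd-length and applied
as a single `same`-mode convolution, which is exactly zero-phase, so
landmark times feed the SW-locked coupling analyses without lag.

Candidate negative peaks (−40…−200 µV) are each paired with the *next*
candidate positive peak (10…150 µV); the text ordering — candidate
ranges at peak picking, the wider logical bounds (40–300 / 10–200 µV,
PTP 75–500 µV) at validation — is preserved, and both sets are exposed
as parameters. Half-wave durations are measured between the
zero-crossings of the filtered trace flanking each peak. Events touching
a stage-mask boundary are discarded (no partial waves). When a negative
peak is followed by several positive candidates, "next positive peak" is
the adopted reading; the duration thresholds weed out implausible
pairings.

Every emitted event can be re-audited with
`slow_waves.check_sw_thresholds`, which re-filters the signal and
re-applies the five logical thresholds from the stored landmarks — the
test suite requires a 100% pass rate.

## Spindle detection

Three decision signals per channel, interpolated to the sample grid:
relative sigma power from 2-s Hanning STFT windows stepped every 200 ms
(a 200-ms *step* is the only reading compatible with 0.5-s events; a
200-ms *overlap* would hop 1.8 s at a time); moving RMS of the
sigma-filtered (12–16 Hz) trace over 300-ms windows stepped 100 ms; and
a moving broadband (1–30 Hz) vs sigma correlation over the same windows
(the correlation window length is unspecified upstream; 300 ms matches
the RMS window). The RMS threshold (mean + 1.5 SD) is estimated per
channel over *all* masked NREM2-3 samples so stimulation and rest share
one reference. Candidates are runs where all three thresholds hold
simultaneously; durations outside 0.5–2 s are discarded.

Temporal resolution: the supra-threshold run extends roughly ± half the
RMS window beyond the true burst, so detected durations carry a ~0.15-s
smear; the duration criteria apply to the detected run, as in the
reference algorithm family.

Cross-channel merging unions events whose *onsets* lie within 500 ms
(onset-to-onset, the adopted reading), with transitive closure; on a
sorted onset axis this is chain grouping, which the tests verify against
a brute-force union-find. Amplitude is the PTP of the sigma-filtered
trace over the event; "frequency" is the mean instantaneous frequency of
the sigma-band analytic signal (derivative of unwrapped phase / 2π).

## Event-related analyses

Event-related potentials and TFRs run on data down-sampled to 100 Hz
(zero-phase FIR anti-alias low-pass at 0.8× the target Nyquist). Epochs
span −1…3 s around the cue; baseline correction subtracts the mean of
−0.3…−0.1 s. ERPs average trials, then channels (the montage is too
sparse for topography), and the trough window is found data-driven: a
one-sample cluster permutation test of the across-condition ERP against
zero; the negative-tail cluster is the trough.

TFR power uses a Hanning-taper FFT with an adaptive five-cycle window
(Δt = 5/f) centred every 20 ms (centred, not causal — the upstream
convention is unstated), on a 1-Hz grid from 5 to 30 Hz. Output points
whose window spills past the epoch are NaN rather than zero-padded so
baseline statistics are never diluted by edge effects. Power is
amplitude-normalized (a unit sinusoid at an on-grid frequency gives
power 1), which cancels in the baseline relative change
(P − P_base)/P_base.

## SO-sigma coupling

Phase (0.5–2 Hz) and amplitude envelopes (centres 7–30 Hz in 1-Hz steps,
±2 Hz bandwidth — fine enough to resolve effects reported with ~0.5 Hz
band edges) are extracted by zero-phase FIR filtering plus Hilbert
transform on the *continuous* channel-averaged trace (or on extended
trials with an explicit edge margin of half the filter length), and only
then epoched. Phase convention: 0 at the positive SO peak, ±π at the
trough.

The ERPAC statistic is the circular-linear correlation across trials,
clipped to [0, 1]; points with zero amplitude variance return ρ = 0 by
convention. Under independence E[ρ] ≈ 1.253/√n (ρ² ~ χ²₂/n), which the
null tests check. The preferred phase uses 18 bins of 20°; ties are
broken by the circular mean of tied bin centres. Rayleigh significance
uses the standard finite-n approximation p = exp(−z)(1 + (2z − z²)/4n),
z = nR². The Watson–Williams F applies the usual κ-based correction and
warns when the mean resultant length falls below 0.45. A minimum of 30
trials per condition guards ERPAC and preferred-phase estimates.

## Cluster-based permutation tests

Pointwise statistics are thresholded per tail at α = 0.025 (two
one-tailed families, matching a 0.05 two-sided family-wise level);
contiguity is 1-D runs in time or 4-neighbourhood on time-frequency
grids. The cluster statistic is the summed pointwise statistic (the
field's common default); "maximum statistic retained per permutation"
is read as the maximum *cluster-level* statistic. Null distributions
come from 500 within-subject sign flips (contrasts) or covariate
permutations (Spearman correlations); p-values include the observed
statistic (+1 convention), so the permutation floor is 1/501 ≈ 0.002.
With `exact=True` all 2ⁿ sign assignments are enumerated (n ≤ 20) and
the p-value is the exact tail fraction — the suite verifies bit-level
agreement with an independently coded enumeration at n = 8. The Spearman
cluster-forming threshold converts the t critical value via
ρ_crit = t/√(n − 2 + t²). Degenerate inputs: zero-variance points with
zero mean contribute t = 0; a constant nonzero difference raises. FDR
correction delegates to the standard Benjamini–Hochberg step-up.

## Behavior

Cleaning removes correct trials beyond 3 SD of the participant × block
correct-trial mean (mean and SD computed before exclusion; the
correct-trials-only reading of the criterion is adopted). Blocks with
fewer than three correct trials are flagged and left untouched. Offline
change uses blocks 2–4 of the pre-nap test (block 1 is warm-up) against
the first four blocks of each retest, as mean-of-block-means so blocks
weigh equally regardless of trial counts (the aggregation rule is
otherwise unspecified); the sign convention makes faster-at-retest
positive. The TMR index averages the condition difference over the two
retests. Generation accuracy scores each press against the cued
sequence's key at that ordinal position, averaged over four attempts;
length-mismatched attempts score over the overlapping positions and are
flagged. rmANOVA-style omnibus tests are not re-implemented; standard
statistical routines apply downstream of the returned tables.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
with full ground truth:

- **Background**: band-limited (0.1–45 Hz) Gaussian 1/f noise (α = 1),
  default 12 µV RMS — the aperiodic floor of NREM EEG without explicit
  microstructure.
- **Slow waves**: negative + positive half-sine pairs with a small
  (30%) trailing negative rebound, Poisson-placed (default 5/min) in
  NREM2-3 with overlap rejection. Two deliberate design points: (1) the
  configured PTP (default 100–150 µV) is calibrated on the
  *detection-filtered* template, because the detection thresholds apply
  to the filtered trace; (2) half-wave durations are drawn near-balanced
  (negative 0.45–0.9 s, positive 0.85–1.05× that), since a strongly
  asymmetric pair loses its DC content to the band-pass and smears its
  positive lobe past the 1-s duration bound, and the rebound gives the
  positive lobe a crisp terminal zero-crossing instead of a near-zero
  plateau whose crossing time is unstable under any background. The
  ground truth records each embed's filtered landmarks and whether it
  meets the five detection thresholds.
- **Spindles**: Hann-enveloped sigma bursts (default 13 Hz, 0.7–1.4 s,
  30 µV envelope peak), Poisson-placed (2/min) away from slow waves.
- **Coupling**: either a continuous SO plus sigma carrier whose envelope
  is 1 + depth·cos(φ_SO − pp) inside the recording, or — for controlled
  estimator studies — `simulate_coupled_trials`, which builds trials
  with uniformly random SO phase offsets so the across-trial phase
  distribution at any time point is uniform, optionally confining the
  modulation to a time window.
- **Stimulation**: alternating 3-min cue blocks (5-s ISI) and 1-min
  rests, cues suppressed outside NREM2-3 (emulating the manual stop); a
  Gaussian negative evoked deflection (default −30 / −20 µV at 0.5 s,
  σ = 0.12 s) follows each cue.
- **Behavior**: per-block mean RTs follow an exponential learning curve
  (baseline 500 ms → plateau 380 ms, τ = 4 blocks) during pre-nap
  training, sit at the plateau in the pre-nap test, and drop by the
  configured condition-specific offline gain at the retests; random-SRTT
  blocks are flat. Trials add i.i.d. Gaussian noise (default 40 ms) and,
  optionally, symmetric outliers at 4–8 SD with a configured rate; block
  structure is 64 presses (two 8-element sequences × 4 repetitions).

Everything is driven by one NumPy PCG64 generator per config, so a
config (including its seed) reproduces outputs bit-identically.

**What passing these tests does not show**: the generator has no
artifacts, no stage-transition dynamics, no spatial structure beyond
shared events with independent channel noise, no 50-Hz interference, and
its slow waves/spindles are stereotyped templates. Detector
recall/precision ≥ 0.9 on high-SNR embeds validates the *logic* of the
detection chain, not its sensitivity on real PSG, where thresholds
interact with far richer backgrounds. Likewise the behavioral generator
has no fatigue, no inter-individual gain variability, and no
accuracy–speed trade-off, so parameter recovery validates the metric
arithmetic and cleaning, not psychological assumptions.

## Validation scales

The stock validation battery uses problem sizes chosen to exercise every
code path at desk scale: 10-minute single-recording detector studies,
150–300-trial coupling studies, 200 null simulations × 500 permutations
for each CBP variant (family-wise error checked against the binomial
95% band around 0.05), exhaustive 2⁸ enumeration for the exact
permutation check, and 24-participant behavioral cohorts (three cohorts
pooled for the TMR-index recovery check).

## Known limitations

- EDF output is a minimal EDF+ writer (16-bit, 1-s records, integer
  sampling rates); it is sufficient for round-trips through standard
  readers but does not write annotations.
- The spindle decision signals are interpolated between window centres,
  so event edges inherit the coarser decision-signal grids.
- `build_intervals` assumes cue trains of one condition do not interleave
  with the other inside a single block, as in the blocked protocol it
  models; overlapping opposite-condition trains raise.
- The Watson–Williams test inherits its von Mises assumptions; for
  diffuse phase distributions (R̄ < 0.45) it warns rather than refusing.
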