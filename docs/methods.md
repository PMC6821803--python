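# Methods

## The phenotype model

Cultured excitatory networks on MEAs self-organize, over roughly four weeks
in vitro, into a rhythm of *network bursts*: population events in which most
electrodes fire densely for a fraction of a second to a few seconds,
separated by quiet intervals with sparse background spiking. The package
treats a well as a point in a six-dimensional metric space — mean firing
rate (MFR), network-burst rate, network-burst duration (NBD), network
inter-burst interval (NIBI), the CV of the NIBI, and the percentage of
spikes outside network bursts — because that is the space in which the
disease phenotype separates: affected (KS-like) networks burst less often,
for longer, and more irregularly, with a similar overall firing rate and a
smaller fraction of spikes outside bursts.

Electrodes are multi-unit channels; no spike sorting is attempted or needed
for these population metrics.

## Spike detection

Raw extracellular traces (10 kHz) are high-pass filtered with a Butterworth
filter at 100 Hz. The filter order (2) and the zero-phase forward–backward
application are implementation choices: zero phase preserves spike timing,
which matters because everything downstream is interval arithmetic. Spikes
are threshold crossings of ±`k`·SD with `k` = 4.5. The noise SD is estimated
globally per trace from the median absolute deviation (MAD/0.6745), which
the spikes themselves cannot inflate; `robust_noise=False` restores the
plain sample SD for strict threshold-convention comparisons. Each crossing
is timestamped at the absolute extremum within 1 ms, and crossings within a
1.5 ms dead time are suppressed — typical MEA detector conventions, both
exposed as parameters.

## Single-channel bursts: the logISI method

ISIs are histogrammed on a log₁₀ axis (10 bins per decade, bounded by the
observed ISI range) and smoothed with a 3-bin centered moving average. Peaks
are local maxima of the smoothed histogram (edge bins may qualify). The
intra-burst peak is the *dominant* smoothed peak, required to lie below the
100 ms cap: in a bursting train intra-burst ISIs outnumber the gaps, so the
tallest mode is the fast mode; when the tallest mode is slower than 100 ms
(e.g. a stationary Poisson train) the train is treated as non-bursting and
the threshold falls back to the cap. Requiring dominance (rather than merely
the tallest sub-cap peak) is what makes the fallback fire for unimodal
trains, whose histogram tail otherwise always contains some small sub-cap
bump.

Among peaks after the intra-burst peak, the first one whose *void parameter*

    void(p₁, p₂) = 1 − h(valley) / √(h(p₁)·h(p₂))

reaches 0.7 marks a genuine inter-burst mode; the threshold is the ISI at
the deepest minimum between the two peaks (ties broken toward shorter ISIs),
and is never allowed to exceed 100 ms. The 100 ms figure is read as a cap on
the within-burst ISI threshold — the literal alternative (all spikes ≥
100 ms apart) would preclude bursts altogether. Bin count, smoothing window
and void threshold are parameters with the defaults above.

Bursts are then maximal runs of ≥ 5 spikes with consecutive ISIs at or below
the threshold; `[start, end]` spans the first to the last spike. A channel
is *bursting* when its burst rate reaches 0.4 bursts/s; the boundary is
inclusive (a channel at exactly 0.4 counts), a documented convention since
the boundary behavior is otherwise unspecified.

## Network bursts and well metrics

*Active* electrodes fire at ≥ 0.1 Hz (inclusive; the threshold is exposed as
`min_rate` because no standard numeric definition exists). Channel bursts on
active electrodes are pooled, sorted, and chained transitively whenever they
overlap or the gap between them is ≤ 100 ms (`merge_gap`, tied to the
intra-burst ISI cap for coherence). A candidate event is accepted iff its
distinct channels exceed 80% of the active channels *strictly*: with 10
active channels, 9 participating qualify (90% > 80%), 8 do not (80% is not
> 80%).

NIBI is measured from the end of one network burst to the start of the next
(not onset-to-onset); the convention is switchable but the end-to-start gap
is what the generator's `mean_nibi` parameterizes, so parameter-recovery
statements are exact. CV of the NIBI uses the population SD — it is a
descriptive statistic, and the difference from the sample SD is negligible
at the n ≥ 50 intervals of a 20-min recording. NBD and NIBI histograms use
100 ms and 1 s bins respectively. The percentage of spikes outside network
bursts counts active-electrode spikes only, matching the MFR convention.
Undefined quantities (no active electrodes, fewer than two network bursts)
propagate as NaN sentinels, never as zeros.

## Synthetic data

`simulate_well` lays down network-burst windows first: quiescent gaps are
gamma distributed with shape 1/CV² and scale mean·CV² (so mean and CV are
independently tunable), alternating with gamma-distributed burst durations.
The gap — not the onset-to-onset period — is drawn from the configured
(mean_nibi, cv_nibi), so the measured end-to-start NIBI has exactly the
configured distribution rather than one inflated by the duration variance.
Each active channel then joins each burst with probability
`participation_p`, firing homogeneous Poisson spikes at `intra_burst_rate`
inside the window, plus homogeneous Poisson background over the whole
recording. All draws descend from one `numpy` generator seeded by a single
integer, so identical configs produce byte-identical wells.

Preset parameters (20-min wells, 12 electrodes, participation 1.0,
intra-burst rate 100 Hz):

| parameter | control | KS-like |
|---|---|---|
| mean NIBI (s) | 15 | 40 |
| CV of NIBI | 0.4 | 0.8 |
| mean NBD (s) | 0.5 | 2.0 |
| background rate (Hz/channel) | 1.5 | 0.4 |

These are repository choices tuned to reproduce the qualitative group
ordering (lower burst rate, longer duration, higher irregularity, fewer
spikes outside bursts, similar MFR); no published group-level numbers exist
to anchor them exactly. What the generator does **not** emulate: intra-burst
rate profiles (onset peaks, adaptation), inter-channel propagation delays,
electrode-position effects, development over days in vitro, and
non-stationarity within a recording. Tests passing on this model therefore
certify the *analysis* — detection, interval arithmetic, classification —
not robustness to every property of real recordings.

`simulate_raw_trace` adds a biphasic ~1.5 ms template at each spike time to
Gaussian noise (overlaps sum). `simulate_evoked_pair` builds
difference-of-exponentials synaptic currents (AMPA: 0.5/5 ms rise/decay;
NMDA: 5 ms rise, configurable decay, default 80 ms) scaled so the sampled
AMPA peak and the 65–70 ms NMDA window mean equal the requested amplitudes
exactly before noise, using the same sample indexing as the analysis — the
noiseless ratio is exact to float rounding.

## Patch-clamp quantification

The sEPSC burst rule (≥ 5 events, inter-event interval ≤ 100 ms) reuses the
MEA run scan with a fixed threshold; the equivalence is property-tested.
The NMDA/AMPA ratio baseline is the mean of the 50 ms before the stimulus;
the AMPA peak is searched 2–50 ms post-stimulus (the first 2 ms blanked as
stimulus artifact — the peak rule itself specifies no window); the NMDA
amplitude is the mean over 65–70 ms post-stimulus, anchored at stimulus
onset (the anchor is ambiguous between onset and artifact end in slice
protocols; onset is used, switchable via the window arguments). An AMPA
amplitude below 25 pA raises a QC flag per the slice convention. Decay τ is
a least-squares single exponential from 90% of peak to the sweep end.
Passive properties come from a −25 pA, 0.5 s step: R_in from the
steady-state ΔV (last 20% of the step), membrane τ from the charging
transient. AP threshold uses a 20 V/s dV/dt criterion; rheobase is the
smallest ladder current eliciting an AP.

## Discriminant analysis

Features are standardized internally, making the analysis invariant to
affine rescaling of any column. Canonical axes solve `B v = λ W v` with W
the pooled within-group covariance, ridge-regularized by 1e-8 × trace(W)/p;
axes are scaled to unit pooled within-group variance, so canonical space is
within-group whitened and nearest-centroid classification is Mahalanobis
classification in the original space. Reported accuracy is resubstitution
(the convention of classical stats packages' "reclassification of group
membership"); `leave_one_out_accuracy` provides the honest estimate, and the
chance-level benchmark documents the resubstitution optimism (~58–59% on
identically distributed groups at n = 50/group with 5 features). Priors are
equal by default, switchable to proportional. Envelopes are chi-square
(2 df) confidence ellipses of the canonical scores; a single canonical
function is padded with a degenerate zero dimension, flagged by a warning.

## Pharmacology

Normalization divides each post-treatment segment's metric by the same
well's non-treated value (which must be finite and positive); recovery at an
arbitrary time is piecewise-linear interpolation between recorded segments,
matching how time courses are actually sampled. Chronic treatments are
ordinary condition groups at matched DIV — no longitudinal model is fitted.
Group tables report mean ± SEM and pairwise mean differences only;
hypothesis testing is deliberately out of scope.

## qPCR formulas

`percent_input` and `ddct_fold_change` are closed-form; both are tested to
1e-12 against independent log-space computation. Technical duplicates are
averaged on the Ct scale before exponentiation; no amplification-efficiency
correction is applied (plain 2^−ΔΔCt model).

## Problem sizes and determinism

The test suite and the reproduction script run on synthetic cohorts sized
for tight feedback while keeping estimator error well inside the asserted
tolerances: 1000 Poisson trains for the burst-scan oracle, 10 wells per
condition for parameter recovery and phenotype separation, 100 seeds for
detector performance, ratio recovery and the chance-level control, and
5 × 20-min wells for the conservation check. All randomness flows from
explicit integer seeds (sub-seeds via `numpy.random.SeedSequence`), so every
number in `results/` is exactly reproducible.

## Known limitations

- The logISI internals (smoothing, bin width, void threshold, the dominance
  rule for the intra-burst peak) are reconstructions of common practice, not
  a vendor-software replica; all are parameterized.
- Network-burst onset/offset resolution is limited by the first/last member
  spike; very sparse participation degrades timing before it degrades
  counts.
- The synthetic model's independence assumptions (renewal bursts, Poisson
  spiking) make recovery benchmarks easier than real data with correlated
  noise and drift.
- `pct_outside` counts background spikes that happen to fall inside a
  network-burst window as "inside"; the resulting bias against the
  generative background fraction is about NBD/(NIBI+NBD), a few percent at
  the preset parameters.
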