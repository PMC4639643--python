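# Methods

## Model and scope

`ssrsim` simulates the forward and inverse relationship between transient
auditory-evoked potentials (AEPs) and auditory steady-state responses
(SSRs) under the linear-superposition hypothesis: the SSR is the circular
convolution of a transient template with a binary stimulus-onset train,
`y = x ⊛ h + n`.  Everything downstream — deconvolution, rate sweeps,
significance statistics, phasors — operates on this model.  The package
deliberately excludes what the hypothesis excludes: no rate-dependent
adaptation of the template, no stimulus acoustics, no EEG artifact
handling.  All amplitudes are in arbitrary µV-scale units; recorded AEPs
carry no published absolute calibration that could anchor them.

## Synthetic templates

Templates are sums of signed unimodal bumps with the canonical polarity
sequence V(+), Na(−), Pa(+), Nb(−), Pb(+).  The default kernel is a
Gaussian `A·exp(−(t−μ)²/2w²)` truncated at ±4 widths; a cubic-B-spline
kernel (half-support 2w) is available.  Gaussians were chosen over the
splines of typical hand-drawn constructions because they are smooth,
two-parameter, and admit closed-form oracles (peak value, area
`A·w·√2π`); the ±4w truncation makes component edits strictly local in
time, so a latency shift of one component provably leaves the waveform
untouched outside that component's support.

Default component table (latency ms, width ms, signed amplitude):
V(6, 1.2, +0.30), Na(18, 4, −0.35), Pa(31, 5, +0.50), Nb(40, 5, −0.40),
Pb(55, 7, +0.45), at fs = 10 kHz and 100 ms duration.  The V→Pa interval
is exactly 25 ms, which places the in-phase summation (SSR amplitude
maximum) at 40 Hz.  fs = 10 kHz keeps 0.1 ms features and the preset ISIs
integer-adjacent in samples.  All values are overridable.

Three presets build template pairs:

* **homo** — the second template perturbs amplitudes by ±3% and latencies
  by ±0.3 ms with deterministic alternating signs, mimicking split-half
  averages of one homogeneous cohort;
* **hetero** — Pa amplitude ×0.6, Nb amplitude ×1.3, Pb latency +8 ms,
  mimicking averages from two different recording paradigms;
* **fig7** (ill-posedness construction) — a positive-area variant of the
  five-component morphology (wider positive, weaker negative components,
  so the superposed cycle stays above baseline at the demonstration rate),
  with only the Pb latency differing between the pair.

Subject groups redraw each subject from the mean template with a
multiplicative amplitude scale ~ N(1, amp_cv²), per-component latency
jitter ~ N(0, σ_lat²), and additive white noise.  Defaults
amp_cv = 0.10, σ_lat = 1.0 ms, noise sd = 0.02 were chosen once as
plausible inter-subject variability for averaged evoked potentials; with
them the AEP-level significant percentage lands at ≈2% for the homo pair
(n = 10 per group, unpaired) and ≈61% for the hetero pair (n = 20,
paired) — the two regimes the comparison statistics are meant to span.
Per-subject random substreams are spawned from the master seed
(`SeedSequence.spawn`), so enlarging a group never reshuffles existing
subjects and every result is bit-reproducible from the seed.

What the generator does *not* emulate: correlated (non-white) EEG
background, component-shape variability beyond scale/latency, electrode
or filter effects, and rate-dependent adaptation.  Passing tests therefore
validate the superposition arithmetic and the statistics pipeline, not
claims about real recordings.

## Synthesis and numerical conventions

Time-to-sample conversions round half away from zero, uniformly across
onset placement, sweep lengths and fold periods.  A constant-rate cycle is
synthesized canonically as a single-onset sweep of exactly one period, so
circular convolution implements the wrap-sum `c[t] = Σ_k x[t + k·m]`
directly; multi-stimulus sweeps exist for jittered (CLAD-style) sequences.
For non-integer periods the actual rate `fs·n_stim/sweep_length` is
recorded beside the nominal one (error ≤ 0.03 Hz on the 20–120 Hz grid at
fs = 10 kHz).  Noise defaults to zero — the comparisons concern averaged
templates — and no DC removal is applied anywhere: the ill-posedness
demonstration relies on all-positive cycles, and peak-peak metrics are
DC-invariant regardless.

## Deconvolution

The model statements admit many estimators; the simplest consistent ones
are used.  CLAD divides spectra bin-by-bin, refusing (by default, λ = 0)
whenever some |H(f)| falls below 1e−10·max|H| — which is exactly the
constant-ISI degeneracy — and optionally applies Tikhonov regularisation
`X = Y·conj(H)/(|H|²+λ)`.  Diagnostics report the minimum |H(f)| and the
count of bins below eps·max|H| (default eps = 1e−6).  MSAD stacks one
binary wrap block per rate (row t has ones at template columns t + k·m)
and solves by dense least squares, reporting the condition number;
rank-deficient stacks raise.  The noise term is treated as zero-mean and
ignored (the least-squares reading of both models).  The template length
defaults to the generating template's length and is exposed as a flag,
since real use would not know it.

Preset designs: the 8-click jittered sweep uses ISIs
16, 19.6, 21.6, 23.6, 25.6, 27.6, 29.2, 36.8 ms (range endpoints and the
40 Hz mean rate are the canonical constraints; the interior values are
this package's choice of a well-conditioned jitter).  The multirate preset
uses 27, 31, 35.5, 40, 45, 50, 55.5, 62.5 Hz (canonical endpoints,
near-uniform interior; condition number ≈ 237 for a 100 ms template at
10 kHz).

## Comparison statistics

The significant percentage runs an independent two-tailed t-test at every
time sample (pooled-variance two-sample when unpaired; Welch behind a
flag; paired-difference t when paired) and reports the fraction of samples
with p < α.  No multiple-testing correction is applied — a deliberate
reproduction of common evoked-potential practice, not a recommendation.
Zero-variance samples (possible only in degenerate noise-free groups) are
counted significant iff the means differ.  In rate sweeps, per-subject
cycles are synthesized and the group-mean cycle feeds the amplitude
metrics (a `subject_mean` switch averages per-subject peak-peaks instead)
while the per-subject ensemble feeds the pointwise test; this ordering
makes the significant percentage well-defined for synthetic SSRs.

The relative difference `100·pp(c₁−c₂)/min(pp₁, pp₂)` is scale-invariant
and unbounded above (antiphase pairs reach 200%).  On the homo preset it
attains its grid minimum at the 40 Hz resonance — comparing SSRs flatters
template agreement precisely where the amplitude is enhanced.

A known behaviour of the synthetic presets: the across-rates correlation
between diff-SSR amplitude and significant percentage is reliably positive
for the homo condition (r ≈ 0.3–0.8 across seeds) but reliably *negative*
for the hetero preset, because with a large fixed template difference the
paired test is variance-limited: amplitude-proportional subject
variability is enhanced at resonance together with the difference itself,
moving the significance rate opposite to the amplitude trace.  Real
heterogeneous recordings need not behave this way; the hetero correlation
is reported but not asserted.

Similarly, where the fundamental harmonic collapses is a property of the
particular template: for the default component table the first-harmonic
suppression valley lies at ≈62–68 Hz (at 64 Hz the fundamental nearly
vanishes — the same rate at which the ill-posedness demonstration
operates), while at exactly 70 Hz the fundamental still slightly exceeds
the second harmonic (0.094 vs 0.073).

## Phasors

Harmonics are computed on the folded cycle, so the fundamental is exactly
the stimulus rate.  Convention: one-sided cosine phasors,
amplitude `(2/M)|Σ_t c[t]e^{−i2πkt/M}|`, phase the argument of that sum;
circularly shifting the cycle by s samples rotates harmonic k's phase by
−2πks/M exactly.  Parseval bookkeeping
(`dc² + Σ amp²/2 ≤ mean-square`) bounds the truncation; dc plus three
harmonics capture >80% of the 40 Hz cycle's energy.

## Ill-posedness demonstration

At 64 Hz the demo grid-searches Pb latency shifts (0–20 ms, 0.2 ms steps)
and reports, among shifts whose AEP relative difference is ≥ 20%, the one
minimizing the SSR relative difference.  With the default construction
the best shift is one full period (15.6 ms): the AEP pair differs by
~127% while the cycles differ by <0.1%, both cycles staying entirely
above baseline.  The mechanism is quantified as the flatness of the Pb
component's own periodic summation (peak-peak over mean ≈ 0.075): a bump
wider than about half the period superposes to a near-constant, so the
cycle is nearly blind to that component's latency.

## Problem sizes

Default experiment sizes are the study conditions themselves: 51 rates
(20–120 Hz step 2), 10 or 20 subjects per group, 1000-sample templates.
The pointwise-test null calibration uses 200 replicate group pairs of
n = 10 at noise sd 0.05.  All experiments are deterministic given the
master seed.

## Limitations

Synthetic templates stand in for unavailable recorded AEPs, so all
group-level percentages and correlations characterise the simulation, not
human data; only structural properties (resonance location, degeneracies,
round-trip identities, calibration of the test under the null) transfer.
The CLAD/MSAD preset interiors are package choices constrained by, not
copied from, the published designs.
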