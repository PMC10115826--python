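# Methods

## Scope and model

The package analyzes switch × trigger screens of Cas-responsive
translational regulators. The analytical chain is: per-cell event tables →
gating → median-ratio normalization → fold-change matrix → orthogonality
screening, plus truth-table scoring of multi-input circuits. Everything is
exercised on synthetic data whose ground truth is planted, so each stage's
output can be compared against a known answer.

### Planted effect model

A ground-truth panel is a trigger × switch matrix of multiplicative
effects on reporter expression: the matched (on-target) entry is `< 1` for
OFF switches and `> 1` for ON switches, off-target entries are 1 except
for explicitly planted crosstalk, and a No-gRNA control column is
identically 1 (it is the normalizer downstream). Effects are steady-state
multiplicative factors; mRNA kinetics, the switch-inverting mechanism and
dose–response are deliberately out of the model.

### Event generator

Per-cell fluorescence is log-normal, the standard model for cytometry
intensity data and the one under which median-ratio statistics are
natural:

- reference of a transfected cell: `10^N(μ_ref, σ_ref)` with defaults
  μ_ref = 4.0, σ_ref = 0.4 (log10, arbitrary units);
- reporter of a transfected cell:
  `basal × effect × dose × 10^N(0, σ_noise)`, where
  `dose = reference / 10^μ_ref` ties reporter to transfection dose so the
  per-cell ratio reporter/reference isolates `basal × effect` (default
  σ_noise = 0.1 log10 ≈ 26% CV; the planted-recovery analyses use
  log10(1.05), i.e. 5% multiplicative noise);
- untransfected cells (1 − transfected fraction, default 0.7) and mock
  samples draw both channels from an autofluorescence log-normal
  (μ = 2.0, σ = 0.3);
- debris (default 5% of events) has low forward/side scatter
  (10^3.3 / 10^3.0 vs 10^5.0 / 10^4.7 for intact cells);
- edge events (default 1%) are clamped exactly to a channel limit,
  emulating detector saturation; all channels are clipped to
  [1, 16777215].

Event counts and noise magnitudes are free parameters of the generator,
not claims about any measured dataset; the defaults were chosen once as
values typical of transient-transfection cytometry. Per-sample seeds are
SHA-256 hashes of (master seed, sample id), so datasets are reproducible
and stable under extension. What the generator does *not* emulate:
spectral spillover/compensation, instrument drift between replicates,
correlated plate effects, non-log-normal debris smears. Passing tests
demonstrate the pipeline's correctness under the planted model, not
robustness to those real-data artifacts.

### Gating

Three steps in fixed order, mirroring the usual manual workflow, each a
deterministic stand-in for a hand-drawn gate: (1) debris removal by
rectangular scatter lower bounds (defaults fsc ≥ 2·10⁴, ssc ≥ 10⁴); (2)
removal of events sitting exactly on a channel limit in the
reporter/reference plane; (3) a reference-positive gate at the 99.9th
percentile of the mock sample's reference channel, strictly-greater
comparison. The mock is passed through the debris and edge gates before
its percentile is taken — otherwise its own saturated events would drag
the threshold to the channel maximum. Gating only drops rows; thresholds
and per-step counts are recorded in the gating report.

### Normalization chain

NI = 1000 × median per-cell reporter/reference over gated cells (the
×1000 factor is applied exactly once, in NI; it cancels in every
subsequent ratio). RI = NI(trigger+)/NI(trigger−), computed per replicate
with paired trigger± samples; relative reporter expression = RI divided by
the same replicate's No-gRNA RI, so the control maps to exactly 1. The
fold-change matrix entry for (trigger, switch) is the replicate mean of
relative reporter expression. Even-count medians are the mean of the two
central order statistics. Replicate summaries are mean ± sample SD (n−1);
the SD is reported as absent for a single replicate. Any zero denominator
raises an error instead of propagating infinities. The imaging chain
(DV/RV/NFC/NFI) is the exact analogue on median reporter/reference values
of reference-positive regions, with inputs assumed background-subtracted.
Both RI-level and relative-expression-level replicate statistics are
exposed, since screens differ in which they aggregate.

### Orthogonality

Profiles are centered at 1 before the cosine, so "no effect everywhere"
carries no direction; a trigger whose centered (restricted) profile is the
zero vector raises an error rather than silently scoring. The printed
form of the pairwise statistic in this field is a similarity with a
repeated index; the implemented quantity is the *distance*
1 − cos(centered i, centered j), which is the only orientation consistent
with "≈ 1 means orthogonal, low values mean crosstalk". A combination
scores the minimum pairwise distance; the 0.7 classification threshold is
boundary-inclusive on the orthogonal side.

Whether the profile of trigger *i* within combination C is restricted to
C's own switches (as the conditional notation suggests) or spans all
switches is genuinely ambiguous; both modes are implemented
(`profile_mode="restricted" | "full"`, default full for searches), and
no claim is made about which a given study used. The optimized search —
binary search over the sorted unique pair distances with an exact
max-clique feasibility test (networkx) on the threshold graph, followed by
a lexicographic DFS for the smallest optimal clique — is provably exact
only when pair distances are combination-independent, i.e. in full-profile
mode; in restricted mode it transparently falls back to exhaustive
enumeration with an early-exit lower-bound prune. Ties everywhere break to
the lexicographically smallest sorted index tuple, and the two routes are
tested to return identical subsets.

### Circuit scoring

The net fold-change divides the mean ON-state NI by the mean OFF-state NI;
tables with several ON states (XOR, NAND) use the arithmetic mean of ON
states, a stated generalization of the single-ON AND definition. The
vector proximity angle is computed in degrees with the cosine clipped to
[−1, 1] before arccos; for nonnegative observed vectors θ ∈ [0°, 90°],
with θ = 0 iff the observation is proportional to the truth table. The
pass cutoff (θ ≤ 20°) is boundary-inclusive. Half-subtractor scoring
normalizes each output's four state NIs to its [0,0] state before scoring
(θ itself is scale-invariant; the normalization matches the imaging
convention), scores the difference D against XOR and the borrow Bo against
NIMPLY, with the subtrahend input configurable (default: second input
subtracted from the first, so Bo is ON only in state [0,1]).

## Planted-screen design for set recovery

The recovery analyses use a 16-trigger OFF panel (on-target effect 0.1)
with three *promiscuous* triggers, each cross-reacting with the switches
of two distinct clean partners at 0.5. This structure makes the best
13-subset unique by construction: breaking a promiscuous trigger's two
crosstalk pairs by excluding its partners costs two exclusions versus one
for excluding the trigger itself, so with exactly three exclusions
available the clean 13-set is the only optimum — a single-partner design
would leave the optimum tied between excluding either member of each
crosstalk pair, with noise deciding the winner. Each planted crosstalking
pair scores ≈ 0.56, comfortably below the 0.7 threshold; clean pairs score
≈ 1.

## Problem sizes

The analyses and tests run at 5000 events/sample × 3 replicates for the
16-trigger screen (1635 samples), 2000 events/state for the 60-circuit
gate panel, and a 25-protein panel (matrix-level noise, 5% CV, 3
replicates) for the N = 3–17 sweep — sizes at which median-based
estimates are stable to well under 1% and every analysis completes in
seconds on one core.

## Known limitations

- The generator's dose covariate is linear in the reference; saturation of
  translation capacity at high dose is not modeled.
- The reference-positive gate assumes a clear separation between
  transfected and autofluorescent populations; heavily overlapping
  populations would need a mixture-model gate, which is out of scope.
- Restricted-mode sweeps are exponential in the worst case; they are
  practical here because the pruned search cuts most subsets early, but
  very large panels should use full-profile mode.
- FCS file ingestion is not provided; event tables are exchanged as CSV
  with a fixed header.
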