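# Methods

`eegnetdyn` implements a dynamic functional-connectivity analysis for
multichannel scalp EEG: per-epoch weighted networks from lag-optimized
cross-correlation, detection of quasi-stable network periods by comparing
inter-epoch network change against surrogate null models, weighted graph
summaries of the averaged stable networks, and mixed-design group
statistics. This note documents the model, its assumptions, the parameters
that matter, and the design choices made where the method description left
the design open.

## Per-epoch functional networks

Each recording is split into epochs (resting data: a 30 s analysis window in
16 consecutive epochs of 1.875 s, an integer 960 samples at 512 Hz; event
data: 500 ms epochs locked 100 ms before stimulus onset, baseline-corrected
by the 100 ms pre-stimulus mean). Epochs whose absolute amplitude exceeds
150 µV on any channel are rejected, read as a strict inequality; event
epochs additionally require a correct behavioral response.

For every channel pair the Pearson correlation is computed on the
overlapping samples at every integer lag h in [−max_lag, +max_lag]
(default max_lag = 100 ms of samples, i.e. 51 at 512 Hz — physiological
conduction delays, and small relative to the epoch), and the signed r at
the |r|-maximizing lag becomes the edge weight γ̂_ij. Normalizing per lag on
the overlap (no zero padding) keeps every weight a true correlation in
[−1, 1] and comparable across pairs. Ties in |r| break toward the smallest
|h|, then the negative lag, so results are deterministic. The pipeline
operates on the weighted matrices by default; binarizing at a configurable
threshold is available (`active_mode: binarized`), but weighted mode avoids
an arbitrary cutoff and both the distance and the graph measures are
well-defined on weights.

## Stability via inter-epoch distances

The change between consecutive networks is the entrywise L1 ("edit")
distance dist(S1, S2) = Σ_ij |S1_ij − S2_ij|; the signed sum without
absolute values would not be a norm and could be negative. L2 and
1 − cosine-similarity are available as alternative metrics.

A transition is *stable* when its distance falls **more than two standard
deviations below the mean** of a null distribution pooled per condition
across all subjects of both groups (per-subject nulls are available as a
sensitivity option). Two null models:

* **Matrix randomization** — every connectivity matrix is randomized by a
  signed, weighted rewiring that conserves the weight multiset and binary
  degree sequence exactly and tracks per-node strengths approximately:
  degree-preserving double-edge swaps on the binary topology (skipped when
  the graph is complete, where no rewiring exists), then rank-based
  strength-matched weight reassignment per sign class (repeatedly pick a
  random unassigned edge, rank its expected weight — the product of its
  endpoints' residual strengths — among the remaining edges, give it the
  remaining weight of the same rank, then decrement the residual
  strengths). Strength tracking is inherently approximate: over 100 seeded
  10-node lognormal-weight graphs the input/output strength correlation
  averages ≈ 0.91 with a worst case ≈ 0.54; on strength-homogeneous graphs
  the attainable correlation is intrinsically lower because the rank signal
  is dominated by assignment noise.
* **Temporal shift** — surrogate recordings delete a random prefix of up to
  5 s *independently per channel* (start coordinate uniform on 1..fs·5,
  i.e. 1..2560 at 512 Hz) and trim every channel to exactly 30 s. A common
  shift across channels would leave the network structure intact and defeat
  the surrogate's purpose. The connectivity stage is re-run in full on each
  surrogate with consecutive epoching.

The stability threshold is mean − 2·SD of the pooled null distances; it may
be negative, in which case nothing is stable. A maximal run of k stable
transitions defines one quasi-stable period spanning k + 1 epochs with
duration (k+1) × epoch length; its averaged network is the entrywise mean
of the spanned epochs' matrices. Null replicate count defaults to 100 per
subject-condition and is configurable; all surrogate draws are seeded.

## Graph measures

Negative weights are folded by absolute value (clipping to zero is a config
alternative) and weights map to connection lengths by length = 1/w, the
standard choice for correlation networks (−log w is not offered). From the
all-pairs shortest-path matrix over lengths: eccentricity per node, diameter
(max eccentricity), radius (min eccentricity), characteristic path length
(mean finite off-diagonal distance) and global efficiency (mean inverse
distance, zero for unreachable pairs). Weighted transitivity follows the
geometric-mean triangle convention: Σ_i diag((W^(1/3))^3) / Σ_i k_i(k_i−1)
with k the binary degree. Maximum modularity is the best Newman Q (γ = 1,
weighted) over seeded Louvain restarts (default 100), always including the
all-in-one partition (Q = 0) as a candidate. Disconnected graphs propagate
infinite eccentricities with a structured warning rather than silently
restricting to the largest component. Note that this weighted transitivity
scales linearly with a global weight rescaling (only Q and the partition
are scale-invariant); weights here are correlations in [0, 1] so the ratio
interpretation holds.

## Group statistics

Per subject × condition the summaries are the number of stable periods, the
mean stable duration (missing when there are none — the duration of nothing
is undefined; such subjects keep a count of 0 in the count analysis), and
per-measure means over the averaged stable networks. Each measure gets a
mixed two-way ANOVA (within: condition; between: group) via
`pingouin.mixed_anova`, followed by step-down independent-samples t tests
within conditions (Welch by default; pooled-variance optional). No
multiple-testing correction is applied across the six network measures in
the primary report; a Holm-adjusted column is emitted alongside.

## Synthetic data: what it emulates, and what it does not

No recordings are deposited for this kind of study, so the package ships a
generator whose defaults define the test conditions: 32 channels, 512 Hz,
35 s resting recordings (30 s analysis window + 5 s headroom for the
temporal-shift null), and an event design of 4 blocks × 40 trials (1 s
stimulus + 2 s blank), 160 trials total, with Bernoulli(0.9) behavioral
correctness.

The signal model is the simplest one that makes every downstream statistic
well-defined: within a regime, each coupled channel pair shares a latent
unit-variance white-noise source mixed into both channels at the pair's lag,
the structured part of each channel is scaled to 20 µV RMS, and independent
Gaussian sensor noise (default 5 µV) is added. With these amplitudes
correlations are attenuated by only A²/(A²+σ²) ≈ 6%, the clean signal stays
far inside ±100 µV, and the 150 µV artifact threshold sits beyond 7 SD, so
artifact rejection only fires on injected artifacts. Because each channel
has a unit variance budget, the sum of a channel's coupling weights ("load")
must stay ≤ 1 for realized correlations to track planted weights; the
cohort defaults respect this.

Regime schedules drive the dynamics: contiguous segments, each with its own
coupling graph (a random connected ring backbone — functional networks are
connected, and path measures need a connected graph — plus extra pairs at
density 0.1) and integer lag map. Segment durations are gamma(shape 3) with
a group-specific mean: quasi-stable periods have a characteristic duration
rather than a memoryless profile, and the shape-3 choice leaves negligible
mass below one epoch. Group defaults plant the two directional effects of
interest: the TD-like group has 3.75 s mean segments (2 epochs) and
coupling weights U[0.38, 0.5]; the ASD-like group has 7.5 s mean segments
(4 epochs) and weights U[0.22, 0.34]. Weaker couplings mean longer 1/w path
lengths and hence a larger diameter; planting the diameter contrast through
extra density instead would *reverse* the effect (extra edges shorten
paths), and the generator has no spatial electrode embedding with which to
express "long-range" connectivity. Event-condition schedules scale segment
means by 0.4.

What the generator does **not** emulate: realistic EEG spectra (1/f, alpha
rhythm), volume conduction or any forward head model, spatial electrode
geometry, and non-Gaussian artifacts beyond injected single-sample
deflections. Passing tests therefore demonstrate that the pipeline recovers
planted lagged-correlation regime structure under white-noise conditions —
not that it would behave identically on real EEG, where shared broadband
sources inflate baseline correlations.

Seeding: one master seed per cohort; each subject × condition receives an
independent child stream via `numpy.random.SeedSequence.spawn` in
group → subject → condition order, so cohorts are bit-reproducible and
subjects independent.

## Problem sizes used in tests and the acceptance script

Structural checks run at the study geometry (32 channels, 512 Hz, 30 s,
160 trials). The cohort-level directional-recovery study uses 50 seeded
rest-state cohorts of 5 subjects per group at 8 channels and 512 Hz, with
10 null replicates and 20 modularity restarts per cohort — the smallest
sizes at which the planted effects and the null calibration are
comfortably resolved. ANOVA calibration (type-I error over 500 null
cohorts, power) runs at the statistics stage, drawing per-subject measure
values directly from the mixed model that stage assumes; simulating 500
full EEG cohorts would add nothing to a test of the ANOVA itself.

## Numerical choices and degenerate inputs

* Event-window rounding: start = round(onset − pre·fs), fixed length
  round(0.5·fs), so all event epochs are equally long.
* Constant channels make correlations undefined and raise errors naming the
  channel; zero matrices make cosine distance undefined and raise.
* Strict inequalities at both the artifact threshold (|x| > 150 µV) and the
  stability threshold (d < mean − 2 SD).
* Resting epochs are assumed non-overlapping; no band-pass filter is
  applied by default (none is specified for the analysis); an optional
  band-pass could be added ahead of epoching without touching later stages.
* `temporal_shift_null` with max_delete = 0 degenerates to the leading
  30 s window, unchanged.

## Known limitations

* Strength preservation of the matrix-randomization null is approximate by
  construction (see above); the conserved quantities are the weight
  multiset and the degree sequence.
* On complete weighted graphs (the typical weighted-correlation case) no
  binary rewiring is possible, so that null model reduces to
  strength-matched weight reassignment.
* EDF recordings are read (via MNE) but not written; the text format is the
  interchange format for generated data.
* The alternative metrics (L2, cosine) are implemented and tested, but with
  the default null construction they rarely flag stable transitions —
  consistent with their insensitivity to many small coordinated changes.
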