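# Methods

This note documents the models and conventions behind `meanet`: what each
analysis stage computes, how the synthetic phenotypes are generated, which
defaults were genuinely free choices, and where the approach has known
limits.

## Recording geometry

A recording is a set of spike times per electrode on a regular grid.
Electrode positions are expressed in mm relative to the arena centre,
which for a symmetric grid coincides with the centroid of the electrode
positions (`make_chip_layout` builds coordinates in exact ± pairs, so the
centroid is zero to floating-point precision). The full chip is 64×64 at
42 µm pitch (4096 sites); analyses and tests run on a 10×10 desk-scale
grid with the same pitch, which keeps the pairwise correlogram work
(O(electrodes²)) tractable while preserving every qualitative behaviour.
Spike times are serialised as seconds with 0.1 ms precision, the
resolution ceiling of a 10 kHz acquisition system.

## Activity metrics

MFR is spike count over duration per electrode, silent electrodes
included. ISIs are successive-spike differences within an electrode, in
ms; the "average ISI" of a recording pools ISIs across electrodes into
one distribution (one distribution per culture, matching how per-culture
ISI box plots are drawn); per-electrode averaging is available as an
option. Quantiles use linear interpolation between order statistics
(numpy's default), frozen as the package convention; whiskers follow the
1.5×IQR rule; SEM uses the n−1 standard deviation. The Welch t-test is
computed from the textbook formula with Welch–Satterthwaite degrees of
freedom and is verified against an independent statistics implementation
to 1e-10.

## Burst detection

Neither burst detector has a canonical published parameterisation for
this kind of data, so the package adopts the simplest widely used MEA
conventions and exposes every constant:

* Spike bursts: maximal runs with every ISI ≤ `max_isi` (100 ms) and at
  least `min_spikes` (5) spikes.
* Network bursts: population spike counts in `bin` (25 ms) bins; bins
  above mean + k·σ (k = 3) of the binned counts are candidates; candidate
  bins separated by at most `merge_gap` (100 ms) merge into one event; an
  event is kept when the distinct electrodes spiking *in its
  supra-threshold bins* reach `min_participation` (10 %) of the active
  electrodes (an electrode is active at ≥ 0.02 spikes/s, i.e. 6 spikes in
  5 min). Counting participants in candidate bins rather than across the
  whole merged window matters: at quiet baselines the merged window
  otherwise accumulates enough incidental baseline spikes to pass the
  participation gate.

Two behaviours of this detector family are worth knowing. First, the
mean + 3σ rule is calibrated on the recording itself, so a raster with no
embedded events still flags chance rate excursions; below ~0.2 spikes/s
per electrode (100 electrodes) false events are rare (<5 % of
recordings), but a tonic baseline of ≥0.5 spikes/s produces occasional
chance events — a real property of self-calibrated thresholds, not a bug.
Second, detected-event counts are only coarsely monotone in k: a single-k
increment can split one merged event into two (the bridging candidate bin
drops below threshold), transiently *raising* the count; over coarse k
grids the monotone trend holds.

## Functional connectivity

The cross-correlogram of electrodes i and j counts spike-pair lags
t_j − t_i in 2 ms bins over ±25 ms. Significance is assessed per pair
against 20 surrogates in which every spike of the target train is
displaced uniformly within ±25 ms; the threshold is mean + 4·σ of the
surrogate correlogram peaks. An edge is directed by the lag sign of the
significant peak (the leading train is the source); a peak in the
zero-lag bin is direction-ambiguous and stored as two directed edges
flagged `mutual`. Edge weight is the peak count normalised by the
geometric mean of the two spike counts. Node roles: sender when
out-degree exceeds in-degree, receiver for the converse, broker on a tie
with nonzero degree; isolated nodes carry no role.

The whole-array inference enumerates every ordered spike pair within the
lag-plus-jitter window once and accumulates observed and surrogate
histograms for all pairs simultaneously; it is exactly the pairwise
definition, vectorised. Inference is deterministic given the raster and
the seed in `ConnectivityParams`.

Edge-direction accuracy against the generator's ground truth is defined
over recovered non-mutual edges whose undirected pair exists in the true
graph (orientation precision); mutual pairs carry no direction
information by construction, since module mates fire their burst onsets
simultaneously.

## Graph metrics

All metrics run on the undirected projection of the directed graph.
Clustering is the triangle fraction `2T_i/(k_i(k_i−1))`, zero below
degree 2; the average is over nodes of degree ≥ 2 (nodes that cannot
close a triangle are not averaged in). Path lengths are unweighted BFS
distances; each node's average is over the targets it can reach, so
fragmented networks — expected for the treated phenotype — keep every
node instead of silently dropping small components (a
largest-component-only flag would bias node-degree comparisons). The
path-length histogram uses 0.25-link bins, fine enough to represent
medians such as 2.25, 2.75 or 3.25 links; the reported `pl_median_bin` is
the left edge of the bin containing the median per-node average. Degree
histograms are integer-binned, with a tail-mass statistic (fraction of
nodes above the 90th-percentile degree) as a fat-tail indicator.

## Center-of-activity trajectories

CA(t) is the spike-count-weighted centroid of electrode positions per
10 ms bin inside a network-burst window. Empty bins are flagged and
skipped, never interpolated — interpolation would fabricate motion.
Velocity is total path length over the time between the first and last
defined points; terminal distance is the norm of the last defined CA;
dispersion is the RMS distance of defined points from their own centroid.
Fewer than two defined points makes a trajectory degenerate; degenerate
trajectories are excluded from condition summaries and the reported n
reflects that. The "arena centre" is the electrode-grid centroid, not the
centre of the chip's larger working area; on the symmetric grid the two
coincide for the 64×64 array but the convention matters for partial
layouts.

## The synthetic phenotypes

The generator is spike-level: every downstream analysis consumes spike
times, so simulating membrane voltages would add nothing testable. One
seed drives all randomness in a recording.

Per recording: (1) a spatial weight map — uniform, or a Gaussian hotspot
(σ and centre as fractions of the grid half-extent, plus a 0.05 floor) —
normalised to mean 1 and multiplied by lognormal electrode-to-electrode
dispersion; (2) independent Poisson baselines at base_rate × weight;
(3) a latent directed graph; (4) network bursts placed uniformly at
random without overlap (≥300 ms apart, 1 s margins), each spreading from
an initiator along graph out-edges with a fixed per-hop delay. A
recruited electrode fires a stereotyped onset volley — three spikes 1 ms
apart at its onset time — followed by a Poisson packet at the
within-burst rate for the remainder of the window. The volley is the
load-bearing modelling choice for inference testability: it concentrates
correlogram mass at the true inter-electrode delay so that edge direction
is recoverable from realistic event counts, and its 1 ms spacing keeps
the cross-terms of simultaneous-onset pairs inside the zero-lag bin
(2 ms spacing spilled them into neighbouring bins and flipped ~20 % of
near-pair orientations).

Control graphs are directed ring lattices over grid-ordered nodes (each
node points at its next k/2 neighbours; undirected projection is the
classic lattice of degree k) with 15 % rewiring; degree grows 2→12 over
DIVs 1→16, so the network gains shortcuts and shortens its path length as
it "matures". Treated-phenotype graphs are unions of forward-tournament
modules (projection: cliques, clustering 1) whose heads are linked in a
ring (or, at DIV4, a star) — few inter-module edges, high local
clustering, and a module population that shrinks at late DIVs.

The packaged schedules (`data/phenotypes.yaml`) encode the study
conditions: control base rate rises 0.5→3.0 spikes/s with homogeneous
spatial structure from DIV7; the treated culture rises 0.5→4.6 through
DIV10 and collapses to 0.9 afterwards, always localized off-centre.
Control network bursts grow 0→55 per 5 minutes, recruiting 50→90 % of the
array; treated cultures hold 25 events that recruit only one or two
modules. DIV1 and DIV4 baseline rates (0.5/1.4014 control, 0.5/0.781
treated) are fixed by the observed ISI decline ratios they imply
(100×0.5/1.4014 ≈ 35.7 %, 100×0.5/0.781 ≈ 64.0 %); the remaining values
were calibrated once, jointly, so that the two phenotypes reproduce the
full set of qualitative contrasts simultaneously — the constraints
interact, e.g. tonic hyperactivity raises both the correlogram background
(hurting edge recovery) and the population-rate baseline (spawning
false network-burst events), which is why the treated baseline falls
steeply after DIV10 while its mid-DIV bursts recruit two modules.

What the generator does *not* emulate: refractoriness and spike-waveform
realism, rate non-stationarity outside bursts, inhibition, development
within a session, electrode noise/artifacts, and the possibility that
real propagation delays vary per synapse. Passing tests therefore show
that the analysis stages recover the structure this model embeds at
realistic rates and counts — not that they would recover the biology of
any particular real culture.

## Statistics and sampling units

Cross-condition comparisons are per metric per DIV with Welch's t-test:
per electrode for rates, per event for burst durations, per trajectory
for CAT metrics. No multiple-testing correction is applied by default
(each panel stands on its own, the common convention for this kind of
figure); a Benjamini–Hochberg option exists for family-wise control.
Caveat: per-unit tests are exactly calibrated only when units are
exchangeable across cultures. Per-trajectory CAT metrics inherit each
culture's latent spatial geometry, and spike-burst durations are
cluster-correlated (all electrodes recruited into one network burst share
its packet length), so for those metrics the per-unit t-test is
anticonservative — with only one culture per condition, significance
there should be read as descriptive, which is also how the corresponding
figure panels are usually meant.

## Problem sizes

Tests and the demo use the 10×10 grid, 300 s recordings, six DIVs and two
conditions; the full 64×64 layout is exercised for geometry/metadata and
available to the CLI. The packaged demo (12 recordings end to end,
including all-pairs surrogate inference) runs in roughly two minutes on
one core; the acceptance script (ISI ratios over 10 seeds plus two DIV16
detections) in well under a minute.
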