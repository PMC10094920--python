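# meanet

Network-level analysis of high-density multielectrode-array (HD-MEA)
recordings from developing neuronal cultures — and a synthetic-data
generator that makes every stage of the analysis testable against a known
ground truth.

## The problem

Dissociated cortical cultures grown on an HD-MEA (here a 64×64 CMOS grid,
4096 electrodes at 42 µm pitch, sampled at 10 kHz for 5-minute sessions)
let you watch a neuronal network organise itself over days in vitro (DIV).
Perturbations such as amyloid-β42 oligomers — an Alzheimer's-disease model
— change that trajectory: early hyperactivity, persistent local clustering,
fragmented connectivity and disoriented burst propagation instead of the
control's steady march toward an efficient small-world network.

`meanet` implements the spike-train analyses that quantify those changes:

* **Activity** — per-electrode mean firing rate (MFR) maps, interspike
  interval (ISI) distributions, box/violin summary statistics, and the
  unpaired two-tailed Welch t-test (tiers `*` p<0.05, `**` p<0.01,
  `***` p<0.005).
* **Bursts** — single-channel spike bursts by the max-interval rule
  (every ISI ≤ 100 ms, ≥ 5 spikes) and population network bursts by a
  population-rate threshold (25 ms bins, mean + 3 σ, 100 ms merging, ≥10 %
  of active electrodes participating).
* **Connectivity** — a directed functional graph from binned
  cross-correlograms (2 ms bins, ±25 ms lags): an edge i→j when the peak
  at positive lag exceeds mean + 4 σ of spike-jitter surrogate peaks;
  node roles (sender / receiver / broker) from the in/out-degree balance.
* **Graph metrics** — clustering coefficient
  `cc_i = 2T_i / (k_i(k_i−1))`, characteristic path length in links
  (per-node averages over reachable targets, 0.25-link histograms), and
  node-degree distributions, all on the undirected projection.
* **Center-of-activity trajectories (CAT)** — per 10 ms bin,
  `CA(t) = Σ_i n_i(t)·p_i / Σ_i n_i(t)` with electrode positions `p_i`
  relative to the arena centre; each network burst yields a trajectory
  summarised by duration, mean velocity (path length / duration), terminal
  distance from the centre, and dispersion.
* **Synthetic phenotypes** — Poisson baselines shaped by a spatial weight
  map, plus network bursts that propagate along a latent directed graph
  (small-world ring lattice for controls, dense local modules for the
  treated phenotype) with a fixed per-hop delay, so the connectivity
  inference can be scored against the embedded truth.

## Worked example

```bash
python examples/01_simulate_and_burst_detect.py
python examples/03_cat_trajectories.py
```

prints, for the packaged DIV16 phenotypes on a desk-scale 10×10 grid
(seed 1):

```
control DIV16:
  mean firing rate        5.95 spikes/s per electrode
  network bursts            55  detected (55 embedded)
abeta42 DIV16:
  mean firing rate        0.96 spikes/s per electrode
  network bursts            25  detected (25 embedded)

control DIV16  (55 trajectories):
  velocity            3.17 mm/s mean
  duration             289 ms mean
  terminal distance  0.029 mm from arena centre
abeta42 DIV16  (25 trajectories):
  velocity            5.46 mm/s mean
  duration             164 ms mean
  terminal distance  0.109 mm from arena centre
```

The detector recovers all 55 embedded control events (the ">50 per
5 minutes" regime of a mature culture) and all 25 treated events (the
"constant 20–30" regime). The treated culture's burst trajectories are
faster, shorter and terminate several times farther from the arena centre
— localized activity that never converges on the centre, unlike the
homogeneous control bursts.

`examples/04_full_div_series.py` (a few minutes) runs both conditions
across DIVs 1–16 and writes `metrics.tsv`, graph edge lists, burst and
trajectory tables plus Welch comparisons. The same pipeline is available
from the shell:

```bash
meanet run-demo --seed 1 --out demo_out/
meanet simulate --condition abeta42 --div 16 --out sim_out/
meanet analyze sim_out/raster.tsv sim_out/layout.tsv --out analysis_out/
```

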