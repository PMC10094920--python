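# Packaged phenotype schedules for the two culture conditions across
# days in vitro (DIV) 1-16.  These parameters drive the synthetic spike
# generator so that the two conditions reproduce the qualitative
# developmental contrasts seen in control vs Abeta42-treated cortical
# cultures on a high-density MEA:
#
#   control:  mean firing rate rises monotonically with DIV; network
#             bursts grow from none to >50 per 5-min recording, recruiting
#             most of the array homogeneously; the underlying graph is a
#             small-world ring lattice whose degree grows with DIV.
#   abeta42:  tonic hyperactivity that rises until DIV10 and then
#             declines; a roughly constant 20-30 network bursts that stay
#             confined to small spatial modules; the underlying graph is a
#             union of dense local modules (high clustering) with few
#             inter-module links, and the module population shrinks late.
#
# Units: base_rate / within_burst_rate in spikes/s per electrode,
# burst_duration_mean in ms, propagation_delay in ms per graph hop.
# spatial_profile "localized" takes a centre (fraction of the grid
# half-extent, x then y) and a width (Gaussian sigma as a fraction of the
# half-extent).  Graph parameters target the desk-scale 100-electrode
# layout used throughout testing; node counts are capped at the layout
# size for smaller grids.

divs: [1, 4, 7, 10, 13, 16]

control:
  rate_dispersion: 0.10
  propagation_delay_ms: 5.0
  graph:
    kind: small_world
    rewiring_prob: 0.15
  spatial_profile:
    div1: {kind: localized, center: [0.0, 0.0], width: 1.5}
    div4: {kind: localized, center: [0.0, 0.0], width: 1.5}
    default: {kind: homogeneous}
  by_div:
    div1:  {base_rate: 0.5,    n_network_bursts: 0,  burst_participation: 0.50, within_burst_rate: 30, burst_duration_mean_ms: 500, mean_degree: 2}
    div4:  {base_rate: 1.4014, n_network_bursts: 12, burst_participation: 0.60, within_burst_rate: 30, burst_duration_mean_ms: 400, mean_degree: 4}
    div7:  {base_rate: 1.8,    n_network_bursts: 20, burst_participation: 0.70, within_burst_rate: 35, burst_duration_mean_ms: 380, mean_degree: 6}
    div10: {base_rate: 2.2,    n_network_bursts: 35, burst_participation: 0.80, within_burst_rate: 40, burst_duration_mean_ms: 360, mean_degree: 8}
    div13: {base_rate: 2.6,    n_network_bursts: 46, burst_participation: 0.85, within_burst_rate: 45, burst_duration_mean_ms: 340, mean_degree: 10}
    div16: {base_rate: 3.0,    n_network_bursts: 55, burst_participation: 0.90, within_burst_rate: 50, burst_duration_mean_ms: 320, mean_degree: 12}

abeta42:
  rate_dispersion: 0.30
  propagation_delay_ms: 20.0
  graph:
    kind: modular
  spatial_profile:
    default: {kind: localized, center: [0.45, 0.30], width: 0.6}
  by_div:
    div1:  {base_rate: 0.5,   n_network_bursts: 25, burst_participation: 0.12, within_burst_rate: 120, burst_duration_mean_ms: 280, n_modules: 10, module_size: 3}
    div4:  {base_rate: 0.781, n_network_bursts: 25, burst_participation: 0.36, within_burst_rate: 300, burst_duration_mean_ms: 280, n_modules: 12, module_size: 3, propagation_delay_ms: 5.0}
    div7:  {base_rate: 3.4,   n_network_bursts: 25, burst_participation: 0.24, within_burst_rate: 30,  burst_duration_mean_ms: 260, n_modules: 5,  module_size: 12}
    div10: {base_rate: 4.6,   n_network_bursts: 25, burst_participation: 0.24, within_burst_rate: 30,  burst_duration_mean_ms: 240, n_modules: 5,  module_size: 12}
    div13: {base_rate: 1.1,   n_network_bursts: 25, burst_participation: 0.10, within_burst_rate: 35,  burst_duration_mean_ms: 220, n_modules: 4,  module_size: 10}
    div16: {base_rate: 0.9,   n_network_bursts: 25, burst_participation: 0.08, within_burst_rate: 40,  burst_duration_mean_ms: 200, n_modules: 3,  module_size: 8}
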