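"""Infer a functional graph from spikes and characterise its topology.

Cross-correlogram peaks against jitter surrogates give a directed graph;
node roles follow the in/out-degree balance, and clustering coefficient /
path length / node degree summarise the topology.  The treated phenotype
fragments into dense local modules, so its clustering coefficient exceeds
the control's even though its network is far smaller.
"""

from meanet import (compute_graph_metrics, infer_graph, make_chip_layout,
                    phenotype_schedule, simulate_recording)

layout = make_chip_layout(10, 10, 0.042)

for condition in ("control", "abeta42"):
    cfg = {c.div: c for c in phenotype_schedule(condition, base_seed=1)}[16]
    raster, truth = simulate_recording(cfg, layout, duration=300.0)
    fg = infer_graph(raster)
    metrics = compute_graph_metrics(fg.graph)
    roles = fg.role_counts()

    print(f"{condition} DIV16:")
    print(f"  inferred edges     {fg.n_edges:5d}   (ground truth"
          f" {truth.graph.number_of_edges()})")
    print(f"  clustering coeff   {metrics.avg_cc:7.3f}")
    print(f"  path length        {metrics.network_pl:7.2f} links"
          f" (median bin {metrics.pl_median_bin:.2f})")
    print(f"  mean node degree   {metrics.nd_mean:7.1f}")
    print(f"  roles              {roles['sender']} senders,"
          f" {roles['receiver']} receivers, {roles['broker']} brokers")

# Expected: clustering is higher for the treated culture (activity locked
# inside near-clique modules) while the control supports a much larger,
# better-integrated network (more edges, higher degree).
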