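"""Identify hubs (mean + 1 SD degree rule) and classify network topology.

Hubs are the nodes controlling information flow: degree at least one
standard deviation above the network mean.  The classifier separates
BA-like scale-free networks (low clustering, good negative-exponent degree
fit) from hierarchical ones (high clustering correlated with degree).
"""

from nettopo import analysis, generators

for build, label in [
    (lambda: generators.generate_barabasi_albert(128, 2, seed=1), "BA"),
    (lambda: generators.generate_hierarchical(3, seed=1), "hierarchical"),
]:
    net = build()
    hubs = analysis.identify_hubs(net)
    cls = analysis.classify_topology(net)
    print(f"{label} network {net.graph['name']}:")
    print(f"  mean degree {hubs.mean_degree:.3f}, SD {hubs.degree_sd:.3f}, "
          f"hub threshold {hubs.threshold:.3f}")
    print(f"  {len(hubs.hubs)} hubs, top: {hubs.hubs[:3]}")
    print(f"  class = {cls.label}, small-world = {cls.small_world}")
    print(f"  evidence: clustering {cls.evidence.mean_clustering:.3f}, "
          f"degree-fit gamma {cls.evidence.gamma:.3f}, "
          f"degree-cc r {cls.evidence.degree_cc_r:.3f}")
    print()
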