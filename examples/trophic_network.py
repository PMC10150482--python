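"""Build per-arm co-occurrence networks and classify trophic associations.

Merges four synthetic kingdom tables into an integrated relative-abundance
table, builds one Spearman/BH network per resource arm (|rho| > 0.6,
adjusted p < 0.05, occurrence >= 20 of 30 samples), and summarises the
within-trophic (WTA) vs cross-trophic (CTA) association proportions of
per-sample subnetworks.
"""

from trophostab import (
    IntegratedAbundanceTable,
    NetworkConfig,
    build_network,
    enumerate_edge_types,
    filter_by_occurrence,
    generate_field_study,
    merge_integrated,
    network_properties,
    sample_association_table,
)

types = enumerate_edge_types()
print(f"association taxonomy: {len(types)} (kingdom pair, sign) types in "
      f"{len({t.category for t in types})} categories")

study = generate_field_study(seed=1)
merged = merge_integrated(study.tables)
cfg = NetworkConfig()  # rho > 0.6, BH alpha 0.05, occurrence 20/30

for arm in ("low", "high"):
    samples = [s for s, lv in study.truth.resource_levels.items()
               if lv == arm]
    table = IntegratedAbundanceTable(abundances=merged.abundances[samples],
                                     kingdoms=merged.kingdoms)
    net = build_network(filter_by_occurrence(table, cfg), cfg,
                        name=f"{arm}_resource")
    props = network_properties(net)
    subs = sample_association_table(net, table)
    print(f"{arm:>4}-resource network: {props['n_nodes']:.0f} nodes, "
          f"{props['n_links']:.0f} links, density {props['density']:.4f}; "
          f"mean per-sample CTA proportion {subs['cta_proportion'].mean():.2f}")
# The high-resource arm should carry a visibly larger share of cross-trophic
# (bacteria/fungi <-> protists/nematodes) associations — the planted
# direction that mirrors resource-enriched soils.
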