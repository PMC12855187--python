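"""Pathway over-representation and the pathway-overlap network.

The nine discriminating metabolites are tested against the bundled
metabolite-set library with the upper-tail hypergeometric test; pathways
sharing member metabolites are linked into a network whose node size and
color would encode enrichment ratio and p-value in a plot.
"""

import psametab as pm

significant = ["alanine", "glucose", "glutamine", "glycylproline",
               "isoleucine", "leucine", "methionine", "serine", "valine"]

library = pm.load_builtin_library()
res = pm.hypergeometric_ora(significant, library)
print(res.table.head(6)[["k", "K", "enrichment_ratio", "p", "p_adj"]]
      .round(3))

G = pm.pathway_network(res)
print(f"\nnetwork: {G.number_of_nodes()} pathways, "
      f"{G.number_of_edges()} overlap edges; e.g.")
for a, b, d in sorted(G.edges(data=True), key=lambda e: -e[2]["weight"])[:4]:
    print(f"  {a} -- {b}: shares {d['shared']}")
print("Enrichment ratio is observed/expected hits; edges show pathways "
      "coupled through shared metabolites (e.g. glutathione and alanine "
      "metabolism via glutamate).")
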