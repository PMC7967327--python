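"""Summarize the mined rule set: hub variants, dyads, network, search space.

Writes the item-frequency table (with gene/position annotation), the
bipartite item-rule network of the top 15 rules (GraphML + edge list), the
co-occurrence of the two most frequent items, and the exhaustive-search
combinatorics that rule mining prunes.
"""

from pathlib import Path

import networkx as nx
import pandas as pd

import riskrules as rr
from riskrules import io
from riskrules.mining import rules_from_frame
from riskrules.summaries import item_frequency_frame

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rules = rules_from_frame(pd.read_csv(BASE / "rules.tsv", sep="\t"))
    specs = io.read_variant_specs(BASE / "cohort" / "variant_specs.tsv")
    freq = rr.item_frequency(rules, top_k=15, specs=specs)
    item_frequency_frame(freq).to_csv(BASE / "item_frequency.tsv", sep="\t",
                                      index=False)
    print("most frequent items across rules:")
    for row in freq[:5]:
        print(f"  {row.item_id}: {row.n_rules} rules ({row.pct_rules:.1f}%), "
              f"{row.n_top_k} of top 15")

    if len(freq) >= 2:
        a, b = freq[0].item_id, freq[1].item_id
        co = rr.cooccurrence(rules, a, b)
        print(f"{co['conditional_pct']:.1f}% of rules with {a} also contain {b} "
              f"(joint {co['joint_pct']:.1f}% of all rules)")

    net = rr.rules_network(rules, top_k=15)
    nx.write_graphml(net, BASE / "rules_network.graphml")
    pd.DataFrame(net.edges, columns=["item", "rule"]).to_csv(
        BASE / "rules_network_edges.tsv", sep="\t", index=False)
    print(f"top-15 network: {net.number_of_nodes()} nodes, "
          f"{net.number_of_edges()} edges")

    space = rr.interaction_search_space(196, [2, 3, 4])
    io.write_json(space, BASE / "search_space.json")
    print("exhaustive-search burden over 196 variants:",
          ", ".join(f"{k}-way: {v:,}" for k, v in space["per_order"].items()))


if __name__ == "__main__":
    main()
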