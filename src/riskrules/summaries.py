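"""Rule-set summaries: ranking, item frequencies, dyads, networks, counts.

These operations describe the mined rule set as a whole — which variants are
hubs across rules, which dyads travel together, and how the top rules overlap
— plus the exhaustive-search combinatorics that motivate pruning in the first
place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .containers import VariantSpec
from .mining import Rule


@dataclass(frozen=True)
class ItemFrequencyRow:
    item_id: str
    gene: str
    chromosome: str
    position: int
    n_rules: int
    pct_rules: float
    n_top_k: int
    pct_top_k: float


def rank_rules(rules: list[Rule], key: str = "confidence", top_k: int | None = None,
               p_values: dict[tuple[tuple[str, ...], str], float] | None = None) -> list[Rule]:
    """Deterministic total order on rules.

    Descending by ``key`` (ascending for ``p_value``); ties broken by higher
    support, then lexicographic LHS.  ``p_values`` maps (lhs, rhs) to a
    p-value when ranking by p.
    """
    if key in ("confidence", "support"):
        def sort_key(r: Rule):
            return (-getattr(r, key), -r.support, r.lhs)
    elif key == "p_value":
        if p_values is None:
            raise ValueError("ranking by p_value requires a p_values mapping")
        def sort_key(r: Rule):
            return (p_values[(r.lhs, r.rhs)], -r.support, r.lhs)
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    ordered = sorted(rules, key=sort_key)
    return ordered if top_k is None else ordered[:top_k]


def item_frequency(
    rules: list[Rule],
    top_k: int = 15,
    specs: list[VariantSpec] | None = None,
) -> list[ItemFrequencyRow]:
    """Per-item membership counts over all rules and over the top-k by
    confidence, with percentages of the respective denominators."""
    if not rules:
        return []
    spec_by_id = {s.variant_id: s for s in (specs or [])}
    total = len(rules)
    top = rank_rules(rules, key="confidence", top_k=top_k)
    n_top = len(top)

    counts: dict[str, int] = {}
    top_counts: dict[str, int] = {}
    for r in rules:
        for item in r.lhs:
            counts[item] = counts.get(item, 0) + 1
    for r in top:
        for item in r.lhs:
            top_counts[item] = top_counts.get(item, 0) + 1

    rows = []
    for item, c in counts.items():
        s = spec_by_id.get(item)
        rows.append(
            ItemFrequencyRow(
                item_id=item,
                gene=s.gene if s else "",
                chromosome=s.chromosome if s else "",
                position=s.position if s else 0,
                n_rules=c,
                pct_rules=100.0 * c / total,
                n_top_k=top_counts.get(item, 0),
                pct_top_k=100.0 * top_counts.get(item, 0) / n_top if n_top else 0.0,
            )
        )
    rows.sort(key=lambda r: (-r.n_rules, r.item_id))
    return rows


def item_frequency_frame(rows: list[ItemFrequencyRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SNP": [r.item_id for r in rows],
            "Chr": [r.chromosome for r in rows],
            "Base Pair hg19": [r.position for r in rows],
            "Gene": [r.gene for r in rows],
            "Count": [r.n_rules for r in rows],
            "Pct": [round(r.pct_rules, 1) for r in rows],
            "Count in top k": [r.n_top_k for r in rows],
            "Pct in top k": [round(r.pct_top_k, 1) for r in rows],
        }
    )


def cooccurrence(rules: list[Rule], item_a: str, item_b: str) -> dict:
    """How often item_b travels with item_a across the rule set.

    Returns the conditional percentage P(b in rule | a in rule), the joint
    percentage of all rules containing both, and the underlying counts.  The
    conditional is reported as None (undefined), not 0, when item_a appears
    in no rules.
    """
    n_a = sum(1 for r in rules if item_a in r.lhs)
    n_joint = sum(1 for r in rules if item_a in r.lhs and item_b in r.lhs)
    total = len(rules)
    return {
        "item_a": item_a,
        "item_b": item_b,
        "n_rules_a": n_a,
        "n_rules_joint": n_joint,
        "conditional_pct": 100.0 * n_joint / n_a if n_a else None,
        "joint_pct": 100.0 * n_joint / total if total else None,
    }


def rules_network(rules: list[Rule], top_k: int = 15) -> nx.DiGraph:
    """Bipartite item -> rule membership graph for the top-k rules by
    confidence.  Rule nodes carry a ``support`` size attribute; there are no
    item-item edges.  Serializable as GraphML."""
    top = rank_rules(rules, key="confidence", top_k=top_k)
    G = nx.DiGraph()
    for i, r in enumerate(top, start=1):
        rule_node = f"rule_{i:02d}"
        G.add_node(
            rule_node,
            kind="rule",
            support=float(r.support),
            confidence=float(r.confidence),
            lhs=";".join(r.lhs),
        )
        for item in r.lhs:
            if not G.has_node(item):
                G.add_node(item, kind="item")
            G.add_edge(item, rule_node)
    return G


def interaction_search_space(n_variants: int, orders) -> dict:
    """Exact count of k-way combinations to test per interaction order.

    Uses exact integer binomial coefficients; the total quantifies the
    exhaustive-search burden that itemset mining prunes.
    """
    counts = {}
    for k in orders:
        if k < 2:
            raise ValueError("interaction order must be >= 2")
        if k > n_variants:
            raise ValueError(f"order {k} exceeds n_variants {n_variants}")
        counts[int(k)] = math.comb(n_variants, k)
    return {"per_order": counts, "total": sum(counts.values())}
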