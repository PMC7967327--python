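"""Apriori frequent-itemset mining and disease-consequent rule generation.

Support counting is exact: item columns are packed into bitsets and candidate
conjunctions counted with popcounts — no sampling, no approximation.  The
level-wise search exploits support antimonotonicity (a superset is never more
frequent than its subsets): size-k candidates are joined from frequent
(k-1)-sets sharing a (k-2)-prefix and pruned when any (k-1)-subset is
infrequent.

Only rules with the disease item on the right-hand side are generated; the
item vocabulary contains presence-side items only (no complement items).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IncidenceMatrix

_COUNT_CHUNK = 262_144


class CandidateExplosionError(RuntimeError):
    pass


@dataclass(frozen=True)
class Itemset:
    items: tuple[str, ...]
    count: int
    support: float


@dataclass(frozen=True)
class Rule:
    """An association rule LHS -> RHS with exact counts and derived metrics."""

    lhs: tuple[str, ...]
    rhs: str
    lhs_count: int
    joint_count: int
    rhs_count: int
    n_subjects: int

    @property
    def support(self) -> float:
        return self.joint_count / self.n_subjects

    @property
    def confidence(self) -> float:
        return self.joint_count / self.lhs_count if self.lhs_count else 0.0

    @property
    def lift(self) -> float:
        p_rhs = self.rhs_count / self.n_subjects
        return self.confidence / p_rhs if p_rhs else float("nan")

    @property
    def length(self) -> int:
        return len(self.lhs) + 1

    def __str__(self) -> str:
        return (
            f"{{{', '.join(self.lhs)}}} -> {self.rhs} "
            f"(support={self.support:.3f}, confidence={self.confidence:.3f}, "
            f"lift={self.lift:.2f})"
        )


@dataclass(frozen=True)
class MiningConfig:
    min_support: float = 0.05
    min_confidence: float = 0.80
    max_rule_length: int = 5
    consequent: str = "MS"

    def __post_init__(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")
        if not 0 < self.min_confidence <= 1:
            raise ValueError("min_confidence must be in (0, 1]")
        if self.max_rule_length < 2:
            raise ValueError("max_rule_length must be >= 2")


def _pack(cells: np.ndarray) -> np.ndarray:
    """items x nbytes uint8 bitset, one row per item."""
    return np.packbits(np.ascontiguousarray(cells.T), axis=1)


def _count_sets(packed: np.ndarray, cands: np.ndarray) -> np.ndarray:
    """Exact subject counts for candidate itemsets (rows of column indices)."""
    counts = np.empty(len(cands), dtype=np.int64)
    for lo in range(0, len(cands), _COUNT_CHUNK):
        chunk = cands[lo : lo + _COUNT_CHUNK]
        conj = np.bitwise_and.reduce(packed[chunk], axis=1)
        counts[lo : lo + _COUNT_CHUNK] = np.bitwise_count(conj).sum(axis=1)
    return counts


def _min_count(min_support: float, n: int) -> int:
    # smallest integer count with count / n >= min_support (float-safe)
    return int(np.ceil(min_support * n - 1e-9))


def _apriori_indices(
    cells: np.ndarray,
    min_count: int,
    max_size: int,
    candidate_cap: int,
) -> dict[tuple[int, ...], int]:
    """Level-wise apriori over column indices; returns {itemset: count}."""
    n_items = cells.shape[1]
    packed = _pack(cells)
    item_counts = np.bitwise_count(packed).sum(axis=1)

    out: dict[tuple[int, ...], int] = {}
    frequent = []
    for j in range(n_items):
        if item_counts[j] >= min_count:
            out[(j,)] = int(item_counts[j])
            frequent.append((j,))

    size = 2
    while frequent and size <= max_size:
        prev_set = set(frequent)
        groups: dict[tuple[int, ...], list[int]] = defaultdict(list)
        for t in frequent:
            groups[t[:-1]].append(t[-1])
        cands: list[tuple[int, ...]] = []
        for prefix, lasts in groups.items():
            lasts.sort()
            for a in range(len(lasts)):
                for b in range(a + 1, len(lasts)):
                    cand = prefix + (lasts[a], lasts[b])
                    # drops of the last two positions are frequent by join
                    if all(
                        cand[:x] + cand[x + 1 :] in prev_set
                        for x in range(len(cand) - 2)
                    ):
                        cands.append(cand)
            if len(cands) > candidate_cap:
                raise CandidateExplosionError(
                    f"more than {candidate_cap} size-{size} candidates; raise "
                    "min_support or the candidate cap"
                )
        if not cands:
            break
        arr = np.array(cands, dtype=np.int64)
        counts = _count_sets(packed, arr)
        keep = counts >= min_count
        frequent = [tuple(t) for t in arr[keep]]
        for t, c in zip(frequent, counts[keep]):
            out[t] = int(c)
        size += 1
    return out


def itemset_count(I: IncidenceMatrix, items) -> int:
    """Number of subjects containing every item; the empty set counts all."""
    items = list(items)
    if not items:
        return I.n_subjects
    return int(I.columns(items).all(axis=1).sum())


def frequent_itemsets(
    I: IncidenceMatrix,
    min_support: float,
    max_size: int,
    candidate_cap: int = 5_000_000,
) -> list[Itemset]:
    """All itemsets with support >= min_support and size <= max_size.

    Complete and sound: output equals exhaustive enumeration (property-tested
    against brute force on small instances).
    """
    if not 0 <= min_support <= 1:
        raise ValueError("min_support must be in [0, 1]")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    n = I.n_subjects
    found = _apriori_indices(
        I.cells, _min_count(min_support, n), max_size, candidate_cap
    )
    out = [
        Itemset(
            items=tuple(sorted(I.item_ids[j] for j in t)),
            count=c,
            support=c / n,
        )
        for t, c in found.items()
    ]
    out.sort(key=lambda s: (len(s.items), s.items))
    return out


def generate_rules(
    frequent: list[Itemset],
    config: MiningConfig,
    I: IncidenceMatrix,
) -> list[Rule]:
    """Disease-consequent rules from frequent itemsets.

    For every frequent itemset containing the consequent (and no longer than
    ``max_rule_length``), emits the single rule (itemset minus consequent) ->
    consequent when its confidence clears ``min_confidence``.
    """
    if config.consequent not in I.item_ids:
        raise KeyError(f"consequent {config.consequent!r} not in item vocabulary")
    counts = {s.items: s.count for s in frequent}
    n = I.n_subjects
    rhs_count = counts.get((config.consequent,))
    if rhs_count is None:
        rhs_count = itemset_count(I, [config.consequent])

    rules = []
    for s in frequent:
        if config.consequent not in s.items or len(s.items) < 2:
            continue
        if len(s.items) > config.max_rule_length:
            continue
        lhs = tuple(sorted(i for i in s.items if i != config.consequent))
        lhs_count = counts.get(lhs)
        if lhs_count is None:
            lhs_count = itemset_count(I, lhs)
        rule = Rule(
            lhs=lhs,
            rhs=config.consequent,
            lhs_count=lhs_count,
            joint_count=s.count,
            rhs_count=rhs_count,
            n_subjects=n,
        )
        if rule.confidence >= config.min_confidence - 1e-12:
            rules.append(rule)
    rules.sort(key=lambda r: (r.length, r.lhs))
    return rules


def mine_rules(
    I: IncidenceMatrix,
    config: MiningConfig,
    candidate_cap: int = 5_000_000,
) -> list[Rule]:
    """End-to-end mining of disease-consequent rules.

    Equivalent to ``generate_rules(frequent_itemsets(...), ...)`` but mines
    itemsets on the consequent-conditioned submatrix, using the identity
    count(S ∪ {D}) = count(S among subjects with D): with a fixed consequent
    only itemsets containing it are ever needed, which prunes far harder.
    """
    if config.consequent not in I.item_ids:
        raise KeyError(f"consequent {config.consequent!r} not in item vocabulary")
    n = I.n_subjects
    rhs_col = I.item_index(config.consequent)
    rhs_mask = I.cells[:, rhs_col]
    rhs_count = int(rhs_mask.sum())
    other_cols = [j for j in range(I.n_items) if j != rhs_col]
    sub = I.cells[np.ix_(rhs_mask, other_cols)]

    found = _apriori_indices(
        sub,
        _min_count(config.min_support, n),
        config.max_rule_length - 1,
        candidate_cap,
    )
    if not found:
        return []

    sets = sorted(found)
    arr_list = [np.array([t for t in sets if len(t) == k], dtype=np.int64)
                for k in range(1, config.max_rule_length)]
    packed_full = _pack(I.cells[:, other_cols])
    rules = []
    for arr in arr_list:
        if arr.size == 0:
            continue
        lhs_counts = _count_sets(packed_full, arr)
        for t, lc in zip(arr, lhs_counts):
            t = tuple(int(x) for x in t)
            rule = Rule(
                lhs=tuple(sorted(I.item_ids[other_cols[j]] for j in t)),
                rhs=config.consequent,
                lhs_count=int(lc),
                joint_count=found[t],
                rhs_count=rhs_count,
                n_subjects=n,
            )
            if rule.confidence >= config.min_confidence - 1e-12:
                rules.append(rule)
    rules.sort(key=lambda r: (r.length, r.lhs))
    return rules


def evaluate_itemset(I: IncidenceMatrix, lhs, consequent: str) -> Rule:
    """Metrics for an arbitrary user-specified rule, bypassing thresholds.

    Supports post-hoc evaluation of dyads/triads that did not clear the
    mining thresholds.
    """
    lhs = tuple(sorted(lhs))
    if consequent in lhs:
        raise ValueError("lhs may not contain the consequent")
    lhs_cols = I.columns(lhs)
    rhs_vec = I.cells[:, I.item_index(consequent)]
    lhs_mask = lhs_cols.all(axis=1) if lhs else np.ones(I.n_subjects, dtype=bool)
    return Rule(
        lhs=lhs,
        rhs=consequent,
        lhs_count=int(lhs_mask.sum()),
        joint_count=int((lhs_mask & rhs_vec).sum()),
        rhs_count=int(rhs_vec.sum()),
        n_subjects=I.n_subjects,
    )


def rules_to_frame(rules: list[Rule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lhs": [";".join(r.lhs) for r in rules],
            "rhs": [r.rhs for r in rules],
            "lhs_count": [r.lhs_count for r in rules],
            "joint_count": [r.joint_count for r in rules],
            "rhs_count": [r.rhs_count for r in rules],
            "n_subjects": [r.n_subjects for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
            "length": [r.length for r in rules],
        }
    )


def rules_from_frame(df: pd.DataFrame) -> list[Rule]:
    return [
        Rule(
            lhs=tuple(str(row.lhs).split(";")) if str(row.lhs) else (),
            rhs=str(row.rhs),
            lhs_count=int(row.lhs_count),
            joint_count=int(row.joint_count),
            rhs_count=int(row.rhs_count),
            n_subjects=int(row.n_subjects),
        )
        for row in df.itertuples(index=False)
    ]
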