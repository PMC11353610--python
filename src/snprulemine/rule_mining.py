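"""Apriori frequent-itemset mining and constrained association-rule generation.

The miner is the classic levelwise algorithm of Agrawal & Srikant:
frequent (k-1)-itemsets sharing a (k-2)-prefix are joined into k-candidates,
candidates with an infrequent (k-1)-subset are pruned (support is
anti-monotone), and surviving candidates are counted exactly against the
transactions.  Rules are then generated with a fixed single-item consequent
(the allergy outcome by default) and filtered on inclusive support and
confidence thresholds.

Metrics for a rule X => Y over m transactions, with n_x, n_y, n_xy the
transaction counts containing X, Y and both:

    support    = n_xy / m                     (joint frequency)
    confidence = n_xy / n_x                   (P(Y | X))
    lift       = confidence / (n_y / m)       (observed / expected support)
    conviction = (1 - n_y/m) / (1 - confidence), +inf for exception-free rules

``brute_force_rules`` re-derives the same rule set by exhaustive subset
enumeration and direct counting; it exists as an independent oracle for
equivalence testing and is not used by the mining path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .cohort_io import CohortTable
from .itemset_encoding import EncodingConfig, Item, Transaction, encode_cohort


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[Item]
    count: int
    support: float


@dataclass(frozen=True)
class RuleMetrics:
    support: float
    confidence: float
    lift: float
    conviction: float
    n_xy: int
    n_x: int
    n_y: int
    m: int


@dataclass(frozen=True)
class AssociationRule:
    """X => Y with X ∩ Y = ∅ and both non-empty."""

    antecedent: frozenset[Item]
    consequent: frozenset[Item]
    metrics: RuleMetrics

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def antecedent_sorted(self) -> tuple[Item, ...]:
        return tuple(sorted(self.antecedent))


@dataclass
class MiningConfig:
    """Mining thresholds; defaults are the study's selection settings:
    consequent ("Allergic","Yes"), support >= 0.1, confidence >= 0.9,
    both inclusive, antecedent length unbounded."""

    min_support: float = 0.1
    min_confidence: float = 0.9
    consequent: Item = Item("Allergic", "Yes")
    max_antecedent_len: Optional[int] = None

    def __post_init__(self) -> None:
        for name, v in (("min_support", self.min_support),
                        ("min_confidence", self.min_confidence)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def rule_metrics_from_counts(n_xy: int, n_x: int, n_y: int, m: int) -> RuleMetrics:
    """Compute the four rule metrics from raw transaction counts."""
    if not (0 <= n_xy <= min(n_x, n_y) <= m):
        raise ValueError(f"inconsistent counts n_xy={n_xy}, n_x={n_x}, n_y={n_y}, m={m}")
    if n_x == 0:
        raise ValueError("antecedent never occurs (n_x = 0)")
    if n_y == 0:
        raise ValueError("consequent never occurs (n_y = 0): lift undefined")
    confidence = n_xy / n_x
    support = n_xy / m
    p_y = n_y / m
    lift = confidence / p_y
    conviction = math.inf if confidence == 1.0 else (1.0 - p_y) / (1.0 - confidence)
    return RuleMetrics(support, confidence, lift, conviction, n_xy, n_x, n_y, m)


# ---------------------------------------------------------------------------
# apriori


def _count_candidates(candidates: list[tuple[Item, ...]],
                      transactions: Sequence[frozenset[Item]]) -> dict[tuple[Item, ...], int]:
    counts = {c: 0 for c in candidates}
    cand_sets = [(c, frozenset(c)) for c in candidates]
    for t in transactions:
        for key, cset in cand_sets:
            if cset <= t:
                counts[key] += 1
    return counts


def apriori_frequent_itemsets(transactions: Sequence[Transaction], min_support: float,
                              max_len: Optional[int] = None) -> list[FrequentItemset]:
    """All itemsets with support >= min_support, by levelwise search.

    Output is sorted by (size, lexicographic item order). ``min_support``
    must be positive — a zero threshold would enumerate the power set.
    """
    if min_support <= 0:
        raise ValueError("min_support must be > 0")
    if not transactions:
        raise ValueError("no transactions")
    m = len(transactions)
    tsets = [t.items for t in transactions]
    min_count = min_support * m

    # level 1
    item_counts: dict[Item, int] = {}
    for t in tsets:
        for it in t:
            item_counts[it] = item_counts.get(it, 0) + 1
    frequent: dict[tuple[Item, ...], int] = {
        (it,): c for it, c in item_counts.items() if c >= min_count
    }
    all_frequent = dict(frequent)
    k = 1
    while frequent and (max_len is None or k < max_len):
        k += 1
        prev = sorted(frequent)
        prev_set = set(prev)
        # join step: (k-1)-sets sharing their first k-2 items
        candidates: list[tuple[Item, ...]] = []
        for i, x in enumerate(prev):
            for y in prev[i + 1:]:
                if x[:-1] != y[:-1]:
                    break  # sorted order: no later y shares the prefix
                cand = x + (y[-1],)
                # prune: every (k-1)-subset must be frequent
                if all(tuple(sub) in prev_set for sub in combinations(cand, k - 1)):
                    candidates.append(cand)
        counts = _count_candidates(candidates, tsets)
        frequent = {c: n for c, n in counts.items() if n >= min_count}
        all_frequent.update(frequent)

    out = [FrequentItemset(frozenset(items), n, n / m) for items, n in all_frequent.items()]
    out.sort(key=lambda f: (len(f.items), tuple(sorted(f.items))))
    return out


def _sort_rules(rules: list[AssociationRule]) -> list[AssociationRule]:
    return sorted(rules, key=lambda r: (-r.metrics.confidence, -r.metrics.support,
                                        r.antecedent_sorted))


def generate_rules(frequent_itemsets: Sequence[FrequentItemset],
                   transactions: Sequence[Transaction],
                   config: Optional[MiningConfig] = None) -> list[AssociationRule]:
    """Rules (Z \\ {y}) => {y} from frequent itemsets Z containing the fixed
    consequent y, kept when support >= min_support AND confidence >=
    min_confidence (both inclusive).  Sorted by confidence desc, support
    desc, then antecedent lexicographic."""
    config = config or MiningConfig()
    y = config.consequent
    m = len(transactions)
    count_of = {f.items: f.count for f in frequent_itemsets}
    n_y = count_of.get(frozenset([y]))
    if n_y is None:
        # consequent itself below min_support (or absent): no rule can
        # reach min_support, since support(rule) <= support({y})
        return []
    rules = []
    for f in frequent_itemsets:
        if y not in f.items or len(f.items) < 2:
            continue
        antecedent = f.items - {y}
        if (config.max_antecedent_len is not None
                and len(antecedent) > config.max_antecedent_len):
            continue
        n_x = count_of[antecedent]  # subsets of frequent sets are frequent
        metrics = rule_metrics_from_counts(f.count, n_x, n_y, m)
        if metrics.support >= config.min_support and metrics.confidence >= config.min_confidence:
            rules.append(AssociationRule(antecedent, frozenset([y]), metrics))
    return _sort_rules(rules)


def mine_rules(transactions: Sequence[Transaction],
               config: Optional[MiningConfig] = None) -> list[AssociationRule]:
    """apriori + constrained rule generation over encoded transactions."""
    config = config or MiningConfig()
    max_len = None if config.max_antecedent_len is None else config.max_antecedent_len + 1
    frequent = apriori_frequent_itemsets(transactions, config.min_support, max_len)
    return generate_rules(frequent, transactions, config)


def mine_allergy_rules(table: CohortTable,
                       encoding_config: Optional[EncodingConfig] = None,
                       mining_config: Optional[MiningConfig] = None) -> list[AssociationRule]:
    """End-to-end encode -> apriori -> rule generation on a cohort, with
    the study's default thresholds."""
    transactions, _ = encode_cohort(table, encoding_config)
    return mine_rules(transactions, mining_config)


# ---------------------------------------------------------------------------
# exhaustive oracle (tests only)

BRUTE_FORCE_MAX_ITEMS = 25


def brute_force_rules(transactions: Sequence[Transaction],
                      config: Optional[MiningConfig] = None) -> list[AssociationRule]:
    """Exhaustive rule enumeration by direct counting — the test oracle.

    Counts every itemset occurring in the data by expanding each
    transaction's power set, then applies exactly the same filters and
    ordering as the mining path.  Refuses catalogs above
    ``BRUTE_FORCE_MAX_ITEMS`` items.
    """
    config = config or MiningConfig()
    if not transactions:
        return []
    catalog = frozenset().union(*(t.items for t in transactions))
    if len(catalog) > BRUTE_FORCE_MAX_ITEMS:
        raise ValueError(f"catalog of {len(catalog)} items exceeds the "
                         f"{BRUTE_FORCE_MAX_ITEMS}-item exhaustive bound")
    m = len(transactions)
    counts: dict[frozenset[Item], int] = {}
    for t in transactions:
        items = sorted(t.items)
        for k in range(1, len(items) + 1):
            for combo in combinations(items, k):
                key = frozenset(combo)
                counts[key] = counts.get(key, 0) + 1
    y = config.consequent
    n_y = counts.get(frozenset([y]), 0)
    if n_y == 0:
        return []
    rules = []
    for itemset, n_xy in counts.items():
        if y not in itemset or len(itemset) < 2:
            continue
        antecedent = itemset - {y}
        if (config.max_antecedent_len is not None
                and len(antecedent) > config.max_antecedent_len):
            continue
        metrics = rule_metrics_from_counts(n_xy, counts[antecedent], n_y, m)
        if metrics.support >= config.min_support and metrics.confidence >= config.min_confidence:
            rules.append(AssociationRule(antecedent, frozenset([y]), metrics))
    return _sort_rules(rules)


# ---------------------------------------------------------------------------
# export


def rules_to_records(rules: Sequence[AssociationRule]) -> list[dict]:
    return [
        {
            "antecedent": "; ".join(str(it) for it in r.antecedent_sorted),
            "consequent": str(next(iter(r.consequent))),
            "confidence": r.metrics.confidence,
            "support": r.metrics.support,
            "lift": r.metrics.lift,
            "conviction": r.metrics.conviction,
            "n_xy": r.metrics.n_xy,
            "n_x": r.metrics.n_x,
            "n_y": r.metrics.n_y,
            "m": r.metrics.m,
        }
        for r in rules
    ]


def write_rules(rules: Sequence[AssociationRule], tsv_path=None, json_path=None) -> None:
    """Write rules as TSV (metrics to 3 d.p., antecedent ';'-joined) and/or
    JSON (full precision plus raw counts)."""
    records = rules_to_records(rules)
    if tsv_path is not None:
        with open(tsv_path, "w", encoding="utf-8") as fh:
            fh.write("antecedent\tconsequent\tconfidence\tsupport\tlift\tconviction\n")
            for rec in records:
                conv = "inf" if math.isinf(rec["conviction"]) else f"{rec['conviction']:.3f}"
                fh.write(f"{rec['antecedent']}\t{rec['consequent']}\t"
                         f"{rec['confidence']:.3f}\t{rec['support']:.3f}\t"
                         f"{rec['lift']:.3f}\t{conv}\n")
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1, default=float)


def read_rules_json(path) -> list[AssociationRule]:
    """Load rules previously written by `write_rules(json_path=...)`."""
    with open(path, encoding="utf-8") as fh:
        records = json.load(fh)
    rules = []
    for rec in records:
        antecedent = frozenset(
            Item(*tok.split("=", 1)) for tok in rec["antecedent"].split("; ")
        )
        consequent = frozenset([Item(*rec["consequent"].split("=", 1))])
        metrics = rule_metrics_from_counts(rec["n_xy"], rec["n_x"], rec["n_y"], rec["m"])
        rules.append(AssociationRule(antecedent, consequent, metrics))
    return rules
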