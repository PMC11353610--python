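"""Diagnostic evaluation of mined rules as genotype-cluster classifiers.

A rule's antecedent is treated as a test: a subject is rule-positive iff
their encoded items contain every antecedent item.  Subjects are then
cross-tabulated rule-positive/negative by case/control, giving
sensitivity, specificity, PPV and NPV at the cohort's own case
prevalence, plus the crude odds ratio with a Woolf 95% CI and a Fisher
exact p-value.  The cumulative ("all rules") classifier is positive when
any rule's antecedent applies.

On the cohort the rules were mined from, a rule's PPV equals its mining
confidence and its positive-case fraction equals its mining support,
exactly — both are the same counts in different clothing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .association_stats import AssociationResult, Contingency2x2, odds_ratio_woolf
from .cohort_io import CohortTable
from .itemset_encoding import EncodingConfig, Item, Transaction, encode_cohort
from .rule_mining import AssociationRule


@dataclass(frozen=True)
class RulePerformance:
    """2x2 classifier counts and the derived diagnostic metrics."""

    label: str
    contingency: Contingency2x2  # a=pos cases, b=pos controls, c=neg cases, d=neg controls
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    association: AssociationResult

    @property
    def pos_cases(self) -> int:
        return self.contingency.a

    @property
    def pos_controls(self) -> int:
        return self.contingency.b


def rule_applies(transaction: Transaction, rule: AssociationRule) -> bool:
    """True iff the rule's antecedent is a subset of the transaction's items
    (the outcome item plays no part)."""
    return rule.antecedent <= transaction.items


def performance_from_counts(a: int, b: int, c: int, d: int, label: str = "",
                            haldane: bool = False) -> RulePerformance:
    """Diagnostic metrics from classifier counts (a=pos cases, b=pos
    controls, c=neg cases, d=neg controls)."""
    t = Contingency2x2(a, b, c, d)
    n_cases, n_controls = a + c, b + d
    pos, neg = a + b, c + d
    return RulePerformance(
        label=label,
        contingency=t,
        sensitivity=a / n_cases if n_cases else math.nan,
        specificity=d / n_controls if n_controls else math.nan,
        ppv=a / pos if pos else math.nan,
        npv=d / neg if neg else math.nan,
        association=odds_ratio_woolf(t, haldane=haldane),
    )


def _classify(transactions: Sequence[Transaction], rules: Sequence[AssociationRule],
              positive_item: Item) -> tuple[int, int, int, int]:
    a = b = c = d = 0
    for t in transactions:
        is_case = positive_item in t.items
        positive = any(rule_applies(t, r) for r in rules)
        if positive:
            a, b = (a + 1, b) if is_case else (a, b + 1)
        else:
            c, d = (c + 1, d) if is_case else (c, d + 1)
    return a, b, c, d


def evaluate_rule(table: CohortTable, rule: AssociationRule,
                  encoding_config: Optional[EncodingConfig] = None,
                  label: str = "") -> RulePerformance:
    """Evaluate one rule as a classifier over a cohort."""
    config = encoding_config or EncodingConfig()
    transactions, _ = encode_cohort(table, config)
    a, b, c, d = _classify(transactions, [rule], config.positive_item)
    return performance_from_counts(a, b, c, d, label=label)


def evaluate_rule_set(table: CohortTable, rules: Sequence[AssociationRule],
                      encoding_config: Optional[EncodingConfig] = None
                      ) -> tuple[list[RulePerformance], RulePerformance]:
    """Per-rule performances plus the cumulative any-rule classifier."""
    if not rules:
        raise ValueError("no rules to evaluate")
    config = encoding_config or EncodingConfig()
    transactions, _ = encode_cohort(table, config)
    per_rule = []
    for i, rule in enumerate(rules, start=1):
        a, b, c, d = _classify(transactions, [rule], config.positive_item)
        per_rule.append(performance_from_counts(a, b, c, d, label=f"rule_{i:02d}"))
    a, b, c, d = _classify(transactions, rules, config.positive_item)
    cumulative = performance_from_counts(a, b, c, d, label="all_rules")
    return per_rule, cumulative


def performance_records(results: Sequence[RulePerformance]) -> list[dict]:
    out = []
    for r in results:
        t = r.contingency
        n_cases, n_controls = t.a + t.c, t.b + t.d
        out.append({
            "label": r.label,
            "pos_cases": t.a, "pos_controls": t.b,
            "neg_cases": t.c, "neg_controls": t.d,
            "pos_cases_pct": 100.0 * t.a / n_cases if n_cases else math.nan,
            "pos_controls_pct": 100.0 * t.b / n_controls if n_controls else math.nan,
            "odds_ratio": r.association.odds_ratio,
            "ci_low": r.association.ci_low,
            "ci_high": r.association.ci_high,
            "p_value": r.association.p_value,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "ppv": r.ppv,
            "npv": r.npv,
        })
    return out


def write_performance_report(results: Sequence[RulePerformance],
                             tsv_path=None, json_path=None) -> None:
    """Write per-rule performance blocks; TSV rounds percentages to 2 d.p.
    and the diagnostic metrics to 3 d.p., JSON keeps full precision."""
    records = performance_records(results)
    if tsv_path is not None:
        cols = ["label", "pos_cases", "pos_controls", "neg_cases", "neg_controls",
                "pos_cases_pct", "pos_controls_pct", "odds_ratio", "ci_low",
                "ci_high", "p_value", "sensitivity", "specificity", "ppv", "npv"]
        with open(tsv_path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for rec in records:
                vals = []
                for col in cols:
                    v = rec[col]
                    if col.endswith("_pct") or col in ("odds_ratio", "ci_low", "ci_high"):
                        vals.append(f"{v:.2f}" if v == v else "")
                    elif col in ("sensitivity", "specificity", "ppv", "npv"):
                        vals.append(f"{v:.3f}" if v == v else "")
                    elif col == "p_value":
                        vals.append(f"{v:.4g}" if v == v else "")
                    else:
                        vals.append(str(v))
                fh.write("\t".join(vals) + "\n")
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1, default=float)
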