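"""Encoding of cohort records into transactions of (feature, value) items.

Each subject record becomes one *transaction*: a set of items, where an
item is an exact ("FeatureName", "FeatureValue") pair.  Genotype features
are keyed by rsID with the canonical genotype string as value; the binary
outcome is always present as ("Allergic", "Yes"/"No").  Sex and (binned)
age items are optional and off by default, matching the vocabulary of the
mined genotype rules.  Missing genotypes produce no item, so downstream
support counts are conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Union

from .cohort_io import CohortRecord, CohortTable, SnpPanel

logger = logging.getLogger(__name__)


class Item(NamedTuple):
    """A ("FeatureName", "FeatureValue") pair; equality is exact."""

    feature: str
    value: str

    def __str__(self) -> str:
        return f"{self.feature}={self.value}"


@dataclass(frozen=True)
class Transaction:
    """One encoded record: a unique id and its set of items."""

    id: str
    items: frozenset[Item]


@dataclass
class EncodingConfig:
    """Controls which non-genotype features become items.

    Defaults reproduce the genotype-only rule vocabulary: the outcome item
    plus one item per non-missing SNP call, no sex or age items.
    """

    include_sex: bool = False
    include_age: bool = False
    age_bin_edges: Sequence[float] = (40.0, 50.0, 60.0)
    outcome_feature: str = "Allergic"
    outcome_positive: str = "Yes"
    outcome_negative: str = "No"

    def __post_init__(self) -> None:
        edges = list(self.age_bin_edges)
        if edges != sorted(set(edges)):
            raise ValueError("age_bin_edges must be strictly increasing")

    @property
    def positive_item(self) -> Item:
        return Item(self.outcome_feature, self.outcome_positive)

    @property
    def negative_item(self) -> Item:
        return Item(self.outcome_feature, self.outcome_negative)


def age_band_label(age: float, edges: Sequence[float]) -> str:
    """Half-open band label for an age given ordered cut points.

    Edges (40, 50, 60) yield bands "<40", "40-50", "50-60", ">=60".
    """
    edges = list(edges)
    if age < edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= age < hi:
            return f"{lo:g}-{hi:g}"
    return f">={edges[-1]:g}"


def encode_record(record: CohortRecord, panel: SnpPanel,
                  config: Optional[EncodingConfig] = None) -> Transaction:
    """Encode one record as a transaction.

    One item per non-missing genotype (feature = rsID, value = canonical
    genotype string); the outcome item is always present; sex/age items per
    config.  A missing age with ``include_age`` set omits the age item.
    """
    config = config or EncodingConfig()
    items = {config.positive_item if record.status else config.negative_item}
    for rsid in panel.rsids:
        call = record.genotypes.get(rsid)
        if call is not None:
            items.add(Item(rsid, call))
    if config.include_sex and record.sex in ("F", "M"):
        items.add(Item("gender", record.sex))
    if config.include_age:
        if record.age is None:
            logger.warning("subject %s: age missing, no age item emitted",
                           record.subject_id)
        else:
            items.add(Item("age_band", age_band_label(record.age, config.age_bin_edges)))
    return Transaction(id=record.subject_id, items=frozenset(items))


def encode_cohort(table: CohortTable, config: Optional[EncodingConfig] = None
                  ) -> tuple[list[Transaction], frozenset[Item]]:
    """Encode every record; returns (transactions, item catalog).

    The catalog is the set I of all distinct items observed across the m
    transactions (m = record count, preserved exactly).
    """
    config = config or EncodingConfig()
    transactions = [encode_record(rec, table.panel, config) for rec in table.records]
    catalog = frozenset().union(*(t.items for t in transactions)) if transactions else frozenset()
    return transactions, catalog


def decode_genotypes(transaction: Transaction, panel: SnpPanel) -> dict[str, str]:
    """Recover the non-missing genotype calls encoded in a transaction."""
    return {it.feature: it.value for it in transaction.items if it.feature in panel}


def write_baskets(transactions: Sequence[Transaction], path) -> None:
    """Export transactions as a basket file: one transaction per line,
    comma-separated ``feature=value`` tokens, sorted for determinism."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in transactions:
            tokens = sorted(str(it) for it in t.items)
            fh.write(",".join(tokens) + "\n")
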