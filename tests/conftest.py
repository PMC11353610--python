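import numpy as np
import pytest

from snprulemine import load_panel
from snprulemine.cohort_io import _read_cohort_text
from snprulemine.itemset_encoding import Item, Transaction


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture
def cohort_from_text(panel):
    """Factory: build a CohortTable from inline delimited text."""

    def _build(text):
        return _read_cohort_text(text.strip() + "\n", panel)

    return _build


@pytest.fixture
def tiny_cohort(cohort_from_text):
    """Four subjects, two SNPs typed, the rest missing."""
    return cohort_from_text(
        "subject_id\tstatus\tsex\tage\trs2834167\trs2243250\n"
        "s1\tYes\tF\t41\tG/G\tC/C\n"
        "s2\tYes\tM\t55\tG/G\tC/T\n"
        "s3\tNo\tF\t38\tA/G\tC/C\n"
        "s4\tNo\tM\t60\tA/A\tT/T\n"
    )


def make_transactions(items_per_transaction):
    """Transactions from an iterable of iterables of (feature, value) pairs."""
    return [
        Transaction(id=f"t{i}", items=frozenset(Item(f, v) for f, v in items))
        for i, items in enumerate(items_per_transaction)
    ]


def random_transactions(rng, n_transactions=50, n_features=8, p_item=0.4,
                        p_outcome=0.6):
    """Seeded random basket data with a binary outcome item for rule tests."""
    rows = []
    for _ in range(n_transactions):
        items = [("y", "1" if rng.random() < p_outcome else "0")]
        for j in range(n_features):
            if rng.random() < p_item:
                items.append((f"f{j}", "1"))
        rows.append(items)
    return make_transactions(rows)
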