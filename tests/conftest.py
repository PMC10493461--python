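import numpy as np
import pytest

from fctf import build_transactions, worked_example
from fctf.arm import Transaction, TransactionSet


@pytest.fixture
def demo():
    """The fixed hand-computable fixture: 3 components + 1 disease, N = 4."""
    return worked_example()


@pytest.fixture
def demo_tx(demo):
    return build_transactions(demo.predictions, demo.functions, mode="both")


def random_transaction_set(rng: np.random.Generator,
                           max_items: int = 12,
                           max_transactions: int = 30) -> TransactionSet:
    """A random transaction database for oracle-equivalence checks."""
    n_items = int(rng.integers(2, max_items + 1))
    n_tx = int(rng.integers(1, max_transactions + 1))
    alphabet = [f"G{i}" for i in range(n_items)]
    density = float(rng.uniform(0.15, 0.7))
    transactions = []
    for i in range(n_tx):
        items = frozenset(g for g in alphabet if rng.random() < density)
        if items:
            transactions.append(Transaction(f"t{i}", "component", items))
    if not transactions:
        transactions.append(Transaction("t0", "component", frozenset([alphabet[0]])))
    return TransactionSet(transactions)


@pytest.fixture
def component_table(tmp_path):
    """Write a small long-format component library and return its path."""
    path = tmp_path / "components.tsv"
    path.write_text(
        "name\tcategory\tmethod\tcontent\n"
        "Limonene\tterpene\tGCMS\t20.1\n"
        "limonene\tterpene\tHPLC\t18.3\n"
        "citral\taldehyde\tGCMS\t0.4\n"
    )
    return path
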