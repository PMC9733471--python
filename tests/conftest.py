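import numpy as np
import pandas as pd
import pytest

from irae_screen import FactorMatrix, IraeTermList
from irae_screen.pharmacovigilance import make_report_table


@pytest.fixture
def terms() -> IraeTermList:
    return IraeTermList.from_terms(["Colitis", "Pneumonitis", "Hypophysitis"])


@pytest.fixture
def small_reports() -> pd.DataFrame:
    """Two cancer types, hand-countable irAE composition."""
    rows = []
    for i in range(10):
        reaction = ["colitis"] if i < 4 else ["nausea"]
        rows.append((f"A{i}", ["nivolumab"], "melanoma", reaction))
    for i in range(10):
        reaction = ["pneumonitis"] if i < 2 else ["fatigue"]
        rows.append((f"B{i}", ["pembrolizumab"], "glioma", reaction))
    return make_report_table(rows)


def random_report_table(rng: np.random.Generator, n_types: int = 4, n_reports: int = 80):
    """Random small report table for oracle-equivalence checks."""
    types = [f"T{k}" for k in range(n_types)]
    rows = []
    for i in range(n_reports):
        ct = types[rng.integers(n_types)]
        if rng.random() < 0.4:
            reactions = ["colitis", "nausea"]
        else:
            reactions = ["nausea", "fatigue"]
        rows.append((f"R{i}", ["nivolumab"], ct, reactions))
    return make_report_table(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_factor_matrix(rng: np.random.Generator, n_types: int = 21, factors=("a", "b", "c")):
    X = pd.DataFrame(
        rng.normal(size=(n_types, len(factors))),
        columns=list(factors),
        index=[f"CT{k:02d}" for k in range(n_types)],
    )
    y = pd.Series(rng.normal(size=n_types), index=X.index, name="ROR")
    return FactorMatrix(values=X, outcome=y)
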