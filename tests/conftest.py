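import numpy as np
import pandas as pd
import pytest

from synscreen import ExpressionMatrix


def matrix_from_means(
    means: dict[str, float], n_reps: int = 3, jitter: float = 0.0, n_genes: int = 1
) -> ExpressionMatrix:
    """Build a matrix whose genotype means are exact.

    Replicates are the genotype mean plus a centred pattern of amplitude
    ``jitter`` (sums to zero, so the group mean is preserved exactly while
    giving a non-zero residual variance when ``jitter > 0``).
    """
    pattern = np.linspace(-1.0, 1.0, n_reps)
    pattern -= pattern.mean()
    columns, rows = [], []
    for g, mu in means.items():
        for r in range(n_reps):
            columns.append(f"{g}_{r + 1}")
    data = np.empty((n_genes, len(columns)))
    i = 0
    for g, mu in means.items():
        for r in range(n_reps):
            data[:, i] = mu + jitter * pattern[r]
            i += 1
    values = pd.DataFrame(
        data,
        index=[f"gene_{k + 1}" for k in range(n_genes)],
        columns=columns,
    )
    genotypes = pd.Series(
        [c.rsplit("_", 1)[0] for c in columns], index=columns, name="genotype"
    )
    return ExpressionMatrix(values, genotypes)


@pytest.fixture
def factorial_matrix() -> ExpressionMatrix:
    """Additive four-genotype matrix with exact means and mild jitter."""
    return matrix_from_means({"WT": 10.0, "A": 9.0, "B": 9.0, "AB": 8.0}, jitter=0.1)
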