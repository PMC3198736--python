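"""Array-level QC, cyclic loess normalization, probe-set summarization.

Normalization is pairwise cyclic loess on MA coordinates: for each pair of
arrays (i, j), M = x_i - x_j is regressed on A = (x_i + x_j) / 2 by local
linear regression (tricube weights, span as a fraction of points) and half
of the fitted trend is subtracted from array i and added to array j.  The
correction is symmetric, so the grand mean of the matrix is preserved.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def qc_distribution_summary(
    matrix: ExpressionMatrix, flag_threshold: float = 1.0
) -> pd.DataFrame:
    """Per-array distribution summary used to judge array similarity.

    One row per sample with min, quartiles, median, max, mean and sd, plus a
    ``flagged`` column marking any array whose median deviates from the
    across-array median of medians by more than ``flag_threshold`` log2
    units.
    """
    if matrix.n_samples < 1 or matrix.n_genes < 1:
        raise ValueError("matrix must contain at least one sample and one gene")
    X = matrix.values
    summary = pd.DataFrame(
        {
            "min": X.min(axis=0),
            "q25": X.quantile(0.25, axis=0),
            "median": X.median(axis=0),
            "q75": X.quantile(0.75, axis=0),
            "max": X.max(axis=0),
            "mean": X.mean(axis=0),
            "sd": X.std(axis=0, ddof=1) if matrix.n_genes > 1 else 0.0 * X.mean(axis=0),
        }
    )
    center = summary["median"].median()
    summary["flagged"] = (summary["median"] - center).abs() > flag_threshold
    summary.index.name = "sample_id"
    return summary


def cyclic_loess_normalize(
    matrix: ExpressionMatrix, span: float = 0.3, iterations: int = 2
) -> ExpressionMatrix:
    """Remove intensity-dependent between-array trends by cyclic loess.

    Parameters
    ----------
    matrix
        Log2 expression values; at least two arrays.
    span
        Loess span as the fraction of points used in each local fit.
    iterations
        Full passes over all array pairs.
    """
    if matrix.n_samples < 2:
        raise ValueError("cyclic loess needs at least two arrays")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    X = matrix.values.to_numpy(dtype=float).copy()
    if not np.isfinite(X).all():
        raise ValueError("expression values must be finite")
    n_samples = X.shape[1]
    for _ in range(iterations):
        for i, j in combinations(range(n_samples), 2):
            a = (X[:, i] + X[:, j]) / 2.0
            m = X[:, i] - X[:, j]
            trend = lowess(m, a, frac=span, it=0, return_sorted=False)
            X[:, i] -= trend / 2.0
            X[:, j] += trend / 2.0
    values = pd.DataFrame(X, index=matrix.genes, columns=matrix.samples)
    return ExpressionMatrix(values, matrix.genotypes.copy())


def ma_trend_amplitude(matrix: ExpressionMatrix, span: float = 0.3) -> float:
    """Largest pairwise M-vs-A trend in the matrix.

    For every array pair the loess fit of M on A is computed and its mean
    absolute value taken; the maximum over pairs is returned.  A perfectly
    normalized matrix has amplitude near zero; used to quantify how much of
    an injected distortion survives normalization.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two arrays")
    X = matrix.values.to_numpy(dtype=float)
    amplitudes = []
    for i, j in combinations(range(X.shape[1]), 2):
        a = (X[:, i] + X[:, j]) / 2.0
        m = X[:, i] - X[:, j]
        trend = lowess(m, a, frac=span, it=0, return_sorted=False)
        amplitudes.append(float(np.mean(np.abs(trend))))
    return max(amplitudes)


def summarize_probesets(
    probe_matrix: ExpressionMatrix,
    probe_to_gene: Mapping[str, str] | Iterable[tuple[str, str]] | pd.DataFrame,
) -> ExpressionMatrix:
    """Collapse probes to per-target rows by the arithmetic mean.

    ``probe_to_gene`` maps probe id -> target id; probes mapping to several
    targets (given as an iterable of pairs) contribute to each.  Probes
    present in the matrix but absent from the map are dropped with a logged
    count.
    """
    if isinstance(probe_to_gene, pd.DataFrame):
        pairs = probe_to_gene.iloc[:, :2].itertuples(index=False)
    elif isinstance(probe_to_gene, Mapping):
        pairs = probe_to_gene.items()
    else:
        pairs = probe_to_gene
    mapping = pd.DataFrame(pairs, columns=["probe_id", "target_id"])
    if mapping.empty:
        raise ValueError("probe_to_gene mapping is empty")
    missing = set(mapping["probe_id"]) - set(probe_matrix.genes)
    if missing:
        raise KeyError(f"mapped probes absent from the matrix: {sorted(missing)[:5]}")

    n_unmapped = probe_matrix.n_genes - probe_matrix.genes.isin(
        set(mapping["probe_id"])
    ).sum()
    if n_unmapped:
        logger.info("dropping %d unmapped probes", n_unmapped)

    merged = mapping.join(probe_matrix.values, on="probe_id")
    values = merged.drop(columns="probe_id").groupby("target_id").mean()
    values = values.sort_index()
    values.index.name = "gene_id"
    return ExpressionMatrix(values, probe_matrix.genotypes.copy())
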