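"""Non-additivity (synergy) analysis of the factorial design.

Under the additive null the double-mutant LSmean is the sum of the two
single-mutant effects on the log2 scale:

    E[mu_AB] = mu_A + mu_B - mu_WT.

The per-gene non-additivity deviation

    delta = mu_AB - mu_A - mu_B + mu_WT

is the classical interaction contrast (weights +1, -1, -1, +1); delta < 0
means the double mutant sits below its additive expectation, i.e. a
synergistic loss of expression.  The two-criterion candidate screen keeps
genes for which (1) at least one single mutant is significantly below wild
type and (2) delta is negative and significantly different from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import datasets
from .differential import (
    ContrastResult,
    GeneFit,
    contrast_frame,
    fit_genotype_anova,
    lsmean_contrast,
    pfdr_qvalues,
)
from .matrix import ExpressionMatrix

#: Interaction contrast weights on (WT, A, B, AB).
DELTA_WEIGHTS = {"WT": 1.0, "A": -1.0, "B": -1.0, "AB": 1.0}


def additive_expectation(mu_wt, mu_a, mu_b):
    """Expected double-mutant LSmean if the single-mutant effects add."""
    return np.asarray(mu_a) + np.asarray(mu_b) - np.asarray(mu_wt)


@dataclass
class SynergyRecord:
    """Per-gene non-additivity result with the two screening flags."""

    gene: str
    delta: float
    se: float
    t_stat: float
    p_value: float
    single_down_a: bool
    single_down_b: bool
    passes: bool

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value)) if self.p_value > 0 else np.inf


def nonadditivity_contrast(fit: GeneFit, alpha: float = 0.05) -> SynergyRecord:
    """Test delta = 0 for one fitted gene and evaluate both criteria.

    The single-mutant flags use the raw two-sided contrast p at ``alpha``
    combined with the direction requirement (mean below wild type).
    """
    missing = set(DELTA_WEIGHTS) - set(fit.lsmeans)
    if missing:
        raise ValueError(f"fit lacks genotypes: {sorted(missing)}")
    res: ContrastResult = lsmean_contrast(fit, DELTA_WEIGHTS)
    down_a = _single_down(fit, "A", alpha)
    down_b = _single_down(fit, "B", alpha)
    passes = bool(
        (down_a or down_b) and res.estimate < 0 and res.p_value < alpha
    )
    return SynergyRecord(
        gene=fit.gene,
        delta=res.estimate,
        se=res.se,
        t_stat=res.t_stat,
        p_value=res.p_value,
        single_down_a=down_a,
        single_down_b=down_b,
        passes=passes,
    )


def _single_down(fit: GeneFit, genotype: str, alpha: float) -> bool:
    c = lsmean_contrast(fit, {genotype: 1.0, "WT": -1.0})
    return bool(c.estimate < 0 and c.p_value < alpha)


def synergy_screen(
    matrix: ExpressionMatrix | pd.DataFrame,
    alpha: float = 0.05,
    criterion1: str = "qvalue",
) -> tuple[pd.DataFrame, list[str]]:
    """Two-criterion synergy screen over all genes.

    Parameters
    ----------
    matrix
        Expression matrix covering all four genotypes, or a prefitted frame
        from :func:`fit_genotype_anova`.
    alpha
        Significance cutoff used by both criteria.
    criterion1
        ``"qvalue"`` assesses the single-mutant-below-WT contrasts with
        Storey q-values over all genes (matching a pFDR-screened
        single-mutant list); ``"rawp"`` uses the raw contrast p-values.

    Returns
    -------
    records
        DataFrame (one row per gene, sorted by the non-additivity p) with
        the four LSmeans, ``delta``, ``se``, ``t_stat``, ``p_value``,
        ``neg_log10_p``, the criterion flags, and ``passes``.
    candidates
        Gene ids with ``passes`` true, in record order.
    """
    if criterion1 not in ("qvalue", "rawp"):
        raise ValueError("criterion1 must be 'qvalue' or 'rawp'")
    fits = (
        fit_genotype_anova(matrix) if isinstance(matrix, ExpressionMatrix) else matrix
    )
    missing = [g for g in DELTA_WEIGHTS if f"mu_{g}" not in fits.columns]
    if missing:
        raise ValueError(f"matrix lacks genotypes: {missing}")

    delta = contrast_frame(fits, DELTA_WEIGHTS)
    down = {}
    for g in ("A", "B"):
        c = contrast_frame(fits, {g: 1.0, "WT": -1.0})
        if criterion1 == "qvalue":
            ok = c["p_value"].notna().to_numpy()
            stat = np.full(len(c), np.nan)
            if ok.any():
                stat[ok] = pfdr_qvalues(c["p_value"].to_numpy()[ok])
        else:
            stat = c["p_value"].to_numpy()
        down[g] = (c["estimate"].to_numpy() < 0) & (stat < alpha)

    records = pd.DataFrame(
        {
            "mu_WT": fits["mu_WT"],
            "mu_A": fits["mu_A"],
            "mu_B": fits["mu_B"],
            "mu_AB": fits["mu_AB"],
            "delta": delta["estimate"],
            "se": delta["se"],
            "t_stat": delta["t_stat"],
            "p_value": delta["p_value"],
            "single_down_a": down["A"],
            "single_down_b": down["B"],
        }
    )
    with np.errstate(divide="ignore"):
        records["neg_log10_p"] = -np.log10(records["p_value"])
    records["passes"] = (
        (records["single_down_a"] | records["single_down_b"])
        & (records["delta"] < 0)
        & (records["p_value"] < alpha)
    ).fillna(False)
    records = records.sort_values("p_value", kind="stable")
    candidates = list(records.index[records["passes"]])
    return records, candidates


# -- published-table consistency ------------------------------------------


def lsmean_table_deltas(table: pd.DataFrame | None = None) -> pd.Series:
    """Non-additivity deviation for each row of a published-style LSmean table.

    ``table`` must carry ``lsmean_wt``, ``lsmean_ant``, ``lsmean_seu`` and
    ``lsmean_double`` columns; defaults to the transcribed 31-gene candidate
    list.  delta = lsmean_double - (lsmean_ant + lsmean_seu - lsmean_wt).
    """
    if table is None:
        table = datasets.candidate_genes()
    expected = additive_expectation(
        table["lsmean_wt"], table["lsmean_seu"], table["lsmean_ant"]
    )
    return table["lsmean_double"] - expected


def count_negative_deltas(table: pd.DataFrame | None = None) -> int:
    """Number of table rows whose double-mutant LSmean is sub-additive."""
    return int((lsmean_table_deltas(table) < 0).sum())
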