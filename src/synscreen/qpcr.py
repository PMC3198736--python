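"""qRT-PCR verification: ddCt quantification, reference stability, Tukey HSD.

Relative expression is quantified against a reference gene assuming 100%
amplification efficiency: after averaging technical replicates on the Ct
scale, each biological replicate yields 2**(Ct_ref - Ct_target), so a
target amplifying earlier than the reference scores above 1.  Genotypes are
compared by a Tukey-Kramer honestly-significant-difference test on the
per-replicate values, summarised as a compact letter display (two genotypes
share a letter exactly when they are not significantly different).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import fit_gene_anova
from .matrix import GENOTYPES

REQUIRED_CT_COLUMNS = ("genotype", "bio_rep", "tech_rep", "gene", "ct")


def _check_ct(ct: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")


def _tech_averaged(ct: pd.DataFrame, gene: str) -> pd.Series:
    """Mean Ct per (genotype, bio_rep) for one gene."""
    sub = ct[ct["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from the Ct table")
    return sub.groupby(["genotype", "bio_rep"])["ct"].mean()


def normalized_expression(
    ct: pd.DataFrame, gene: str, reference_gene: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-normalized expression of ``gene``, per replicate and summary.

    Returns
    -------
    per_rep
        ``genotype, bio_rep, value`` with value = 2**(Ct_ref - Ct_target)
        per biological replicate (technical replicates averaged on the Ct
        scale first).  Replicates missing the reference measurement are
        dropped with a warning.
    summary
        Per-genotype ``mean``, ``sem`` and ``n_bio``.
    """
    _check_ct(ct)
    target = _tech_averaged(ct, gene)
    reference = _tech_averaged(ct, reference_gene)
    paired = target.index.intersection(reference.index)
    dropped = target.index.difference(reference.index)
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} biological replicate(s) lack the reference gene "
            f"and were dropped",
            stacklevel=2,
        )
    if not len(paired):
        raise ValueError("no biological replicate has the reference gene measured")
    values = np.power(2.0, reference.loc[paired] - target.loc[paired])
    per_rep = values.rename("value").reset_index()

    order = [g for g in GENOTYPES if g in set(per_rep["genotype"])] + [
        g for g in dict.fromkeys(per_rep["genotype"]) if g not in GENOTYPES
    ]
    grouped = per_rep.groupby("genotype")["value"]
    summary = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "sem": grouped.sem(ddof=1),
            "n_bio": grouped.size(),
        }
    ).reindex(order)
    summary.index.name = "genotype"
    return per_rep, summary


def reference_stability(
    ct: pd.DataFrame, reference_candidates: Sequence[str]
) -> pd.DataFrame:
    """Genotype-effect test on the Ct difference of each reference pair.

    For every pair of candidate reference genes the per-replicate delta-Ct
    (gene1 - gene2, technical replicates averaged) is submitted to a
    one-way ANOVA by genotype.  A pair is called stable when the genotype
    effect is not significant (p >= 0.05); degenerate fits (zero residual
    variance, i.e. perfectly constant differences) are treated as stable.
    Returns ``gene1, gene2, p_value, stable`` per pair.
    """
    _check_ct(ct)
    if len(reference_candidates) < 2:
        raise ValueError("need at least two reference candidates")
    rows = []
    for g1, g2 in combinations(reference_candidates, 2):
        d = _tech_averaged(ct, g1) - _tech_averaged(ct, g2)
        if d.isna().any():
            raise ValueError(
                f"genes {g1!r}/{g2!r} not measured in every (genotype, bio_rep)"
            )
        groups = {
            genotype: d.loc[genotype].to_numpy()
            for genotype in d.index.get_level_values(0).unique()
        }
        fit = fit_gene_anova(groups)
        if fit.degenerate or not np.isfinite(fit.p_value):
            rows.append((g1, g2, np.nan, True))
        else:
            rows.append((g1, g2, fit.p_value, fit.p_value >= 0.05))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "p_value", "stable"])


# -- Tukey-Kramer HSD with compact letter display --------------------------


@dataclass
class TukeyResult:
    """Pairwise Tukey-Kramer p-values and the compact letter display."""

    order: list[str]  # groups by descending mean
    means: dict[str, float]
    p_values: pd.DataFrame  # symmetric matrix of adjusted p
    letters: dict[str, str]
    alpha: float


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> TukeyResult:
    """Tukey-Kramer HSD across all groups plus letter assignment.

    Pairwise p-values come from the studentized range on the pooled
    within-group variance (valid for unequal group sizes).  Letters are
    assigned by insert-and-absorb in descending-mean order, so two groups
    share a letter if and only if their adjusted p is >= ``alpha``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group needs at least two values")
    res = stats.tukey_hsd(*(arrays[g] for g in names))
    pmat = pd.DataFrame(res.pvalue, index=names, columns=names)

    means = {g: float(a.mean()) for g, a in arrays.items()}
    order = sorted(names, key=lambda g: -means[g])
    sig_pairs = [
        (g1, g2)
        for g1, g2 in combinations(order, 2)
        if pmat.loc[g1, g2] < alpha
    ]
    letters = compact_letter_display(order, sig_pairs)
    return TukeyResult(order, means, pmat, letters, alpha)


def compact_letter_display(
    order: Sequence[str], significant_pairs: Sequence[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    ``order`` lists the groups (conventionally by descending mean);
    ``significant_pairs`` are the pairs that must NOT share a letter.  Every
    other pair is guaranteed to share at least one letter.
    """
    columns: list[set[str]] = [set(order)]
    for g1, g2 in significant_pairs:
        new_columns: list[set[str]] = []
        for col in columns:
            if g1 in col and g2 in col:
                new_columns.append(col - {g1})
                new_columns.append(col - {g2})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = [
            col
            for i, col in enumerate(new_columns)
            if col
            and not any(
                col < other or (col == other and i > j)
                for j, other in enumerate(new_columns)
            )
        ]
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    letters = {g: "" for g in order}
    for letter, col in zip(alphabet, columns):
        for g in order:
            if g in col:
                letters[g] += letter
    return letters


def compare_genotypes(per_rep: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Genotype summary with Tukey-Kramer letters for one gene.

    ``per_rep`` is the per-replicate frame from
    :func:`normalized_expression`.  Returns per-genotype ``mean``, ``sem``,
    ``n_bio`` and ``letters``.
    """
    groups = {
        g: sub["value"].to_numpy() for g, sub in per_rep.groupby("genotype")
    }
    result = tukey_hsd(groups, alpha=alpha)
    grouped = per_rep.groupby("genotype")["value"]
    out = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "sem": grouped.sem(ddof=1),
            "n_bio": grouped.size(),
        }
    ).reindex(result.order)
    out["letters"] = [result.letters[g] for g in out.index]
    out.index.name = "genotype"
    return out


def analyze_gene(
    ct: pd.DataFrame, gene: str, reference_gene: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Normalized expression of one gene with per-genotype Tukey letters."""
    per_rep, _ = normalized_expression(ct, gene, reference_gene)
    return compare_genotypes(per_rep, alpha=alpha)
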