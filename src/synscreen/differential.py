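"""Per-gene one-way ANOVA, LSmean contrasts, Storey q-values, DE screens.

Every gene is fitted with the one-way fixed-effect model

    y_gr = mu_g + e_gr,   e_gr ~ N(0, sigma^2),

where g indexes genotype.  In this balanced, single-factor setting the
least-squares genotype mean (LSmean) equals the arithmetic genotype mean;
contrasts sum{w_g mu_g} are tested with t = estimate / SE on the pooled
residual degrees of freedom, SE = sqrt(s^2 * sum{w_g^2 / n_g}).

Multiple testing uses Storey's positive false discovery rate: pi0 is
estimated from the flat right tail of the p-value distribution and q_i is
the minimum estimated pFDR over rejection thresholds at or above p_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = [
    "GeneFit",
    "ContrastResult",
    "DEGeneSet",
    "fit_gene_anova",
    "fit_genotype_anova",
    "lsmean_contrast",
    "contrast_frame",
    "grand_mean_weights",
    "pfdr_qvalues",
    "differential_screen",
]


@dataclass
class GeneFit:
    """One-way ANOVA result for a single gene."""

    gene: str
    lsmeans: dict[str, float]
    counts: dict[str, int]
    s2: float  # residual mean square
    df_resid: int
    f_stat: float
    p_value: float
    degenerate: bool = False


@dataclass
class ContrastResult:
    estimate: float
    se: float
    t_stat: float
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value)) if self.p_value > 0 else np.inf


def fit_gene_anova(groups: Mapping[str, Sequence[float]], gene: str = "") -> GeneFit:
    """Fit the one-way genotype model to a single gene's replicate values.

    Degenerate fits (zero residual df, or zero residual variance) are
    returned flagged rather than raised: with all values identical the fit
    reports F = 0, p = 1; with residual variance zero but group means apart
    the p-value is undefined (NaN).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two genotypes")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(a.size < 1 for a in arrays.values()):
        raise ValueError("every genotype needs at least one replicate")
    n_total = sum(a.size for a in arrays.values())
    k = len(labels)
    nu = n_total - k
    means = {g: float(a.mean()) for g, a in arrays.items()}
    counts = {g: int(a.size) for g, a in arrays.items()}
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays.values())
    grand = sum(a.sum() for a in arrays.values()) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())

    if nu == 0:
        return GeneFit(gene, means, counts, np.nan, 0, np.nan, np.nan, True)
    s2 = ss_within / nu
    if s2 == 0.0:
        if ss_between == 0.0:
            return GeneFit(gene, means, counts, 0.0, nu, 0.0, 1.0, False)
        return GeneFit(gene, means, counts, 0.0, nu, np.inf, np.nan, True)
    f = (ss_between / (k - 1)) / s2
    p = float(stats.f.sf(f, k - 1, nu))
    return GeneFit(gene, means, counts, float(s2), nu, float(f), p, False)


def fit_genotype_anova(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Vectorised one-way ANOVA for every gene in the matrix.

    Returns a DataFrame indexed by gene with per-genotype columns ``n_<g>``
    and ``mu_<g>``, plus ``s2``, ``df_resid``, ``f_stat``, ``p_value`` and
    ``degenerate``.  The genotype order follows ``matrix.groups()``.
    """
    groups = matrix.groups()
    if len(groups) < 2:
        raise ValueError("need at least two genotypes")
    X = matrix.values
    n_total = matrix.n_samples
    k = len(groups)
    nu = n_total - k

    out = pd.DataFrame(index=X.index)
    ss_within = np.zeros(matrix.n_genes)
    ss_between = np.zeros(matrix.n_genes)
    grand = X.to_numpy().mean(axis=1)
    for g, cols in groups.items():
        block = X[cols].to_numpy()
        mu = block.mean(axis=1)
        out[f"n_{g}"] = block.shape[1]
        out[f"mu_{g}"] = mu
        ss_within += ((block - mu[:, None]) ** 2).sum(axis=1)
        ss_between += block.shape[1] * (mu - grand) ** 2

    if nu == 0:
        out["s2"] = np.nan
        out["df_resid"] = 0
        out["f_stat"] = np.nan
        out["p_value"] = np.nan
        out["degenerate"] = True
        return out

    s2 = ss_within / nu
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(s2 > 0, (ss_between / (k - 1)) / np.where(s2 > 0, s2, 1.0), np.inf)
    p = stats.f.sf(f, k - 1, nu)
    # degenerate cases: zero residual variance
    all_equal = (s2 == 0) & (ss_between == 0)
    zero_resid = (s2 == 0) & (ss_between > 0)
    f = np.where(all_equal, 0.0, f)
    p = np.where(all_equal, 1.0, np.where(zero_resid, np.nan, p))
    out["s2"] = s2
    out["df_resid"] = nu
    out["f_stat"] = f
    out["p_value"] = p
    out["degenerate"] = zero_resid
    return out


def lsmean_contrast(fit: GeneFit, weights: Mapping[str, float]) -> ContrastResult:
    """Estimate and test sum{w_g * mu_g} for one fitted gene."""
    if fit.degenerate or not np.isfinite(fit.s2):
        raise ValueError(f"degenerate fit for gene {fit.gene!r}")
    unknown = set(weights) - set(fit.lsmeans)
    if unknown:
        raise KeyError(f"weights refer to unknown genotypes: {sorted(unknown)}")
    est = sum(w * fit.lsmeans[g] for g, w in weights.items())
    se = float(
        np.sqrt(fit.s2 * sum(w**2 / fit.counts[g] for g, w in weights.items()))
    )
    if se == 0.0:
        t = 0.0 if est == 0 else np.inf * np.sign(est)
        p = 1.0 if est == 0 else 0.0
        return ContrastResult(float(est), se, float(t), float(p))
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), fit.df_resid))
    return ContrastResult(float(est), se, float(t), p)


def contrast_frame(
    fits: pd.DataFrame, weights: Mapping[str, float]
) -> pd.DataFrame:
    """Vectorised LSmean contrast over a ``fit_genotype_anova`` frame.

    Returns columns ``estimate``, ``se``, ``t_stat``, ``p_value`` indexed
    like ``fits``.  Degenerate genes get NaN statistics.
    """
    est = np.zeros(len(fits))
    var_mult = 0.0
    for g, w in weights.items():
        est = est + w * fits[f"mu_{g}"].to_numpy()
        var_mult = var_mult + w**2 / fits[f"n_{g}"].to_numpy()
    s2 = fits["s2"].to_numpy()
    nu = fits["df_resid"].to_numpy()
    se = np.sqrt(s2 * var_mult)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), nu)
    bad = fits["degenerate"].to_numpy() | ~np.isfinite(se) | (se == 0)
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)
    return pd.DataFrame(
        {"estimate": est, "se": se, "t_stat": t, "p_value": p}, index=fits.index
    )


def grand_mean_weights(genotypes: Sequence[str], target: str) -> dict[str, float]:
    """Contrast weights for genotype ``target`` against the grand mean."""
    if target not in genotypes:
        raise ValueError(f"unknown genotype {target!r}")
    k = len(genotypes)
    return {g: (1.0 - 1.0 / k) if g == target else -1.0 / k for g in genotypes}


def pfdr_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a collection of p-values.

    ``pi0`` (the null proportion) is estimated, unless supplied, by a
    least-squares straight line through pi0_hat(lambda) = #{p > lambda} /
    (m (1 - lambda)) on the grid lambda = 0.05, 0.10, ..., 0.95, evaluated
    at lambda = 0.95 and clipped to [1/m, 1].  Passing ``pi0=1`` gives the
    Benjamini-Hochberg adjusted p-values exactly.  Output is monotone
    non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
        slope, intercept = np.polyfit(lam, pi0_lam, 1)
        pi0 = float(slope * 0.95 + intercept)
    pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class DEGeneSet:
    """One directional differential-expression gene set from a screen."""

    direction: str  # "under" | "over"
    baseline: str  # "wt" | "grand_mean"
    target: str
    alpha: float
    min_abs_lfc: float
    table: pd.DataFrame = field(repr=False)  # gene-indexed members

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def differential_screen(
    matrix: ExpressionMatrix | pd.DataFrame,
    target: str,
    baseline: str = "wt",
    alpha: float = 0.05,
    min_abs_lfc: float = 0.35,
    multiple_testing: str = "pfdr",
) -> tuple[DEGeneSet, DEGeneSet]:
    """Screen for genes under-/over-expressed in ``target``.

    The per-gene statistic is the LSmean contrast of ``target`` against
    either wild type (``baseline="wt"``) or the grand mean of all genotypes
    (``baseline="grand_mean"``).  Membership requires q <= alpha (Storey
    pFDR, or Benjamini-Hochberg with ``multiple_testing="bh"``), an absolute
    contrast strictly greater than ``min_abs_lfc`` log2 units, and the
    matching sign.  Returns the (under, over) gene sets.
    """
    fits = (
        fit_genotype_anova(matrix) if isinstance(matrix, ExpressionMatrix) else matrix
    )
    genotypes = [c[3:] for c in fits.columns if c.startswith("mu_")]
    if target not in genotypes:
        raise ValueError(f"unknown genotype {target!r}")
    if baseline == "wt":
        if "WT" not in genotypes:
            raise ValueError("wt baseline requires a WT genotype")
        weights = {target: 1.0, "WT": -1.0}
    elif baseline == "grand_mean":
        weights = grand_mean_weights(genotypes, target)
    else:
        raise ValueError("baseline must be 'wt' or 'grand_mean'")
    if multiple_testing not in ("pfdr", "bh"):
        raise ValueError("multiple_testing must be 'pfdr' or 'bh'")

    res = contrast_frame(fits, weights)
    ok = res["p_value"].notna()
    q = np.full(len(res), np.nan)
    if ok.any():
        q[ok.to_numpy()] = pfdr_qvalues(
            res.loc[ok, "p_value"].to_numpy(),
            pi0=1.0 if multiple_testing == "bh" else None,
        )
    res = res.assign(q_value=q)
    res = res.sort_index()

    def subset(direction: str) -> DEGeneSet:
        sign = -1.0 if direction == "under" else 1.0
        keep = (
            (res["q_value"] <= alpha)
            & (res["estimate"].abs() > min_abs_lfc)
            & (np.sign(res["estimate"]) == sign)
        )
        return DEGeneSet(
            direction=direction,
            baseline=baseline,
            target=target,
            alpha=alpha,
            min_abs_lfc=min_abs_lfc,
            table=res.loc[keep.fillna(False)].copy(),
        )

    return subset("under"), subset("over")
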