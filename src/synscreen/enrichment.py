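"""Hypergeometric over-representation of gene families among candidates.

The probability of observing at least k annotated genes in a candidate set
of size n drawn without replacement from a universe of N genes of which K
carry the annotation is the upper tail P(X >= k) of
Hypergeometric(N, K, n).  Following the screening convention reproduced
here, term p-values are reported without multiple-testing correction and a
fixed cutoff (default p < 0.001) flags enriched terms; an optional
Benjamini-Hochberg column can be requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationMap:
    """Flat term -> gene-set annotation over a gene universe."""

    terms: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} is empty")
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} annotates genes outside the universe")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], universe: Iterable[str] | None = None
    ) -> "AnnotationMap":
        """Build from (gene, term) pairs, e.g. a two-column TSV."""
        terms: dict[str, set[str]] = {}
        genes_seen: set[str] = set()
        for gene, term in pairs:
            terms.setdefault(term, set()).add(gene)
            genes_seen.add(gene)
        uni = frozenset(universe) if universe is not None else frozenset(genes_seen)
        return cls({t: frozenset(g) for t, g in terms.items()}, uni)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` annotated candidates, ``K`` annotated genes in the universe,
    ``n`` candidates, ``N`` universe size.  Exact for k = 0 (probability 1).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    candidates: Iterable[str],
    annotation: AnnotationMap,
    p_cutoff: float = 0.001,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of every term against a candidate set.

    Candidates outside the universe are dropped with a logged warning.
    Terms with no candidate overlap are suppressed.  Returns one row per
    term — ``term, k, K, n, N, p_value, enriched`` — sorted by p ascending;
    ``enriched`` marks p < ``p_cutoff`` (uncorrected, by design).  With
    ``bh_correct`` a ``p_adjusted`` column is added for reference.
    """
    cand = set(candidates)
    outside = cand - annotation.universe
    if outside:
        logger.warning(
            "dropping %d candidate genes outside the universe", len(outside)
        )
        cand &= annotation.universe
    N = len(annotation.universe)
    n = len(cand)
    rows = []
    for term, genes in annotation.terms.items():
        k = len(cand & genes)
        if k == 0:
            continue
        rows.append((term, k, len(genes), n, N, hypergeom_upper_tail(k, len(genes), n, N)))
    out = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "p_value"]
    ).sort_values(["p_value", "term"], kind="stable", ignore_index=True)
    out["enriched"] = out["p_value"] < p_cutoff
    if bh_correct and len(out):
        from .differential import pfdr_qvalues

        out["p_adjusted"] = pfdr_qvalues(out["p_value"].to_numpy(), pi0=1.0)
    return out
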