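"""Synthetic-data generators with known ground truth.

Emulates the measured quantities of a four-genotype factorial transcriptome
experiment (WT, single mutants A and B, double mutant AB):

* a log2 expression matrix in which every gene has a baseline ``mu0`` and
  genotype means ``mu0`` (WT), ``mu0+a`` (A), ``mu0+b`` (B) and
  ``mu0+a+b+d`` (AB), where ``d`` is the interaction — non-zero only for
  synergistic genes — plus homoscedastic Gaussian replicate noise;
* flat term -> gene annotation maps with one family deliberately enriched
  among a candidate set;
* long-format qPCR Ct tables with a genotype-stable reference gene.

All generators are driven by a single integer seed and are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import GENOTYPES, ExpressionMatrix


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the factorial expression simulator (log2 units).

    ``single_shift_a`` / ``single_shift_b`` are the mean single-mutant
    effects given to synergistic genes so that the first screening criterion
    (single mutant below wild type) is satisfiable; ``effect_sd_a`` /
    ``effect_sd_b`` add zero-centred background effects to every gene.
    Synergistic genes draw their interaction from
    Normal(``synergy_shift``, 0.1*|``synergy_shift``|); all other genes have
    an exactly additive interaction of zero, giving a sharp null for
    type-I-error measurement.
    """

    n_genes: int = 2000
    n_reps: int = 3
    frac_synergistic: float = 0.05
    baseline_mean: float = 9.0
    baseline_sd: float = 1.0
    effect_sd_a: float = 0.0
    effect_sd_b: float = 0.0
    single_shift_a: float = -0.3
    single_shift_b: float = -0.3
    synergy_shift: float = -1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 <= self.frac_synergistic <= 1.0:
            raise ValueError("frac_synergistic must lie in [0, 1]")
        for name in ("baseline_sd", "effect_sd_a", "effect_sd_b", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a factorial expression matrix and its ground-truth table.

    Returns
    -------
    matrix
        ``ExpressionMatrix`` with ``4 * n_reps`` samples labelled
        ``WT_1 ... AB_n``.
    truth
        DataFrame indexed by gene id with columns ``baseline``, ``effect_a``,
        ``effect_b``, ``interaction_d`` and ``is_synergistic``
        (``is_synergistic`` is equivalent to ``interaction_d != 0``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = pd.Index([f"gene_{i + 1:05d}" for i in range(n)], name="gene_id")

    n_syn = int(round(config.frac_synergistic * n))
    syn = np.zeros(n, dtype=bool)
    syn[rng.choice(n, size=n_syn, replace=False)] = True

    mu0 = rng.normal(config.baseline_mean, config.baseline_sd, n)
    a = rng.normal(0.0, config.effect_sd_a, n) if config.effect_sd_a > 0 else np.zeros(n)
    b = rng.normal(0.0, config.effect_sd_b, n) if config.effect_sd_b > 0 else np.zeros(n)
    a[syn] += config.single_shift_a
    b[syn] += config.single_shift_b
    d = np.zeros(n)
    if n_syn:
        d[syn] = rng.normal(
            config.synergy_shift, 0.1 * abs(config.synergy_shift), n_syn
        )

    means = {
        "WT": mu0,
        "A": mu0 + a,
        "B": mu0 + b,
        "AB": mu0 + a + b + d,
    }
    columns: list[str] = []
    blocks: list[np.ndarray] = []
    for g in GENOTYPES:
        noise = rng.normal(0.0, config.noise_sd, (n, config.n_reps))
        blocks.append(means[g][:, None] + noise)
        columns.extend(f"{g}_{r + 1}" for r in range(config.n_reps))
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    genotypes = pd.Series(
        [c.rsplit("_", 1)[0] for c in columns], index=columns, name="genotype"
    )

    truth = pd.DataFrame(
        {
            "baseline": mu0,
            "effect_a": a,
            "effect_b": b,
            "interaction_d": d,
            "is_synergistic": d != 0.0,
        },
        index=genes,
    )
    return ExpressionMatrix(values, genotypes), truth


# -- array-level distortion ------------------------------------------------


def inject_intensity_distortion(
    matrix: ExpressionMatrix,
    sample: str,
    curve: Callable[[np.ndarray], np.ndarray],
) -> ExpressionMatrix:
    """Pass one array's values through a smooth intensity-dependent curve.

    Creates the class of artefact that loess normalization is meant to
    remove.  Other arrays are untouched; a new matrix is returned.
    """
    if sample not in matrix.samples:
        raise KeyError(f"unknown sample id: {sample!r}")
    out = matrix.copy()
    col = out.values[sample].to_numpy(dtype=float)
    out.values[sample] = np.asarray(curve(col), dtype=float)
    return out


def quadratic_curve(
    coeff: float, center: float | None = None
) -> Callable[[np.ndarray], np.ndarray]:
    """x -> x + coeff * (x - center)**2, centred on the array mean by default.

    Monotone as long as ``|2 * coeff * (x - center)| < 1`` over the data
    range, which holds for the gentle distortions used here.
    """

    def f(x: np.ndarray) -> np.ndarray:
        c = float(np.mean(x)) if center is None else center
        return x + coeff * (x - c) ** 2

    return f


# -- annotation ------------------------------------------------------------


def simulate_annotation(
    universe: Sequence[str],
    families: Iterable[tuple[str, int]],
    enriched_family: str,
    candidate_genes: Sequence[str],
    overlap: int,
    seed: int = 0,
):
    """Draw a flat term -> gene annotation with one planted enrichment.

    Every family is a random gene set of the requested size; the enriched
    family contains exactly ``overlap`` members of ``candidate_genes`` (its
    remaining members are drawn outside the candidate set).  Decoy families
    overlap the candidates only by chance.
    """
    from .enrichment import AnnotationMap

    rng = np.random.default_rng(seed)
    universe = list(universe)
    candidates = list(candidate_genes)
    families = list(families)
    names = [name for name, _ in families]
    if enriched_family not in names:
        raise ValueError(f"enriched_family {enriched_family!r} not among families")
    uni_set = set(universe)
    if not set(candidates) <= uni_set:
        raise ValueError("candidate_genes must be a subset of the universe")
    non_candidates = [g for g in universe if g not in set(candidates)]

    terms: dict[str, frozenset[str]] = {}
    for name, size in families:
        if size > len(universe):
            raise ValueError(f"family {name!r} larger than the universe")
        if name == enriched_family:
            if overlap > min(size, len(candidates)):
                raise ValueError("requested overlap is infeasible")
            if size - overlap > len(non_candidates):
                raise ValueError("requested overlap is infeasible")
            inside = rng.choice(candidates, size=overlap, replace=False)
            outside = rng.choice(non_candidates, size=size - overlap, replace=False)
            terms[name] = frozenset(inside) | frozenset(outside)
        else:
            terms[name] = frozenset(rng.choice(universe, size=size, replace=False))
    return AnnotationMap(terms=terms, universe=frozenset(universe))


# -- qPCR ------------------------------------------------------------------


def simulate_qpcr(
    truth: pd.DataFrame,
    reference_gene: str,
    n_bio_reps: int = 4,
    n_tech_reps: int = 3,
    noise_sd: float = 0.1,
    tech_noise_sd: float = 0.05,
    ct_offset: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a long-format Ct table from a ground-truth subset.

    Amplification is assumed 100% efficient (one cycle per doubling), so a
    gene whose log2 abundance is ``mu`` in a genotype amplifies at
    ``ct_offset - mu`` cycles before noise.  Biological noise (sd
    ``noise_sd`` cycles) is shared by a gene's technical replicates within a
    biological replicate; technical noise (sd ``tech_noise_sd``) is per well.
    Columns: ``sample, genotype, bio_rep, tech_rep, gene, ct``.
    """
    if n_bio_reps < 1 or n_tech_reps < 1:
        raise ValueError("replicate counts must be >= 1")
    if reference_gene not in truth.index:
        raise ValueError(f"reference gene {reference_gene!r} missing from truth")
    ref = truth.loc[reference_gene]
    if any(
        ref[c] != 0.0 for c in ("effect_a", "effect_b", "interaction_d")
    ):
        warnings.warn(
            f"reference gene {reference_gene!r} is not genotype-stable",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for genotype in GENOTYPES:
        for bio in range(1, n_bio_reps + 1):
            sample = f"{genotype}_{bio}"
            for gene, row in truth.iterrows():
                mu = row["baseline"]
                if genotype in ("A", "AB"):
                    mu += row["effect_a"]
                if genotype in ("B", "AB"):
                    mu += row["effect_b"]
                if genotype == "AB":
                    mu += row["interaction_d"]
                bio_shift = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                for tech in range(1, n_tech_reps + 1):
                    tech_shift = (
                        rng.normal(0.0, tech_noise_sd) if tech_noise_sd > 0 else 0.0
                    )
                    rows.append(
                        (
                            sample,
                            genotype,
                            bio,
                            tech,
                            gene,
                            ct_offset - mu + bio_shift + tech_shift,
                        )
                    )
    return pd.DataFrame(
        rows, columns=["sample", "genotype", "bio_rep", "tech_rep", "gene", "ct"]
    )
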