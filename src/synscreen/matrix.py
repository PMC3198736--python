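"""Expression-matrix container and plain-text I/O.

The whole pipeline operates on log2-scale expression values arranged as a
genes x samples table plus a sample sheet assigning each array to one of the
four genotypes of a 2x2 factorial mutant design: wild type (``WT``), the two
single mutants (``A``, ``B``) and the double mutant (``AB``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical genotype labels of the factorial design, in display order.
GENOTYPES = ("WT", "A", "B", "AB")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with a sample -> genotype map.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or probe-set) id with one column per
        sample; all entries must be finite log2 intensities.
    genotypes
        Series mapping every sample id (column of ``values``) to a genotype
        label.
    """

    values: pd.DataFrame
    genotypes: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if not isinstance(self.genotypes, pd.Series):
            self.genotypes = pd.Series(self.genotypes)
        if self.values.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ValueError("expression values must be finite")
        missing = [s for s in self.values.columns if s not in self.genotypes.index]
        if missing:
            raise ValueError(f"samples without a genotype label: {missing}")
        # keep the map aligned with (and restricted to) the matrix columns
        self.genotypes = self.genotypes.loc[list(self.values.columns)]
        if self.genotypes.isna().any():
            raise ValueError("genotype labels must not be missing")

    # -- basic accessors ---------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> dict[str, list[str]]:
        """Samples per genotype, canonical genotypes first."""
        seen = list(dict.fromkeys(self.genotypes))
        order = [g for g in GENOTYPES if g in seen] + [
            g for g in seen if g not in GENOTYPES
        ]
        return {
            g: [s for s in self.samples if self.genotypes[s] == g] for g in order
        }

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.genotypes.copy())

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        """Write the matrix and its sample sheet as tab-separated text.

        The matrix file has a ``gene_id`` first column; the sample sheet is
        two columns, ``sample_id<TAB>genotype``, no header beyond these names.
        """
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(matrix_path, sep="\t", float_format="%.6f")
        sheet = self.genotypes.rename("genotype").rename_axis("sample_id")
        sheet.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, matrix_path: str | Path, samples_path: str | Path
    ) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
        sheet = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(values, sheet["genotype"])
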