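"""Binary gene x sample mutation matrices.

The :class:`MutationMatrix` is the single substrate of all interaction
tests: a 0/1 incidence of genes (rows) by tumor samples (columns), with a
cancer-type label per sample.  Rows and columns are kept in a canonical
alphabetical order so that every downstream computation is deterministic.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["MutationMatrix"]


class MutationMatrix:
    """Binary gene x sample incidence with per-sample cancer-type labels.

    Parameters
    ----------
    genes, samples : sequences of str
        Unique row / column identifiers.
    incidence : array-like of 0/1 or bool, shape (n_genes, n_samples)
    cancer_types : sequence of str, one per sample.
    """

    def __init__(self, genes, samples, incidence, cancer_types) -> None:
        genes = np.asarray(genes, dtype=object)
        samples = np.asarray(samples, dtype=object)
        X = np.asarray(incidence)
        if X.dtype != bool:
            vals = np.unique(X)
            if not np.isin(vals, [0, 1]).all():
                raise DataError("incidence entries must be exactly 0 or 1")
            X = X.astype(bool)
        if X.shape != (len(genes), len(samples)):
            raise DataError(
                f"incidence shape {X.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if len(np.unique(genes)) != len(genes):
            raise DataError("duplicate gene symbols")
        if len(np.unique(samples)) != len(samples):
            raise DataError("duplicate sample IDs")
        cancer_types = np.asarray(cancer_types, dtype=object)
        if cancer_types.shape != (len(samples),):
            raise DataError("need one cancer-type label per sample")
        self.genes = genes
        self.samples = samples
        self.X = X
        self.cancer_types = cancer_types

    # -- basic properties -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def margins(self) -> np.ndarray:
        """Number of mutated samples per gene (row sums)."""
        return self.X.sum(axis=1)

    def loads(self) -> np.ndarray:
        """Mutation load per sample: number of mutated genes (column sums)."""
        return self.X.sum(axis=0)

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.genes == gene)
        if idx.size == 0:
            raise KeyError(gene)
        return int(idx[0])

    # -- structure --------------------------------------------------------
    def blocks(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (cancer_type, column index array), types in sorted order."""
        for ct in sorted(set(self.cancer_types)):
            yield ct, np.flatnonzero(self.cancer_types == ct)

    def canonicalize(self) -> "MutationMatrix":
        """Return a copy with genes and samples sorted alphabetically."""
        gi = np.argsort(self.genes.astype(str), kind="stable")
        si = np.argsort(self.samples.astype(str), kind="stable")
        return MutationMatrix(
            self.genes[gi], self.samples[si],
            self.X[np.ix_(gi, si)], self.cancer_types[si],
        )

    def subset_samples(self, index: np.ndarray) -> "MutationMatrix":
        index = np.asarray(index)
        return MutationMatrix(
            self.genes, self.samples[index],
            self.X[:, index], self.cancer_types[index],
        )

    def subset_genes(self, index: np.ndarray) -> "MutationMatrix":
        index = np.asarray(index)
        return MutationMatrix(
            self.genes[index], self.samples,
            self.X[index, :], self.cancer_types,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationMatrix):
            return NotImplemented
        return (
            np.array_equal(self.genes, other.genes)
            and np.array_equal(self.samples, other.samples)
            and np.array_equal(self.X, other.X)
            and np.array_equal(self.cancer_types, other.cancer_types)
        )

    def __repr__(self) -> str:
        return (
            f"MutationMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"{int(self.X.sum())} entries, "
            f"{len(set(self.cancer_types))} cancer type(s))"
        )

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X.astype(int), index=self.genes, columns=self.samples
        )

    def write_tsv(self, matrix_path, types_path) -> None:
        """Serialize as a gene x sample 0/1 TSV plus a sample->type sidecar."""
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(matrix_path, sep="\t")
        pd.DataFrame(
            {"sample_id": self.samples, "cancer_type": self.cancer_types}
        ).to_csv(types_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, matrix_path, types_path) -> "MutationMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(types_path, sep="\t", dtype=str)
        ct = dict(zip(meta["sample_id"], meta["cancer_type"]))
        missing = [s for s in df.columns if s not in ct]
        if missing:
            raise DataError(f"samples without cancer-type label: {missing[:5]}")
        return cls(
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
            df.to_numpy(),
            [ct[s] for s in df.columns],
        )
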