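"""Expression matrices: the gene x sample container and its TSV representation.

An :class:`ExpressionMatrix` holds one expression compendium dataset —
microarray intensities or RNA-seq counts — as a dense ``genes x samples``
array with ordered, unique gene and sample identifiers. All downstream
scoring assumes at least two samples (Pearson correlation is undefined
otherwise) and finite values after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

PLATFORMS = ("microarray", "rnaseq_counts", "rnaseq_fpkm")


@dataclass
class ExpressionMatrix:
    """One expression dataset.

    Parameters
    ----------
    dataset_id : str
        Short identifier for the compendium dataset.
    gene_ids : list of str
        Ordered, unique gene identifiers (rows).
    sample_ids : list of str
        Ordered, unique sample identifiers (columns).
    values : ndarray of shape (n_genes, n_samples)
        Unitless expression values.
    platform : {"microarray", "rnaseq_counts", "rnaseq_fpkm"}
    """

    dataset_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform: str = "microarray"
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.n_samples < 2:
            raise ValidationError(
                f"dataset {self.dataset_id!r} has {self.n_samples} sample(s); "
                "at least 2 are required"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"dataset {self.dataset_id!r} contains non-finite values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        return self._gene_index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def subset(self, row_indices: np.ndarray) -> "ExpressionMatrix":
        """Row subset preserving order of ``row_indices``."""
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in row_indices],
            values=self.values[row_indices],
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return replace(self, values=values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    return {x for x in items if x in seen or seen.add(x)}


def read_expression_matrix(
    path, platform: str = "microarray", dataset_id: str | None = None
) -> ExpressionMatrix:
    """Read a gene x sample expression TSV.

    The file has a header row of sample ids; the first column holds gene ids
    and the body is numeric. Duplicate gene rows are an error, never silently
    merged.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().to_numpy().any() and not df.isna().to_numpy().any():
        bad = np.argwhere(body.isna().to_numpy() & ~df.isna().to_numpy())[0]
        raise ParseError(
            f"non-numeric value at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r} in {path}"
        )
    if body.isna().to_numpy().any():
        bad = np.argwhere(body.isna().to_numpy())[0]
        raise ParseError(
            f"missing or non-numeric value at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r} in {path}"
        )
    if dataset_id is None:
        dataset_id = _stem(path)
    return ExpressionMatrix(
        dataset_id=dataset_id,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=body.to_numpy(dtype=float),
        platform=platform,
    )


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write the matrix in the TSV layout :func:`read_expression_matrix` reads."""
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
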