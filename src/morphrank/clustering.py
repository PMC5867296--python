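"""Clustering solutions and dataset/clustering configurations.

A :class:`ClusteringSolution` partitions (part of) one dataset's genes into
modules; genes outside every module are "unclustered" and can never be
scored under that solution. A :class:`Configuration` pairs a dataset with
one of its clustering solutions — the unit over which model selection runs.

Clustering solutions are normally an input (the original tool used CLICK,
external software); :func:`cluster_kmeans` is a self-contained stand-in so
the pipeline runs end-to-end without external binaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .exceptions import ParameterError, ValidationError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-12  # below this a gene row is treated as constant


@dataclass
class ClusteringSolution:
    """Partition of a dataset's genes into modules.

    ``assignment`` maps gene_id -> non-negative integer module id; genes in
    ``unclustered`` carry no module. Every module has at least 2 members
    (singletons are dissolved by the readers).
    """

    clustering_id: str
    dataset_id: str
    assignment: dict[str, int]
    unclustered: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.assignment) & self.unclustered
        if overlap:
            raise ValidationError(
                f"genes both assigned and unclustered: {sorted(overlap)[:5]}"
            )
        sizes: dict[int, int] = {}
        for mod in self.assignment.values():
            if mod < 0:
                raise ValidationError("module ids must be non-negative")
            sizes[mod] = sizes.get(mod, 0) + 1
        small = [m for m, n in sizes.items() if n < 2]
        if small:
            raise ValidationError(f"modules with <2 members: {sorted(small)}")

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def members(self, module_id: int) -> set[str]:
        return {g for g, m in self.assignment.items() if m == module_id}


@dataclass
class Configuration:
    """A dataset paired with one of its clustering solutions."""

    matrix: ExpressionMatrix
    clustering: ClusteringSolution

    def __post_init__(self) -> None:
        if self.clustering.dataset_id != self.matrix.dataset_id:
            raise ValidationError(
                f"clustering {self.clustering.clustering_id!r} targets dataset "
                f"{self.clustering.dataset_id!r}, not {self.matrix.dataset_id!r}"
            )
        missing = [g for g in self.clustering.assignment if g not in self.matrix]
        if missing:
            raise ValidationError(
                f"clustered genes absent from matrix: {sorted(missing)[:5]}"
            )

    @property
    def config_id(self) -> str:
        return f"{self.matrix.dataset_id}/{self.clustering.clustering_id}"


def _dissolve_singletons(
    assignment: dict[str, int], unclustered: set[str], context: str
) -> tuple[dict[str, int], set[str]]:
    sizes: dict[int, int] = {}
    for mod in assignment.values():
        sizes[mod] = sizes.get(mod, 0) + 1
    singles = {m for m, n in sizes.items() if n < 2}
    if singles:
        moved = sorted(g for g, m in assignment.items() if m in singles)
        logger.warning(
            "%s: dissolving %d singleton module(s) into unclustered (%s)",
            context,
            len(singles),
            ", ".join(moved[:5]),
        )
        unclustered = unclustered | set(moved)
        assignment = {g: m for g, m in assignment.items() if m not in singles}
    return assignment, unclustered


def read_clustering(
    path, matrix: ExpressionMatrix, clustering_id: str | None = None
) -> ClusteringSolution:
    """Read a two-column gene_id<TAB>module_id TSV against ``matrix``.

    Module id ``-1`` (or a missing value) marks a gene as unclustered. Genes
    absent from the matrix are dropped with a logged count; singleton modules
    are dissolved into the unclustered set. A gene listed twice with
    different modules is a validation error.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "module_id"], dtype={0: str}
    )
    if df["gene_id"].iloc[0] == "gene_id":  # tolerate an optional header line
        df = df.iloc[1:]
    df["module_id"] = pd.to_numeric(df["module_id"], errors="coerce")
    conflicts = (
        df.dropna(subset=["module_id"]).groupby("gene_id")["module_id"].nunique()
    )
    bad = conflicts[conflicts > 1]
    if len(bad):
        raise ValidationError(
            f"genes assigned to multiple modules: {sorted(bad.index)[:5]}"
        )
    assignment: dict[str, int] = {}
    unclustered: set[str] = set()
    n_dropped = 0
    for gene, mod in zip(df["gene_id"], df["module_id"]):
        gene = str(gene)
        if gene not in matrix:
            n_dropped += 1
            continue
        if pd.isna(mod) or int(mod) < 0:
            unclustered.add(gene)
        else:
            assignment[gene] = int(mod)
    unclustered -= set(assignment)  # duplicate consistent rows are harmless
    if n_dropped:
        logger.warning(
            "%s: dropped %d gene(s) absent from dataset %s",
            path,
            n_dropped,
            matrix.dataset_id,
        )
    if clustering_id is None:
        from .matrix import _stem

        clustering_id = _stem(path)
    assignment, unclustered = _dissolve_singletons(
        assignment, unclustered, str(path)
    )
    return ClusteringSolution(
        clustering_id=clustering_id,
        dataset_id=matrix.dataset_id,
        assignment=assignment,
        unclustered=unclustered,
    )


def write_clustering(solution: ClusteringSolution, path) -> None:
    rows = [(g, m) for g, m in solution.assignment.items()]
    rows += [(g, -1) for g in solution.unclustered]
    pd.DataFrame(sorted(rows), columns=["gene_id", "module_id"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def cluster_kmeans(
    m: ExpressionMatrix, k: int, seed: int = 0, clustering_id: str | None = None
) -> ClusteringSolution:
    """k-means partition of row-standardized expression profiles.

    Rows are standardized to mean 0, SD 1 before clustering so that modules
    reflect profile shape rather than magnitude; constant rows (SD below
    1e-12) are kept but standardize to zero vectors. Deterministic given
    ``seed``. Singleton clusters are dissolved into the unclustered set.
    """
    if k < 2 or k > m.n_genes // 2:
        raise ParameterError(
            f"k={k} out of range [2, {m.n_genes // 2}] for {m.n_genes} genes"
        )
    x = m.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flagged = np.flatnonzero(sd[:, 0] < SD_FLOOR)
    if len(flagged):
        logger.warning(
            "dataset %s: %d constant-expression gene row(s) (zero-variance guard)",
            m.dataset_id,
            len(flagged),
        )
    z = (x - mean) / np.maximum(sd, SD_FLOOR)
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(z)
    assignment = {g: int(lab) for g, lab in zip(m.gene_ids, labels)}
    if clustering_id is None:
        clustering_id = f"kmeans{k}"
    assignment, unclustered = _dissolve_singletons(
        assignment, set(), f"kmeans(k={k}, seed={seed})"
    )
    return ClusteringSolution(
        clustering_id=clustering_id,
        dataset_id=m.dataset_id,
        assignment=assignment,
        unclustered=unclustered,
    )
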