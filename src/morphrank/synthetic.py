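"""Synthetic expression compendia with planted co-expression modules.

Each planted module draws one latent sample-profile f_m per dataset; a
member gene's profile is ``sqrt(rho) * f_m + sqrt(1 - rho) * noise``, so
the expected pairwise within-module Pearson correlation is exactly rho.
Background genes are pure noise and remain unclustered in the truth
partition. Annotations split each module into a bait subset and a held-out
remainder, mirroring the missing-pathway-genes scenario the ranker is
meant to solve, plus uniformly drawn random terms as negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .clustering import ClusteringSolution
from .core import MorphResult
from .exceptions import ParameterError
from .matrix import ExpressionMatrix


@dataclass
class SyntheticSpec:
    """Generation parameters for a planted-module compendium."""

    n_modules: int = 10
    genes_per_module: int = 20
    n_background_genes: int = 100
    n_samples: int = 50
    n_datasets: int = 2
    rho: float = 0.9  # target within-module Pearson correlation
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_modules", "genes_per_module", "n_background_genes",
                     "n_samples", "n_datasets"):
            if getattr(self, name) < 1 and name != "n_background_genes":
                raise ParameterError(f"{name} must be positive")
        if self.n_background_genes < 0:
            raise ParameterError("n_background_genes must be >= 0")
        if not 0.0 < self.rho < 1.0:
            raise ParameterError(f"rho must lie in (0, 1), got {self.rho}")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")

    @property
    def n_genes(self) -> int:
        return self.n_modules * self.genes_per_module + self.n_background_genes


def _gene_ids(spec: SyntheticSpec) -> list[str]:
    width = max(4, len(str(spec.n_genes)))
    return [f"g{i:0{width}d}" for i in range(spec.n_genes)]


def generate_compendium(
    spec: SyntheticSpec,
) -> tuple[list[ExpressionMatrix], list[ClusteringSolution], pd.DataFrame]:
    """Generate matrices, matching truth clusterings, and the truth table.

    Returns one matrix per dataset (each an independent realization of the
    same planted module structure), the truth partition per dataset
    (background genes unclustered), and a gene/module truth table
    (module -1 = background). Reproducible from ``spec.seed``.
    """
    gene_ids = _gene_ids(spec)
    module_of = np.repeat(np.arange(spec.n_modules), spec.genes_per_module)
    module_of = np.concatenate([module_of, np.full(spec.n_background_genes, -1)])
    matrices: list[ExpressionMatrix] = []
    clusterings: list[ClusteringSolution] = []
    for d in range(spec.n_datasets):
        rng = np.random.default_rng([spec.seed, d])
        latent = rng.standard_normal((spec.n_modules, spec.n_samples))
        noise = rng.standard_normal((spec.n_genes, spec.n_samples)) * spec.noise_sd
        values = np.sqrt(1.0 - spec.rho) * noise
        planted = module_of >= 0
        values[planted] += np.sqrt(spec.rho) * latent[module_of[planted]]
        dataset_id = f"ds{d}"
        matrices.append(
            ExpressionMatrix(
                dataset_id=dataset_id,
                gene_ids=gene_ids,
                sample_ids=[f"s{j:03d}" for j in range(spec.n_samples)],
                values=values,
                platform="microarray",
            )
        )
        clusterings.append(
            ClusteringSolution(
                clustering_id="truth",
                dataset_id=dataset_id,
                assignment={
                    g: int(m) for g, m in zip(gene_ids, module_of) if m >= 0
                },
                unclustered={g for g, m in zip(gene_ids, module_of) if m < 0},
            )
        )
    truth = pd.DataFrame({"gene_id": gene_ids, "module": module_of})
    return matrices, clusterings, truth


def make_annotation(
    truth: pd.DataFrame,
    bait_fraction: float = 0.5,
    n_random_terms: int = 10,
    seed: int = 0,
    random_size_range: tuple[int, int] = (5, 30),
) -> tuple[AnnotationSet, dict[str, frozenset[str]]]:
    """Coherent terms (per planted module) plus random negative controls.

    Each planted module yields a coherent term holding a ``bait_fraction``
    sample of its genes; the remainder is recorded as that term's held-out
    true candidates. ``n_random_terms`` additional terms draw genes
    uniformly from the whole gene list with sizes uniform on
    ``random_size_range`` (matching the permutation-null size grid).
    """
    if not 0.0 < bait_fraction < 1.0:
        raise ParameterError(f"bait_fraction must lie in (0, 1), got {bait_fraction}")
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    held_out: dict[str, frozenset[str]] = {}
    all_genes = truth["gene_id"].to_numpy(dtype=object)
    for module, group in truth[truth["module"] >= 0].groupby("module"):
        genes = np.sort(group["gene_id"].to_numpy(dtype=object))
        n_bait = int(round(bait_fraction * len(genes)))
        n_bait = min(max(n_bait, 1), len(genes) - 1)
        baits = rng.choice(genes, size=n_bait, replace=False)
        term_id = f"COH:{int(module):03d}"
        terms[term_id] = (f"coherent module {module}", frozenset(map(str, baits)))
        held_out[term_id] = frozenset(map(str, set(genes) - set(baits)))
    lo, hi = random_size_range
    for i in range(n_random_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(all_genes, size=size, replace=False)
        terms[f"RND:{i:03d}"] = (f"random control {i}", frozenset(map(str, genes)))
    return AnnotationSet(source="custom", terms=terms), held_out


def evaluate_recovery(result: MorphResult, held_out, k: int = 100) -> float:
    """recall@k: fraction of held-out genes among the top-k candidates."""
    held = set(held_out)
    if not held:
        raise ParameterError("empty held-out set")
    top = {c.gene_id for c in result.candidates[:k]}
    return len(held & top) / len(held)
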