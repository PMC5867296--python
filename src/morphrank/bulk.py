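"""Genome-wide ("bulk") MORPH: jobs, permutation null, p-values, reports.

The bulk pipeline turns a whole functional annotation into MORPH jobs (one
per term), discards terms too small to score reliably, attaches empirical
p-values from a permutation null of random same-size bait sets, corrects
them with Benjamini–Hochberg, and extracts two downstream products:

* *extended annotations* — gene -> term assignments for significant terms
  (q below threshold) and strongly scoring candidates (z above the 97.5th
  standard-normal percentile, printed as 1.96);
* *record tables* — per significant term (empirical p below threshold) the
  up-to-top-100 candidates with z above the 90th percentile (1.28), the
  storage rule of the comparative database layer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotations import AnnotationSet
from .clustering import Configuration
from .core import DEFAULT_R_MAX, BaitSet, MorphResult, run_morph
from .exceptions import EmptyScorableSet, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_MIN_JOB_GENES = 5
DEFAULT_NULL_SIZES = tuple(range(5, 31))
DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_EXTENSION_Z = 1.96  # 97.5th percentile of the standard normal
DEFAULT_RECORD_P = 0.10
DEFAULT_RECORD_Z = 1.28  # 90th percentile of the standard normal
DEFAULT_TOP_K = 100


@dataclass
class NullDistribution:
    """Per-bait-set-size AUSR values from random MORPH runs."""

    values: dict[int, np.ndarray]  # size -> AUSR array
    seed: int
    r_max: int = DEFAULT_R_MAX
    gene_pool: str = "genome"

    def __post_init__(self) -> None:
        self.values = {int(s): np.asarray(v, dtype=float) for s, v in self.values.items()}
        for s, v in self.values.items():
            if np.any((v < 0) | (v > 1)):
                raise ParameterError(f"null AUSR values for size {s} outside [0, 1]")

    @property
    def sizes(self) -> list[int]:
        return sorted(self.values)

    def n(self, size: int) -> int:
        return len(self.values[size])

    def save(self, path) -> None:
        payload = {
            "seed": self.seed,
            "r_max": self.r_max,
            "gene_pool": self.gene_pool,
            "values": {str(s): [round(float(x), 12) for x in v] for s, v in sorted(self.values.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=0, sort_keys=True)

    @classmethod
    def load(cls, path) -> "NullDistribution":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            values={int(s): np.asarray(v) for s, v in payload["values"].items()},
            seed=payload["seed"],
            r_max=payload["r_max"],
            gene_pool=payload.get("gene_pool", "genome"),
        )


def build_jobs(
    ann: AnnotationSet,
    configs: list[Configuration],
    min_genes: int = DEFAULT_MIN_JOB_GENES,
) -> list[BaitSet]:
    """Terms worth running: at least ``min_genes`` annotated genes present
    in at least one dataset. Co-expression-based guilt-by-association is
    unreliable for very small query sets, so smaller terms are discarded
    (with per-dataset presence counts logged)."""
    if not configs:
        raise ParameterError("no configurations supplied")
    if len(ann) == 0:
        raise ParameterError("empty annotation set")
    datasets: dict[str, set[str]] = {}
    for c in configs:
        datasets.setdefault(c.matrix.dataset_id, set()).update(c.matrix.gene_ids)
    jobs: list[BaitSet] = []
    for term_id, (desc, genes) in sorted(ann.terms.items()):
        counts = {d: len(genes & pool) for d, pool in datasets.items()}
        if max(counts.values()) >= min_genes:
            jobs.append(BaitSet(term_id=term_id, genes=genes, description=desc))
        else:
            logger.info("discarding %s: per-dataset gene counts %s", term_id, counts)
    return jobs


def empirical_pvalue(
    ausr_star: float, size: int, null: NullDistribution, pseudocount: bool = False
) -> float:
    """Fraction of null AUSR values strictly larger than ``ausr_star``.

    The bait-set size is clamped to the null's size grid (larger random
    sets score lower by chance, so clamping above the grid overestimates p
    — conservative); if the clamped size is absent, the nearest available
    size is used. With ``pseudocount`` the estimator becomes
    (count + 1) / (n + 1), which never reports exactly zero.
    """
    sizes = null.sizes
    s = int(np.clip(size, sizes[0], sizes[-1]))
    if s not in null.values:
        s = min(sizes, key=lambda x: (abs(x - s), x))
    v = null.values[s]
    count = int(np.count_nonzero(v > ausr_star))
    if pseudocount:
        return float((count + 1) / (len(v) + 1))
    return float(count / len(v))


def bh_adjust(p_values) -> list[float]:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def random_null(
    configs: list[Configuration],
    sizes=DEFAULT_NULL_SIZES,
    n: int = 1000,
    seed: int = 0,
    gene_pool: str = "genome",
    annotated_genes=None,
    r_max: int = DEFAULT_R_MAX,
    min_baits_per_module: int = 1,
) -> NullDistribution:
    """Permutation null: AUSR of random bait sets of each size.

    For every size S and replicate, a dataset is chosen uniformly at
    random, S distinct genes are drawn from that dataset's pool (the whole
    genome, or its annotated subset when ``gene_pool='annotated'``), and a
    full MORPH run — model selection included — records the AUSR. Each
    (size, replicate) pair draws from its own counter-derived RNG stream,
    so results are reproducible and order-independent.
    """
    sizes = sorted(int(s) for s in sizes)
    if gene_pool not in ("genome", "annotated"):
        raise ParameterError(f"gene_pool must be 'genome' or 'annotated', got {gene_pool!r}")
    if gene_pool == "annotated" and annotated_genes is None:
        raise ParameterError("gene_pool='annotated' requires annotated_genes")
    dataset_ids = sorted({c.matrix.dataset_id for c in configs})
    pools = {}
    for d in dataset_ids:
        genes = sorted(
            {g for c in configs if c.matrix.dataset_id == d for g in c.matrix.gene_ids}
        )
        if gene_pool == "annotated":
            genes = sorted(set(genes) & set(annotated_genes))
        pools[d] = np.asarray(genes, dtype=object)
    max_size = max(sizes)
    if all(len(p) < max_size for p in pools.values()):
        raise ParameterError(
            f"no dataset pool holds {max_size} genes (pool sizes: "
            f"{ {d: len(p) for d, p in pools.items()} })"
        )
    values: dict[int, np.ndarray] = {}
    for size in sizes:
        eligible = [d for d in dataset_ids if len(pools[d]) >= size]
        out = np.empty(n, dtype=float)
        for rep in range(n):
            rng = np.random.default_rng([seed, size, rep])
            d = eligible[int(rng.integers(len(eligible)))]
            genes = rng.choice(pools[d], size=size, replace=False)
            baits = BaitSet(term_id=f"random:{size}:{rep}", genes=frozenset(map(str, genes)))
            try:
                result = run_morph(configs, baits, r_max, min_baits_per_module)
                out[rep] = result.ausr
            except EmptyScorableSet:
                out[rep] = 0.0  # a set no configuration can score ranks nothing
        values[size] = out
    return NullDistribution(values=values, seed=seed, r_max=r_max, gene_pool=gene_pool)


@dataclass
class BulkResult:
    """Per-term bulk-run table plus the full per-term MORPH results."""

    table: pd.DataFrame
    results: dict[str, MorphResult] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_bulk(
    jobs: list[BaitSet],
    configs: list[Configuration],
    null: NullDistribution,
    r_max: int = DEFAULT_R_MAX,
    min_baits_per_module: int = 1,
) -> BulkResult:
    """Run MORPH on every job and attach empirical p and BH q values.

    A job that no configuration can score is recorded as a failed row
    (status ``unscorable``, empty statistics) rather than aborting the run.
    The p-value uses the number of baits present in the chosen
    configuration as the bait-set size S, matching the null construction
    where every sampled gene is present by design.
    """
    rows = []
    results: dict[str, MorphResult] = {}
    for job in sorted(jobs, key=lambda b: b.term_id):
        try:
            res = run_morph(configs, job, r_max, min_baits_per_module)
        except EmptyScorableSet:
            rows.append(
                {
                    "term_id": job.term_id,
                    "n_genes_annotated": len(job),
                    "n_baits_used": 0,
                    "chosen_config_id": "",
                    "ausr": np.nan,
                    "p_value": np.nan,
                    "status": "unscorable",
                }
            )
            continue
        results[job.term_id] = res
        rows.append(
            {
                "term_id": job.term_id,
                "n_genes_annotated": len(job),
                "n_baits_used": res.n_baits_used,
                "chosen_config_id": res.chosen_config_id,
                "ausr": res.ausr,
                "p_value": empirical_pvalue(res.ausr, res.n_baits_used, null),
                "status": "ok",
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = np.nan
    ok = table["status"] == "ok"
    if ok.any():
        table.loc[ok, "q_value"] = bh_adjust(table.loc[ok, "p_value"])
    table = table[
        ["term_id", "n_genes_annotated", "n_baits_used", "chosen_config_id",
         "ausr", "p_value", "q_value", "status"]
    ]
    return BulkResult(table=table, results=results)


def extend_annotations(
    bulk: BulkResult,
    results: dict[str, MorphResult] | None = None,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    z_threshold: float = DEFAULT_EXTENSION_Z,
    annotation: AnnotationSet | None = None,
) -> tuple[pd.DataFrame, int]:
    """Extended annotation rows and the count of newly annotated genes.

    For every term with q strictly below ``q_threshold``, every candidate
    with z strictly above ``z_threshold`` yields a
    (gene_id, term_id, z, evidence) row. The second return value counts
    genes receiving their first annotation — genes in the output absent
    from ``annotation`` (or, if none is given, from the union of job bait
    sets).
    """
    if results is None:
        results = bulk.results
    rows = []
    ok = bulk.table[bulk.table["status"] == "ok"]
    for _, rec in ok.iterrows():
        if not rec["q_value"] < q_threshold:
            continue
        res = results[rec["term_id"]]
        for c in res.candidates:
            if c.z > z_threshold:
                rows.append((c.gene_id, rec["term_id"], c.z, "MORPH"))
    df = pd.DataFrame(rows, columns=["gene_id", "term_id", "z", "evidence"])
    if annotation is not None:
        known = set(annotation.genes())
    else:  # fall back to the union of bait genes across the runs
        known = set()
        for res in results.values():
            known |= set(res.self_ranks)
    n_new = int(df.loc[~df["gene_id"].isin(known), "gene_id"].nunique())
    return df, n_new


def morphdb_records(
    bulk: BulkResult,
    results: dict[str, MorphResult] | None = None,
    p_threshold: float = DEFAULT_RECORD_P,
    top_k: int = DEFAULT_TOP_K,
    z_threshold: float = DEFAULT_RECORD_Z,
) -> pd.DataFrame:
    """Storage-rule records: per term with empirical p strictly below
    ``p_threshold``, the up-to-``top_k`` highest-ranked candidates whose z
    strictly exceeds ``z_threshold``."""
    if results is None:
        results = bulk.results
    rows = []
    ok = bulk.table[bulk.table["status"] == "ok"]
    for _, rec in ok.iterrows():
        if not rec["p_value"] < p_threshold:
            continue
        res = results[rec["term_id"]]
        kept = [c for c in res.candidates if c.z > z_threshold][:top_k]
        for c in kept:
            rows.append((rec["term_id"], c.gene_id, c.module_id, c.z, c.rank))
    return pd.DataFrame(rows, columns=["term_id", "gene_id", "module_id", "z", "rank"])
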