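"""The MORPH guilt-by-association ranking algorithm.

Given a *bait set* — genes annotated to one functional term — and a
collection of dataset/clustering configurations, MORPH

1. scores every candidate gene by its module-partitioned co-expression
   with the baits: within each module that contains baits, a candidate's
   raw score is its mean Pearson correlation with the in-module baits,
   standardized to a z-score over the module's candidates so that scores
   are comparable across modules;
2. estimates how well each configuration supports the term by
   leave-one-out cross-validation: each bait in turn is removed, re-ranked
   as a candidate against the remaining baits, and its *self-rank*
   recorded; the area under the self-rank curve (AUSR, in [0, 1], 1 =
   perfect) summarizes the self-ranks;
3. selects the configuration with maximal AUSR (model selection) and
   reports the globally ranked candidate list from a full run on it.

:class:`MorphRanker` is the sklearn-style estimator; ``score_candidates``,
``self_rank``, ``ausr``, ``select_config`` and ``run_morph`` are the
functional surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .clustering import SD_FLOOR, Configuration
from .exceptions import EmptyScorableSet, ParameterError

#: sentinel for a bait that received no rank in a LOOCV run
UNSCORED = None

DEFAULT_R_MAX = 1000


@dataclass(frozen=True)
class BaitSet:
    """A functional term and its annotated genes (the query set)."""

    term_id: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ParameterError(f"bait set {self.term_id!r} is empty")

    def without(self, gene_id: str) -> "BaitSet":
        if gene_id not in self.genes:
            raise ParameterError(f"{gene_id!r} is not a bait of {self.term_id!r}")
        return BaitSet(self.term_id, self.genes - {gene_id}, self.description)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class CandidateScore:
    """Score of one candidate gene against a bait set."""

    gene_id: str
    module_id: int
    raw_score: float  # mean Pearson r with in-module baits, in [-1, 1]
    z: float  # within-module standardized score
    rank: int  # 1 = best


@dataclass
class MorphResult:
    """Outcome of a full MORPH run for one bait set."""

    term_id: str
    chosen_config_id: str
    ausr: float
    self_ranks: dict[str, int | None]  # bait gene -> rank or UNSCORED
    candidates: list[CandidateScore]
    n_baits_used: int

    def candidate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.term_id, self.chosen_config_id, c.gene_id, c.module_id,
                 c.raw_score, c.z, c.rank)
                for c in self.candidates
            ],
            columns=["term_id", "config_id", "gene_id", "module_id",
                     "raw_score", "z", "rank"],
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.term_id, self.chosen_config_id, self.n_baits_used, self.ausr)],
            columns=["term_id", "config_id", "n_baits_used", "ausr"],
        )


class _ConfigCache:
    """Precomputed arrays for fast repeated scoring of one configuration.

    Rows are centred and scaled to unit norm so that Pearson correlation
    between two genes is the dot product of their rows; constant rows
    (SD < 1e-12) become zero vectors, i.e. correlate 0 with everything.
    """

    def __init__(self, config: Configuration):
        self.config = config
        m = config.matrix
        x = m.values
        centred = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centred, axis=1, keepdims=True)
        small = norms[:, 0] < SD_FLOOR * np.sqrt(m.n_samples)
        norms[small, 0] = 1.0
        self.unit = centred / norms
        self.unit[small] = 0.0
        self.gene_index = m._gene_index
        # module id per row; -1 = unclustered / unassigned
        module_of = np.full(m.n_genes, -1, dtype=int)
        for g, mod in config.clustering.assignment.items():
            module_of[self.gene_index[g]] = mod
        self.module_of = module_of
        self.module_rows: dict[int, np.ndarray] = {
            mod: np.flatnonzero(module_of == mod)
            for mod in config.clustering.module_ids
        }
        # lexicographic position of each gene id, for deterministic tie-breaks
        lex = np.argsort(np.asarray(m.gene_ids, dtype=object), kind="stable")
        pos = np.empty(m.n_genes, dtype=int)
        pos[lex] = np.arange(m.n_genes)
        self.lex_pos = pos
        self.gene_ids = np.asarray(m.gene_ids, dtype=object)


def _as_cache(config: Configuration) -> _ConfigCache:
    cache = getattr(config, "_morph_cache", None)
    if cache is None:
        cache = _ConfigCache(config)
        object.__setattr__(config, "_morph_cache", cache)
    return cache


def _score_arrays(
    cache: _ConfigCache, bait_genes, min_baits_per_module: int
):
    """Core scoring: returns (row_indices, module_ids, raw, z) pooled arrays.

    Candidates are sorted by z descending, ties broken lexicographically by
    gene id; position i corresponds to rank i+1.
    """
    bait_rows = np.array(
        [cache.gene_index[g] for g in bait_genes if g in cache.gene_index],
        dtype=int,
    )
    if len(bait_rows) == 0:
        raise EmptyScorableSet("no bait gene present in the dataset")
    bait_mods = cache.module_of[bait_rows]
    assigned = bait_mods >= 0
    mods, counts = np.unique(bait_mods[assigned], return_counts=True)
    scorable = mods[counts >= min_baits_per_module]
    if len(scorable) == 0:
        raise EmptyScorableSet("no module holds enough bait genes")
    rows_list, mod_list, raw_list, z_list = [], [], [], []
    for mod in scorable:
        members = cache.module_rows[mod]
        in_bait = np.isin(members, bait_rows, assume_unique=False)
        baits_here = members[in_bait]
        cand = members[~in_bait]
        if len(cand) == 0:
            continue
        bbar = cache.unit[baits_here].mean(axis=0)
        raw = cache.unit[cand] @ bbar
        sd = raw.std()
        z = (raw - raw.mean()) / sd if sd >= SD_FLOOR else np.zeros_like(raw)
        rows_list.append(cand)
        mod_list.append(np.full(len(cand), mod, dtype=int))
        raw_list.append(raw)
        z_list.append(z)
    if not rows_list:
        raise EmptyScorableSet("all scorable modules contain only bait genes")
    rows = np.concatenate(rows_list)
    mods_arr = np.concatenate(mod_list)
    raw = np.concatenate(raw_list)
    z = np.concatenate(z_list)
    order = np.lexsort((cache.lex_pos[rows], -z))
    return rows[order], mods_arr[order], raw[order], z[order]


def score_candidates(
    config: Configuration, baits: BaitSet, min_baits_per_module: int = 1
) -> list[CandidateScore]:
    """Rank all candidate genes of ``config`` against the bait set.

    Only modules containing at least ``min_baits_per_module`` baits are
    scorable; their non-bait members are the candidates. Raw score = mean
    Pearson r with the in-module baits; z = within-module standardization
    over candidates (a module whose candidates all tie gets z = 0). The
    pooled candidates are ranked by z descending, ties broken
    lexicographically by gene id.
    """
    cache = _as_cache(config)
    rows, mods, raw, z = _score_arrays(cache, baits.genes, min_baits_per_module)
    return [
        CandidateScore(
            gene_id=str(cache.gene_ids[r]),
            module_id=int(m),
            raw_score=float(s),
            z=float(zz),
            rank=i + 1,
        )
        for i, (r, m, s, zz) in enumerate(zip(rows, mods, raw, z))
    ]


def self_rank(
    config: Configuration,
    baits: BaitSet,
    left_out: str,
    min_baits_per_module: int = 1,
) -> int | None:
    """Rank of ``left_out`` when scored against the remaining baits.

    Returns UNSCORED (None) when the left-out gene cannot be ranked in this
    configuration: it is absent from the matrix, unclustered, or its module
    retains no (or too few) baits after removal.
    """
    reduced = baits.without(left_out)  # raises ParameterError if not a bait
    cache = _as_cache(config)
    row = cache.gene_index.get(left_out)
    if row is None or cache.module_of[row] < 0:
        return UNSCORED
    try:
        rows, _, _, _ = _score_arrays(cache, reduced.genes, min_baits_per_module)
    except EmptyScorableSet:
        return UNSCORED
    hits = np.flatnonzero(rows == row)
    if len(hits) == 0:
        return UNSCORED
    return int(hits[0]) + 1


def ausr(self_ranks, r_max: int = DEFAULT_R_MAX) -> float:
    """Area under the self-rank curve.

    ``AUSR = (1 / (|G| * r_max)) * sum_i max(0, r_max - r_i + 1)`` with an
    UNSCORED entry contributing 0 — equivalently, the mean over thresholds
    t = 1..r_max of the fraction of baits with self-rank <= t. Accepts any
    collection of ranks / UNSCORED or a mapping gene -> rank.
    """
    if r_max < 1:
        raise ParameterError(f"r_max must be >= 1, got {r_max}")
    ranks = list(self_ranks.values()) if isinstance(self_ranks, dict) else list(self_ranks)
    if not ranks:
        raise ParameterError("empty self-rank collection")
    total = sum(max(0, r_max - r + 1) for r in ranks if r is not UNSCORED)
    return total / (len(ranks) * r_max)


def _loocv(
    config: Configuration, baits: BaitSet, min_baits_per_module: int
) -> dict[str, int | None]:
    if len(baits) < 2:
        # a single bait cannot be left out and still leave a query set
        return {g: UNSCORED for g in baits.genes}
    return {
        g: self_rank(config, baits, g, min_baits_per_module)
        for g in sorted(baits.genes)
    }


def select_config(
    configs: list[Configuration],
    baits: BaitSet,
    r_max: int = DEFAULT_R_MAX,
    min_baits_per_module: int = 1,
):
    """LOOCV model selection: the configuration with maximal AUSR.

    Returns ``(config, ausr, self_ranks)``; ties (and hence reruns) resolve
    to the earliest configuration in input order. Configurations in which
    no bait is scorable are skipped; if none remains, EmptyScorableSet.
    """
    if not configs:
        raise ParameterError("no configurations supplied")
    best = None
    for config in configs:
        try:
            # a configuration must be able to score the full bait set
            _score_arrays(_as_cache(config), baits.genes, min_baits_per_module)
        except EmptyScorableSet:
            continue
        ranks = _loocv(config, baits, min_baits_per_module)
        score = ausr(ranks, r_max)
        if best is None or score > best[1]:
            best = (config, score, ranks)
    if best is None:
        raise EmptyScorableSet(
            f"bait set {baits.term_id!r} is unscorable in every configuration"
        )
    return best


def run_morph(
    configs: list[Configuration],
    baits: BaitSet,
    r_max: int = DEFAULT_R_MAX,
    min_baits_per_module: int = 1,
) -> MorphResult:
    """Model selection followed by a full-bait-set run on the winner."""
    config, score, ranks = select_config(configs, baits, r_max, min_baits_per_module)
    candidates = score_candidates(config, baits, min_baits_per_module)
    cache = _as_cache(config)
    n_used = sum(g in cache.gene_index for g in baits.genes)
    return MorphResult(
        term_id=baits.term_id,
        chosen_config_id=config.config_id,
        ausr=score,
        self_ranks=ranks,
        candidates=candidates,
        n_baits_used=n_used,
    )


class MorphRanker(BaseEstimator):
    """sklearn-style estimator wrapping the MORPH procedure.

    Parameters
    ----------
    r_max : int, default 1000
        Rank-threshold ceiling of the self-rank curve.
    min_baits_per_module : int, default 1
        Minimum number of baits a module must hold to be scorable.

    After :meth:`fit`, the fitted attributes are ``chosen_config_``,
    ``chosen_config_id_``, ``ausr_``, ``self_ranks_``, ``result_`` and
    ``n_baits_used_``; :meth:`rank` returns the candidate table.
    """

    def __init__(self, r_max: int = DEFAULT_R_MAX, min_baits_per_module: int = 1):
        self.r_max = r_max
        self.min_baits_per_module = min_baits_per_module

    def fit(self, X: list[Configuration], y: BaitSet):
        """Select the best configuration for bait set ``y`` among ``X``."""
        result = run_morph(X, y, self.r_max, self.min_baits_per_module)
        self.result_ = result
        self.chosen_config_id_ = result.chosen_config_id
        self.chosen_config_ = next(
            c for c in X if c.config_id == result.chosen_config_id
        )
        self.ausr_ = result.ausr
        self.self_ranks_ = result.self_ranks
        self.n_baits_used_ = result.n_baits_used
        return self

    def rank(self) -> pd.DataFrame:
        """Globally ranked candidate table of the fitted run."""
        return self.result_.candidate_frame()

    def predict(self, top_k: int | None = None) -> list[str]:
        """Top-ranked candidate gene ids (all of them when ``top_k`` is None)."""
        genes = [c.gene_id for c in self.result_.candidates]
        return genes if top_k is None else genes[:top_k]


def write_result(result: MorphResult, stem) -> tuple[str, str]:
    """Serialize a MorphResult as two TSVs: ``<stem>.candidates.tsv`` and
    ``<stem>.summary.tsv``. Returns the two paths."""
    cand_path = f"{stem}.candidates.tsv"
    sum_path = f"{stem}.summary.tsv"
    result.candidate_frame().to_csv(
        cand_path, sep="\t", index=False, float_format="%.10g"
    )
    result.summary_frame().to_csv(
        sum_path, sep="\t", index=False, float_format="%.10g"
    )
    return cand_path, sum_path
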