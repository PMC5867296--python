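"""Expression preprocessing: variance filtering and normalization.

Three sklearn-style transformers operate on :class:`ExpressionMatrix`
objects (genes in rows, samples in columns):

* :class:`SDFilter` — keep the most variable genes (default: the top 75%
  by gene-wise sample standard deviation).
* :class:`QuantileNormalizer` — force every sample (column) onto the same
  empirical distribution; the standard choice for microarray intensities.
* :class:`TMMNormalizer` — trimmed-mean-of-M-values library-size
  normalization for RNA-seq count data, followed by log2(CPM + 1).

Module-level functions (:func:`filter_by_sd`, :func:`quantile_normalize`,
:func:`tmm_normalize`) are thin wrappers over the transformers.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ParameterError, ValidationError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


class SDFilter(BaseEstimator, TransformerMixin):
    """Retain the ``ceil(retain_fraction * n_genes)`` most variable genes.

    Variability is the gene-wise sample standard deviation (ddof=1). Ties at
    the cutoff are broken in favour of the lower row index; the surviving
    genes keep their original order.
    """

    def __init__(self, retain_fraction: float = 0.75):
        self.retain_fraction = retain_fraction

    def fit(self, m: ExpressionMatrix, y=None):
        if not 0.0 < self.retain_fraction <= 1.0:
            raise ParameterError(
                f"retain_fraction must be in (0, 1], got {self.retain_fraction}"
            )
        sd = m.values.std(axis=1, ddof=1)
        n_keep = int(np.ceil(self.retain_fraction * m.n_genes))
        # stable sort on -sd => ties resolved toward the lower row index
        order = np.argsort(-sd, kind="stable")[:n_keep]
        self.kept_indices_ = np.sort(order)
        self.n_kept_ = n_keep
        return self

    def transform(self, m: ExpressionMatrix) -> ExpressionMatrix:
        return m.subset(self.kept_indices_)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization across samples.

    Every column is mapped onto the reference distribution formed by the
    per-rank mean of the sorted columns, so after transformation every
    sample shares the identical sorted value vector. Ties within a column
    receive the mean of the reference values at their tied ranks. The
    transformation is stateless and idempotent.
    """

    def fit(self, m: ExpressionMatrix, y=None):
        return self

    def transform(self, m: ExpressionMatrix) -> ExpressionMatrix:
        if m.n_samples < 2:
            logger.warning(
                "dataset %s has a single sample; quantile normalization is a no-op",
                m.dataset_id,
            )
            return m
        x = m.values
        reference = np.sort(x, axis=0).mean(axis=1)
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            col = x[:, j]
            order = np.argsort(col, kind="stable")
            sorted_col = col[order]
            # runs of equal values share the mean reference over their ranks
            boundaries = np.flatnonzero(np.r_[True, np.diff(sorted_col) != 0])
            run_sums = np.add.reduceat(reference, boundaries)
            run_lens = np.diff(np.r_[boundaries, len(col)])
            run_means = run_sums / run_lens
            assigned = np.repeat(run_means, run_lens)
            out[order, j] = assigned
        return m.with_values(out)


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Trimmed mean of M-values normalization for count data.

    Per-sample scale factors follow Robinson & Oshlack: the reference column
    is the sample whose upper-quartile (of counts relative to library size)
    is closest to the mean upper-quartile; for each other column, per-gene
    log-ratios (M) and average log-abundances (A) are formed on genes with
    positive counts in both columns, the most extreme 30% of M and 5% of A
    are trimmed from each tail (rank windows), and the factor is
    2**(precision-weighted mean of the remaining M). Precision weights use
    relative counts p = x / library_size, w = (1-p_j)/p_j + (1-p_ref)/p_ref,
    which makes the factors exactly invariant to rescaling any single
    sample. Factors are rescaled to geometric mean 1. Output values are
    log2(CPM / factor + 1).
    """

    def __init__(
        self,
        trim_m: float = 0.30,
        trim_a: float = 0.05,
        ref_quantile: float = 0.75,
        log_offset: float = 1.0,
    ):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.ref_quantile = ref_quantile
        self.log_offset = log_offset

    def fit(self, m: ExpressionMatrix, y=None):
        x = np.asarray(m.values, dtype=float)
        if np.any(x < 0):
            raise ValidationError("TMM requires non-negative counts")
        lib = x.sum(axis=0)
        zero = np.flatnonzero(lib == 0)
        if len(zero):
            raise ValidationError(
                f"all-zero sample(s): {[m.sample_ids[j] for j in zero]}"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            uq = np.array(
                [np.quantile(x[:, j] / lib[j], self.ref_quantile) for j in range(x.shape[1])]
            )
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        factors = np.array(
            [self._pair_factor(x[:, j], x[:, ref], lib[j], lib[ref]) for j in range(x.shape[1])]
        )
        factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
        self.scale_factors_ = factors
        self.ref_sample_ = m.sample_ids[ref]
        return self

    def _pair_factor(self, xj, xr, nj, nr) -> float:
        pos = (xj > 0) & (xr > 0)
        if not pos.any():
            return 1.0
        pj = xj[pos] / nj
        pr = xr[pos] / nr
        m_vals = np.log2(pj / pr)
        a_vals = 0.5 * np.log2(pj * pr)
        if np.max(np.abs(m_vals)) < 1e-6:
            return 1.0
        n = len(m_vals)
        lo_m = np.floor(n * self.trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * self.trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m_vals)
        ra = rankdata(a_vals)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            return 1.0
        w = (1 - pj[keep]) / pj[keep] + (1 - pr[keep]) / pr[keep]
        # inverse-variance weights: genes with higher relative counts count more
        return float(2 ** (np.sum(m_vals[keep] / w) / np.sum(1.0 / w)))

    def transform(self, m: ExpressionMatrix) -> ExpressionMatrix:
        x = np.asarray(m.values, dtype=float)
        lib = x.sum(axis=0)
        cpm = x / (lib * self.scale_factors_) * 1e6
        out = np.log2(cpm + self.log_offset)
        return m.with_values(out)


def filter_by_sd(m: ExpressionMatrix, retain_fraction: float = 0.75) -> ExpressionMatrix:
    """Keep the ``ceil(retain_fraction * n_genes)`` genes with largest SD."""
    return SDFilter(retain_fraction).fit(m).transform(m)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to a common empirical distribution."""
    return QuantileNormalizer().fit(m).transform(m)


def tmm_normalize(m: ExpressionMatrix, **kwargs) -> ExpressionMatrix:
    """TMM-normalize a count matrix and return log2(CPM + 1) values."""
    return TMMNormalizer(**kwargs).fit(m).transform(m)


def prepare_dataset(
    m: ExpressionMatrix,
    retain_fraction: float = 0.75,
    normalize_first: bool = True,
) -> ExpressionMatrix:
    """Platform-appropriate normalization plus SD filtering.

    Microarray data is quantile-normalized, raw counts are TMM-normalized,
    FPKM values pass through unchanged. By default the matrix is normalized
    before the variance filter (``normalize_first=False`` swaps the order).
    """
    def norm(mm: ExpressionMatrix) -> ExpressionMatrix:
        if mm.platform == "microarray":
            return quantile_normalize(mm)
        if mm.platform == "rnaseq_counts":
            return tmm_normalize(mm)
        return mm

    if normalize_first:
        return filter_by_sd(norm(m), retain_fraction)
    return norm(filter_by_sd(m, retain_fraction))
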