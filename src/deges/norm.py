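"""Per-sample normalization factors for count matrices.

Four methods are provided, matching the standard sweep for one-way
RNA-seq designs: TMM (trimmed mean of M-values), median-of-ratios (RLE /
DESeq-style size factors), upper-quartile scaling, and no normalization.
All methods emit the same contract: factors rescaled to geometric mean
1, with effective library size = raw library size * factor.  Every
method accepts a gene mask so factors can be recomputed on a DEG-free
subset — the core step of DEGES — while library sizes stay those of the
full raw matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from deges.core import CountMatrix

METHODS = ("tmm", "medianratio", "upperquartile", "none")


class DegenerateInputError(ValueError):
    """Raised when a matrix cannot support the requested normalization."""


@dataclass(frozen=True)
class NormalizationResult:
    """Per-sample factors with method provenance.

    Invariants: geometric mean of ``factors`` is 1;
    ``effective_library_sizes = library_sizes * factors``.
    """

    method: str
    factors: np.ndarray
    library_sizes: np.ndarray
    subset_size: int

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.factors

    def offsets(self) -> np.ndarray:
        """log effective library sizes, the GLM offset vector."""
        return np.log(self.effective_library_sizes)


def _rescale(factors: np.ndarray) -> np.ndarray:
    """Rescale positive factors to geometric mean 1."""
    factors = np.asarray(factors, dtype=float)
    return factors / np.exp(np.mean(np.log(factors)))


def _check_mask(m: CountMatrix, gene_mask: np.ndarray | None) -> np.ndarray:
    if gene_mask is None:
        return np.ones(m.n_genes, dtype=bool)
    gene_mask = np.asarray(gene_mask, dtype=bool)
    if gene_mask.shape != (m.n_genes,):
        raise ValueError("gene_mask length must equal number of genes")
    return gene_mask


def tmm_factors(
    m: CountMatrix,
    gene_mask: np.ndarray | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationResult:
    """Trimmed mean of M-values factors.

    Per sample j against a reference r, per-gene log-ratios
    M = log2((y_gj/N_j) / (y_gr/N_r)) and average abundances
    A = 0.5*log2((y_gj/N_j) * (y_gr/N_r)) are computed over genes
    positive in both samples; the top and bottom ``trim_m`` fraction by
    M and ``trim_a`` fraction by A are discarded; the factor is 2 to the
    inverse-asymptotic-variance weighted mean of the surviving M.  The
    reference is the sample whose upper-quartile/library-size ratio is
    closest to the across-sample mean of that ratio.  Library sizes N
    are taken from the full raw matrix even when ``gene_mask`` restricts
    the genes entering the M/A computation.
    """
    if m.n_samples < 2:
        raise DegenerateInputError("TMM needs at least 2 samples")
    mask = _check_mask(m, gene_mask)
    lib = m.library_sizes()
    if np.any(lib == 0):
        raise DegenerateInputError("sample with zero total count")
    y = m.counts[mask].astype(float)
    if y.shape[0] == 0:
        raise DegenerateInputError("gene mask removed all genes")

    # reference choice: upper quartile of scaled counts closest to mean
    with np.errstate(invalid="ignore"):
        uq = np.quantile(y / lib, 0.75, axis=0)
    if np.all(uq == 0):
        raise DegenerateInputError("all upper quartiles are zero")
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(m.n_samples, dtype=float)
    yr = y[:, ref]
    for j in range(m.n_samples):
        if j == ref:
            continue
        factors[j] = _tmm_pair(y[:, j], yr, lib[j], lib[ref], trim_m, trim_a)
    return NormalizationResult("tmm", _rescale(factors), lib, int(mask.sum()))


def _tmm_pair(
    yj: np.ndarray, yr: np.ndarray, nj: float, nr: float, trim_m: float, trim_a: float
) -> float:
    """Doubly trimmed, precision-weighted mean of M-values for one pair."""
    pos = (yj > 0) & (yr > 0)
    if not np.any(pos):
        raise DegenerateInputError("no gene positive in both samples of a TMM pair")
    yj = yj[pos]
    yr = yr[pos]
    pj = yj / nj
    pr = yr / nr
    m_vals = np.log2(pj / pr)
    a_vals = 0.5 * np.log2(pj * pr)
    w = (nj - yj) / (nj * yj) + (nr - yr) / (nr * yr)

    n = m_vals.size
    lo_m = int(np.floor(n * trim_m) + 1)
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a) + 1)
    hi_a = n + 1 - lo_a
    # rank-based double trim: keep genes inside both central bands
    rank_m = _rank(m_vals)
    rank_a = _rank(a_vals)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        warnings.warn("TMM trim removed all genes; falling back to untrimmed mean")
        keep = np.ones(n, dtype=bool)
    wk = 1.0 / w[keep]
    return float(2.0 ** (np.sum(wk * m_vals[keep]) / np.sum(wk)))


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based, midranks for ties)."""
    from scipy.stats import rankdata

    return rankdata(x)


def median_ratio_factors(
    m: CountMatrix, gene_mask: np.ndarray | None = None
) -> NormalizationResult:
    """Median-of-ratios (RLE) factors.

    The size factor of sample j is the median over genes — restricted to
    genes with strictly positive counts in every sample — of
    y_gj / geomean_g, where geomean_g is the geometric mean of gene g
    across samples.  Size factors are converted to normalization factors
    (divided by library size) and rescaled to geometric mean 1, so every
    method shares one contract.
    """
    mask = _check_mask(m, gene_mask)
    lib = m.library_sizes()
    y = m.counts[mask].astype(float)
    pos = np.all(y > 0, axis=1)
    if not np.any(pos):
        raise DegenerateInputError(
            "median-of-ratios needs at least one gene positive in all samples"
        )
    y = y[pos]
    log_geo = np.mean(np.log(y), axis=1)
    size = np.exp(np.median(np.log(y) - log_geo[:, None], axis=0))
    factors = _rescale(size / lib)
    return NormalizationResult("medianratio", factors, lib, int(mask.sum()))


def simple_factors(
    m: CountMatrix, method: str = "none", gene_mask: np.ndarray | None = None
) -> NormalizationResult:
    """Upper-quartile or unit factors.

    ``none`` returns all-ones factors (library-size-only scaling).
    ``upperquartile`` sets factor_j proportional to the 75th percentile
    (linear interpolation) of sample j's nonzero counts divided by its
    library size, rescaled to geometric mean 1.
    """
    if method not in ("upperquartile", "none"):
        raise ValueError(f"unknown simple method {method!r}")
    mask = _check_mask(m, gene_mask)
    lib = m.library_sizes()
    if method == "none":
        return NormalizationResult("none", np.ones(m.n_samples), lib, int(mask.sum()))
    if np.any(lib == 0):
        raise DegenerateInputError("sample with zero total count")
    y = m.counts[mask].astype(float)
    q = np.empty(m.n_samples)
    for j in range(m.n_samples):
        col = y[:, j]
        col = col[col > 0]
        if col.size == 0:
            raise DegenerateInputError(f"sample {m.sample_ids[j]!r} has no nonzero count")
        q[j] = np.quantile(col, 0.75)
    if np.any(q <= 0):
        raise DegenerateInputError("non-positive upper quartile")
    return NormalizationResult("upperquartile", _rescale(q / lib), lib, int(mask.sum()))


def normalization_factors(
    m: CountMatrix,
    method: str,
    gene_mask: np.ndarray | None = None,
) -> NormalizationResult:
    """Dispatch to the requested normalization method."""
    if method == "tmm":
        return tmm_factors(m, gene_mask)
    if method == "medianratio":
        return median_ratio_factors(m, gene_mask)
    if method in ("upperquartile", "none"):
        return simple_factors(m, method, gene_mask)
    raise ValueError(f"unknown normalization method {method!r}; choose from {METHODS}")
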