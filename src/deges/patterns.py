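"""Three-group expression-pattern classification and sample clustering.

Each DEG is assigned one of the canonical three-group expression
patterns (G1 = G2 = G3, G1 > G2 = G3, G1 > G2 > G3, ...) by fitting the
five constrained one-way NB models — one pooled mean per block of the
group-equality partition — and selecting the best by BIC; the ordering
of the fitted block means (descending) then names the pattern.

Sample clustering follows the raw-count recipe: drop all-zero genes,
collapse duplicate count rows to unique expression patterns, use
1 - Spearman correlation as the distance, agglomerate with average
linkage, and emit Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from skbio import TreeNode

from deges.core import CountMatrix, GroupDesign
from deges.glm import DEResult, _fit_oneway, _group_index_lists, nb_loglik

#: the five group-equality partitions of three groups, as tuples of blocks
PARTITIONS: tuple[tuple[tuple[int, ...], ...], ...] = (
    ((0, 1, 2),),
    ((0,), (1, 2)),
    ((1,), (0, 2)),
    ((2,), (0, 1)),
    ((0,), (1,), (2,)),
)

#: the ten patterns commonly tabulated for three-group data; two-block
#: partitions with the pair above the singleton add three more labels
#: (e.g. "G2=G3>G1"), which this classifier also emits when the data
#: demand them.
TEN_PATTERNS = (
    "G1=G2=G3",
    "G1>G2=G3",
    "G1>G2>G3",
    "G1>G3>G2",
    "G2>G1=G3",
    "G2>G1>G3",
    "G2>G3>G1",
    "G3>G1=G2",
    "G3>G1>G2",
    "G3>G2>G1",
)


@dataclass(frozen=True)
class ExpressionPattern:
    pattern: str
    selected_partition: tuple[tuple[int, ...], ...]
    score: float  # BIC of the selected model (lower is better)


def _pattern_label(partition, block_means: np.ndarray, labels) -> str:
    """Order blocks by descending fitted mean, break ties by group index."""
    blocks = [
        (float(block_means[b]), min(block)) for b, block in enumerate(partition)
    ]
    order = sorted(range(len(partition)), key=lambda b: (-blocks[b][0], blocks[b][1]))
    parts = []
    for b in order:
        members = sorted(partition[b])
        parts.append("=".join(labels[i] for i in members))
    return ">".join(parts)


def classify_genes(
    m: CountMatrix,
    design: GroupDesign,
    offsets: np.ndarray | None = None,
    phi: np.ndarray | float = 0.1,
    gene_mask: np.ndarray | None = None,
) -> list[ExpressionPattern]:
    """Classify (a subset of) genes into expression patterns.

    For every partition the blocks share a pooled NB mean; models are
    compared by BIC = -2*loglik + k*log(n_samples).  Vectorized across
    genes.  All-zero genes come back flat (G1 = G2 = G3).
    """
    if design.n_groups != 3:
        raise ValueError("pattern classification is defined for three groups")
    if offsets is None:
        offsets = np.log(m.library_sizes())
    offsets = np.asarray(offsets, dtype=float)
    if gene_mask is None:
        gene_mask = np.ones(m.n_genes, dtype=bool)
    y = m.counts[gene_mask].astype(float)
    n_genes, n_samples = y.shape
    if n_genes == 0:
        return []
    phi_vec = np.asarray(phi, dtype=float)
    if phi_vec.ndim == 1:
        phi_vec = phi_vec[gene_mask]
    gidx = design.group_indices(m.sample_ids)
    group_lists = _group_index_lists(gidx, 3)

    bics = np.empty((n_genes, len(PARTITIONS)))
    means = []  # per partition: (n_genes, n_blocks) block means
    for pi, partition in enumerate(PARTITIONS):
        block_lists = [
            np.concatenate([group_lists[g] for g in block]) for block in partition
        ]
        beta, mu = _fit_oneway(y, offsets, block_lists, phi_vec)
        ll = nb_loglik(y, mu, phi_vec)
        k = len(partition)
        bics[:, pi] = -2.0 * ll + k * np.log(n_samples)
        means.append(np.exp(beta))

    best = np.argmin(bics, axis=1)
    labels = design.group_order
    zero = y.sum(axis=1) == 0
    out: list[ExpressionPattern] = []
    for g in range(n_genes):
        if zero[g]:
            out.append(ExpressionPattern("=".join(labels), PARTITIONS[0], float(bics[g, 0])))
            continue
        pi = int(best[g])
        label = _pattern_label(PARTITIONS[pi], means[pi][g], labels)
        out.append(ExpressionPattern(label, PARTITIONS[pi], float(bics[g, pi])))
    return out


def classify_pattern(
    counts_g: np.ndarray,
    design: GroupDesign,
    offsets: np.ndarray | None = None,
    phi: float = 0.1,
    sample_ids=None,
) -> ExpressionPattern:
    """Classify a single gene (see :func:`classify_genes`)."""
    sample_ids = sample_ids if sample_ids is not None else list(design.sample_to_group)
    m = CountMatrix(["g"], sample_ids, np.asarray(counts_g, dtype=np.int64)[None, :])
    return classify_genes(m, design, offsets, phi)[0]


def pattern_distribution(
    m: CountMatrix,
    design: GroupDesign,
    de: DEResult,
    fdr: float = 0.05,
    offsets: np.ndarray | None = None,
    phi: np.ndarray | float = 0.1,
) -> pd.DataFrame:
    """Percentage of DEGs (q < fdr) assigned to each expression pattern.

    Returns one row per observed pattern with columns ``pattern``,
    ``percent`` and ``count``, plus the total in ``df.attrs["total"]``.
    Percentages sum to 100 (up to floating point) over a non-empty set.
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must lie in (0, 1)")
    mask = (de.q_value < fdr) & de.tested
    total = int(mask.sum())
    if total == 0:
        df = pd.DataFrame(columns=["pattern", "percent", "count"])
        df.attrs["total"] = 0
        return df
    patterns = classify_genes(m, design, offsets, phi, gene_mask=mask)
    counts = pd.Series([p.pattern for p in patterns]).value_counts()
    df = pd.DataFrame(
        {
            "pattern": counts.index,
            "percent": 100.0 * counts.to_numpy() / total,
            "count": counts.to_numpy(),
        }
    ).reset_index(drop=True)
    df.attrs["total"] = total
    return df


def cluster_samples(m: CountMatrix) -> TreeNode:
    """Average-linkage clustering of samples with 1 - Spearman distance.

    Genes with zero counts in all samples are dropped and duplicate
    count rows collapsed to unique rows before computing pairwise
    Spearman correlations between samples.  Returns the dendrogram as a
    ``skbio.TreeNode`` (write with ``tree.write(path)`` for Newick);
    branch lengths encode the merge heights.
    """
    if m.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    y = m.counts[m.counts.sum(axis=1) > 0]
    y = np.unique(y, axis=0)
    if y.shape[0] < 2:
        raise ValueError("fewer than 2 distinct nonzero genes; cannot cluster")
    if m.n_samples == 2:
        rho = np.array([[1.0, spearmanr(y[:, 0], y[:, 1]).statistic]] * 2)
        rho[0, 0] = rho[1, 1] = 1.0
        corr = rho
    else:
        corr = spearmanr(y).statistic
    dist = 1.0 - np.asarray(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    z = average(squareform(dist, checks=False))
    tree = TreeNode.from_linkage_matrix(z, list(m.sample_ids))
    return tree


def linkage_matrix(m: CountMatrix) -> np.ndarray:
    """The raw SciPy linkage matrix behind :func:`cluster_samples`."""
    y = m.counts[m.counts.sum(axis=1) > 0]
    y = np.unique(y, axis=0)
    corr = spearmanr(y).statistic if m.n_samples > 2 else np.array(
        [[1.0, spearmanr(y[:, 0], y[:, 1]).statistic], [spearmanr(y[:, 0], y[:, 1]).statistic, 1.0]]
    )
    dist = 1.0 - np.asarray(corr)
    np.fill_diagonal(dist, 0.0)
    return average(squareform(np.maximum(dist, 0.0), checks=False))
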