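"""Negative-binomial GLM testing for one-way (multi-group) designs.

Per-gene counts are modeled as NB with log link and per-sample offsets
(log effective library sizes): the full model fits one mean parameter
per group, the null model one overall mean, and genes are ranked by the
ANOVA-like likelihood-ratio p-value (chi-square, df = G - 1).

Dispersion phi (variance mu + phi*mu^2) is estimated from the data by
maximizing the Cox-Reid adjusted profile likelihood (APL): a single
common value across genes, optionally shrunk towards gene-wise values by
weighted-likelihood (tagwise) estimation.  Designs without replicates
must use blind estimation, which ignores group labels; differential
expression then inflates phi, making the downstream test conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from deges.core import CountMatrix, GroupDesign
from deges.norm import NormalizationResult

_BETA_FLOOR = -50.0
_MAX_NEWTON = 50
_NEWTON_TOL = 1e-10
_PHI_GRID = np.exp(np.linspace(np.log(1e-6), np.log(10.0), 25))


@dataclass(frozen=True)
class DispersionEstimates:
    """Dispersion values feeding the LRT.

    ``mode`` is ``"replicated"`` (common + tagwise shrinkage) or
    ``"blind"`` (group labels ignored; tagwise equals common).
    """

    common_phi: float
    tagwise_phi: np.ndarray
    prior_df: float = 10.0
    mode: str = "replicated"

    def __post_init__(self):
        if self.common_phi < 0 or np.any(self.tagwise_phi < 0):
            raise ValueError("dispersions must be non-negative")
        if self.mode not in ("replicated", "blind"):
            raise ValueError(f"unknown dispersion mode {self.mode!r}")
        if self.mode == "blind" and not np.allclose(self.tagwise_phi, self.common_phi):
            raise ValueError("blind mode forbids tagwise shrinkage")


@dataclass(frozen=True)
class DEResult:
    """Ranked per-gene test results.

    Genes with zero counts in every sample are excluded from testing;
    they carry p = q = 1 and ranks after all tested genes.
    """

    gene_ids: tuple[str, ...]
    lr_stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    rank: np.ndarray
    group_means: np.ndarray  # (n_genes, n_groups) fitted normalized means
    group_labels: tuple[str, ...]
    tested: np.ndarray  # boolean per gene

    @property
    def n_filtered(self) -> int:
        return int((~self.tested).sum())

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "gene_id": list(self.gene_ids),
                "lr_stat": self.lr_stat,
                "p_value": self.p_value,
                "q_value": self.q_value,
                "rank": self.rank,
            }
        )
        for k, g in enumerate(self.group_labels):
            df[f"mean_{g}"] = self.group_means[:, k]
        return df


def _group_index_lists(group_idx: np.ndarray, n_groups: int) -> list[np.ndarray]:
    return [np.nonzero(group_idx == k)[0] for k in range(n_groups)]


def _fit_oneway(
    y: np.ndarray,
    offsets: np.ndarray,
    group_lists: list[np.ndarray],
    phi: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene MLE of one mean parameter per group.

    Newton iteration on the NB score equation
    sum_j (y_j - mu_j) / (1 + phi*mu_j) = 0 within each group, with
    mu_j = exp(beta_k + offset_j).  ``phi`` may be a scalar or a per-gene
    vector.  Returns (beta of shape (n_genes, n_groups), mu of shape y).
    Groups whose counts are all zero get ``beta`` at a numerical floor.
    """
    n_genes, _ = y.shape
    n_groups = len(group_lists)
    phi_col = np.asarray(phi, dtype=float)
    if phi_col.ndim == 0:
        phi_col = np.full(n_genes, float(phi_col))
    phi_col = phi_col[:, None]

    esum = np.array([np.exp(offsets[idx]).sum() for idx in group_lists])
    beta = np.empty((n_genes, n_groups))
    zero_grp = np.empty((n_genes, n_groups), dtype=bool)
    for k, idx in enumerate(group_lists):
        ysum = y[:, idx].sum(axis=1)
        zero_grp[:, k] = ysum == 0
        with np.errstate(divide="ignore"):
            beta[:, k] = np.where(zero_grp[:, k], _BETA_FLOOR, np.log(np.maximum(ysum, 1e-12) / esum[k]))

    active = ~zero_grp
    for _ in range(_MAX_NEWTON):
        mu_b = np.exp(np.clip(beta, _BETA_FLOOR, 60.0))
        step_max = 0.0
        for k, idx in enumerate(group_lists):
            if not active[:, k].any():
                continue
            mu = mu_b[:, k : k + 1] * np.exp(offsets[idx])[None, :]
            denom = 1.0 + phi_col * mu
            score = ((y[:, idx] - mu) / denom).sum(axis=1)
            info = (mu / denom).sum(axis=1)
            step = np.where(active[:, k], score / np.maximum(info, 1e-300), 0.0)
            step = np.clip(step, -5.0, 5.0)
            beta[:, k] += step
            step_max = max(step_max, float(np.max(np.abs(step))))
        if step_max < _NEWTON_TOL:
            break
    beta = np.clip(beta, _BETA_FLOOR, 60.0)
    # assemble mu over all samples
    n_samples = offsets.size
    mu_full = np.empty((n_genes, n_samples))
    for k, idx in enumerate(group_lists):
        mu_full[:, idx] = np.exp(beta[:, k : k + 1] + offsets[idx][None, :])
    return beta, mu_full


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples (Poisson at phi=0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    phi_col = np.asarray(phi, dtype=float)
    if phi_col.ndim == 0:
        phi_col = np.full(y.shape[0], float(phi_col))
    out = np.empty(y.shape[0])
    pois = phi_col == 0
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = (yp * np.log(mp) - mp - gammaln(yp + 1.0)).sum(axis=1)
    nb = ~pois
    if nb.any():
        yn, mn = y[nb], mu[nb]
        r = (1.0 / phi_col[nb])[:, None]
        out[nb] = (
            gammaln(yn + r)
            - gammaln(r)
            - gammaln(yn + 1.0)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn))
        ).sum(axis=1)
    return out


def _apl(
    y: np.ndarray,
    offsets: np.ndarray,
    group_lists: list[np.ndarray],
    phi: np.ndarray | float,
) -> np.ndarray:
    """Per-gene Cox-Reid adjusted profile log-likelihood at dispersion phi.

    The adjustment subtracts half the log-determinant of the Fisher
    information of the one-way fit, which is block diagonal: one term
    sum_j mu/(1 + phi*mu) per group.
    """
    _, mu = _fit_oneway(y, offsets, group_lists, phi)
    ll = nb_loglik(y, mu, phi)
    phi_col = np.asarray(phi, dtype=float)
    if phi_col.ndim == 0:
        phi_col = np.full(y.shape[0], float(phi_col))
    adj = np.zeros(y.shape[0])
    for idx in group_lists:
        info = (mu[:, idx] / (1.0 + phi_col[:, None] * mu[:, idx])).sum(axis=1)
        adj += 0.5 * np.log(np.maximum(info, 1e-300))
    return ll - adj


def _prepare(
    m: CountMatrix, design: GroupDesign, offsets: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    y = m.counts.astype(float)
    if offsets is None:
        offsets = np.log(m.library_sizes())
    offsets = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    gidx = design.group_indices(m.sample_ids)
    return y, offsets, _group_index_lists(gidx, design.n_groups)


def estimate_common_dispersion(
    m: CountMatrix,
    design: GroupDesign,
    offsets: np.ndarray | None = None,
    subset: int = 2000,
    seed: int = 0,
) -> float:
    """Common dispersion by maximizing the summed Cox-Reid APL.

    A coarse log-spaced grid over [1e-6, 10] brackets the maximum, which
    is then refined by bounded scalar optimization.  For large matrices
    a deterministic random subset of ``subset`` genes with any nonzero
    count is used, which is accurate for a genome-wide common value.
    """
    y, offsets, group_lists = _prepare(m, design, offsets)
    df_resid = y.shape[1] - len(group_lists)
    if df_resid < 1:
        raise ValueError(
            "no residual degrees of freedom: use blind dispersion estimation "
            "for designs without replicates"
        )
    keep = np.nonzero(y.sum(axis=1) > 0)[0]
    if keep.size == 0:
        raise ValueError("all genes are zero")
    if subset and keep.size > subset:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(keep, size=subset, replace=False))
    ys = y[keep]
    return _maximize_common_apl(ys, offsets, group_lists)


def _maximize_common_apl(
    y: np.ndarray, offsets: np.ndarray, group_lists: list[np.ndarray]
) -> float:
    grid = _PHI_GRID
    vals = np.array([_apl(y, offsets, group_lists, p).sum() for p in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if lo == hi:
        return float(grid[i])
    res = minimize_scalar(
        lambda x: -_apl(y, offsets, group_lists, float(np.exp(x))).sum(),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def estimate_blind_dispersion(
    m: CountMatrix, offsets: np.ndarray | None = None, subset: int = 2000, seed: int = 0
) -> float:
    """Common dispersion with all samples treated as one group.

    The only option without replicates; DE signal inflates the estimate,
    which makes downstream testing conservative.
    """
    if m.n_samples < 2:
        raise ValueError("blind dispersion needs at least 2 samples")
    y = m.counts.astype(float)
    if offsets is None:
        offsets = np.log(m.library_sizes())
    offsets = np.asarray(offsets, dtype=float)
    group_lists = [np.arange(m.n_samples)]
    keep = np.nonzero(y.sum(axis=1) > 0)[0]
    if keep.size == 0:
        raise ValueError("all genes are zero")
    if subset and keep.size > subset:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(keep, size=subset, replace=False))
    return _maximize_common_apl(y[keep], offsets, group_lists)


def estimate_tagwise_dispersion(
    m: CountMatrix,
    design: GroupDesign,
    offsets: np.ndarray | None = None,
    common_phi: float | None = None,
    prior_df: float = 10.0,
) -> np.ndarray:
    """Per-gene dispersions shrunk towards the common value.

    Each gene maximizes APL_g(phi) + w * APL_shared(phi), where
    APL_shared is the across-gene mean APL and w = prior_df / residual
    degrees of freedom.  prior_df -> infinity recovers the common value
    for every gene; prior_df = 0 gives unshrunk gene-wise estimates.
    Maximization is over the dispersion grid with parabolic refinement
    in log-phi.
    """
    if prior_df < 0:
        raise ValueError("prior_df must be non-negative")
    y, offsets, group_lists = _prepare(m, design, offsets)
    df_resid = y.shape[1] - len(group_lists)
    if df_resid < 1:
        raise ValueError("tagwise estimation requires replicates")
    w = prior_df / df_resid

    grid = _PHI_GRID
    apl_mat = np.column_stack([_apl(y, offsets, group_lists, p) for p in grid])
    shared = apl_mat.mean(axis=0)
    objective = apl_mat + w * shared[None, :]
    return _argmax_parabolic(objective, grid)


def _argmax_parabolic(objective: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Per-row argmax over a log-spaced grid with parabolic interpolation."""
    logg = np.log(grid)
    i = np.argmax(objective, axis=1)
    i = np.clip(i, 1, grid.size - 2)
    rows = np.arange(objective.shape[0])
    y0, y1, y2 = objective[rows, i - 1], objective[rows, i], objective[rows, i + 1]
    x0, x1, x2 = logg[i - 1], logg[i], logg[i + 1]
    denom = (y0 - y1) * (x1 - x2) - (y1 - y2) * (x0 - x1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = 0.5 * (
            (y0 - y1) * (x1 * x1 - x2 * x2) - (y1 - y2) * (x0 * x0 - x1 * x1)
        ) / np.where(denom == 0, np.nan, denom)
    # wrong-curvature or flat rows fall back to the grid point
    bad = ~np.isfinite(vertex) | (vertex < x0) | (vertex > x2)
    vertex = np.where(bad, x1, vertex)
    # rows whose raw argmax sat on the boundary keep the boundary value
    raw_i = np.argmax(objective, axis=1)
    vertex = np.where(raw_i == 0, logg[0], vertex)
    vertex = np.where(raw_i == grid.size - 1, logg[-1], vertex)
    return np.exp(vertex)


def estimate_dispersions(
    m: CountMatrix,
    design: GroupDesign,
    offsets: np.ndarray | None = None,
    prior_df: float = 10.0,
    seed: int = 0,
) -> DispersionEstimates:
    """Common + tagwise estimation, or blind when there are no replicates."""
    if m.n_samples - design.n_groups >= 1:
        common = estimate_common_dispersion(m, design, offsets, seed=seed)
        tagwise = estimate_tagwise_dispersion(m, design, offsets, common, prior_df)
        return DispersionEstimates(common, tagwise, prior_df, "replicated")
    common = estimate_blind_dispersion(m, offsets, seed=seed)
    return DispersionEstimates(common, np.full(m.n_genes, common), prior_df, "blind")


def fit_gene_nb(
    counts_g: np.ndarray,
    offsets: np.ndarray,
    groups: GroupDesign | np.ndarray,
    phi: float,
    model: str = "full",
) -> tuple[np.ndarray, float]:
    """Fit the full (one mean per group) or null (one mean) NB model for
    a single gene; returns (fitted means per sample, log-likelihood)."""
    y = np.asarray(counts_g, dtype=float)[None, :]
    offsets = np.asarray(offsets, dtype=float)
    if model == "null":
        group_lists = [np.arange(y.shape[1])]
    else:
        if isinstance(groups, GroupDesign):
            raise TypeError("pass a group-index array for single-gene fits")
        gidx = np.asarray(groups)
        group_lists = _group_index_lists(gidx, int(gidx.max()) + 1)
    _, mu = _fit_oneway(y, offsets, group_lists, float(phi))
    ll = nb_loglik(y, mu, float(phi))
    return mu[0], float(ll[0])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def lrt_test(
    m: CountMatrix,
    design: GroupDesign,
    norm: NormalizationResult | np.ndarray,
    disp: DispersionEstimates,
) -> DEResult:
    """ANOVA-like NB-GLM likelihood-ratio test for every gene.

    LR = 2*(loglik_full - loglik_null) against chi-square with G - 1
    degrees of freedom; q-values by Benjamini–Hochberg; ranks ascend in
    p with ties broken by descending LR then input order.
    """
    offsets = norm.offsets() if isinstance(norm, NormalizationResult) else np.asarray(norm)
    y, offsets, group_lists = _prepare(m, design, offsets)
    n_genes = y.shape[0]
    tested = y.sum(axis=1) > 0

    phi = np.atleast_1d(np.asarray(disp.tagwise_phi, dtype=float))
    if phi.size == 1:
        phi = np.full(n_genes, float(phi[0]))
    if phi.size != n_genes:
        raise ValueError("tagwise_phi length must match number of genes")

    beta_full, mu_full = _fit_oneway(y, offsets, group_lists, phi)
    _, mu_null = _fit_oneway(y, offsets, [np.arange(y.shape[1])], phi)
    ll_full = nb_loglik(y, mu_full, phi)
    ll_null = nb_loglik(y, mu_null, phi)
    lr = 2.0 * (ll_full - ll_null)
    lr = np.where(tested, np.maximum(lr, 0.0), 0.0)

    df = design.n_groups - 1
    p = np.ones(n_genes)
    p[tested] = chi2.sf(lr[tested], df)
    q = np.ones(n_genes)
    q[tested] = bh_adjust(p[tested])

    rank = _rank_results(p, lr, tested)
    # normalized group means: fitted mean at the average effective depth
    scale = np.exp(np.mean(offsets))
    group_means = np.exp(beta_full) * scale
    return DEResult(
        gene_ids=m.gene_ids,
        lr_stat=lr,
        p_value=p,
        q_value=q,
        rank=rank,
        group_means=group_means,
        group_labels=design.group_order,
        tested=tested,
    )


def _rank_results(p: np.ndarray, lr: np.ndarray, tested: np.ndarray) -> np.ndarray:
    """1-based ranks: ascending p, ties by descending LR then input
    order; untested genes follow all tested genes in input order."""
    n = p.size
    # lexsort uses the last key as primary: tested first, then p ascending,
    # then LR descending, then input order
    order_keys = np.lexsort((np.arange(n), -lr, p, ~tested))
    rank = np.empty(n, dtype=np.int64)
    rank[order_keys] = np.arange(1, n + 1)
    return rank


def run_nb_test(
    m: CountMatrix,
    design: GroupDesign,
    norm: NormalizationResult,
    prior_df: float = 10.0,
    seed: int = 0,
) -> DEResult:
    """Dispersion estimation followed by the LRT, choosing replicated or
    blind mode from the design's residual degrees of freedom."""
    offsets = norm.offsets()
    disp = estimate_dispersions(m, design, offsets, prior_df=prior_df, seed=seed)
    return lrt_test(m, design, norm, disp)
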