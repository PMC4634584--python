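"""Multi-group negative-binomial count simulator with known DEG truth.

Counts are drawn gene by gene from a negative-binomial model with
variance V = mu + phi * mu**2.  Each gene takes its (mu, phi) pair from a
parameter pool emulating the joint empirical distribution seen in real
bulk RNA-seq (heavy-tailed means, dispersion decreasing with the mean).
A configurable fraction of genes (P_DEG) are differentially expressed:
each DEG is up-regulated in exactly one group, chosen according to a
proportion vector (P_G1, ..., P_GG), by multiplying its mean in that
group by a fold change (fixed, default four-fold, or 1.2 + Gamma draws).

Because the pool pair is drawn before the fold-change multiplication,
the marginal count distribution of DEGs matches that of non-DEGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from deges.core import CountMatrix, GroupDesign


@dataclass(frozen=True)
class NBParamPool:
    """Pool of per-gene NB (mean, dispersion) pairs sampled with replacement."""

    mu: np.ndarray
    phi: np.ndarray
    source_tag: str = "synthetic"

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        if mu.size == 0:
            raise ValueError("empty parameter pool")
        if mu.shape != phi.shape:
            raise ValueError("mu and phi must have equal length")
        if np.any(mu <= 0):
            raise ValueError("all pool means must be positive")
        if np.any(phi < 0):
            raise ValueError("all pool dispersions must be non-negative")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "phi", phi)

    def __len__(self) -> int:
        return self.mu.size


@dataclass(frozen=True)
class FoldChangeSpec:
    """Distribution of DEG fold changes.

    ``fixed`` gives every DEG the same ratio (default 4.0).
    ``gamma_shifted`` draws ``offset + Gamma(shape, scale)`` — with the
    defaults 1.2 + Gamma(2.0, 0.5), mean fold change 2.2.
    """

    kind: str = "fixed"
    fixed_value: float = 4.0
    offset: float = 1.2
    shape: float = 2.0
    scale: float = 0.5

    def __post_init__(self):
        if self.kind not in ("fixed", "gamma_shifted"):
            raise ValueError(f"unknown fold-change kind {self.kind!r}")
        if self.fixed_value <= 1:
            raise ValueError("fixed fold change must exceed 1")
        if self.offset < 1:
            raise ValueError("gamma offset must be >= 1")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulated dataset.

    Defaults follow the standard three-group benchmark: 10,000 genes,
    four-fold DE, equal DEG proportions across groups.
    """

    n_gene: int = 10000
    p_deg: float = 0.05
    group_sizes: tuple[int, ...] = (3, 3, 3)
    deg_proportions: tuple[float, ...] = None  # type: ignore[assignment]
    fold_change: FoldChangeSpec = field(default_factory=FoldChangeSpec)
    pool: NBParamPool | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_gene < 1:
            raise ValueError("n_gene must be >= 1")
        if not (0 <= self.p_deg < 1):
            raise ValueError("p_deg must lie in [0, 1)")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("all group sizes must be >= 1")
        props = self.deg_proportions
        if props is None:
            g = len(self.group_sizes)
            props = tuple(1.0 / g for _ in range(g))
        props = tuple(float(p) for p in props)
        if len(props) != len(self.group_sizes):
            raise ValueError("deg_proportions length must match number of groups")
        if abs(sum(props) - 1.0) > 1e-12:
            raise ValueError("deg_proportions must sum to 1")
        if any(p < 0 for p in props):
            raise ValueError("deg_proportions must be non-negative")
        object.__setattr__(self, "deg_proportions", props)
        object.__setattr__(self, "group_sizes", tuple(int(n) for n in self.group_sizes))

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def n_deg(self) -> int:
        return int(round(self.n_gene * self.p_deg))

    def group_labels(self) -> tuple[str, ...]:
        return tuple(f"G{k + 1}" for k in range(self.n_groups))


@dataclass(frozen=True)
class SimTruth:
    """Per-gene ground truth emitted alongside simulated counts."""

    is_deg: np.ndarray
    deg_group: np.ndarray  # group label per gene, "" for non-DEGs
    fold_change: np.ndarray  # 1.0 for non-DEGs

    def to_frame(self, gene_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "is_deg": self.is_deg.astype(int),
                "deg_group": self.deg_group,
                "fold_change": self.fold_change,
            }
        )


def generate_default_pool(n: int, seed: int) -> NBParamPool:
    """Synthetic NB parameter pool emulating bulk RNA-seq marginals.

    Means are log-normal (median ~60, spanning roughly 1 to 1e4);
    dispersions follow a decreasing power-law trend in the mean with
    log-normal scatter, clipped to [0.005, 1.0].  Deterministic in
    ``seed``.
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(np.log(60.0), 1.5, size=n))
    mu = np.clip(mu, 1.0, 5e4)
    # decreasing dispersion-mean trend: phi ~ 0.15 at mu = 60
    trend = 0.15 * (mu / 60.0) ** -0.3
    phi = trend * np.exp(rng.normal(0.0, 0.5, size=n))
    phi = np.clip(phi, 0.005, 1.0)
    return NBParamPool(mu, phi, source_tag=f"synthetic(seed={seed})")


def load_pool(path: str | Path) -> NBParamPool:
    """Load an external (mu, phi) pool from a two-column TSV."""
    df = pd.read_csv(Path(path), sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: pool file needs two columns (mu, phi)")
    mu = df.iloc[:, 0].to_numpy(dtype=float)
    phi = df.iloc[:, 1].to_numpy(dtype=float)
    return NBParamPool(mu, phi, source_tag=str(path))


def write_pool(pool: NBParamPool, path: str | Path) -> None:
    pd.DataFrame({"mu": pool.mu, "phi": pool.phi}).to_csv(Path(path), sep="\t", index=False)


def draw_fold_changes(
    spec: FoldChangeSpec, n_deg: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample fold changes for ``n_deg`` DEGs according to ``spec``."""
    if n_deg < 0:
        raise ValueError("n_deg must be >= 0")
    if spec.kind == "fixed":
        return np.full(n_deg, spec.fixed_value, dtype=float)
    return spec.offset + rng.gamma(spec.shape, spec.scale, size=n_deg)


def _largest_remainder(total: int, proportions: Sequence[float]) -> np.ndarray:
    """Integer apportionment of ``total`` by largest remainder."""
    props = np.asarray(proportions, dtype=float)
    raw = total * props
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def assign_truth(config: SimulationConfig, rng: np.random.Generator) -> SimTruth:
    """Flag DEGs, assign up-regulated groups, and attach fold changes.

    Exactly ``round(n_gene * p_deg)`` genes are flagged — the first rows
    of the matrix — and partitioned among groups by largest-remainder
    apportionment of the DEG-proportion vector.
    """
    n_deg = config.n_deg
    labels = config.group_labels()
    per_group = _largest_remainder(n_deg, config.deg_proportions)
    is_deg = np.zeros(config.n_gene, dtype=bool)
    is_deg[:n_deg] = True
    deg_group = np.full(config.n_gene, "", dtype=object)
    start = 0
    for k, cnt in enumerate(per_group):
        deg_group[start : start + cnt] = labels[k]
        start += cnt
    fold = np.ones(config.n_gene, dtype=float)
    fold[:n_deg] = draw_fold_changes(config.fold_change, n_deg, rng)
    return SimTruth(is_deg, np.asarray(deg_group), fold)


def nb_draw(
    mean: np.ndarray, phi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw NB counts with variance mean + phi * mean**2.

    Uses the gamma–Poisson mixture (gamma shape 1/phi, scale phi*mean) so
    the quadratic mean–variance relation holds exactly; phi = 0 cells
    short-circuit to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if np.any(nb):
        lam = rng.gamma(1.0 / phi[nb], phi[nb] * mean[nb])
        out[nb] = rng.poisson(lam)
    return out


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, SimTruth, GroupDesign]:
    """Generate one multi-group dataset with its truth and design.

    Per gene a pool pair (mu, phi) is drawn with replacement; the
    expected count of a sample is mu times the gene's fold change when
    the sample belongs to the gene's up-regulated group, else mu; each
    count is an independent NB draw.  Deterministic in ``config.seed``.
    """
    pool = config.pool if config.pool is not None else generate_default_pool(
        50000, seed=config.seed + 104729
    )
    rng = np.random.default_rng(config.seed)
    truth = assign_truth(config, rng)
    idx = rng.integers(0, len(pool), size=config.n_gene)
    mu = pool.mu[idx]
    phi = pool.phi[idx]

    labels = config.group_labels()
    sample_ids: list[str] = []
    sample_group_idx: list[int] = []
    for k, (label, nrep) in enumerate(zip(labels, config.group_sizes)):
        for r in range(nrep):
            sample_ids.append(f"{label}_rep{r + 1}")
            sample_group_idx.append(k)
    group_idx = np.asarray(sample_group_idx)

    # per-gene, per-sample expected counts
    means = np.repeat(mu[:, None], len(sample_ids), axis=1)
    label_to_k = {lab: k for k, lab in enumerate(labels)}
    deg_rows = np.nonzero(truth.is_deg)[0]
    if deg_rows.size:
        deg_k = np.array([label_to_k[truth.deg_group[g]] for g in deg_rows])
        up = group_idx[None, :] == deg_k[:, None]
        means[deg_rows] = np.where(up, means[deg_rows] * truth.fold_change[deg_rows, None], means[deg_rows])

    counts = nb_draw(means, phi[:, None], rng)
    gene_ids = [f"gene_{i + 1}" for i in range(config.n_gene)]
    m = CountMatrix(gene_ids, sample_ids, counts)
    design = GroupDesign(dict(zip(sample_ids, (labels[k] for k in group_idx))), labels)
    return m, truth, design
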