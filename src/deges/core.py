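"""Shared data model and file I/O for count matrices and group designs.

Count matrices are genes × samples tables of non-negative integers, read
and written as plain TSV: first column ``gene_id``, header row of sample
identifiers.  Group designs map each sample to a group label and are
stored as a two-column TSV (``sample_id``, ``group``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("deges")

_GENE_ID_HEADER = "gene_id"


class CountMatrixFormatError(ValueError):
    """Raised when a count table violates the expected TSV layout."""


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene × sample count matrix with identifiers.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer read counts.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __init__(self, gene_ids: Sequence[str], sample_ids: Sequence[str], counts: np.ndarray):
        gene_ids = tuple(str(g) for g in gene_ids)
        sample_ids = tuple(str(s) for s in sample_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise CountMatrixFormatError("duplicate gene identifiers")
        if len(set(sample_ids)) != len(sample_ids):
            raise CountMatrixFormatError("duplicate sample identifiers")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.argwhere((counts != np.floor(counts)) | ~np.isfinite(counts))
                g, s = bad[0]
                raise ValueError(
                    f"non-integer count at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            g, s = np.argwhere(counts < 0)[0]
            raise ValueError(f"negative count at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Raw per-sample totals (column sums) as float."""
        return self.counts.sum(axis=0).astype(float)

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask, dtype=bool)
        ids = tuple(g for g, m in zip(self.gene_ids, mask) if m)
        return CountMatrix(ids, self.sample_ids, self.counts[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.gene_ids, sample_ids, self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.sample_ids))
        df.insert(0, _GENE_ID_HEADER, list(self.gene_ids))
        return df


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to experimental groups.

    ``group_order`` fixes the order in which group means, DEG proportions
    and per-group results are reported (e.g. G1, G2, G3).
    """

    sample_to_group: Mapping[str, str]
    group_order: tuple[str, ...]

    def __init__(self, sample_to_group: Mapping[str, str], group_order: Sequence[str] | None = None):
        sample_to_group = dict(sample_to_group)
        if group_order is None:
            seen: list[str] = []
            for g in sample_to_group.values():
                if g not in seen:
                    seen.append(g)
            group_order = tuple(seen)
        else:
            group_order = tuple(group_order)
        if len(set(group_order)) != len(group_order):
            raise ValueError("duplicate group labels in group_order")
        present = set(sample_to_group.values())
        missing = [g for g in group_order if g not in present]
        if missing:
            raise ValueError(f"groups with no samples: {missing}")
        extra = present - set(group_order)
        if extra:
            raise ValueError(f"samples assigned to unknown groups: {sorted(extra)}")
        if len(group_order) < 2:
            raise ValueError("need at least 2 groups")
        object.__setattr__(self, "sample_to_group", sample_to_group)
        object.__setattr__(self, "group_order", group_order)

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in self.group_order}
        for g in self.sample_to_group.values():
            sizes[g] += 1
        return sizes

    def group_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Integer group index (position in ``group_order``) per sample.

        Raises if a sample is missing from the design.
        """
        lookup = {g: k for k, g in enumerate(self.group_order)}
        idx = np.empty(len(sample_ids), dtype=np.intp)
        for j, s in enumerate(sample_ids):
            if s not in self.sample_to_group:
                raise ValueError(f"sample {s!r} missing from design")
            idx[j] = lookup[self.sample_to_group[s]]
        return idx


@dataclass(frozen=True)
class RunConfig:
    """Plumbing for a reproducible run: seed, logging, output location."""

    seed: int = 0
    log_level: str = "INFO"
    output_dir: Path = field(default_factory=lambda: Path("."))

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Named substream: ``seed + stream`` so trials are individually
        reproducible."""
        return np.random.default_rng(self.seed + stream)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene × sample count matrix from TSV.

    The first column holds gene identifiers; the header row holds sample
    identifiers.  All body cells must parse as non-negative integers.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise CountMatrixFormatError(f"{path}: duplicated sample identifier in header")
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] != len(header):
        raise CountMatrixFormatError(f"{path}: ragged table")
    df.columns = header
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(gene_ids)) != len(gene_ids):
        raise CountMatrixFormatError(f"{path}: duplicated gene identifier")
    body = df.iloc[:, 1:]
    counts = np.zeros((len(gene_ids), len(sample_ids)), dtype=np.int64)
    for j, col in enumerate(body.columns):
        values = body[col].to_numpy()
        try:
            as_float = np.asarray(values, dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric count in column {col!r}") from exc
        if np.any(~np.isfinite(as_float)) or np.any(as_float != np.floor(as_float)):
            bad = int(np.argmax((as_float != np.floor(as_float)) | ~np.isfinite(as_float)))
            raise ValueError(
                f"{path}: non-integer count at gene {gene_ids[bad]!r}, sample {col!r}"
            )
        if np.any(as_float < 0):
            bad = int(np.argmax(as_float < 0))
            raise ValueError(f"{path}: negative count at gene {gene_ids[bad]!r}, sample {col!r}")
        counts[:, j] = as_float.astype(np.int64)
    return CountMatrix(gene_ids, sample_ids, counts)


def write_counts(m: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV (inverse of :func:`read_counts`)."""
    m.to_frame().to_csv(Path(path), sep="\t", index=False)


def read_design(path: str | Path, group_order: Sequence[str] | None = None) -> GroupDesign:
    """Read a two-column (sample_id, group) design TSV."""
    df = pd.read_csv(Path(path), sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise CountMatrixFormatError(f"{path}: design needs two columns (sample_id, group)")
    samples = df.iloc[:, 0].tolist()
    if len(set(samples)) != len(samples):
        raise CountMatrixFormatError(f"{path}: duplicated sample in design")
    mapping = dict(zip(samples, df.iloc[:, 1].tolist()))
    return GroupDesign(mapping, group_order)


def write_design(design: GroupDesign, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample_id": list(design.sample_to_group), "group": list(design.sample_to_group.values())}
    )
    df.to_csv(Path(path), sep="\t", index=False)


def collapse_technical_replicates(
    m: CountMatrix, replicate_map: Mapping[str, str]
) -> CountMatrix:
    """Sum columns of technical replicates into one column per library.

    Every sample of ``m`` must appear in ``replicate_map``; the collapsed
    matrix has one column per distinct ``collapsed_id``, ordered by first
    appearance, and each cell is the integer sum of its member columns.
    Total counts are conserved.
    """
    missing = [s for s in m.sample_ids if s not in replicate_map]
    if missing:
        raise ValueError(f"samples missing from replicate map: {missing}")
    collapsed_ids: list[str] = []
    members: dict[str, list[int]] = {}
    for j, s in enumerate(m.sample_ids):
        cid = replicate_map[s]
        if cid not in members:
            members[cid] = []
            collapsed_ids.append(cid)
        members[cid].append(j)
    out = np.zeros((m.n_genes, len(collapsed_ids)), dtype=np.int64)
    for k, cid in enumerate(collapsed_ids):
        out[:, k] = m.counts[:, members[cid]].sum(axis=1)
    return CountMatrix(m.gene_ids, collapsed_ids, out)
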