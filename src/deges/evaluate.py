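"""Evaluation of ranked gene lists and DEG sets.

AUC against simulation truth is the headline metric: the area under the
ROC curve of the p-value ranking, equal to the normalized Mann-Whitney
U statistic with midrank tie handling.  Reproducibility utilities
(top-k overlap / POG, Jaccard, Spearman list similarity) and the
multi-condition study harness that averages paired AUCs over trials
complete the kit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from deges.pipeline import resolve_pipeline_name, run_deges
from deges.simulate import SimTruth, SimulationConfig, simulate_counts


@dataclass(frozen=True)
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class StudyTable:
    """Mean AUC per (condition, pipeline) cell over paired trials."""

    frame: pd.DataFrame
    n_trials: int
    base_seed: int


def auc_from_ranking(pvalues: np.ndarray, truth: SimTruth | np.ndarray) -> ROCResult:
    """AUC of the ascending-p ranking against the DEG truth.

    Computed from ranks only: with midranks R over ascending p, AUC =
    (sum of ranks of negatives - n_neg*(n_neg+1)/2) / (n_pos * n_neg),
    i.e. the probability that a random DEG precedes a random non-DEG,
    counting ties as half.  Equals the trapezoidal area under the ROC
    curve.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    is_deg = truth.is_deg if isinstance(truth, SimTruth) else np.asarray(truth, dtype=bool)
    if pvalues.shape != is_deg.shape:
        raise ValueError("pvalues and truth must have equal length")
    n_pos = int(is_deg.sum())
    n_neg = int((~is_deg).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one DEG and one non-DEG")
    ranks = rankdata(pvalues)
    auc = (ranks[~is_deg].sum() - n_neg * (n_neg + 1) / 2.0) / (n_pos * n_neg)
    return ROCResult(float(auc), n_pos, n_neg)


def top_overlap(
    rankings: Sequence[Sequence[str]], k: int
) -> tuple[int, float]:
    """Common-gene count and POG among the top-k of several ranked lists.

    All lists must range over the same gene universe; POG is
    |intersection of top-k| / k.
    """
    if len(rankings) < 2:
        raise ValueError("need at least 2 ranked lists")
    universes = [frozenset(r) for r in rankings]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("ranked lists must cover the same gene universe")
    if k > len(universes[0]):
        raise ValueError("k exceeds the universe size")
    common = set(list(rankings[0])[:k])
    for r in rankings[1:]:
        common &= set(list(r)[:k])
    return len(common), len(common) / k


def pog_curve(rankings: Sequence[Sequence[str]], ks: Sequence[int]) -> pd.DataFrame:
    rows = [(k, *top_overlap(rankings, k)) for k in ks]
    return pd.DataFrame(rows, columns=["k", "n_common", "pog"])


def jaccard(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets give 1 by convention."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def spearman_list_similarity(rank_a: np.ndarray, rank_b: np.ndarray) -> float:
    """Spearman correlation between two rankings of the same universe."""
    rank_a = np.asarray(rank_a, dtype=float)
    rank_b = np.asarray(rank_b, dtype=float)
    if rank_a.shape != rank_b.shape:
        raise ValueError("rankings must have equal length")
    if np.unique(rank_a).size < 2 or np.unique(rank_b).size < 2:
        raise ValueError("Spearman similarity undefined for a constant ranking")
    rho = spearmanr(rank_a, rank_b).statistic
    return float(rho)


def split_replicates(
    sample_ids: Sequence[str], design, chunks: Sequence[Sequence[int]]
) -> list[list[str]]:
    """Column-selection utility for reproducibility subsets.

    ``chunks`` lists, per subset, the 1-based replicate numbers to keep
    within each group (e.g. [(1, 2), (3, 4), (5, 6)]).
    """
    by_group: dict[str, list[str]] = {g: [] for g in design.group_order}
    for s in sample_ids:
        by_group[design.sample_to_group[s]].append(s)
    out = []
    for chunk in chunks:
        subset: list[str] = []
        for g in design.group_order:
            for r in chunk:
                subset.append(by_group[g][r - 1])
        out.append(subset)
    return out


def run_study(
    conditions: Sequence[SimulationConfig],
    pipelines: Sequence[str],
    n_trials: int,
    base_seed: int = 0,
) -> StudyTable:
    """Average AUC of each pipeline under each simulation condition.

    Per (condition, trial) one dataset is simulated with seed
    ``base_seed + trial`` and every pipeline is evaluated on that same
    dataset, so pipeline comparisons within a row are paired.  Fully
    deterministic in ``base_seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    specs = {code: resolve_pipeline_name(code) for code in pipelines}
    rows = []
    for ci, cond in enumerate(conditions):
        aucs = {code: [] for code in pipelines}
        for t in range(n_trials):
            trial_cfg = replace(cond, seed=base_seed + 10000 * ci + t)
            m, truth, design = simulate_counts(trial_cfg)
            for code, spec in specs.items():
                rec = run_deges(m, design, spec, seed=trial_cfg.seed)
                res = auc_from_ranking(rec.final_result.p_value, truth)
                aucs[code].append(res.auc)
        for code in pipelines:
            rows.append(
                {
                    "pipeline": code,
                    "p_deg": cond.p_deg,
                    "deg_proportions": "/".join(f"{p:g}" for p in cond.deg_proportions),
                    "n_rep": cond.group_sizes[0],
                    "mean_auc_percent": 100.0 * float(np.mean(aucs[code])),
                    "n_trials": n_trials,
                    "seed": base_seed,
                }
            )
    return StudyTable(pd.DataFrame(rows), n_trials, base_seed)
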