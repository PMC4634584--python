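"""The iterative DEG-elimination (DEGES) pipelines X-(Y-X)n-Z.

Normalization factors computed on all genes are distorted when the
proportions of DEGs up-regulated in individual groups are unequal.
DEGES alleviates this: normalize (X), flag potential DEGs with a test
(Y), recompute the factors on the unflagged genes only, and iterate;
the final DEG identification test (Z) then runs with the cleaned-up
factors.  Pipelines are named by letter codes such as ``EEE-E``
(TMM-based X with the NB-LRT as Y and Z, three iterations) or ``E-E``
(no iteration, the plain two-step pipeline).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from deges.core import CountMatrix, GroupDesign
from deges.glm import DEResult, estimate_dispersions, lrt_test
from deges.norm import NormalizationResult, normalization_factors

logger = logging.getLogger("deges")

#: letter -> normalization method used for the X step
_LETTER_NORM = {"E": "tmm", "D": "medianratio", "S": "medianratio"}
_LETTERS = set(_LETTER_NORM)


@dataclass(frozen=True)
class PipelineSpec:
    """A DEGES recipe: X/Y/Z method choices, iterations and flagging rules.

    ``n_iterations = 0`` reduces to the plain X-Z pipeline.  Potential
    DEGs are flagged at BH FDR ``flag_fdr``; if fewer than
    ``floor_pdeg`` of the genes are flagged, the top-ranked
    ``floor_pdeg`` fraction is removed instead, so step 3 always works
    on a list with at least that share of candidates excluded.
    """

    x_method: str = "tmm"
    y_method: str = "nbtest"
    z_method: str = "nbtest"
    n_iterations: int = 3
    floor_pdeg: float = 0.05
    flag_fdr: float = 0.10
    prior_df: float = 10.0

    def __post_init__(self):
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if not (0 < self.floor_pdeg < 1) or not (0 < self.flag_fdr < 1):
            raise ValueError("floor_pdeg and flag_fdr must lie in (0, 1)")


@dataclass
class IterationRecord:
    factors: np.ndarray
    estimated_pdeg: float
    n_flagged: int
    flag_source: str  # "fdr" or "floor"


@dataclass
class DegesRunRecord:
    """Everything a DEGES run produced, step by step."""

    spec: PipelineSpec
    initial_factors: NormalizationResult
    iterations: list[IterationRecord] = field(default_factory=list)
    final_norm: NormalizationResult | None = None
    final_result: DEResult | None = None


def resolve_pipeline_name(code: str) -> PipelineSpec:
    """Parse a letter code like ``EEE-E``, ``DED-S`` or ``E-E``.

    Grammar: ``XYX-Z`` (three letters, iterated with n = 3) or ``X-Z``
    (single letter, no iteration), letters in {E, D, S}.  E maps to TMM
    normalization, D and S to median-of-ratios; Y and Z are the NB-LRT
    (blind dispersion mode engages automatically for designs without
    replicates).
    """
    parts = code.split("-")
    if len(parts) != 2 or len(parts[1]) != 1 or len(parts[0]) not in (1, 3):
        raise ValueError(
            f"malformed pipeline code {code!r}: expected XYX-Z or X-Z with "
            f"letters in {sorted(_LETTERS)}"
        )
    head, z = parts
    for ch in head + z:
        if ch not in _LETTERS:
            raise ValueError(
                f"unknown letter {ch!r} in pipeline code {code!r}; "
                f"supported letters: {sorted(_LETTERS)}"
            )
    if len(head) == 3:
        x, y = head[0], head[1]
        if head[2] != head[0]:
            raise ValueError(
                f"malformed pipeline code {code!r}: the first and third "
                "letters (the X steps) must match"
            )
        n = 3
    else:
        x, y = head[0], head[0]
        n = 0
    return PipelineSpec(
        x_method=_LETTER_NORM[x],
        y_method="nbtest",
        z_method="nbtest",
        n_iterations=n,
    )


def flag_potential_degs(
    de: DEResult, flag_fdr: float, floor_pdeg: float
) -> tuple[np.ndarray, float, str]:
    """Mark genes to exclude from the next normalization round.

    Genes with q < ``flag_fdr`` are flagged; when their number falls
    below ``round(floor_pdeg * n_tested)`` the same number of top-ranked
    genes is flagged instead (``flag_source = "floor"``).  Equality at
    the boundary keeps the FDR-based mask.  The returned
    ``estimated_pdeg`` always reports the FDR-based proportion.
    """
    tested = de.tested
    n_tested = int(tested.sum())
    fdr_mask = (de.q_value < flag_fdr) & tested
    n_fdr = int(fdr_mask.sum())
    estimated_pdeg = n_fdr / n_tested if n_tested else 0.0
    floor_n = int(math.floor(floor_pdeg * n_tested + 0.5))  # round half up
    if n_fdr >= floor_n:
        return fdr_mask, estimated_pdeg, "fdr"
    floor_mask = tested & (de.rank <= floor_n)
    return floor_mask, estimated_pdeg, "floor"


def run_deges(
    m: CountMatrix, design: GroupDesign, spec: PipelineSpec, seed: int = 0
) -> DegesRunRecord:
    """Run the full X-(Y-X)n-Z pipeline.

    Step 1 computes X factors on all genes.  Each iteration runs the Y
    test with the current factors, flags potential DEGs, and recomputes
    X on the unflagged genes of the full raw matrix (no cascading
    subsetting); the resulting factors apply to all genes.  Finally Z
    tests every gene with the last factors.
    """
    norm = normalization_factors(m, spec.x_method)
    record = DegesRunRecord(spec=spec, initial_factors=norm)
    for it in range(spec.n_iterations):
        de = _run_test(m, design, norm, spec, seed)
        mask, est_pdeg, source = flag_potential_degs(de, spec.flag_fdr, spec.floor_pdeg)
        if mask.all():
            raise ValueError("all genes flagged as potential DEGs; cannot renormalize")
        norm = normalization_factors(m, spec.x_method, gene_mask=~mask)
        record.iterations.append(
            IterationRecord(norm.factors.copy(), est_pdeg, int(mask.sum()), source)
        )
        logger.info(
            "DEGES iteration %d: estimated P_DEG = %.2f%%, flagged %d genes (%s)",
            it + 1,
            100 * est_pdeg,
            int(mask.sum()),
            source,
        )
    record.final_norm = norm
    record.final_result = _run_test(m, design, norm, spec, seed)
    return record


def _run_test(
    m: CountMatrix,
    design: GroupDesign,
    norm: NormalizationResult,
    spec: PipelineSpec,
    seed: int,
) -> DEResult:
    disp = estimate_dispersions(
        m, design, norm.offsets(), prior_df=spec.prior_df, seed=seed
    )
    return lrt_test(m, design, norm, disp)
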