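"""Protein-group confidence scores from peptide posterior error probabilities.

Two scorers are provided.  ``best_pep`` takes ``-log10`` of the group's best
(lowest) peptide PEP.  ``multiply_pep`` multiplies peptide PEPs after
dividing each by a constant ``c``; peptides with PEP above ``c`` then lower
the score, which is why permissive peptide filtering hurts this scorer.  The
constant is chosen by a grid search maximizing the number of target groups
accepted at the FDR threshold.  Both scorers use each peptide's best PEP
once (peptide-level, not PSM-level).
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Iterable, Mapping

import numpy as np

from .fdr import ScoredGroup
from .groups import GroupingResult, ProteinGroup

logger = logging.getLogger(__name__)

DEFAULT_PEP_FLOOR = 1e-20


def _clamped_peps(
    group: ProteinGroup, pep_by_peptide: Mapping[str, float], floor: float
) -> list[float]:
    if not group.peptides:
        raise ValueError("cannot score a group without assigned peptides")
    peps = []
    for peptide in group.peptides:
        pep = pep_by_peptide[peptide]
        if pep <= 0:
            logger.warning("PEP %g clamped to floor %g", pep, floor)
            pep = floor
        peps.append(max(pep, floor))
    return peps


def score_best_pep(
    group: ProteinGroup,
    pep_by_peptide: Mapping[str, float],
    pep_floor: float = DEFAULT_PEP_FLOOR,
) -> float:
    """``-log10`` of the best peptide PEP in the group; larger is better."""
    return -math.log10(min(_clamped_peps(group, pep_by_peptide, pep_floor)))


def score_multiply_pep(
    group: ProteinGroup,
    pep_by_peptide: Mapping[str, float],
    divisor: float,
    pep_floor: float = DEFAULT_PEP_FLOOR,
) -> float:
    """``-log10`` of the product of peptide PEPs, each divided by ``divisor``."""
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return sum(
        math.log10(divisor) - math.log10(pep)
        for pep in _clamped_peps(group, pep_by_peptide, pep_floor)
    )


def default_divisor_grid() -> np.ndarray:
    """Logarithmic grid 10^-4 .. 10^0 in 13 steps."""
    return np.logspace(-4.0, 0.0, 13)


def optimize_pep_divisor(
    grouping: GroupingResult,
    pep_by_peptide: Mapping[str, float],
    run_fdr: Callable[[list[ScoredGroup]], list[ScoredGroup]],
    make_scored: Callable[[ProteinGroup, float], ScoredGroup],
    threshold: float = 0.01,
    grid: Iterable[float] | None = None,
    pep_floor: float = DEFAULT_PEP_FLOOR,
) -> float:
    """Grid search for the PEP divisor maximizing accepted target groups.

    ``run_fdr`` applies the configured competition and FDR estimation to a
    scored list; ``make_scored`` attaches decoy/contaminant flags.  Ties are
    resolved toward the larger divisor.
    """
    grid = list(grid) if grid is not None else list(default_divisor_grid())
    if not grid:
        raise ValueError("empty divisor grid")
    scorable = [g for g in grouping.groups if g.peptides]
    best_c = None
    best_n = -1
    for c in sorted(grid):
        scored = [
            make_scored(g, score_multiply_pep(g, pep_by_peptide, c, pep_floor))
            for g in scorable
        ]
        result = run_fdr(scored)
        n = sum(
            1
            for sg in result
            if not sg.is_decoy and not sg.is_contaminant and sg.q_value <= threshold
        )
        if n >= best_n:  # >= resolves ties toward larger c (grid is ascending)
            best_n = n
            best_c = c
    logger.info("PEP divisor grid search: c=%g (%d target groups at q<=%g)", best_c, best_n, threshold)
    return float(best_c)
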