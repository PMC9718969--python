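"""Calibration measurement: reported FDR versus observed FDR.

Observed FDR comes either from simulation ground truth (a group is false
when none of its assigned peptides was correctly detected for a protein in
the group) or from an entrapment database (a group is observed-false when
all of its leading proteins are entrapment entries, scaled up to account
for false positives hitting the original target database).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .fasta import SequenceDatabase
from .fdr import ScoredGroup, sort_groups


def _accepted_targets(
    groups: Sequence[ScoredGroup], threshold: float
) -> list[ScoredGroup]:
    return [
        sg
        for sg in groups
        if not sg.is_decoy
        and not sg.is_contaminant
        and sg.q_value is not None
        and sg.q_value <= threshold
    ]


def _is_true_group(sg: ScoredGroup, truth: Mapping[str, frozenset[str]]) -> bool:
    members = set(sg.group.member_proteins)
    return any(truth.get(p, frozenset()) & members for p in sg.group.peptides)


def empirical_fdp(
    groups: Sequence[ScoredGroup],
    truth: Mapping[str, frozenset[str]],
    threshold: float,
) -> float | None:
    """False discovery proportion among target groups at ``q <= threshold``.

    ``truth`` maps each peptide to the proteins for which it was correctly
    detected; a group counts false when no assigned peptide is correct for
    any of its member proteins.  Returns ``None`` (undefined, distinct from
    zero) when no group is accepted.
    """
    accepted = _accepted_targets(groups, threshold)
    if not accepted:
        return None
    n_false = sum(1 for sg in accepted if not _is_true_group(sg, truth))
    return n_false / len(accepted)


def groups_at_empirical_fdr(
    groups: Sequence[ScoredGroup],
    truth: Mapping[str, frozenset[str]],
    threshold: float = 0.01,
) -> int:
    """Largest score-sorted prefix of target groups with observed FDP <= threshold."""
    targets = [
        sg for sg in sort_groups(list(groups)) if not sg.is_decoy and not sg.is_contaminant
    ]
    best = 0
    n_false = 0
    for k, sg in enumerate(targets, start=1):
        if not _is_true_group(sg, truth):
            n_false += 1
        if n_false / k <= threshold:
            best = k
    return best


def entrapment_fdr(
    groups: Sequence[ScoredGroup],
    db: SequenceDatabase,
    threshold: float,
    corrected: bool = True,
) -> float:
    """Entrapment-based FDR among accepted target-side groups.

    Groups whose leading proteins are all entrapment entries are observed
    false; mixed original/entrapment groups conservatively count as not
    observed false.  With ``corrected`` the count is scaled by
    ``1 + n_targets / n_entrapment`` to account for false positives that hit
    the original target database.
    """
    n_entrapment = len(db.entries("entrapment"))
    if n_entrapment == 0:
        raise ValueError("database contains no entrapment entries")
    accepted = _accepted_targets(groups, threshold)
    if not accepted:
        return 0.0
    observed_false = sum(
        1
        for sg in accepted
        if all(
            db.entry_class(a) == "entrapment"
            for a in sg.group.leading_proteins
            if a in db
        )
        and sg.group.leading_proteins
    )
    correction = 1.0 + len(db.entries("target")) / n_entrapment if corrected else 1.0
    return observed_false * correction / len(accepted)


def calibration_curve(
    groups: Sequence[ScoredGroup],
    truth: Mapping[str, frozenset[str]],
    thresholds: Iterable[float],
    point: float = 0.01,
) -> tuple[list[tuple[float, float | None]], float | None]:
    """Observed FDP at each reported-FDR threshold, plus the ratio at ``point``.

    Returns ``(curve, ratio)`` where ``curve`` is a list of
    ``(reported, observed)`` pairs and ``ratio`` is observed/reported at the
    named point (``None`` when undefined).
    """
    curve = [(t, empirical_fdp(groups, truth, t)) for t in thresholds]
    observed_at_point = empirical_fdp(groups, truth, point)
    ratio = None if observed_at_point is None else observed_at_point / point
    return curve, ratio
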