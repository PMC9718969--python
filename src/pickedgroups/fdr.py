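"""Target-decoy competition and protein group-level FDR estimation.

Three competition strategies are provided.  *Classic* passes every group to
the FDR calculation.  *Picked* competes each target protein against its
reversed decoy counterpart and keeps the higher-scoring one.  *Picked group*
generalizes this to protein groups: walking down the score-sorted list, a
group is eliminated when a counterpart of one of its leading proteins was
already seen among the leading proteins of a retained, higher-scoring group.
On singleton groups the picked-group competition reduces exactly to the
picked competition.

The group-level FDR at a group is the ratio of decoy to target groups with
at least its score; q-values are the usual running minimum over worse-scoring
groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .fasta import DECOY_PREFIX
from .groups import ProteinGroup


@dataclass
class ScoredGroup:
    """A protein group with its identification score and FDR estimates."""

    group: ProteinGroup
    score: float
    is_decoy: bool
    is_contaminant: bool = False
    fdr: float | None = None
    q_value: float | None = None


def counterpart_accession(accession: str, decoy_prefix: str = DECOY_PREFIX) -> str:
    if accession.startswith(decoy_prefix):
        return accession[len(decoy_prefix):]
    return decoy_prefix + accession


def sort_key(sg: ScoredGroup) -> tuple:
    # descending score; accession tiebreak for determinism
    return (-sg.score, sg.group.leading_proteins[0])


def sort_groups(groups: list[ScoredGroup]) -> list[ScoredGroup]:
    return sorted(groups, key=sort_key)


def _check_sorted(groups: list[ScoredGroup]) -> None:
    scores = [sg.score for sg in groups]
    if any(a < b for a, b in zip(scores, scores[1:])):
        raise ValueError("groups must be sorted by decreasing score")


def picked_tds(
    groups: list[ScoredGroup], decoy_prefix: str = DECOY_PREFIX
) -> list[ScoredGroup]:
    """Protein-level target-decoy competition for singleton groups.

    For each target/decoy pair with both observed, only the higher-scoring
    member is retained; score ties keep both.  Unpaired entries pass through.
    """
    for sg in groups:
        if len(sg.group.member_proteins) != 1:
            raise ValueError("picked_tds requires singleton protein groups")
    by_base: dict[str, list[ScoredGroup]] = {}
    for sg in groups:
        acc = sg.group.member_proteins[0]
        base = acc[len(decoy_prefix):] if acc.startswith(decoy_prefix) else acc
        by_base.setdefault(base, []).append(sg)
    retained = []
    for entries in by_base.values():
        best = max(sg.score for sg in entries)
        retained.extend(sg for sg in entries if sg.score == best)
    return sort_groups(retained)


def picked_group_tds(
    groups: list[ScoredGroup], decoy_prefix: str = DECOY_PREFIX
) -> list[ScoredGroup]:
    """Target-decoy competition at the protein-group level.

    Input must already be sorted by decreasing score.  Groups with equal
    scores are handled as one batch so that neither eliminates the other,
    matching the tie behaviour of the protein-level competition.
    """
    _check_sorted(groups)
    retained: list[ScoredGroup] = []
    banned: set[str] = set()  # counterparts of leading proteins of retained groups
    for _, batch_iter in itertools.groupby(groups, key=lambda sg: sg.score):
        batch = list(batch_iter)
        survivors = [
            sg for sg in batch if not (set(sg.group.leading_proteins) & banned)
        ]
        retained.extend(survivors)
        for sg in survivors:
            banned.update(
                counterpart_accession(a, decoy_prefix)
                for a in sg.group.leading_proteins
            )
    return retained


def estimate_group_fdr(
    groups: list[ScoredGroup], exclude_contaminants: bool = True
) -> list[ScoredGroup]:
    """Fill in FDR and q-value for a score-sorted group list.

    ``fdr(g) = D(g) / T(g)`` where D and T count decoy and target groups
    scoring at least as well as g (g counts itself in its own class); groups
    before the first target get infinite FDR.  q-values are the running
    minimum of FDR over the group and everything scoring worse.  Contaminant
    groups are excluded from both counts but still receive q-values.
    """
    ordered = sort_groups(groups)
    n = len(ordered)
    fdr = np.empty(n)
    cum_decoy = 0
    cum_target = 0
    i = 0
    while i < n:
        j = i
        while j < n and ordered[j].score == ordered[i].score:
            j += 1
        for sg in ordered[i:j]:
            if sg.is_contaminant and exclude_contaminants:
                continue
            if sg.is_decoy:
                cum_decoy += 1
            else:
                cum_target += 1
        fdr[i:j] = cum_decoy / cum_target if cum_target > 0 else np.inf
        i = j
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    for sg, f, qv in zip(ordered, fdr, q):
        sg.fdr = float(f)
        sg.q_value = float(qv)
    return ordered


def psm_cutoff_for_group_fdr(
    groups: list[ScoredGroup], threshold: float = 0.01
) -> float | None:
    """Lowest group score whose q-value clears ``threshold``.

    With best-PEP scoring, a group score is a monotone function of its best
    peptide's PEP, so evidence with ``-log10(PEP) >= s*`` is exactly the
    evidence strong enough to carry a group past the threshold.  Returns
    ``None`` when no group passes (callers fall back).
    """
    passing = [sg.score for sg in groups if sg.q_value is not None and sg.q_value <= threshold]
    if not passing:
        return None
    return min(passing)
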