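"""Assignment of peptides to protein groups: razor or discard.

Peptides whose proteins all fall within one group are assigned to that
group.  Peptides spanning several groups are either dropped (``discard``)
or force-assigned Occam's-razor style to the candidate group with the most
unique peptides (``razor``), ties broken by a seeded uniform draw.  Decoy
groups take part in razor competition exactly like target groups; the
symmetry is what makes decoy counts a valid model for false targets.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .groups import GroupingResult, ProteinGroup
from .psms import PeptideEvidence


def _peptide_group_ids(
    evidence: Sequence[PeptideEvidence], grouping: GroupingResult
) -> list[tuple[PeptideEvidence, list[int]]]:
    out = []
    acc_to_group = grouping.accession_to_group
    for ev in evidence:
        gids = {acc_to_group[a] for a in ev.accessions if a in acc_to_group}
        out.append((ev, sorted(gids)))
    return out


def _rebuild(
    grouping: GroupingResult,
    assigned: dict[int, set[str]],
    razor: dict[int, set[str]],
) -> GroupingResult:
    groups = [
        g.with_peptides(
            frozenset(assigned.get(i, ())), frozenset(razor.get(i, ()))
        )
        for i, g in enumerate(grouping.groups)
    ]
    return GroupingResult(groups, dict(grouping.accession_to_group))


def discard_shared(
    grouping: GroupingResult, evidence: Sequence[PeptideEvidence]
) -> GroupingResult:
    """Assign within-group peptides; drop peptides spanning several groups.

    Groups can end up with zero peptides; they receive no score downstream
    and are not reported.
    """
    assigned: dict[int, set[str]] = defaultdict(set)
    for ev, gids in _peptide_group_ids(evidence, grouping):
        if len(gids) == 1:
            assigned[gids[0]].add(ev.peptide)
    return _rebuild(grouping, assigned, {})


def assign_razor(
    grouping: GroupingResult,
    evidence: Sequence[PeptideEvidence],
    rng: np.random.Generator,
) -> GroupingResult:
    """Razor assignment of cross-group peptides.

    A shared peptide goes to the candidate group with the largest number of
    peptides unique to it (counted before any razor assignment, so the
    result does not depend on processing order).  Ties are broken by a
    uniform draw from ``rng``; an explicit generator is required so runs are
    reproducible.
    """
    if rng is None:
        raise ValueError("assign_razor requires a seeded random generator")
    with_gids = _peptide_group_ids(evidence, grouping)

    unique_counts: dict[int, int] = defaultdict(int)
    for ev, gids in with_gids:
        if len(gids) == 1:
            unique_counts[gids[0]] += 1

    assigned: dict[int, set[str]] = defaultdict(set)
    razor: dict[int, set[str]] = defaultdict(set)
    for ev, gids in with_gids:
        if not gids:
            continue
        if len(gids) == 1:
            assigned[gids[0]].add(ev.peptide)
            continue
        counts = [unique_counts[g] for g in gids]
        best = max(counts)
        tied = [g for g, c in zip(gids, counts) if c == best]
        winner = tied[0] if len(tied) == 1 else tied[rng.integers(len(tied))]
        assigned[winner].add(ev.peptide)
        razor[winner].add(ev.peptide)
    return _rebuild(grouping, assigned, razor)
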