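"""Protein grouping strategies: none, subset, and rescued subset.

Subset grouping merges a protein into another protein's group when its
observed peptides are a subset of the other's; proteins with identical
observed peptide sets are merged and co-leading.  Rescued subset grouping
repeats the grouping after removing evidence below the score equivalent to
a 1% group-level FDR, so that low-confidence peptides cannot split a group,
then re-appends first-pass groups whose proteins vanished entirely.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .assignment import discard_shared
from .fasta import DECOY_PREFIX
from .fdr import ScoredGroup, estimate_group_fdr, picked_group_tds, psm_cutoff_for_group_fdr, sort_groups
from .groups import GroupingResult, ProteinGroup
from .psms import PeptideEvidence
from .scoring import score_best_pep

logger = logging.getLogger(__name__)


def _observed_sets(evidence: Sequence[PeptideEvidence]) -> dict[str, set[str]]:
    observed: dict[str, set[str]] = {}
    for ev in evidence:
        for acc in ev.accessions:
            observed.setdefault(acc, set()).add(ev.peptide)
    return observed


def no_grouping(evidence: Sequence[PeptideEvidence]) -> GroupingResult:
    """One singleton group per protein with at least one observed peptide."""
    observed = _observed_sets(evidence)
    groups = [
        ProteinGroup(leading_proteins=(acc,), member_proteins=(acc,))
        for acc in sorted(observed)
    ]
    return GroupingResult(groups)


def subset_grouping(evidence: Sequence[PeptideEvidence]) -> GroupingResult:
    """Group proteins whose observed peptides nest inside another protein's.

    Proteins with identical observed peptide sets form one cluster and are
    co-leading (alphabetical order).  Every non-maximal cluster is attached
    to one maximal (non-subsumed) superset cluster — the one with the most
    observed peptides, alphabetical tiebreak — so the result is a partition.
    """
    observed = _observed_sets(evidence)
    if not observed:
        return GroupingResult([])

    # clusters of proteins with identical peptide sets
    by_set: dict[frozenset[str], list[str]] = {}
    for acc, peptides in observed.items():
        by_set.setdefault(frozenset(peptides), []).append(acc)
    cluster_sets = list(by_set.keys())
    cluster_accs = [sorted(by_set[s]) for s in cluster_sets]

    peptide_to_clusters: dict[str, set[int]] = {}
    for ci, pset in enumerate(cluster_sets):
        for p in pset:
            peptide_to_clusters.setdefault(p, set()).add(ci)

    def strict_supersets(ci: int) -> set[int]:
        pset = cluster_sets[ci]
        candidates: set[int] | None = None
        for p in pset:
            holders = peptide_to_clusters[p]
            candidates = set(holders) if candidates is None else candidates & holders
            if len(candidates) == 1:
                break
        candidates.discard(ci)
        return {c for c in candidates if len(cluster_sets[c]) > len(pset)}

    supersets = [strict_supersets(ci) for ci in range(len(cluster_sets))]
    maximal = [ci for ci in range(len(cluster_sets)) if not supersets[ci]]

    # attach each subsumed cluster to one maximal superset cluster
    attachment: dict[int, list[int]] = {ci: [] for ci in maximal}
    for ci in range(len(cluster_sets)):
        if not supersets[ci]:
            continue
        maximal_supers = [c for c in supersets[ci] if not supersets[c]]
        host = min(
            maximal_supers, key=lambda c: (-len(cluster_sets[c]), cluster_accs[c][0])
        )
        attachment[host].append(ci)

    groups = []
    for ci in sorted(maximal, key=lambda c: cluster_accs[c][0]):
        leading = tuple(cluster_accs[ci])
        subsumed = sorted(
            attachment[ci], key=lambda c: (-len(cluster_sets[c]), cluster_accs[c][0])
        )
        members = list(leading)
        for c in subsumed:
            members.extend(cluster_accs[c])
        groups.append(
            ProteinGroup(leading_proteins=leading, member_proteins=tuple(members))
        )
    return GroupingResult(groups)


def _internal_group_score_cutoff(
    evidence: Sequence[PeptideEvidence],
    pg1: GroupingResult,
    threshold: float,
    decoy_prefix: str,
    pep_floor: float,
) -> float | None:
    """Evidence-score cutoff equivalent to a group-level FDR threshold.

    The internal pass always uses discarded shared peptides, best-PEP
    scoring, and the picked-group competition, independent of the outer
    method, so the cutoff is computed on a calibrated scale.
    """
    pep_by_peptide = {ev.peptide: ev.best_pep for ev in evidence}
    assigned = discard_shared(pg1, evidence)
    scored = [
        ScoredGroup(
            group=g,
            score=score_best_pep(g, pep_by_peptide, pep_floor),
            is_decoy=all(a.startswith(decoy_prefix) for a in g.leading_proteins),
        )
        for g in assigned.groups
        if g.peptides
    ]
    if not scored:
        return None
    competed = picked_group_tds(sort_groups(scored), decoy_prefix)
    estimated = estimate_group_fdr(competed)
    return psm_cutoff_for_group_fdr(estimated, threshold)


def rescued_subset_grouping(
    evidence: Sequence[PeptideEvidence],
    threshold: float = 0.01,
    decoy_prefix: str = DECOY_PREFIX,
    pep_floor: float = 1e-20,
) -> GroupingResult:
    """Two-pass subset grouping robust to low-confidence evidence.

    Pass one groups all evidence (PG1) and derives the evidence-level score
    cutoff equivalent to ``threshold`` group-level FDR.  Pass two regroups
    only the evidence passing that cutoff (PG2).  The result is PG2 plus
    every PG1 group none of whose proteins occurs in PG2, so that groups
    above the FDR threshold still receive estimates.  Falls back to PG1 with
    a warning when no group reaches the threshold.
    """
    pg1 = subset_grouping(evidence)
    cutoff = _internal_group_score_cutoff(
        evidence, pg1, threshold, decoy_prefix, pep_floor
    )
    if cutoff is None:
        logger.warning(
            "no protein group reached %g group-level FDR; keeping first-pass grouping",
            threshold,
        )
        return pg1
    # tiny relative slack so peptides exactly at the cutoff are kept despite
    # round-tripping through -log10
    max_pep = 10.0 ** (-cutoff) * (1.0 + 1e-9)
    filtered = [ev for ev in evidence if ev.best_pep <= max_pep]
    pg2 = subset_grouping(filtered)
    pg2_accessions = set(pg2.accession_to_group)
    rescued = [
        g
        for g in pg1.groups
        if not any(acc in pg2_accessions for acc in g.member_proteins)
    ]
    return GroupingResult(list(pg2.groups) + rescued)


def group_proteins(
    evidence: Sequence[PeptideEvidence],
    strategy: str,
    threshold: float = 0.01,
    decoy_prefix: str = DECOY_PREFIX,
    pep_floor: float = 1e-20,
) -> GroupingResult:
    """Dispatch on the grouping strategy name."""
    if strategy == "none":
        return no_grouping(evidence)
    if strategy == "subset":
        return subset_grouping(evidence)
    if strategy == "rescued_subset":
        return rescued_subset_grouping(evidence, threshold, decoy_prefix, pep_floor)
    raise ValueError(f"unknown grouping strategy {strategy!r}")
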