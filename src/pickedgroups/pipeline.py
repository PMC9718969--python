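"""End-to-end orchestration: PSM tables to a scored protein-group report.

The pipeline runs read -> remap -> per-raw-file peptide FDR filter ->
collapse -> grouping -> shared-peptide assignment -> scoring -> target-decoy
competition -> group-level FDR, with every stage configured by a
:class:`~pickedgroups.config.MethodConfig` or a named preset.  Multiple
input tables are concatenated before collapsing, which is how results from
several searches merge into one consistent protein-group list.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assignment import assign_razor, discard_shared
from .config import MethodConfig, resolve_method
from .fasta import PeptideIndex, SequenceDatabase, build_peptide_index
from .fdr import (
    ScoredGroup,
    estimate_group_fdr,
    picked_group_tds,
    picked_tds,
    sort_groups,
)
from .grouping import group_proteins
from .groups import ProteinGroup
from .psms import PeptideEvidence, collapse_to_peptides, filter_peptide_fdr_per_file, remap_peptides
from .scoring import optimize_pep_divisor, score_best_pep, score_multiply_pep

logger = logging.getLogger(__name__)


def _group_flags(group: ProteinGroup, config: MethodConfig) -> tuple[bool, bool]:
    leading = group.leading_proteins
    is_decoy = all(a.startswith(config.decoy_prefix) for a in leading)
    is_contaminant = any(
        a.startswith(config.contaminant_prefix)
        or a.startswith(config.decoy_prefix + config.contaminant_prefix)
        for a in leading
    )
    return is_decoy, is_contaminant


def _apply_tds(scored: list[ScoredGroup], config: MethodConfig) -> list[ScoredGroup]:
    ordered = sort_groups(scored)
    if config.tds == "classic":
        return ordered
    if config.tds == "picked":
        return picked_tds(ordered, config.decoy_prefix)
    if config.tds == "picked_group":
        return picked_group_tds(ordered, config.decoy_prefix)
    raise ValueError(f"unknown TDS {config.tds!r}")


def run_from_evidence(
    evidence: Sequence[PeptideEvidence], config: MethodConfig
) -> list[ScoredGroup]:
    """Grouping/assignment/scoring/competition/FDR on collapsed evidence."""
    grouping = group_proteins(
        evidence,
        config.grouping,
        threshold=config.fdr_threshold,
        decoy_prefix=config.decoy_prefix,
        pep_floor=config.pep_floor,
    )
    logger.info("grouping (%s): %d groups from %d peptides", config.grouping, len(grouping), len(evidence))

    if config.shared_peptides == "discard":
        assigned = discard_shared(grouping, evidence)
    else:
        rng = np.random.default_rng(config.razor_seed)
        assigned = assign_razor(grouping, evidence, rng)
    n_assigned = sum(len(g.peptides) for g in assigned.groups)
    logger.info(
        "assignment (%s): %d of %d peptides assigned",
        config.shared_peptides,
        n_assigned,
        len(evidence),
    )

    pep_by_peptide = {ev.peptide: ev.best_pep for ev in evidence}

    def make_scored(group: ProteinGroup, score: float) -> ScoredGroup:
        is_decoy, is_contaminant = _group_flags(group, config)
        return ScoredGroup(group=group, score=score, is_decoy=is_decoy, is_contaminant=is_contaminant)

    scorable = [g for g in assigned.groups if g.peptides]
    if config.scoring == "best_pep":
        scored = [
            make_scored(g, score_best_pep(g, pep_by_peptide, config.pep_floor))
            for g in scorable
        ]
    else:
        divisor = optimize_pep_divisor(
            assigned,
            pep_by_peptide,
            run_fdr=lambda s: estimate_group_fdr(_apply_tds(s, config)),
            make_scored=make_scored,
            threshold=config.fdr_threshold,
            grid=config.divisor_grid,
            pep_floor=config.pep_floor,
        )
        scored = [
            make_scored(g, score_multiply_pep(g, pep_by_peptide, divisor, config.pep_floor))
            for g in scorable
        ]

    competed = _apply_tds(scored, config)
    logger.info("TDS (%s): %d of %d groups retained", config.tds, len(competed), len(scored))
    return estimate_group_fdr(competed)


def run_method_preset(
    psm_tables: Sequence[pd.DataFrame],
    db: SequenceDatabase,
    preset: str | MethodConfig,
    peptide_index: PeptideIndex | None = None,
) -> list[ScoredGroup]:
    """Run a full method (named preset or explicit config) on PSM tables.

    Tables must be in the canonical layout (see :mod:`pickedgroups.psms`).
    They are concatenated, remapped against the database's peptide index,
    filtered at the per-raw-file peptide FDR, collapsed to peptides, and fed
    through the group-level pipeline.
    """
    config = resolve_method(preset)
    if not psm_tables:
        raise ValueError("no PSM tables supplied")
    table = pd.concat(list(psm_tables), ignore_index=True)
    logger.info("input: %d PSMs from %d table(s)", len(table), len(psm_tables))

    if peptide_index is None:
        peptide_index = build_peptide_index(db, config.digest)
    table = remap_peptides(table, peptide_index, config.decoy_prefix)
    logger.info("remap: %d PSMs mapped to the database", len(table))

    table = filter_peptide_fdr_per_file(table, config.peptide_fdr)
    logger.info("peptide FDR filter (%g per raw file): %d PSMs", config.peptide_fdr, len(table))

    evidence = collapse_to_peptides(table, config.decoy_prefix)
    logger.info("collapse: %d distinct peptides", len(evidence))
    return run_from_evidence(evidence, config)


REPORT_COLUMNS = [
    "Protein IDs",
    "Leading proteins",
    "Unique peptides",
    "Peptide counts",
    "Score",
    "FDR",
    "Q-value",
    "Reverse",
    "Potential contaminant",
]


def write_protein_groups(
    result: Sequence[ScoredGroup],
    path: str | Path,
    experiments: Sequence[str] | None = None,
    evidence: Sequence[PeptideEvidence] | None = None,
) -> pd.DataFrame:
    """Write a tab-separated protein-groups report.

    Rows are ordered by descending score with an accession tiebreak;
    q-values are capped at 1.  When ``experiments`` and ``evidence`` are
    given, summed intensities of each group's assigned peptides are appended
    per experiment (pass-through quantification, no normalization).
    """
    intensity_of = {}
    if evidence is not None:
        intensity_of = {ev.peptide: ev.intensity for ev in evidence}
    rows = []
    for sg in sort_groups(list(result)):
        group = sg.group
        row = {
            "Protein IDs": ";".join(group.member_proteins),
            "Leading proteins": ";".join(group.leading_proteins),
            "Unique peptides": len(group.peptides - group.razor_peptides),
            "Peptide counts": len(group.peptides),
            "Score": sg.score,
            "FDR": sg.fdr,
            "Q-value": min(sg.q_value, 1.0) if sg.q_value is not None else None,
            "Reverse": "+" if sg.is_decoy else "",
            "Potential contaminant": "+" if sg.is_contaminant else "",
        }
        if experiments is not None:
            for experiment in experiments:
                row[f"Intensity {experiment}"] = sum(
                    intensity_of.get(p, {}).get(experiment, 0.0) for p in group.peptides
                )
        rows.append(row)
    columns = REPORT_COLUMNS + (
        [f"Intensity {e}" for e in experiments] if experiments is not None else []
    )
    report = pd.DataFrame(rows, columns=columns)
    report.to_csv(path, sep="\t", index=False)
    return report
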