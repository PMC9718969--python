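"""Method configuration and named presets.

A method is a combination of four options: protein grouping (``none``,
``subset``, ``rescued_subset``), shared-peptide handling (``discard``,
``razor``), group scoring (``best_pep``, ``multiply_pep``), and target-decoy
strategy (``classic``, ``picked``, ``picked_group``).  The named presets are
the seven combinations commonly compared in the field; whether the input
PEPs come from the original search engine or from Percolator rescoring is a
property of the input table, not of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .fasta import CONTAMINANT_PREFIX, DECOY_PREFIX, DigestParams

GROUPING_OPTIONS = ("none", "subset", "rescued_subset")
SHARED_OPTIONS = ("discard", "razor")
SCORING_OPTIONS = ("best_pep", "multiply_pep")
TDS_OPTIONS = ("classic", "picked", "picked_group")


@dataclass(frozen=True)
class MethodConfig:
    grouping: str = "rescued_subset"
    shared_peptides: str = "discard"
    scoring: str = "best_pep"
    tds: str = "picked_group"
    fdr_threshold: float = 0.01
    peptide_fdr: float = 0.01
    razor_seed: int = 0
    pep_floor: float = 1e-20
    divisor_grid: tuple[float, ...] | None = None
    decoy_prefix: str = DECOY_PREFIX
    contaminant_prefix: str = CONTAMINANT_PREFIX
    digest: DigestParams = field(default_factory=DigestParams)

    def __post_init__(self) -> None:
        for value, options, name in [
            (self.grouping, GROUPING_OPTIONS, "grouping"),
            (self.shared_peptides, SHARED_OPTIONS, "shared_peptides"),
            (self.scoring, SCORING_OPTIONS, "scoring"),
            (self.tds, TDS_OPTIONS, "tds"),
        ]:
            if value not in options:
                raise ValueError(f"{name} must be one of {options}, got {value!r}")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")

    def replace(self, **changes) -> "MethodConfig":
        return replace(self, **changes)


PRESETS: dict[str, MethodConfig] = {
    "maxquant": MethodConfig(
        grouping="subset", shared_peptides="razor", scoring="multiply_pep", tds="classic"
    ),
    "savitski": MethodConfig(
        grouping="none", shared_peptides="discard", scoring="best_pep", tds="picked"
    ),
    "picked_protein_group_fdr": MethodConfig(
        grouping="rescued_subset",
        shared_peptides="discard",
        scoring="best_pep",
        tds="picked_group",
    ),
    "savitski_classic": MethodConfig(
        grouping="none", shared_peptides="discard", scoring="best_pep", tds="classic"
    ),
    "discard_picked_group": MethodConfig(
        grouping="subset", shared_peptides="discard", scoring="best_pep", tds="picked_group"
    ),
    "razor_picked_group": MethodConfig(
        grouping="subset", shared_peptides="razor", scoring="best_pep", tds="picked_group"
    ),
    "classic_protein_group_fdr": MethodConfig(
        grouping="rescued_subset", shared_peptides="discard", scoring="best_pep", tds="classic"
    ),
}


def resolve_method(preset_or_config) -> MethodConfig:
    """Turn a preset name or explicit :class:`MethodConfig` into a config."""
    if isinstance(preset_or_config, MethodConfig):
        return preset_or_config
    try:
        return PRESETS[preset_or_config]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset_or_config!r}; valid presets: {sorted(PRESETS)}"
        ) from None
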