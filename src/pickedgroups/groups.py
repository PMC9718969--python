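"""Core protein-group containers shared across grouping, assignment, and FDR."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ProteinGroup:
    """A set of proteins treated as a single identification unit.

    ``leading_proteins`` cover all observed peptides associated with the
    group; ``member_proteins`` lists leading proteins first, then subsumed
    ones.  ``peptides`` (and the ``razor_peptides`` subset) are filled by
    peptide assignment; until then they are empty.
    """

    leading_proteins: tuple[str, ...]
    member_proteins: tuple[str, ...]
    peptides: frozenset[str] = frozenset()
    razor_peptides: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.leading_proteins:
            raise ValueError("a protein group needs at least one leading protein")
        members = set(self.member_proteins)
        if not set(self.leading_proteins) <= members:
            raise ValueError("leading proteins must be members")

    def with_peptides(
        self, peptides: frozenset[str], razor: frozenset[str] = frozenset()
    ) -> "ProteinGroup":
        return replace(self, peptides=peptides, razor_peptides=razor)


@dataclass
class GroupingResult:
    """A partition of the observed proteins into protein groups."""

    groups: list[ProteinGroup]
    accession_to_group: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accession_to_group:
            self.accession_to_group = {
                acc: i for i, g in enumerate(self.groups) for acc in g.member_proteins
            }

    def __len__(self) -> int:
        return len(self.groups)

    def group_of(self, accession: str) -> ProteinGroup:
        return self.groups[self.accession_to_group[accession]]
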