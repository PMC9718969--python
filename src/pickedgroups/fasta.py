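"""Protein sequence databases and in-silico tryptic digestion.

A :class:`SequenceDatabase` holds FASTA records classified as target, decoy,
entrapment, or contaminant entries based on accession prefixes (MaxQuant
convention: ``REV__`` for reversed decoys, ``CON__`` for contaminants;
entrapment entries produced by :mod:`pickedgroups.entrapment` carry an
``ENTRAP{r}__`` prefix).  Databases are digested in silico with trypsin or
trypsin/P into a :class:`PeptideIndex`, the peptide-to-protein map that
grouping, entrapment construction, and simulation are built on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

DECOY_PREFIX = "REV__"
CONTAMINANT_PREFIX = "CON__"

_ENTRAPMENT_RE = re.compile(r"^ENTRAP\d+__")

#: Residues that never act as cleavage sites (non-standard symbols included).
_CLEAVE_AFTER = frozenset("KR")


@dataclass(frozen=True)
class ProteinEntry:
    """A single FASTA record with its database role."""

    accession: str
    sequence: str
    entry_class: str  # target | decoy | entrapment | contaminant

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        if self.entry_class not in ("target", "decoy", "entrapment", "contaminant"):
            raise ValueError(f"unknown entry class {self.entry_class!r}")


def classify_accession(
    accession: str,
    decoy_prefix: str = DECOY_PREFIX,
    contaminant_prefix: str = CONTAMINANT_PREFIX,
) -> str:
    """Infer the database role of an accession from its prefixes.

    Decoy status takes precedence: ``REV__CON__X`` is a decoy, as is
    ``REV__ENTRAP1__X``.
    """
    if accession.startswith(decoy_prefix):
        return "decoy"
    if accession.startswith(contaminant_prefix):
        return "contaminant"
    if _ENTRAPMENT_RE.match(accession):
        return "entrapment"
    return "target"


class SequenceDatabase:
    """Ordered collection of :class:`ProteinEntry` with unique accessions."""

    def __init__(
        self,
        entries: Iterable[ProteinEntry],
        decoy_prefix: str = DECOY_PREFIX,
        contaminant_prefix: str = CONTAMINANT_PREFIX,
    ):
        self.decoy_prefix = decoy_prefix
        self.contaminant_prefix = contaminant_prefix
        self._entries: list[ProteinEntry] = []
        self._by_accession: dict[str, ProteinEntry] = {}
        for entry in entries:
            if entry.accession in self._by_accession:
                raise ValueError(f"duplicate accession {entry.accession!r}")
            self._entries.append(entry)
            self._by_accession[entry.accession] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[ProteinEntry]:
        return iter(self._entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def __getitem__(self, accession: str) -> ProteinEntry:
        return self._by_accession[accession]

    def entries(self, entry_class: str | None = None) -> list[ProteinEntry]:
        if entry_class is None:
            return list(self._entries)
        return [e for e in self._entries if e.entry_class == entry_class]

    def accessions(self, entry_class: str | None = None) -> list[str]:
        return [e.accession for e in self.entries(entry_class)]

    def entry_class(self, accession: str) -> str:
        return self._by_accession[accession].entry_class

    def counterpart(self, accession: str) -> str:
        """Target accession of a decoy (and vice versa) under the prefix rule."""
        if accession.startswith(self.decoy_prefix):
            return accession[len(self.decoy_prefix):]
        return self.decoy_prefix + accession

    def concat(self, other: "SequenceDatabase") -> "SequenceDatabase":
        return SequenceDatabase(
            list(self._entries) + list(other._entries),
            decoy_prefix=self.decoy_prefix,
            contaminant_prefix=self.contaminant_prefix,
        )

    def write(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as handle:
            for entry in self._entries:
                handle.write(f">{entry.accession}\n")
                for i in range(0, len(entry.sequence), width):
                    handle.write(entry.sequence[i : i + width] + "\n")


def read_fasta(
    path: str | Path,
    decoy_prefix: str = DECOY_PREFIX,
    contaminant_prefix: str = CONTAMINANT_PREFIX,
) -> SequenceDatabase:
    """Read a FASTA database, classifying entries by accession prefix.

    The accession is the first whitespace-delimited token of the header.
    Sequences are uppercased.  Raises ``ValueError`` on an empty file or a
    duplicate accession.
    """
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        if not accession:
            raise ValueError(f"{path}: record with empty header")
        sequence = str(record.seq).upper()
        if not sequence:
            raise ValueError(f"{path}: no sequence for record {accession!r}")
        entries.append(
            ProteinEntry(
                accession=accession,
                sequence=sequence,
                entry_class=classify_accession(accession, decoy_prefix, contaminant_prefix),
            )
        )
    if not entries:
        raise ValueError(f"{path}: no records")
    return SequenceDatabase(entries, decoy_prefix, contaminant_prefix)


def with_reversed_decoys(db: SequenceDatabase) -> SequenceDatabase:
    """Append a reversed-sequence decoy for every non-decoy entry."""
    decoys = [
        ProteinEntry(db.decoy_prefix + e.accession, e.sequence[::-1], "decoy")
        for e in db
        if e.entry_class != "decoy"
    ]
    return SequenceDatabase(
        list(db) + decoys, db.decoy_prefix, db.contaminant_prefix
    )


@dataclass(frozen=True)
class DigestParams:
    """Proteolytic digestion settings.

    ``trypsin`` cleaves after K/R but not before proline; ``trypsin/p``
    cleaves after K/R regardless.  ``max_length=None`` means unbounded.
    """

    enzyme: str = "trypsin"
    missed_cleavages: int = 2
    min_length: int = 7
    max_length: int | None = 50

    def __post_init__(self) -> None:
        if self.enzyme not in ("trypsin", "trypsin/p"):
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")
        if self.max_length is not None and self.min_length > self.max_length:
            raise ValueError("min_length > max_length")


#: Digestion used for entrapment-database construction: trypsin/P, no missed
#: cleavages, peptides longer than six residues, no upper length bound.
ENTRAPMENT_DIGEST = DigestParams(
    enzyme="trypsin/p", missed_cleavages=0, min_length=7, max_length=None
)


def cleavage_positions(sequence: str, enzyme: str) -> list[int]:
    """Positions i such that the peptide bond after residue i-1 is cleaved."""
    proline_rule = enzyme == "trypsin"
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in _CLEAVE_AFTER
        and not (proline_rule and sequence[i + 1] == "P")
    ]


def digest_spans(sequence: str, enzyme: str) -> list[tuple[int, int]]:
    """Fully cleaved (zero missed cleavage) peptide spans, in order."""
    cuts = [0] + cleavage_positions(sequence, enzyme) + [len(sequence)]
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


def digest_protein(sequence: str, params: DigestParams) -> list[str]:
    """In-silico digest of one protein sequence.

    Returns peptides with at most ``params.missed_cleavages`` internal
    cleavage sites, within the length bounds, deduplicated in order of first
    occurrence.  Unknown residues (X/U/B/Z and anything else outside K/R)
    never act as cleavage sites.
    """
    if not sequence:
        raise ValueError("empty sequence")
    spans = digest_spans(sequence, params.enzyme)
    seen: dict[str, None] = {}
    max_len = params.max_length if params.max_length is not None else float("inf")
    for i in range(len(spans)):
        start = spans[i][0]
        for j in range(i, min(i + params.missed_cleavages + 1, len(spans))):
            end = spans[j][1]
            length = end - start
            if length > max_len:
                break
            if length >= params.min_length:
                seen.setdefault(sequence[start:end])
    return list(seen)


class PeptideIndex:
    """Peptide-sequence to protein-accession map from an in-silico digest."""

    def __init__(self, mapping: dict[str, frozenset[str]]):
        self._mapping = mapping

    def __len__(self) -> int:
        return len(self._mapping)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self._mapping

    def __getitem__(self, peptide: str) -> frozenset[str]:
        return self._mapping[peptide]

    def get(self, peptide: str, default=None):
        return self._mapping.get(peptide, default)

    def peptides(self) -> list[str]:
        return list(self._mapping)

    def items(self):
        return self._mapping.items()

    def is_shared(self, peptide: str) -> bool:
        return len(self._mapping[peptide]) > 1

    @property
    def shared_fraction(self) -> float:
        if not self._mapping:
            return 0.0
        shared = sum(1 for accs in self._mapping.values() if len(accs) > 1)
        return shared / len(self._mapping)

    @property
    def unique_fraction(self) -> float:
        if not self._mapping:
            return 0.0
        return 1.0 - self.shared_fraction

    def il_equivalent_view(self) -> dict[str, frozenset[str]]:
        """Peptide map with I and L collapsed (for peptide remapping only)."""
        merged: dict[str, set[str]] = {}
        for peptide, accs in self._mapping.items():
            merged.setdefault(peptide.replace("I", "L"), set()).update(accs)
        return {p: frozenset(a) for p, a in merged.items()}


def build_peptide_index(
    db: SequenceDatabase,
    params: DigestParams,
    entry_classes: Iterable[str] | None = None,
) -> PeptideIndex:
    """Digest every database entry and invert to a peptide->accessions map.

    ``entry_classes`` restricts the index to a subset of database roles
    (e.g. targets only when measuring entrapment overlap).
    """
    if len(db) == 0:
        raise ValueError("empty database")
    classes = set(entry_classes) if entry_classes is not None else None
    mapping: dict[str, set[str]] = {}
    for entry in db:
        if classes is not None and entry.entry_class not in classes:
            continue
        for peptide in digest_protein(entry.sequence, params):
            mapping.setdefault(peptide, set()).add(entry.accession)
    return PeptideIndex({p: frozenset(a) for p, a in mapping.items()})
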