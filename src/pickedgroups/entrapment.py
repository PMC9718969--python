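"""Entrapment-database construction by peptide-level shuffling.

An entrapment database extends the target database with protein sequences
known to be false, so the realized false discovery rate can be measured
empirically.  Each entrapment protein is built from a target protein by
replacing its fully cleaved tryptic peptides in place with shuffled versions
(C-terminal residue fixed), except for a controlled fraction ``S`` of
peptides that are kept verbatim and therefore shared between the target and
entrapment entries.  Repeating the construction yields an entrapment
database a multiple of the target-database size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fasta import (
    ENTRAPMENT_DIGEST,
    DigestParams,
    ProteinEntry,
    SequenceDatabase,
    build_peptide_index,
    digest_protein,
    digest_spans,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntrapmentConfig:
    """Settings for entrapment-database construction.

    ``shared_fraction`` is the probability that a digested peptide is kept
    verbatim (shared with the target).  ``num_repeats=4`` produces five
    entrapment copies per target, i.e. an entrapment database five times the
    size of the target database.  ``exact_fraction`` switches the keep/shuffle
    selection from independent Bernoulli draws to an exact per-protein count.
    """

    shared_fraction: float
    random_seed: int
    num_repeats: int = 4
    max_reshuffle_attempts: int = 10
    exact_fraction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.random_seed is None:
            raise ValueError("an explicit random_seed is required")
        if self.num_repeats < 1:
            raise ValueError("num_repeats must be positive")
        if self.max_reshuffle_attempts < 0:
            raise ValueError("max_reshuffle_attempts must be non-negative")


def shuffle_peptide(peptide: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of a peptide, C-terminal residue fixed.

    Inputs shorter than two residues are returned unchanged.
    """
    if len(peptide) < 2:
        return peptide
    head = np.frombuffer(peptide[:-1].encode(), dtype="S1")
    perm = rng.permutation(len(head))
    return b"".join(head[perm]).decode() + peptide[-1]


def _shuffle_avoiding(
    peptide: str,
    forbidden: set[str],
    rng: np.random.Generator,
    max_attempts: int,
) -> str:
    """Shuffle, reshuffling on collision with the target peptide set."""
    shuffled = shuffle_peptide(peptide, rng)
    attempts = 0
    while shuffled in forbidden and attempts < max_attempts:
        shuffled = shuffle_peptide(peptide, rng)
        attempts += 1
    return shuffled


def build_entrapment_database(
    db: SequenceDatabase,
    cfg: EntrapmentConfig,
    digest: DigestParams = ENTRAPMENT_DIGEST,
) -> SequenceDatabase:
    """Extend ``db`` with shuffled-peptide entrapment entries.

    Per repeat and per target protein, one entrapment entry is created whose
    sequence is the target sequence with each retained peptide (length >=
    ``digest.min_length`` under fully cleaved ``digest.enzyme`` digestion)
    either kept verbatim (probability ``cfg.shared_fraction``) or replaced in
    place by a shuffle with fixed C-terminal residue.  Shorter fragments are
    always left in place, so entrapment proteins keep the length of their
    source.  Entrapment accessions are ``ENTRAP{r}__{accession}``.
    """
    if digest.missed_cleavages != 0:
        raise ValueError("entrapment construction requires a fully cleaved digest")
    targets = db.entries("target")
    if not targets:
        raise ValueError("database contains no target entries")
    rng = np.random.default_rng(cfg.random_seed)

    # Shuffles colliding with any target peptide would create unintended
    # shared peptides; collect the target peptide set once.
    target_peptides = set(
        build_peptide_index(db, digest, entry_classes=("target",)).peptides()
    )

    n_copies = cfg.num_repeats + 1
    entrapment_entries = []
    for repeat in range(1, n_copies + 1):
        for entry in targets:
            spans = digest_spans(entry.sequence, digest.enzyme)
            pieces = [entry.sequence[s:e] for s, e in spans]
            eligible = [i for i, p in enumerate(pieces) if len(p) >= digest.min_length]
            keep = _select_kept(len(eligible), cfg, rng)
            for pos, kept in zip(eligible, keep):
                if not kept:
                    pieces[pos] = _shuffle_avoiding(
                        pieces[pos], target_peptides, rng, cfg.max_reshuffle_attempts
                    )
            entrapment_entries.append(
                ProteinEntry(
                    accession=f"ENTRAP{repeat}__{entry.accession}",
                    sequence="".join(pieces),
                    entry_class="entrapment",
                )
            )
    logger.info(
        "built %d entrapment entries (%d copies of %d targets)",
        len(entrapment_entries),
        n_copies,
        len(targets),
    )
    return SequenceDatabase(
        list(db) + entrapment_entries, db.decoy_prefix, db.contaminant_prefix
    )


def _select_kept(
    n: int, cfg: EntrapmentConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.exact_fraction:
        n_keep = int(round(cfg.shared_fraction * n))
        keep = np.zeros(n, dtype=bool)
        keep[rng.choice(n, size=n_keep, replace=False)] = True
        return keep
    return rng.random(n) < cfg.shared_fraction


def entrapment_shared_fraction(
    db: SequenceDatabase, digest: DigestParams = ENTRAPMENT_DIGEST
) -> float:
    """Fraction of digested entrapment peptides found verbatim in the target index.

    Peptides are counted per entrapment entry (duplicates within one entry
    counted once, as returned by the digest).
    """
    target_peptides = set(
        build_peptide_index(db, digest, entry_classes=("target",)).peptides()
    )
    entrapment = db.entries("entrapment")
    if not entrapment:
        raise ValueError("database contains no entrapment entries")
    total = 0
    shared = 0
    for entry in entrapment:
        for peptide in digest_protein(entry.sequence, digest):
            total += 1
            if peptide in target_peptides:
                shared += 1
    if total == 0:
        raise ValueError("entrapment entries produced no peptides")
    return shared / total
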