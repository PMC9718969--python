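"""Synthetic protein databases with isoform-like redundancy.

Proteins are built as concatenations of random tryptic-style peptides:
interior residues avoid K/R and each peptide ends in K or R, so a fully
cleaved trypsin/P digest recovers exactly the designed peptides.  Genes
carry an ordered pool of peptides ("exons"); the canonical protein contains
the whole pool, and additional isoforms are derived by deleting one
contiguous residue substring (exon skipping) and, usually, appending a
novel terminal peptide (alternative terminal exon).  Deleting at the
residue level means the splice junction fuses two partial peptides into a
chimeric peptide unique to the isoform — and, because the same happens on
the reversed sequence, the decoy database carries the same per-isoform
novelty.  Isoforms share contiguous stretches of sequence rather than a
bag of peptides, so the redundancy structure of real isoform databases is
mirrored on both sides of the target-decoy divide; breaking this symmetry
would bias decoy-based group FDR estimates on simulated data.
"""

from __future__ import annotations

import numpy as np

from .fasta import ProteinEntry, SequenceDatabase, with_reversed_decoys

# interior alphabet excludes K/R (no internal cleavage sites) and also
# P, so sequences behave identically under trypsin and trypsin/P
_INTERIOR = np.array(list("ACDEFGHILMNQSTVWY"), dtype="U1")
_TERMINAL = np.array(list("KR"), dtype="U1")


def random_tryptic_peptide(
    rng: np.random.Generator, min_length: int = 7, max_length: int = 18
) -> str:
    length = int(rng.integers(min_length, max_length + 1))
    interior = rng.choice(_INTERIOR, size=length - 1)
    terminal = rng.choice(_TERMINAL)
    return "".join(interior) + str(terminal)


def make_synthetic_database(
    n_proteins: int,
    seed: int,
    isoform_fraction: float = 0.6,
    mean_pool_size: float = 8.0,
    novel_terminal_prob: float = 0.6,
    with_decoys: bool = True,
) -> SequenceDatabase:
    """Generate a target database of ``n_proteins`` entries.

    ``isoform_fraction`` is the expected fraction of proteins that are
    non-canonical isoforms (isoform counts per gene are geometric); genes
    are created until the protein budget is spent.  Each gene's canonical
    entry concatenates its full peptide pool (3 + Poisson around
    ``mean_pool_size - 3``); an isoform deletes one contiguous block of up
    to half the pool and with probability ``novel_terminal_prob`` appends
    one novel isoform-specific terminal peptide.  With ``with_decoys`` a
    reversed decoy is appended for every entry.  Accessions are
    ``GENE{g}-{i}`` with ``i = 1`` for the canonical form.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be positive")
    if not 0.0 <= isoform_fraction < 1.0:
        raise ValueError("isoform_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    entries: list[ProteinEntry] = []
    gene = 0
    while len(entries) < n_proteins:
        gene += 1
        pool_size = 3 + int(rng.poisson(max(mean_pool_size - 3.0, 0.0)))
        pool = [random_tryptic_peptide(rng) for _ in range(pool_size)]
        canonical = "".join(pool)
        if isoform_fraction > 0:
            n_isoforms = int(rng.geometric(1.0 - isoform_fraction))
        else:
            n_isoforms = 1
        n_isoforms = min(n_isoforms, n_proteins - len(entries))
        for iso in range(1, n_isoforms + 1):
            if iso == 1:
                sequence = canonical
            else:
                # exon-skipping at the residue level: delete one contiguous
                # substring, so the splice junction yields a chimeric
                # peptide novel to the isoform — on the target sequence and
                # equally on its reversal
                n_res = len(canonical)
                span = int(rng.integers(max(n_res // 10, 1), max(n_res // 2, 2)))
                start = int(rng.integers(0, n_res - span + 1))
                sequence = canonical[:start] + canonical[start + span :]
                if rng.random() < novel_terminal_prob:
                    sequence += random_tryptic_peptide(rng)
            entries.append(
                ProteinEntry(
                    accession=f"GENE{gene:06d}-{iso}",
                    sequence=sequence,
                    entry_class="target",
                )
            )
    db = SequenceDatabase(entries)
    return with_reversed_decoys(db) if with_decoys else db
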