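"""Shared fixtures: small synthetic databases and evidence builders."""

import numpy as np
import pandas as pd
import pytest

from pickedgroups import (
    ENTRAPMENT_DIGEST,
    PeptideEvidence,
    build_peptide_index,
    make_synthetic_database,
)


@pytest.fixture(scope="session")
def small_db():
    """200-protein synthetic database with reversed decoys."""
    return make_synthetic_database(200, seed=7)


@pytest.fixture(scope="session")
def small_index(small_db):
    return build_peptide_index(small_db, ENTRAPMENT_DIGEST)


def make_evidence(spec):
    """Build PeptideEvidence records from (peptide, pep, accessions) tuples."""
    return [
        PeptideEvidence(
            peptide=pep,
            best_pep=p,
            accessions=frozenset(accs),
            is_decoy=all(a.startswith("REV__") for a in accs),
        )
        for pep, p, accs in spec
    ]


def make_psm_frame(rows):
    """Canonical PSM DataFrame from (peptide, proteins, raw_file, pep, is_decoy)."""
    return pd.DataFrame(
        {
            "peptide": [r[0] for r in rows],
            "modified_peptide": "",
            "proteins": [r[1] for r in rows],
            "raw_file": [r[2] for r in rows],
            "experiment": [r[2] for r in rows],
            "pep": [r[3] for r in rows],
            "score": [-np.log10(r[3]) for r in rows],
            "intensity": np.nan,
            "is_decoy": [r[4] for r in rows],
        }
    )
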