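"""Reading, filtering, and collapsing PSM evidence tables.

Tables are held as pandas DataFrames with canonical columns::

    peptide, modified_peptide, proteins, raw_file, experiment,
    pep, score, intensity, is_decoy

``proteins`` is a semicolon-joined accession list.  Two tab-separated input
dialects are supported: ``maxquant_evidence`` (MaxQuant's evidence.txt
column names) and ``generic_tsv`` (the canonical names above, as written by
the simulator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fasta import DECOY_PREFIX, PeptideIndex

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "peptide",
    "modified_peptide",
    "proteins",
    "raw_file",
    "experiment",
    "pep",
    "score",
    "intensity",
    "is_decoy",
]

_MAXQUANT_MAP = {
    "Sequence": "peptide",
    "Modified sequence": "modified_peptide",
    "Proteins": "proteins",
    "Leading proteins": "leading_proteins",
    "Raw file": "raw_file",
    "Experiment": "experiment",
    "PEP": "pep",
    "Score": "score",
    "Intensity": "intensity",
    "Reverse": "reverse",
    "Potential contaminant": "potential_contaminant",
}

_REQUIRED = {
    "maxquant_evidence": ["Sequence", "Proteins", "Raw file", "PEP"],
    "generic_tsv": ["peptide", "proteins", "raw_file", "pep"],
}


@dataclass(frozen=True)
class PeptideEvidence:
    """Best evidence for one peptide sequence across all retained PSMs."""

    peptide: str
    best_pep: float
    accessions: frozenset[str]
    is_decoy: bool
    intensity: dict = field(default_factory=dict, compare=False)


def _all_decoy(proteins: str, decoy_prefix: str) -> bool:
    accs = proteins.split(";")
    return bool(accs) and all(a.startswith(decoy_prefix) for a in accs)


def read_psm_table(
    path: str | Path,
    dialect: str = "maxquant_evidence",
    decoy_prefix: str = DECOY_PREFIX,
) -> pd.DataFrame:
    """Read a PSM table into the canonical DataFrame layout.

    Rows with a missing/unparsable PEP or an empty peptide sequence are
    dropped with a logged count.  The decoy flag comes from the dialect's
    reverse column when present, otherwise from the accession prefix.
    """
    if dialect not in _REQUIRED:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED[dialect] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if dialect == "maxquant_evidence":
        df = df.rename(columns=_MAXQUANT_MAP)

    n_input = len(df)
    df["pep"] = pd.to_numeric(df["pep"], errors="coerce")
    keep = df["pep"].notna() & (df["peptide"].str.len() > 0) & (df["proteins"].str.len() > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d of %d rows (missing PEP or peptide)", path, n_dropped, n_input)
    df = df.loc[keep].copy()

    for col, default in [
        ("modified_peptide", ""),
        ("experiment", ""),
        ("score", np.nan),
        ("intensity", np.nan),
    ]:
        if col in df.columns:
            if default == "":
                df[col] = df[col].fillna("")
            else:
                df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = default

    if "reverse" in df.columns:
        df["is_decoy"] = df["reverse"].astype(str).str.strip() == "+"
    elif "is_decoy" in df.columns:
        df["is_decoy"] = df["is_decoy"].astype(str).str.lower().isin(("true", "1", "+"))
    else:
        df["is_decoy"] = df["proteins"].map(lambda p: _all_decoy(p, decoy_prefix))
    return df[CANONICAL_COLUMNS].reset_index(drop=True)


def write_psm_table(df: pd.DataFrame, path: str | Path, dialect: str = "generic_tsv") -> None:
    """Write a canonical PSM table in the requested dialect."""
    if dialect == "generic_tsv":
        df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)
        return
    if dialect == "maxquant_evidence":
        out = pd.DataFrame(
            {
                "Sequence": df["peptide"],
                "Modified sequence": df["modified_peptide"],
                "Proteins": df["proteins"],
                "Raw file": df["raw_file"],
                "Experiment": df["experiment"],
                "PEP": df["pep"],
                "Score": df["score"],
                "Intensity": df["intensity"],
                "Reverse": np.where(df["is_decoy"], "+", ""),
                "Potential contaminant": "",
            }
        )
        out.to_csv(path, sep="\t", index=False)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def remap_peptides(
    table: pd.DataFrame,
    index: PeptideIndex,
    decoy_prefix: str = DECOY_PREFIX,
    il_equivalent: bool = False,
) -> pd.DataFrame:
    """Replace protein accessions by index lookup; drop unmapped peptides.

    Records whose peptide is absent from the index are discarded rather than
    rescued, so a table filtered against a reduced database mirrors a search
    against that database.  With ``il_equivalent`` the lookup treats I and L
    as the same residue.
    """
    if il_equivalent:
        view = index.il_equivalent_view()
        lookup = lambda p: view.get(p.replace("I", "L"))  # noqa: E731
    else:
        lookup = index.get
    unique_peptides = table["peptide"].unique()
    mapped = {
        p: ";".join(sorted(accs))
        for p in unique_peptides
        if (accs := lookup(p)) is not None
    }
    out = table.loc[table["peptide"].isin(mapped.keys())].copy()
    out["proteins"] = out["peptide"].map(mapped)
    proteins_unique = out["proteins"].unique()
    decoy_map = {p: _all_decoy(p, decoy_prefix) for p in proteins_unique}
    out["is_decoy"] = out["proteins"].map(decoy_map)
    return out.reset_index(drop=True)


def filter_peptide_fdr_per_file(table: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Apply a peptide-level FDR cutoff separately within each raw file.

    Within a file, PSMs collapse to the best (lowest-PEP) PSM per peptide
    and peptides are ranked by ascending PEP.  The q-value at rank i is the
    decoy/target count ratio over ranks <= i, monotonized by a cumulative
    minimum from the worst rank upward; PEP ties share the worst q of the
    tie, so they pass or fail together.  All PSMs of retained peptides are
    kept.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if threshold == 1.0 or table.empty:
        return table

    best = (
        table.sort_values("pep", kind="stable")
        .drop_duplicates(["raw_file", "peptide"], keep="first")
        .sort_values(["raw_file", "pep"], kind="stable")
        .reset_index(drop=True)
    )
    grouped = best.groupby("raw_file", sort=False)
    rank = grouped.cumcount() + 1
    cum_decoy = grouped["is_decoy"].cumsum()
    cum_target = rank - cum_decoy
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(cum_target > 0, cum_decoy / cum_target, np.inf)
    best["fdr"] = fdr

    for raw_file, sub in grouped:
        if not sub["is_decoy"].any():
            logger.warning("raw file %r has no decoy peptides; q-values are 0", raw_file)

    # monotonize from worst to best within each file
    best["q"] = (
        best.iloc[::-1].groupby("raw_file", sort=False)["fdr"].cummin().iloc[::-1]
    )
    # PEP ties all pass or all fail together
    best["q"] = best.groupby(["raw_file", "pep"], sort=False)["q"].transform("max")

    passing = best.loc[best["q"] <= threshold, ["raw_file", "peptide"]]
    merged = table.merge(passing.assign(_pass=True), on=["raw_file", "peptide"], how="left")
    return (
        merged.loc[merged["_pass"].notna()]
        .drop(columns="_pass")
        .reset_index(drop=True)
    )


def collapse_to_peptides(
    table: pd.DataFrame,
    decoy_prefix: str = DECOY_PREFIX,
    use_modified: bool = False,
) -> list[PeptideEvidence]:
    """Collapse PSMs to one record per peptide sequence.

    ``best_pep`` is the minimum PEP over all PSMs; accessions are the union
    over PSMs (relevant when merging tables remapped against different
    databases); intensities are summed per experiment.  A peptide is a decoy
    only if every mapped accession is decoy-class.  Output is sorted by
    peptide so the collapse is independent of input row order.
    """
    key = "modified_peptide" if use_modified else "peptide"
    if table.empty:
        return []
    pairs = table[[key, "proteins"]].drop_duplicates()
    accessions: dict[str, set[str]] = {}
    for pep_seq, proteins in pairs.itertuples(index=False):
        accessions.setdefault(pep_seq, set()).update(proteins.split(";"))

    best_pep = table.groupby(key)["pep"].min()

    intensity: dict[str, dict[str, float]] = {}
    if table["intensity"].notna().any():
        sums = (
            table.dropna(subset=["intensity"])
            .groupby([key, "experiment"])["intensity"]
            .sum()
        )
        for (pep_seq, experiment), value in sums.items():
            intensity.setdefault(pep_seq, {})[experiment] = float(value)

    evidence = []
    for pep_seq in sorted(accessions):
        accs = frozenset(accessions[pep_seq])
        evidence.append(
            PeptideEvidence(
                peptide=pep_seq,
                best_pep=float(best_pep[pep_seq]),
                accessions=accs,
                is_decoy=all(a.startswith(decoy_prefix) for a in accs),
                intensity=intensity.get(pep_seq, {}),
            )
        )
    return evidence
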