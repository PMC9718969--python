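"""PSM table reading, remapping, per-file peptide FDR, and collapsing."""

import numpy as np
import pandas as pd
import pytest

from pickedgroups import (
    PeptideIndex,
    collapse_to_peptides,
    filter_peptide_fdr_per_file,
    read_psm_table,
    remap_peptides,
    write_psm_table,
)

from conftest import make_psm_frame


def test_maxquant_dialect_round_trip(tmp_path):
    frame = make_psm_frame(
        [
            ("AAAAAAK", "P1", "f1", 0.001, False),
            ("CCCCCCK", "P2;P3", "f1", 0.01, False),
            ("DDDDDDK", "REV__P1", "f1", 0.5, True),
            ("EEEEEEK", "P4", "f2", 0.02, False),
            ("FFFFFFK", "P5", "f2", 0.03, False),
        ]
    )
    path = tmp_path / "evidence.txt"
    write_psm_table(frame, path, dialect="maxquant_evidence")
    back = read_psm_table(path, dialect="maxquant_evidence")
    assert len(back) == 5
    assert list(back["peptide"]) == list(frame["peptide"])
    assert list(back["proteins"]) == list(frame["proteins"])
    assert list(back["is_decoy"]) == [False, False, True, False, False]
    np.testing.assert_allclose(back["pep"], frame["pep"])


def test_unparsable_peps_dropped(tmp_path, caplog):
    lines = ["Sequence\tProteins\tRaw file\tPEP"]
    for i in range(8):
        lines.append(f"PEPTIDE{i}K\tP{i}\tf1\t0.01")
    lines.append("PEPTIDEXK\tPX\tf1\tnot_a_number")
    lines.append("PEPTIDEYK\tPY\tf1\t")
    path = tmp_path / "t.tsv"
    path.write_text("\n".join(lines) + "\n")
    with caplog.at_level("WARNING"):
        table = read_psm_table(path, dialect="maxquant_evidence")
    assert len(table) == 8
    assert "dropped 2" in caplog.text


def test_missing_column_is_an_error(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("Sequence\tRaw file\n" + "AAAK\tf1\n")
    with pytest.raises(ValueError, match="PEP"):
        read_psm_table(path, dialect="maxquant_evidence")


def test_remap_replaces_accessions_and_drops_unmapped():
    table = make_psm_frame(
        [
            ("AAAAAAK", "X1", "f1", 0.001, False),
            ("CCCCCCK", "X2", "f1", 0.01, False),
        ]
    )
    index = PeptideIndex({"AAAAAAK": frozenset({"P1", "P2", "P3"})})
    out = remap_peptides(table, index)
    assert len(out) == 1
    assert out.loc[0, "proteins"] == "P1;P2;P3"
    empty = remap_peptides(table, PeptideIndex({}))
    assert empty.empty


def test_remap_decoy_flag_requires_all_decoy():
    table = make_psm_frame([("AAAAAAK", "X", "f1", 0.001, False)])
    both = PeptideIndex({"AAAAAAK": frozenset({"P1", "REV__P2"})})
    assert not remap_peptides(table, both).loc[0, "is_decoy"]
    only = PeptideIndex({"AAAAAAK": frozenset({"REV__P2"})})
    assert remap_peptides(table, only).loc[0, "is_decoy"]


def test_remap_il_equivalence():
    table = make_psm_frame([("AAIAAAK", "X", "f1", 0.001, False)])
    index = PeptideIndex({"AALAAAK": frozenset({"P1"})})
    assert remap_peptides(table, index).empty
    out = remap_peptides(table, index, il_equivalent=True)
    assert len(out) == 1 and out.loc[0, "proteins"] == "P1"


def _rank_walk_oracle(rows, threshold):
    """Independent per-file q-value computation by an explicit rank walk."""
    passing = set()
    by_file = {}
    for pep, raw, p, dec in rows:
        by_file.setdefault(raw, {})
        if pep not in by_file[raw] or p < by_file[raw][pep][0]:
            by_file[raw][pep] = (p, dec)
    for raw, best in by_file.items():
        ranked = sorted(best.items(), key=lambda kv: kv[1][0])
        fdrs = []
        d = t = 0
        for pep, (p, dec) in ranked:
            d += dec
            t += not dec
            fdrs.append(d / t if t else float("inf"))
        qs = list(fdrs)
        for i in range(len(qs) - 2, -1, -1):
            qs[i] = min(qs[i], qs[i + 1])
        # PEP ties share the worst member's q
        for i in range(len(qs)):
            worst = qs[i]
            for j in range(len(qs)):
                if ranked[j][1][0] == ranked[i][1][0]:
                    worst = max(worst, qs[j])
            if worst <= threshold:
                passing.add((raw, ranked[i][0]))
    return passing


def test_per_file_fdr_matches_rank_walk_oracle():
    rng = np.random.default_rng(42)
    rows = []
    for raw in ("f1", "f2", "f3"):
        for i in range(120):
            dec = rng.random() < 0.25
            rows.append((f"PEP{raw}{i}K", raw, float(rng.random()), dec))
    table = make_psm_frame(
        [(pep, "REV__P" if dec else "P", raw, p, dec) for pep, raw, p, dec in rows]
    )
    out = filter_peptide_fdr_per_file(table, 0.3)
    got = set(zip(out["raw_file"], out["peptide"]))
    assert got == _rank_walk_oracle(rows, 0.3)


def test_per_file_fdr_edge_cases():
    clean = make_psm_frame(
        [(f"PEP{i}K", "P", "f1", 0.001 * (i + 1), False) for i in range(20)]
    )
    # no decoys: q = 0 everywhere, everything passes
    assert len(filter_peptide_fdr_per_file(clean, 0.01)) == 20
    # threshold 1.0: table unchanged
    assert filter_peptide_fdr_per_file(clean, 1.0) is clean
    all_decoy = make_psm_frame(
        [(f"PEP{i}K", "REV__P", "f1", 0.001 * (i + 1), True) for i in range(5)]
    )
    assert filter_peptide_fdr_per_file(all_decoy, 0.5).empty


def test_per_file_fdr_monotone_in_threshold():
    rng = np.random.default_rng(3)
    table = make_psm_frame(
        [
            (
                f"PEP{i}K",
                "REV__P" if i % 4 == 0 else "P",
                "f1",
                float(rng.random()),
                i % 4 == 0,
            )
            for i in range(200)
        ]
    )
    kept = [
        set(filter_peptide_fdr_per_file(table, t)["peptide"])
        for t in (0.05, 0.1, 0.3, 0.9)
    ]
    for smaller, larger in zip(kept, kept[1:]):
        assert smaller <= larger


def test_collapse_takes_best_pep_and_is_order_independent():
    rows = [
        ("AAAAAAK", "P1", "f1", 0.01, False),
        ("AAAAAAK", "P1", "f2", 0.001, False),
        ("AAAAAAK", "P1", "f3", 0.1, False),
        ("CCCCCCK", "P2", "f1", 0.05, False),
    ]
    table = make_psm_frame(rows)
    evidence = collapse_to_peptides(table)
    assert [ev.peptide for ev in evidence] == ["AAAAAAK", "CCCCCCK"]
    assert evidence[0].best_pep == 0.001
    shuffled = make_psm_frame(rows[::-1])
    assert collapse_to_peptides(shuffled) == evidence


def test_collapse_merges_overlapping_tables():
    t1 = make_psm_frame([("AAAAAAK", "P1", "f1", 0.01, False)])
    t2 = make_psm_frame([("AAAAAAK", "P1", "f9", 0.0001, False)])
    merged = collapse_to_peptides(pd.concat([t1, t2], ignore_index=True))
    assert len(merged) == 1 and merged[0].best_pep == 0.0001


def test_collapse_sums_intensity_per_experiment():
    table = make_psm_frame(
        [
            ("AAAAAAK", "P1", "e1", 0.01, False),
            ("AAAAAAK", "P1", "e1", 0.02, False),
            ("AAAAAAK", "P1", "e2", 0.03, False),
        ]
    )
    table["intensity"] = [100.0, 50.0, 10.0]
    (ev,) = collapse_to_peptides(table)
    assert ev.intensity == {"e1": 150.0, "e2": 10.0}
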