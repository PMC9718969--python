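"""Protein grouping strategies and the rescued two-pass procedure."""

import itertools

import numpy as np
import pytest

from pickedgroups import no_grouping, rescued_subset_grouping, subset_grouping
from pickedgroups.grouping import group_proteins

from conftest import make_evidence


def test_no_grouping_one_singleton_per_observed_protein():
    evidence = make_evidence(
        [
            ("p1", 0.01, {"A"}),
            ("p2", 0.01, {"B"}),
            ("p3", 0.01, {"C", "A"}),  # shared: C still gets its own group
        ]
    )
    result = no_grouping(evidence)
    assert len(result) == 3
    assert all(len(g.member_proteins) == 1 for g in result.groups)
    assert no_grouping([]).groups == []


def test_subset_grouping_definition():
    evidence = make_evidence(
        [
            ("p1", 0.01, {"A", "B"}),
            ("p2", 0.01, {"A", "B"}),
            ("p3", 0.01, {"B"}),
        ]
    )
    result = subset_grouping(evidence)
    assert len(result) == 1
    (group,) = result.groups
    assert group.leading_proteins == ("B",)
    assert group.member_proteins == ("B", "A")


def test_subset_grouping_disjoint_and_identical():
    two = subset_grouping(make_evidence([("p1", 0.01, {"A"}), ("p2", 0.01, {"B"})]))
    assert len(two) == 2
    same = subset_grouping(make_evidence([("p1", 0.01, {"A", "B"})]))
    assert len(same) == 1
    assert same.groups[0].leading_proteins == ("A", "B")  # co-leading, alphabetical


def _oracle_subset_grouping(observed):
    """Quadratic pairwise-subset closure with the same attachment tie rule."""
    accs = sorted(observed)
    # merge identical sets
    clusters = {}
    for a in accs:
        clusters.setdefault(frozenset(observed[a]), []).append(a)
    items = list(clusters.items())
    maximal = [
        i
        for i, (s, _) in enumerate(items)
        if not any(s < s2 for s2, _ in items)
    ]
    groups = {}
    for i in maximal:
        groups[i] = list(items[i][1])
    for i, (s, members) in enumerate(items):
        if i in groups:
            continue
        hosts = [j for j in maximal if s < items[j][0]]
        best = min(hosts, key=lambda j: (-len(items[j][0]), sorted(items[j][1])[0]))
        groups[best].extend(members)
    return {frozenset(v) for v in groups.values()}


def test_subset_grouping_matches_quadratic_oracle():
    rng = np.random.default_rng(17)
    for trial in range(20):
        observed = {}
        peptides = [f"p{i}" for i in range(60)]
        for i in range(30):
            k = int(rng.integers(1, 6))
            observed[f"PR{i:02d}"] = set(rng.choice(peptides, size=k, replace=False))
        # add explicit subset/equal relations
        observed["SUB1"] = set(list(observed["PR00"])[:1])
        observed["EQ1"] = set(observed["PR01"])
        evidence_spec = {}
        for acc, peps in observed.items():
            for p in peps:
                evidence_spec.setdefault(p, set()).add(acc)
        evidence = make_evidence(
            [(p, 0.01, accs) for p, accs in evidence_spec.items()]
        )
        result = subset_grouping(evidence)
        got = {frozenset(g.member_proteins) for g in result.groups}
        assert got == _oracle_subset_grouping(observed)


def test_grouping_is_a_partition(small_db, small_index):
    import pickedgroups as pg

    cfg = pg.SimulationConfig(n_exp=3, n_prot_mean=100, n_prot_stdev=10, random_seed=2)
    table, _ = pg.simulate_dataset(small_db, small_index, cfg)
    evidence = pg.collapse_to_peptides(table)
    for strategy in ("none", "subset", "rescued_subset"):
        result = group_proteins(evidence, strategy)
        seen = [a for g in result.groups for a in g.member_proteins]
        assert len(seen) == len(set(seen))
        observed = {a for ev in evidence for a in ev.accessions}
        if strategy in ("none", "subset"):
            assert set(seen) == observed
        else:  # rescued grouping may drop proteins only observed below the cutoff
            assert set(seen) <= observed
        for g in result.groups:
            assert set(g.leading_proteins) <= set(g.member_proteins)


def _rescue_fixture():
    """Two isoforms sharing one high-confidence peptide, split by weak evidence.

    200 well-supported background proteins set the score cutoff; A and B each
    carry a weak unique peptide so plain subset grouping keeps them apart.
    """
    spec = []
    for i in range(200):
        spec.append((f"bg{i}", 1e-4, {f"T{i:03d}"}))
    for i in range(5):
        spec.append((f"dec{i}", 0.05, {f"REV__T{i:03d}X"}))
    spec.append(("shared_hi", 1e-4, {"A", "B"}))
    spec.append(("weak_a", 0.2, {"A"}))
    spec.append(("weak_b1", 0.2, {"B"}))
    spec.append(("weak_b2", 0.25, {"B"}))
    # protein C observed only through weak evidence: vanishes after the
    # internal filter and must be rescued from the first-pass grouping
    spec.append(("weak_c", 0.3, {"C"}))
    return make_evidence(spec)


def test_rescued_grouping_reunites_split_isoforms():
    evidence = _rescue_fixture()
    pg1 = subset_grouping(evidence)
    assert pg1.group_of("A") is not pg1.group_of("B")
    rescued = rescued_subset_grouping(evidence)
    group_ab = rescued.group_of("A")
    assert set(group_ab.leading_proteins) == {"A", "B"}


def test_rescued_grouping_reappends_vanished_groups():
    rescued = rescued_subset_grouping(_rescue_fixture())
    assert "C" in rescued.accession_to_group


def test_rescued_is_fixed_point_on_high_confidence_evidence():
    evidence = make_evidence(
        [(f"p{i}", 1e-4, {f"T{i}"}) for i in range(50)]
        + [("pd", 0.05, {"REV__TX"})]
    )
    pg1 = subset_grouping(evidence)
    rescued = rescued_subset_grouping(evidence)
    assert {frozenset(g.member_proteins) for g in rescued.groups} == {
        frozenset(g.member_proteins) for g in pg1.groups
    }


def test_rescued_falls_back_without_passing_groups(caplog):
    # nothing clears 1% group FDR: a decoy outscores every target
    evidence = make_evidence(
        [("p1", 0.5, {"A"}), ("p2", 0.01, {"REV__A"})]
    )
    with caplog.at_level("WARNING"):
        rescued = rescued_subset_grouping(evidence)
    assert {frozenset(g.member_proteins) for g in rescued.groups} == {
        frozenset({"A"}),
        frozenset({"REV__A"}),
    }


def test_subset_grouping_invariant_to_input_order():
    spec = [
        ("p1", 0.01, {"A", "B"}),
        ("p2", 0.02, {"B"}),
        ("p3", 0.03, {"C"}),
        ("p4", 0.04, {"C", "D"}),
    ]
    expected = None
    for perm in itertools.permutations(spec):
        result = subset_grouping(make_evidence(list(perm)))
        got = {frozenset(g.member_proteins) for g in result.groups}
        expected = got if expected is None else expected
        assert got == expected
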