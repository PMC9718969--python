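# pickedgroups

Protein group-level FDR estimation for shotgun proteomics, built around the
picked protein-group target-decoy strategy and rescued subset grouping,
together with the two instruments needed to validate any such method: an
entrapment-database builder and a multi-experiment PSM simulator with
ground-truth labels.

## Who this is for

Proteomics researchers who combine many search results — tissue atlases,
repository reanalyses, metaproteomes — and need protein-group FDRs that
stay accurate as data accumulates, and method developers who want a
self-contained benchmark for group-level FDR estimators.

## The method in brief

Peptide evidence (PEPs from a search engine or rescorer) is filtered at 1%
peptide FDR per raw file, collapsed to best evidence per peptide, and
grouped: protein *A* joins protein *B*'s group when *A*'s observed peptides
⊆ *B*'s.  **Rescued subset grouping** repeats the grouping after removing
evidence below the score equivalent to 1% group FDR — so low-confidence
peptides cannot split a group — then re-appends first-pass groups whose
proteins vanished.  Peptides still shared between groups are discarded (or
razor-assigned, for comparison).  Each group is scored by
s = −log10(min PEP) over its peptides.  The **picked group competition**
walks down the score-sorted list and eliminates any group carrying a
leading protein whose counterpart (target ↔ `REV__` decoy) was a leading
protein of an already retained, higher-scoring group; on ungrouped data
this reduces to the classic picked protein competition.  Finally

    FDR(g) = D(g) / T(g),   q(g) = min over g' with s(g') ≤ s(g) of FDR(g')

where D and T count decoy and target groups scoring at least s(g).

Validation uses (a) entrapment databases — five shuffled-peptide copies of
each target with a controlled fraction *S* of peptides shared verbatim —
and (b) simulation: per experiment, present proteins are drawn from
per-protein presence probabilities, their peptides detected with
per-peptide proteotypicities, correct scores from a truncated N(2.5, 0.7)
and incorrect scores from a truncated N(0, 0.7) on the −log10(PEP) scale.
Truth labels give the observed false discovery proportion to compare
against the reported 1%.  See `docs/methods.md` for the full model.

## Worked example

Generate a 300-protein isoform-redundant database with reversed decoys,
simulate four experiments, and run the full method from the shell:

```sh
python -c "import pickedgroups as pg; pg.make_synthetic_database(300, seed=13).write('demo.fasta')"
pickedgroups simulate --fasta demo.fasta --experiments 4 --seed 3 --out psms.tsv
pickedgroups run --preset picked_protein_group_fdr \
    --fasta demo.fasta --psms psms.tsv --dialect generic_tsv --out out
```

which prints

```
1921 simulated PSMs over 4 experiments -> psms.tsv
225 protein groups written; 223 target groups at q<=0.01
```

meaning the simulator produced 1921 peptide observations, and the pipeline
assembled them into 225 protein groups of which 223 target groups pass the
1% group-level FDR.  `out/proteinGroups.txt` lists, per group, its member
and leading proteins, peptide counts, score, FDR, q-value, and decoy /
contaminant flags:

```
Protein IDs     Leading proteins  Unique peptides  Peptide counts  Score   FDR  Q-value  Reverse  Potential contaminant
GENE000066-1    GENE000066-1      3                3               5.34    0.0  0.0
GENE000046-1    GENE000046-1      2                2               4.69    0.0  0.0
```

The same run is available from Python:

```python
import pickedgroups as pg

db = pg.make_synthetic_database(300, seed=13)
index = pg.build_peptide_index(db, pg.ENTRAPMENT_DIGEST)
table, truth = pg.simulate_dataset(db, index, pg.SimulationConfig(n_exp=4, random_seed=3,
                                                                  n_prot_mean=150, n_prot_stdev=15))
result = pg.run_method_preset([table], db, "picked_protein_group_fdr", peptide_index=index)
print(pg.empirical_fdp(result, truth, 0.01))   # observed FDP at reported 1%
```

Other subcommands: `pickedgroups entrapment` (build an entrapment FASTA),
`pickedgroups digest` (in-silico digest to TSV), `pickedgroups calibrate`
(reported-vs-observed FDR curve on simulated data).  Method presets:
`picked_protein_group_fdr`, `maxquant`, `savitski`, `savitski_classic`,
`discard_picked_group`, `razor_picked_group`, `classic_protein_group_fdr`.

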