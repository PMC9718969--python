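# Methods

## The problem

Shotgun proteomics identifies proteins indirectly, through peptide-spectrum
matches (PSMs).  When a database contains closely related sequences —
splice isoforms, SNP variants, orthologues — many peptides map to several
proteins, and proteins whose observed peptides nest inside another
protein's are conventionally merged into *protein groups*.  Estimating a
false discovery rate (FDR) for such groups is harder than for single
proteins: decoy counterparts of grouped targets are not grouped the same
way, and popular heuristics for shared peptides (Occam's razor) silently
accumulate unaccounted false positives as datasets grow.

This package implements a group-level FDR pipeline built around two ideas:
**picked-group target-decoy competition** (each group competes against the
groups carrying the decoy counterparts of its leading proteins, restoring
the symmetry between decoys and false targets) and **rescued subset
grouping** (a second grouping pass on high-confidence evidence only, so
low-confidence peptides cannot split groups, with first-pass groups
re-appended when they vanish).  It also ships the two validation
instruments needed to test any such method: an entrapment-database builder
and a multi-experiment PSM simulator with ground-truth labels.

## Pipeline stages

Input is one or more PSM tables (MaxQuant `evidence.txt` dialect or a
generic TSV).  The stages, each with the options a `MethodConfig` selects:

1. **Remap** peptides against the in-silico digest of the analysis
   database; peptides absent from the database are discarded, not rescued.
2. **Peptide-level FDR filter**, 1% by default, applied *per raw file*:
   within a file, peptides are ranked by their best PSM's posterior error
   probability (PEP); the q-value at rank *i* is the decoy/target count
   ratio over ranks ≤ *i*, monotonized by a cumulative minimum from the
   worst rank upward.  PEP ties pass or fail together.  The target-only
   denominator carries no +1 pseudo-count.
3. **Collapse** to one record per peptide sequence (best PEP, summed
   intensities per experiment).  Identity uses the plain sequence by
   default; a modified-sequence mode exists.
4. **Grouping**: `none` (every protein its own group), `subset` (a protein
   joins a group when its observed peptides are a subset of another
   protein's; identical sets are merged and co-leading), or
   `rescued_subset` (see below).
5. **Shared-peptide assignment**: `discard` drops peptides spanning
   several groups; `razor` forces each to the candidate group with the most
   unique peptides, ties broken by a seeded uniform draw.  Decoy groups
   compete in razor assignment exactly like targets — any asymmetry here
   would invalidate the decoy model.
6. **Scoring**: `best_pep` = −log10 of the group's best peptide PEP;
   `multiply_pep` = −log10 of the product of peptide PEPs, each divided by
   a constant chosen by grid search (default 10⁻⁴…10⁰ in 13 steps) to
   maximize accepted target groups; ties resolve to the larger divisor.
   Each peptide contributes its best PEP once.
7. **Target-decoy competition**: `classic` (none), `picked` (each
   target/decoy pair keeps its higher-scoring member; ties keep both), or
   `picked_group` (walking down the score-sorted list, a group is
   eliminated when a counterpart of one of its leading proteins is a
   leading protein of an already retained, higher-scoring group; groups
   with equal scores are processed as one batch and never eliminate each
   other).  On singleton groups `picked_group` and `picked` are identical.
8. **Group FDR**: after sorting by score, `fdr(g) = D(g)/T(g)` with D and
   T the decoy and target groups scoring at least as well as g (g counts
   itself in its own class — excluding it would leave the top group 0/0);
   q-values are the running minimum over worse-scoring groups, capped at 1
   in reports.  Contaminant groups are excluded from both counts but still
   receive q-values.

### Rescued subset grouping

The first pass groups all evidence (PG1) and computes the evidence-level
cutoff equivalent to 1% group FDR: with best-PEP scoring the group score is
a monotone function of its best peptide's PEP, so the lowest group score
with q ≤ 1% translates exactly into a PEP cutoff.  The second pass regroups
only evidence passing the cutoff (PG2); PG1 groups none of whose proteins
occur in PG2 are re-appended so that sub-threshold groups still get FDR
estimates.  The internal pass always uses discarded shared peptides,
best-PEP scoring, and picked-group competition regardless of the outer
configuration, so the cutoff is computed on a calibrated scale.  When
nothing reaches 1%, the procedure falls back to PG1 with a warning.

When several maximal proteins could host a subsumed protein, the host with
the most observed peptides wins, alphabetical tiebreak; mutual-subset
proteins are merged with all of them marked leading.

## Entrapment databases

An entrapment database appends known-false protein sequences so the
realized FDR can be counted directly.  Construction: digest each target
with trypsin/P and no missed cleavages; keep each peptide of length > 6
verbatim with probability *S* (creating target/entrapment shared peptides)
and otherwise replace it in place by a random permutation that fixes the
C-terminal residue; repeat to obtain five entrapment copies per target
(accessions `ENTRAP{r}__{accession}`).  Shorter fragments stay in place, so
entrapment proteins keep their source's length.  Keep/shuffle decisions are
independent Bernoulli draws by default (an exact-count mode exists); a
shuffle colliding with an existing target peptide is reshuffled up to 10
times, then accepted — collisions are rare for peptides of 7+ residues, and
the measured shared fraction at *S* = 0 doubles as the collision baseline.
Decoys for entrapment entries are made by sequence reversal like all other
decoys.

## Simulation model

Per experiment: draw the number of present proteins from
N(`n_prot_mean`, `n_prot_stdev`) (rounded, clamped to the target count);
select that many targets without replacement with probability proportional
to per-protein presence probabilities; detect each peptide of a present
protein independently with its proteotypicity; give correct peptides
scores from a normal truncated below at `min_score`, where

    min_score = Φ⁻¹(1 − peptide_fdr · (1 − incorrect_ratio) / incorrect_ratio;
                    fp_score_mean, fp_score_stdev),

so the per-experiment list sits at the configured decoy-estimated peptide
FDR.  The number of incorrect peptides is
`round(2 · n_correct · peptide_fdr / (1 − peptide_fdr))`, drawn uniformly
from the combined target+decoy peptide universe with scores from the
incorrect-score normal, truncated at the same bound.  Scores live on a
−log10(PEP) scale (PEP = 10^−score), so simulated tables flow through the
identical pipeline as real ones — there is no simulation-specific code
path.  A duplicate draw of the same peptide within an experiment keeps the
higher score.

Defaults (typical of a deep-proteome tissue series): `n_prot_mean` 10,000,
`n_prot_stdev` 1,000, correct scores N(2.5, 0.7), incorrect scores
N(0, 0.7), `incorrect_ratio` 0.6, `peptide_fdr` 0.01.

Ground truth: a peptide is recorded as correct *for* every present protein
containing it in an experiment where it was detected as a true positive.
A group then counts as a false discovery when none of its assigned peptides
is correct for any of its member proteins — the group-level null
hypothesis.  The observed false discovery proportion (FDP) among groups at
reported q ≤ 1%, divided by 0.01, is the calibration ratio; values in
[0.67, 1.5] are considered well calibrated.

### Presence probabilities

Real repositories show two patterns: some proteins appear in nearly every
experiment while others are rare, *and* a large share of database entries
(unreviewed isoforms and the like) is never correctly identified at all.
The default presence model is therefore a mixture: a *detectable* pool —
every canonical entry plus a random subset of isoforms, 60% of the database
by default — with Beta(2, 2) probabilities, and a *dark* remainder at
probability 10⁻³.  The dark pool matters for validation, not just realism:
if essentially every database entry is eventually truly detected, false
positives have nowhere to land, the data cannot express an FDP anywhere
near 1%, and calibration at that level is untestable.  The detectable pool
must comfortably exceed the per-experiment protein count, otherwise forced
sampling drags dark entries into presence.  Proteotypicities are
Beta(1.2, 3).  Both can be overridden per accession/peptide.

## The synthetic database generator

Proteins are concatenations of random tryptic-style peptides (interior
residues exclude K/R/P, terminal residue K or R), so a fully cleaved
trypsin/P digest returns exactly the designed peptides.  A gene is an
ordered peptide pool (3 + Poisson, mean 8); the canonical protein carries
the full pool; each additional isoform (geometric count, 60% of entries
are isoforms by default) deletes one contiguous *residue* substring — exon
skipping — and usually appends a novel terminal peptide.

Deleting at the residue level, rather than removing whole peptides, is
deliberate: the splice junction fuses two partial peptides into a chimeric
peptide unique to the isoform, and the same happens on the reversed decoy
sequence.  Isoforms therefore share contiguous stretches — as real splice
variants do — and the decoy database mirrors the targets' redundancy
structure: near-identical peptide counts, shared fractions, and
per-isoform novelty on both sides.  An earlier peptide-pool-subset design
broke this symmetry (deletions shifted every reversed-sequence junction,
inflating distinct decoy peptides and decoy-only novelty) and biased
decoy-based group FDR estimates conservative by a factor of ~2.5 on
otherwise identical simulations.  Features of real data the generator does
not emulate: homology across genes, missed cleavages, variable peptide
detectability by physicochemistry, intensity structure, and spectrum-level
effects — so passing tests speak to the FDR machinery, not to search-engine
behaviour.

## Numerical and tie-breaking choices

- PEPs ≤ 0 are clamped to a floor (default 10⁻²⁰) with a warning before
  taking logs.
- Sorting ties on score break by leading accession for determinism;
  competition ties retain both entries (conservative; ties have measure
  zero for continuous PEPs).
- The rescued-grouping PEP cutoff gets a 10⁻⁹ relative slack so peptides
  exactly at the boundary survive the −log10 round trip.
- Razor tie-breaks and simulation draws take explicit seeds; seedless
  calls are errors, and fixed seeds reproduce results bit for bit.
- Razor "unique" counts are computed once, before any razor assignment,
  so the outcome does not depend on peptide processing order.
- Entrapment-based FDR multiplies observed entrapment hits by
  1 + n_targets/n_entrapment to account for false positives landing in the
  original database (configurable off); groups with mixed
  original/entrapment leading proteins conservatively count as not
  observed-false.

## Problem sizes used by the test suite

The acceptance-style tests run at desk scale chosen to keep the qualitative
regimes intact: entrapment recovery on 200–500 proteins; calibration on a
20,000-protein isoform-redundant database with ten simulated experiments at
the default parameters; and the razor breakdown on a 4,000-protein database
with 400 experiments of ~2,000 proteins each — the database-to-proteome
ratio, not absolute size, is what drives these behaviours.

## Known limitations

- Picked-group competition is a heuristic: adversarial group compositions
  can be constructed where a one-protein false target eliminates a large
  decoy group.  Calibration holds because competing groups are
  compositionally similar in practice; no mitigation is attempted.
- The razor breakdown at hundreds of experiments leaves "essentially zero"
  groups at 1% true FDR; whether the count is exactly zero depends on the
  single top-ranked group, a coin-flip at desk scale.
- Gene-level FDR roll-up, probabilistic peptide apportionment, and
  quantification beyond pass-through intensity sums are out of scope.
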