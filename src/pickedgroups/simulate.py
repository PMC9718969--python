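"""Multi-experiment peptide-list simulation with correct/incorrect labels.

Each experiment draws a number of present proteins from a normal
distribution, selects them without replacement according to per-protein
presence probabilities, and detects each of their peptides independently
with a per-peptide proteotypicity.  Correct peptide scores come from a
truncated normal; incorrect (false positive) peptides are drawn uniformly
from the combined target+decoy peptide universe with scores from a second
truncated normal.  Both distributions are truncated at the score
corresponding to the configured peptide-level FDR, so the simulated lists
mimic per-experiment FDR-filtered search output.  Scores live on a
``-log10(PEP)`` scale, so the standard pipeline consumes simulated tables
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .fasta import PeptideIndex, SequenceDatabase


@dataclass
class SimulationConfig:
    """Simulation parameters.

    Defaults are typical of a deep-proteome experiment series: roughly
    10,000 +/- 1,000 proteins present per experiment, correct scores
    N(2.5, 0.7) and incorrect scores N(0, 0.7) on the -log10(PEP) scale, a
    60% incorrect ratio before FDR filtering, and a 1% peptide FDR per
    experiment.
    """

    n_exp: int = 10
    n_prot_mean: float = 10_000.0
    n_prot_stdev: float = 1_000.0
    tp_score_mean: float = 2.5
    tp_score_stdev: float = 0.7
    fp_score_mean: float = 0.0
    fp_score_stdev: float = 0.7
    incorrect_ratio: float = 0.6
    peptide_fdr: float = 0.01
    protein_probs: dict[str, float] | None = None
    peptide_probs: dict[str, float] | None = None
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_exp <= 0:
            raise ValueError("n_exp must be positive")
        if not 0 < self.incorrect_ratio < 1:
            raise ValueError("incorrect_ratio must be in (0, 1)")
        if not 0 < self.peptide_fdr < 1:
            raise ValueError("peptide_fdr must be in (0, 1)")
        if self.tp_score_stdev <= 0 or self.fp_score_stdev <= 0:
            raise ValueError("score stdevs must be positive")


def min_score_for_fdr(cfg: SimulationConfig) -> float:
    """Score threshold matching the configured peptide FDR.

    The inverse normal CDF of the incorrect-score distribution evaluated at
    ``1 - peptide_fdr * (1 - incorrect_ratio) / incorrect_ratio``.
    """
    quantile = 1.0 - cfg.peptide_fdr * (1.0 - cfg.incorrect_ratio) / cfg.incorrect_ratio
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile {quantile} outside (0, 1)")
    return float(
        stats.norm.ppf(quantile, loc=cfg.fp_score_mean, scale=cfg.fp_score_stdev)
    )


def default_detection_probs(
    db: SequenceDatabase,
    index: PeptideIndex,
    seed: int,
    detectable_fraction: float = 0.6,
    dark_prob: float = 1e-3,
) -> tuple[dict[str, float], dict[str, float]]:
    """Heterogeneous presence/proteotypicity probabilities.

    Presence probabilities are a two-component mixture over the target
    entries: a *detectable* pool — every canonical form plus a random
    subset of isoforms up to ``detectable_fraction`` of the database — with
    Beta(2, 2) probabilities, and a *dark* remainder at ``dark_prob``,
    emulating the unreviewed/isoform entries of large sequence databases
    that are essentially never observed.  This reproduces the two
    qualitative patterns repository data show: some proteins appear in
    almost every experiment while others are rare, and a large share of
    database entries is never correctly identified at all.  Peptide
    detection probabilities (proteotypicity) are Beta(1.2, 3).  All values
    are drawn once from ``seed``.
    """
    rng = np.random.default_rng(seed)
    targets = db.accessions("target")
    canonical = [a for a in targets if a.endswith("-1")]
    isoforms = [a for a in targets if not a.endswith("-1")]
    n_detectable = max(int(round(detectable_fraction * len(targets))), len(canonical))
    n_extra = min(n_detectable - len(canonical), len(isoforms))
    extra = (
        list(rng.choice(np.array(isoforms, dtype=object), size=n_extra, replace=False))
        if n_extra > 0
        else []
    )
    detectable = set(canonical) | set(extra)
    protein_probs = {}
    betas = iter(rng.beta(2.0, 2.0, size=len(targets)))
    for acc in targets:
        protein_probs[acc] = float(next(betas)) if acc in detectable else dark_prob
    peptides = index.peptides()
    peptide_probs = dict(zip(peptides, rng.beta(1.2, 3.0, size=len(peptides))))
    return protein_probs, peptide_probs


def _truncnorm(
    rng: np.random.Generator, lower: float, mean: float, stdev: float, size: int
) -> np.ndarray:
    a = (lower - mean) / stdev
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=stdev, size=size, random_state=rng)


class _IndexArrays:
    """Flat array views of a peptide index for fast per-experiment sampling."""

    def __init__(self, db: SequenceDatabase, index: PeptideIndex):
        self.peptides = np.array(index.peptides(), dtype=object)
        pep_id = {p: i for i, p in enumerate(self.peptides)}
        self.proteins_str = np.array(
            [";".join(sorted(index[p])) for p in self.peptides], dtype=object
        )
        decoy_prefix = db.decoy_prefix
        self.is_decoy = np.array(
            [all(a.startswith(decoy_prefix) for a in index[p]) for p in self.peptides],
            dtype=bool,
        )
        self.target_accs = np.array(db.accessions("target"), dtype=object)
        acc_id = {a: i for i, a in enumerate(self.target_accs)}

        rows, cols = [], []  # (peptide, target protein) incidence
        for p, accs in index.items():
            for a in accs:
                if a in acc_id:
                    rows.append(pep_id[p])
                    cols.append(acc_id[a])
        self.incidence = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(len(self.peptides), len(self.target_accs)),
        )
        # per-protein peptide id lists, flattened
        by_col = self.incidence.tocsc()
        self.prot_pep_ids = by_col.indices
        self.prot_offsets = by_col.indptr


def simulate_dataset(
    db: SequenceDatabase,
    index: PeptideIndex,
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, frozenset[str]]]:
    """Simulate per-experiment peptide lists.

    Returns a PSM table in the canonical layout (one raw file per
    experiment, ``pep = 10**-score``) with an extra boolean ``is_correct``
    column, together with the ground truth: for every peptide, the set of
    target proteins that were present in at least one experiment in which
    the peptide was correctly detected.
    """
    if cfg.random_seed is None:
        raise ValueError("an explicit random_seed is required")
    if len(index) == 0:
        raise ValueError("empty peptide index")
    rng = np.random.default_rng(cfg.random_seed)
    arrays = _IndexArrays(db, index)
    n_targets = len(arrays.target_accs)
    if n_targets == 0:
        raise ValueError("database contains no target proteins")

    if cfg.protein_probs is None or cfg.peptide_probs is None:
        protein_probs, peptide_probs = default_detection_probs(
            db, index, seed=cfg.random_seed
        )
    else:
        protein_probs, peptide_probs = cfg.protein_probs, cfg.peptide_probs
    prot_p = np.array([protein_probs[a] for a in arrays.target_accs])
    pep_p = np.array([peptide_probs[p] for p in arrays.peptides])

    min_score = min_score_for_fdr(cfg)
    draw_weights = prot_p / prot_p.sum()

    frames = []
    truth_pairs: list[np.ndarray] = []
    for exp in range(cfg.n_exp):
        raw_file = f"exp{exp:04d}"
        n_prot = int(round(rng.normal(cfg.n_prot_mean, cfg.n_prot_stdev)))
        n_prot = min(max(n_prot, 1), n_targets)
        present = rng.choice(n_targets, size=n_prot, replace=False, p=draw_weights)

        # candidate peptide ids of present proteins (shared peptides may
        # appear several times; each (protein, peptide) pair is an
        # independent detection opportunity)
        spans = [
            arrays.prot_pep_ids[arrays.prot_offsets[i] : arrays.prot_offsets[i + 1]]
            for i in present
        ]
        candidates = np.concatenate(spans) if spans else np.empty(0, dtype=np.int64)
        detected = candidates[rng.random(len(candidates)) < pep_p[candidates]]
        tp_ids = np.unique(detected)
        tp_scores = _truncnorm(
            rng, min_score, cfg.tp_score_mean, cfg.tp_score_stdev, len(tp_ids)
        )

        # ground truth: a present protein counts as a correct source for
        # every detected peptide it contains
        if len(tp_ids):
            present_mask = np.zeros(n_targets, dtype=bool)
            present_mask[present] = True
            coo = arrays.incidence[tp_ids].tocoo()
            keep = present_mask[coo.col]
            truth_pairs.append(
                np.stack([tp_ids[coo.row[keep]], coo.col[keep]])
            )

        n_fp = int(round(2.0 * len(tp_ids) * cfg.peptide_fdr / (1.0 - cfg.peptide_fdr)))
        fp_ids = rng.integers(0, len(arrays.peptides), size=n_fp)
        fp_scores = _truncnorm(
            rng, min_score, cfg.fp_score_mean, cfg.fp_score_stdev, n_fp
        )

        ids = np.concatenate([tp_ids, fp_ids])
        scores = np.concatenate([tp_scores, fp_scores])
        correct = np.zeros(len(ids), dtype=bool)
        correct[: len(tp_ids)] = True
        frame = pd.DataFrame(
            {
                "peptide": arrays.peptides[ids],
                "modified_peptide": "",
                "proteins": arrays.proteins_str[ids],
                "raw_file": raw_file,
                "experiment": raw_file,
                "pep": np.power(10.0, -scores),
                "score": scores,
                "intensity": np.nan,
                "is_decoy": arrays.is_decoy[ids],
                "is_correct": correct,
            }
        )
        # a false positive duplicating a correct peptide keeps the higher score
        frame = (
            frame.sort_values(["score", "is_correct"], ascending=False, kind="stable")
            .drop_duplicates("peptide", keep="first")
            .reset_index(drop=True)
        )
        frames.append(frame)

    table = pd.concat(frames, ignore_index=True)

    truth: dict[str, frozenset[str]] = {}
    if truth_pairs:
        pairs = np.unique(np.concatenate(truth_pairs, axis=1), axis=1)
        collected: dict[str, set[str]] = {}
        for pep_id, acc_id in pairs.T:
            collected.setdefault(arrays.peptides[pep_id], set()).add(
                arrays.target_accs[acc_id]
            )
        truth = {p: frozenset(a) for p, a in collected.items()}
    return table, truth
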