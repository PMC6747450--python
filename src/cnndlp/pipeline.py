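"""Cross-validation protocol and novel-candidate prediction.

Five-fold cross-validation over the known associations: positives are
shuffled and split into five near-equal subsets; for each fold the test
positives are removed from the association matrix and every A-derived
similarity (L, L1, D1 and the fusions) is recomputed from the masked
matrix, so no test association leaks into training features. Training uses
the fold's positive pairs plus an equal number of randomly sampled
negative pairs; the test set is the fold's positives plus all negative
pairs (the literal protocol; training negatives can optionally be
excluded from the test set to measure the mild bias this induces).

Novel prediction trains on all known positives and ranks, per disease,
every unknown pair by its fused score.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .embedding import build_embedding_batch
from .evaluation import DEFAULT_KS, EvalReport, per_disease_report, summarize
from .model import DualModel, ModelConfig, fuse_scores
from .netio import DiseaseOntology, HeterogeneousNetwork, RankedPredictions
from .similarity import compute_bundle

__all__ = [
    "FoldSplit",
    "make_folds",
    "sample_negatives",
    "run_fold",
    "cross_validate",
    "predict_novel",
]


@dataclasses.dataclass
class FoldSplit:
    """One fold: index-pair lists for train/test positives and train negatives."""

    fold: int
    train_positives: np.ndarray  # (n, 2) of (lncRNA, disease) indices
    test_positives: np.ndarray
    train_negatives: np.ndarray
    seed: int


def make_folds(A: np.ndarray, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Shuffle all positives with ``seed`` and split into k near-equal folds.

    Each fold's training negatives are sampled (same seed stream) to match
    the number of its training positives, disjoint from all positives.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    A = np.asarray(A)
    positives = np.argwhere(A == 1)
    if len(positives) < k:
        raise ValueError(f"need at least k={k} positives, found {len(positives)}")
    rng = np.random.default_rng(seed)
    positives = positives[rng.permutation(len(positives))]
    chunks = np.array_split(positives, k)
    pos_set = {tuple(p) for p in positives}
    folds = []
    for f, test in enumerate(chunks):
        train = np.vstack([c for g, c in enumerate(chunks) if g != f])
        negs = sample_negatives(
            A, exclude=pos_set, n=len(train), seed=int(rng.integers(2**31))
        )
        folds.append(
            FoldSplit(
                fold=f,
                train_positives=train,
                test_positives=test,
                train_negatives=negs,
                seed=seed,
            )
        )
    return folds


def sample_negatives(
    A: np.ndarray, exclude: set[tuple[int, int]], n: int, seed: int = 0
) -> np.ndarray:
    """Sample n distinct zero entries of A, avoiding ``exclude``."""
    A = np.asarray(A)
    zeros = np.argwhere(A == 0)
    if exclude:
        keep = np.array([tuple(z) not in exclude for z in zeros])
        zeros = zeros[keep]
    if n > len(zeros):
        raise ValueError(f"requested {n} negatives but only {len(zeros)} available")
    rng = np.random.default_rng(seed)
    return zeros[rng.choice(len(zeros), size=n, replace=False)]


def _mask_self_entries(X: np.ndarray, Y: np.ndarray, pairs: np.ndarray, nl: int) -> None:
    """Zero each training pair's own association entry inside its embeddings.

    A pair's embedding contains A[i, j] twice (row 1 at the disease block,
    row 2 at the lncRNA block); for training positives that entry is the
    label itself and the model learns to read it instead of generalizable
    structure. Test pairs carry 0 there anyway, so masking aligns the
    training inputs with the inference-time ones.
    """
    idx = np.arange(len(pairs))
    for Z in (X, Y):
        Z[idx, 0, nl + pairs[:, 1]] = 0.0
        Z[idx, 1, pairs[:, 0]] = 0.0


def _masked_A(A: np.ndarray, test_positives: np.ndarray) -> np.ndarray:
    A_train = np.asarray(A, float).copy()
    if len(test_positives):
        A_train[test_positives[:, 0], test_positives[:, 1]] = 0.0
    return A_train


def _test_pairs(
    A: np.ndarray, fold: FoldSplit, exclude_train_negatives: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Fold test set: the fold's positives plus all negative pairs."""
    negatives = np.argwhere(np.asarray(A) == 0)
    if exclude_train_negatives:
        train_neg = {tuple(p) for p in fold.train_negatives}
        negatives = negatives[[tuple(p) not in train_neg for p in negatives]]
    pairs = np.vstack([fold.test_positives, negatives])
    labels = np.concatenate(
        [np.ones(len(fold.test_positives)), np.zeros(len(negatives))]
    )
    return pairs, labels


def run_fold(
    network: HeterogeneousNetwork,
    ontology: DiseaseOntology,
    config: ModelConfig,
    fold: FoldSplit,
    exclude_train_negatives: bool = False,
) -> dict:
    """Train on one fold and score its test pairs.

    Test positives are zeroed out of A before any A-derived similarity is
    computed and before any embedding is built, so the trained model never
    observes them. Returns the test pairs with left/right/fused scores and
    labels.
    """
    A_train = _masked_A(network.A, fold.test_positives)
    bundle = compute_bundle(
        network, ontology, alpha=config.alpha, beta=config.beta, A_override=A_train
    )
    train_pairs = np.vstack([fold.train_positives, fold.train_negatives])
    train_labels = np.concatenate(
        [np.ones(len(fold.train_positives)), np.zeros(len(fold.train_negatives))]
    )

    def embed(pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = build_embedding_batch(bundle.L, A_train, bundle.D, network.B, network.C, pairs)
        Y = build_embedding_batch(bundle.Lc, A_train, bundle.Dc, network.B, network.C, pairs)
        return X, Y

    X_train, Y_train = embed(train_pairs)
    _mask_self_entries(X_train, Y_train, train_pairs, network.n_lncrna)
    n_cols = network.n_lncrna + network.n_disease + network.n_mirna
    model = DualModel(n_cols, dataclasses.replace(config, seed=config.seed + fold.fold))
    model.fit(X_train, Y_train, train_labels)

    test_pairs, test_labels = _test_pairs(network.A, fold, exclude_train_negatives)
    X_test, Y_test = embed(test_pairs)
    score_left, score_right, score = model.score(X_test, Y_test)
    return {
        "fold": fold.fold,
        "pairs": test_pairs,
        "labels": test_labels,
        "score_left": score_left,
        "score_right": score_right,
        "score": score,
    }


def cross_validate(
    network: HeterogeneousNetwork,
    ontology: DiseaseOntology,
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
    ks: tuple[int, ...] = DEFAULT_KS,
    exclude_train_negatives: bool = False,
    lam_ablation: bool = True,
) -> dict:
    """Full k-fold cross-validation.

    Returns a dict with the fused-score :class:`EvalReport` under
    ``"report"`` and, when ``lam_ablation`` is set, reports for the
    left-branch-only (lambda=1) and right-branch-only (lambda=0) scorers
    computed from the same trained models.
    """
    folds = make_folds(network.A, k=k, seed=seed)
    results = [
        run_fold(network, ontology, config, fold, exclude_train_negatives)
        for fold in folds
    ]
    out: dict = {"folds": folds, "fold_results": results}
    variants = {"report": config.lam}
    if lam_ablation:
        variants.update({"report_left_only": 1.0, "report_right_only": 0.0})
    for name, lam in variants.items():
        out[name] = _combine(results, lam, ks, seed, k)
    return out


def _combine(results: list[dict], lam: float, ks, seed: int, k: int) -> EvalReport:
    frames, all_d, all_s, all_y = [], [], [], []
    for r in results:
        scores = fuse_scores(r["score_left"], r["score_right"], lam)
        diseases = r["pairs"][:, 1]
        frames.append(
            per_disease_report(diseases, scores, r["labels"], ks=ks, fold=r["fold"])
        )
        all_d.append(diseases)
        all_s.append(scores)
        all_y.append(r["labels"])
    per_disease = pd.concat(frames, ignore_index=True)
    return summarize(
        per_disease,
        np.concatenate(all_d),
        np.concatenate(all_s),
        np.concatenate(all_y),
        ks,
        seed,
        k,
    )


def predict_novel(
    network: HeterogeneousNetwork,
    ontology: DiseaseOntology,
    config: ModelConfig,
    top_n: int = 50,
    seed: int = 0,
) -> RankedPredictions:
    """Train on all known positives and rank unknown pairs per disease."""
    A = network.A
    positives = np.argwhere(A == 1)
    pos_set = {tuple(p) for p in positives}
    negatives = sample_negatives(A, exclude=pos_set, n=len(positives), seed=seed)
    bundle = compute_bundle(network, ontology, alpha=config.alpha, beta=config.beta)

    def embed(pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = build_embedding_batch(bundle.L, A, bundle.D, network.B, network.C, pairs)
        Y = build_embedding_batch(bundle.Lc, A, bundle.Dc, network.B, network.C, pairs)
        return X, Y

    train_pairs = np.vstack([positives, negatives])
    train_labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    X_train, Y_train = embed(train_pairs)
    _mask_self_entries(X_train, Y_train, train_pairs, network.n_lncrna)
    n_cols = network.n_lncrna + network.n_disease + network.n_mirna
    model = DualModel(n_cols, config)
    model.fit(X_train, Y_train, train_labels)

    unknown = np.argwhere(A == 0)
    _, _, scores = model.score(*embed(unknown))
    rows: list[tuple[str, str, float, int, bool]] = []
    for j in range(network.n_disease):
        mask = unknown[:, 1] == j
        if not mask.any():
            continue  # every lncRNA already known for this disease
        cand = unknown[mask]
        cand_scores = scores[mask]
        order = np.argsort(-cand_scores, kind="stable")[:top_n]
        for rank, idx in enumerate(order, start=1):
            rows.append(
                (
                    network.disease_ids[j],
                    network.lncrna_ids[cand[idx][0]],
                    float(cand_scores[idx]),
                    rank,
                    False,
                )
            )
    return RankedPredictions(rows=rows)
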