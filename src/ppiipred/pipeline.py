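"""Dataset splitting, fivefold cross-validation, the proline-window
baseline, and high-scoring-region extraction."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import brnn
from .brnn import BRNNModel, TrainConfig


@dataclass
class SplitPlan:
    test_ids: list[str]
    folds: list[list[str]]
    seed: int


@dataclass
class ScoredRegion:
    id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    mean_score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def split_every_tenth(ids: Sequence[str]):
    """Every 10th id (positions 10, 20, ... 1-based) goes to the test set."""
    ids = list(ids)
    test = ids[9::10]
    test_set = set(test)
    train = [i for i in ids if i not in test_set]
    return train, test


def make_folds(train_ids: Sequence[str], k: int = 5, seed: int = 0):
    """Seeded random permutation dealt round-robin into k folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = list(train_ids)
    if len(ids) < k:
        raise ValueError(f"cannot make {k} folds from {len(ids)} ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(perm):
        folds[pos % k].append(ids[idx])
    return folds


@dataclass
class CrossvalResult:
    models: list[BRNNModel]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    fold_histories: list[list] = field(default_factory=list)


def run_crossval(corpus: dict, config: TrainConfig, k: int = 5,
                 folds: Optional[list[list[str]]] = None,
                 verbose: bool = False) -> CrossvalResult:
    """Fivefold cross-validation over an encoded, labelled corpus.

    ``corpus`` maps id -> (FeatureMatrix, labels).  Each fold is held out
    once for validation (it also drives the learning-rate schedule, as
    the validation set monitors training progress without tuning
    parameters); predictions on held-out folds are pooled.  The k
    trained models form the ensemble.
    """
    ids = list(corpus.keys())
    if folds is None:
        folds = make_folds(ids, k=k, seed=config.seed)
    input_dim = next(iter(corpus.values()))[0].width
    models = []
    histories = []
    pooled_s: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []
    for fi, fold in enumerate(folds):
        held = set(fold)
        train_data = [corpus[i] for i in ids if i not in held]
        val_data = [corpus[i] for i in fold]
        model = brnn.init_model(input_dim, hidden_dim=config.hidden_dim,
                                mlp_hidden=config.mlp_hidden,
                                seed=config.seed + fi)
        model, hist = brnn.train(model, train_data, config,
                                 validation=val_data, verbose=verbose)
        models.append(model)
        histories.append(hist)
        for feats, labels in val_data:
            pooled_s.append(brnn.forward(model, feats))
            pooled_y.append(np.asarray(labels))
    return CrossvalResult(models=models,
                          pooled_scores=np.concatenate(pooled_s),
                          pooled_labels=np.concatenate(pooled_y),
                          fold_histories=histories)


def proline_window_score(seq: str, halfwidth: int) -> np.ndarray:
    """Fraction of prolines in the window of ``halfwidth`` residues to
    either side of each position; truncated windows are normalized by
    their actual size so scores stay in [0, 1]."""
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    n = len(seq)
    is_p = np.array([1.0 if c.upper() == "P" else 0.0 for c in seq])
    cum = np.concatenate([[0.0], np.cumsum(is_p)])
    scores = np.empty(n)
    for j in range(n):
        lo = max(0, j - halfwidth)
        hi = min(n, j + halfwidth + 1)
        scores[j] = (cum[hi] - cum[lo]) / (hi - lo)
    return scores


def high_scoring_regions(scores, cutoff: float = 0.5,
                         min_len_exclusive: int = 3,
                         seq_id: str = "") -> list[ScoredRegion]:
    """Maximal runs of score >= cutoff with length strictly greater than
    ``min_len_exclusive``, sorted by mean score descending."""
    s = np.asarray(scores, float)
    regions = []
    n = len(s)
    i = 0
    while i < n:
        if s[i] >= cutoff:
            j = i
            while j + 1 < n and s[j + 1] >= cutoff:
                j += 1
            if (j - i + 1) > min_len_exclusive:
                regions.append(ScoredRegion(id=seq_id, start=i + 1, end=j + 1,
                                            mean_score=float(s[i:j + 1].mean())))
            i = j + 1
        else:
            i += 1
    regions.sort(key=lambda r: r.mean_score, reverse=True)
    return regions


def planted_benchmark(seed: int = 1, n_sequences: int = 500,
                      single_epochs: int = 200, cv_epochs: int = 80,
                      hidden_dim: int = 8, verbose: bool = False) -> dict:
    """Scaled-down learning benchmark on the planted-rule corpus.

    Generates the synthetic corpus, holds out every 10th sequence, trains
    one model at full epoch count plus a fivefold cross-validated
    ensemble at a reduced epoch count, and evaluates everything on the
    held-out split alongside the proline-window baseline.
    """
    from .evalmetrics import auc_score
    from .features import encode_sequence
    from .synthetic import CorpusSpec, make_corpus

    corpus = make_corpus(CorpusSpec(n_sequences=n_sequences, seed=seed))
    by_id = {c.id: c for c in corpus}
    train_ids, test_ids = split_every_tenth([c.id for c in corpus])
    enc = {c.id: (encode_sequence(c.seq, seq_id=c.id), np.asarray(c.labels))
           for c in corpus}
    test_data = [enc[i] for i in test_ids]
    test_labels = np.concatenate([y for _, y in test_data])

    cfg = TrainConfig(epochs=single_epochs, hidden_dim=hidden_dim,
                      mlp_hidden=hidden_dim, seed=seed)
    model = brnn.init_model(enc[train_ids[0]][0].width, hidden_dim=hidden_dim,
                            mlp_hidden=hidden_dim, seed=seed)
    model, _ = brnn.train(model, [enc[i] for i in train_ids], cfg,
                          validation=test_data, verbose=verbose)
    single_scores = np.concatenate([brnn.forward(model, f) for f, _ in test_data])
    single_auc = auc_score(single_scores, test_labels)

    cv_cfg = TrainConfig(epochs=cv_epochs, hidden_dim=hidden_dim,
                         mlp_hidden=hidden_dim, seed=seed)
    cv = run_crossval({i: enc[i] for i in train_ids}, cv_cfg, verbose=verbose)
    member_aucs = []
    for m in cv.models:
        s = np.concatenate([brnn.forward(m, f) for f, _ in test_data])
        member_aucs.append(auc_score(s, test_labels))
    ens_scores = np.concatenate(
        [brnn.ensemble_predict(cv.models, f) for f, _ in test_data])
    ensemble_auc = auc_score(ens_scores, test_labels)
    cv_pooled_auc = auc_score(cv.pooled_scores, cv.pooled_labels)

    best_w, baseline_auc, per_w = best_proline_window(
        [(by_id[i].seq, by_id[i].labels) for i in test_ids])
    return {
        "single_auc": single_auc,
        "member_aucs": member_aucs,
        "ensemble_auc": ensemble_auc,
        "cv_pooled_auc": cv_pooled_auc,
        "baseline_best_w": best_w,
        "baseline_auc": baseline_auc,
        "baseline_auc_per_w": per_w,
        "n_test_sequences": len(test_ids),
        "n_test_residues": int(len(test_labels)),
    }


def best_proline_window(sequences: Sequence[tuple], max_halfwidth: int = 9):
    """Scan halfwidths 0..max and return (best_w, best_auc, per_w_auc).

    ``sequences`` holds (seq, labels) pairs; AUC is computed over the
    pooled residues.
    """
    from .evalmetrics import auc_score

    labels = np.concatenate([np.asarray(y) for _, y in sequences])
    per_w = {}
    for w in range(max_halfwidth + 1):
        scores = np.concatenate([proline_window_score(s, w) for s, _ in sequences])
        per_w[w] = auc_score(scores, labels)
    best_w = max(per_w, key=per_w.get)
    return best_w, per_w[best_w], per_w
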