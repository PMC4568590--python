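"""Linear SVM over the four conservation features.

Training sets follow the pipeline's rules: positives are annotated small
ORFs (at most 101 codons) from a curated small-protein list with alignment
coverage and positive selection score, minus a user-supplied exclusion list
of fast-evolving peptides; negatives are ORFs on classical ncRNAs with
alignment coverage and no CDS overlap.  Features are whitened to zero mean
and unit variance before the max-margin fit; error rates come from 100
50/50 resampling runs, and score cutoffs from the minimum-average-error
point of the ROC curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

log = logging.getLogger(__name__)


@dataclass
class TrainingSets:
    positives: list[str]
    negatives: list[str]
    exclusion_list: list[str] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"ids in both classes: {sorted(overlap)[:5]}")


@dataclass
class LinearModel:
    mean: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    bias: float
    threshold: float = 0.0

    def margin(self, X: np.ndarray) -> np.ndarray:
        Xw = (np.asarray(X, dtype=float) - self.mean) / self.scale
        return Xw @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.margin(X) >= self.threshold

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist(),
                "weights": self.weights.tolist(), "bias": self.bias,
                "threshold": self.threshold}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(mean=np.array(d["mean"]), scale=np.array(d["scale"]),
                   weights=np.array(d["weights"]), bias=float(d["bias"]),
                   threshold=float(d.get("threshold", 0.0)))


def build_training_sets(catalog, features: dict[str, "np.ndarray"],
                        curated_small_protein_ids: set[str],
                        exclusion_list: set[str] | None = None,
                        coverage: dict[str, float] | None = None,
                        cds_overlap_bp: dict[str, int] | None = None,
                        max_codons: int = 101) -> TrainingSets:
    """Assemble positive and negative training ids from a classified ORF
    catalog.

    ``features`` maps orf_id -> feature array whose first entry is the
    selection score; ``coverage`` maps orf_id -> best species coverage
    fraction (any positive value counts as "some alignment coverage").
    """
    exclusion_list = exclusion_list or set()
    coverage = coverage or {}
    cds_overlap_bp = cds_overlap_bp or {}
    pos, neg = [], []
    for orf in catalog:
        if orf.id not in features:
            continue
        cov = coverage.get(orf.id, 0.0)
        score = features[orf.id][0]
        if (orf.category == "annotated" and orf.n_codons <= max_codons
                and orf.id in curated_small_protein_ids and cov > 0
                and score > 0 and orf.id not in exclusion_list):
            pos.append(orf.id)
        elif (orf.category == "ncRNA" and cov > 0
              and cds_overlap_bp.get(orf.id, 0) == 0):
            neg.append(orf.id)
    if not pos or not neg:
        raise ValueError(
            f"empty training class (positives={len(pos)}, "
            f"negatives={len(neg)})")
    return TrainingSets(positives=pos, negatives=neg,
                        exclusion_list=sorted(exclusion_list))


def fit(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> LinearModel:
    """Whiten features on the training data and fit a linear max-margin
    classifier; y is boolean (True = positive)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if y.sum() < 10 or (~y).sum() < 10:
        raise ValueError("need >= 10 examples per class")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    degenerate = scale <= 0
    if degenerate.any():
        log.warning("constant feature(s) %s; scale set to 1",
                    np.where(degenerate)[0].tolist())
        scale = np.where(degenerate, 1.0, scale)
    Xw = (X - mean) / scale
    # C is interpreted per-sample-average so that duplicating the training
    # set leaves the objective (and hence the model) unchanged
    svc = LinearSVC(C=C * 100.0 / len(y), loss="squared_hinge",
                    max_iter=200000, tol=1e-10)
    svc.fit(Xw, y.astype(int))
    return LinearModel(mean=mean, scale=scale,
                       weights=svc.coef_.ravel().copy(),
                       bias=float(svc.intercept_[0]))


def cross_validate(X_pos: np.ndarray, X_neg: np.ndarray, runs: int = 100,
                   p_train: float = 0.5, seed: int = 0, C: float = 1.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Resampling error estimate: each run assigns every example to the
    training set with probability ``p_train``, fits, and evaluates FNR and
    FPR on the held-out remainder.  Runs with an empty held-out or training
    class are redrawn (logged)."""
    rng = np.random.default_rng(seed)
    X_pos, X_neg = np.asarray(X_pos, float), np.asarray(X_neg, float)
    fnr, fpr = [], []
    done = 0
    while done < runs:
        pos_train = rng.random(len(X_pos)) < p_train
        neg_train = rng.random(len(X_neg)) < p_train
        if (pos_train.all() or neg_train.all()
                or not pos_train.any() or not neg_train.any()):
            log.info("redrawing resampling run with an empty class")
            continue
        Xtr = np.vstack([X_pos[pos_train], X_neg[neg_train]])
        ytr = np.concatenate([np.ones(pos_train.sum(), bool),
                              np.zeros(neg_train.sum(), bool)])
        try:
            model = fit(Xtr, ytr, C=C)
        except ValueError:
            log.info("redrawing resampling run with too few examples")
            continue
        fnr.append(float((~model.predict(X_pos[~pos_train])).mean()))
        fpr.append(float(model.predict(X_neg[~neg_train]).mean()))
        done += 1
    return np.array(fnr), np.array(fpr)


def roc_min_avg_error_cutoff(pos_scores, neg_scores) -> float:
    """Threshold minimizing (FNR + FPR) / 2; a score >= threshold is called
    positive.  Candidates are the unique scores and the midpoints between
    consecutive sorted unique scores; ties pick the smallest threshold."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("empty score set")
    uniq = np.unique(np.concatenate([pos, neg]))
    candidates = np.unique(np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2])
                           if uniq.size > 1 else uniq)
    best_t, best_err = None, np.inf
    for t in candidates:
        fnr = float((pos < t).mean())
        fpr = float((neg >= t).mean())
        err = (fnr + fpr) / 2
        if err < best_err - 1e-12:
            best_err, best_t = err, float(t)
    return best_t
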