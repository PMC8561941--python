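"""Negative sampling, dataset assembly and the five supported classifiers.

Negatives are unannotated (entry-0) lncRNA-disease cells of the binary
association matrix, drawn uniformly without replacement — the conventional
assumption that unconfirmed pairs are (mostly) true negatives.  Classifiers
run with library defaults; only the random seed is fixed, plus a single
worker thread where the library exposes one, so scores are reproducible.
"LR" denotes logistic regression: a regression on {0, 1} labels used as a
classifier, the standard reading in this literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ContractError, EntityLookupError
from .integrate import IntegratedFeatures, pair_vector
from .linear_features import AssociationMatrix

CLASSIFIER_KINDS = ("LR", "NB", "RF", "ADB", "XGB")

Pair = tuple[str, str]


@dataclass(frozen=True)
class LabeledDataset:
    samples: tuple[Pair, ...]
    X: np.ndarray
    y: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if not (len(self.samples) == self.X.shape[0] == self.y.shape[0]):
            raise ContractError("samples, X and y must have equal length")
        if len(set(self.samples)) != len(self.samples):
            raise ContractError("duplicate pair key in dataset")


def sample_negatives(
    matrix: AssociationMatrix,
    n: int,
    seed: int,
    restrict_to: tuple[Sequence[str] | None, Sequence[str] | None] | None = None,
) -> list[Pair]:
    """Draw ``n`` distinct unannotated pairs uniformly without replacement.

    ``restrict_to`` optionally limits the candidate lncRNAs and/or diseases.
    """
    if n < 0:
        raise ContractError(f"n must be >= 0, got {n}")
    rows = np.arange(len(matrix.row_names))
    cols = np.arange(len(matrix.col_names))
    if restrict_to is not None:
        lncs, diss = restrict_to
        if lncs is not None:
            ridx = matrix.row_index
            rows = np.array(sorted(ridx[name] for name in lncs))
        if diss is not None:
            cidx = matrix.col_index
            cols = np.array(sorted(cidx[name] for name in diss))
    sub = matrix.values[np.ix_(rows, cols)]
    zr, zc = np.nonzero(sub == 0)
    if n > zr.size:
        raise ContractError(
            f"requested {n} negatives but only {zr.size} unannotated pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zr.size, size=n, replace=False)
    return [
        (matrix.row_names[rows[zr[c]]], matrix.col_names[cols[zc[c]]])
        for c in chosen
    ]


def build_dataset(
    positives: Sequence[Pair],
    negatives: Sequence[Pair],
    feats: IntegratedFeatures,
    seed: int,
) -> LabeledDataset:
    """Label positives 1 and negatives 0, featurize via pair vectors, and
    shuffle rows reproducibly."""
    overlap = set(positives) & set(negatives)
    if overlap:
        raise ContractError(f"pair(s) labeled both 0 and 1: {sorted(overlap)[:3]}")
    pairs = list(positives) + list(negatives)
    y = np.concatenate(
        [np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)]
    )
    X = np.stack([pair_vector(feats, l, d) for l, d in pairs])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return LabeledDataset(
        tuple(pairs[i] for i in order), X[order], y[order], seed=seed
    )


def make_classifier(kind: str, seed: int):
    """Instantiate one of the five supported classifiers with defaults."""
    if kind == "LR":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(random_state=seed)
    if kind == "NB":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB()
    if kind == "RF":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if kind == "ADB":
        from sklearn.ensemble import AdaBoostClassifier

        return AdaBoostClassifier(random_state=seed)
    if kind == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, n_jobs=1)
    raise ContractError(
        f"unknown classifier kind {kind!r}; supported: {', '.join(CLASSIFIER_KINDS)}"
    )


def train_classifier(dataset: LabeledDataset, kind: str = "XGB", seed: int = 0):
    """Fit a scorer exposing probability-like scores in [0, 1]."""
    if len(np.unique(dataset.y)) < 2:
        raise ContractError("dataset must contain both classes")
    model = make_classifier(kind, seed)
    model.fit(dataset.X, dataset.y)
    return model


def score_pairs(
    scorer, feats: IntegratedFeatures, pairs: Sequence[Pair]
) -> np.ndarray:
    """Positive-class score per pair, order-preserving with the input."""
    if len(pairs) == 0:
        return np.empty(0)
    for l, d in pairs:
        if l not in feats.lnc:
            raise EntityLookupError(l, "integrated lncRNA features")
        if d not in feats.dis:
            raise EntityLookupError(d, "integrated disease features")
    X = np.stack([pair_vector(feats, l, d) for l, d in pairs])
    return scorer.predict_proba(X)[:, 1]
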