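"""Random-forest classification of cohort samples on the exonic signature.

The evaluation primitive is a stratified 70/30 split repeated with distinct
seeds; each repeat trains a forest (default 5000 trees, all features
considered at every split, mirroring an mtry-of-all-variables forest) and
reports out-of-bag error on the training block plus accuracy and per-class
sensitivity on the test block.  Unclassifiable (U) samples never enter
training; they are assigned by averaging class probabilities over the
repeated forests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .types import SampleInfo

NEAR_TIE_MARGIN = 0.05


@dataclass
class RfConfig:
    n_trees: int = 5000
    mtry: int | str = "all"
    train_fraction: float = 0.70
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    @property
    def max_features(self):
        return None if self.mtry == "all" else int(self.mtry)


@dataclass
class RfReport:
    oob_error: float
    oob_error_sd: float
    test_accuracy: float
    test_accuracy_sd: float
    per_class_sensitivity: dict[str, float]
    n_repeats: int
    classes: list[str]
    dropped_samples: list[str] = field(default_factory=list)
    missing_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "oob_error": self.oob_error,
            "oob_error_sd": self.oob_error_sd,
            "test_accuracy": self.test_accuracy,
            "test_accuracy_sd": self.test_accuracy_sd,
            "per_class_sensitivity": self.per_class_sensitivity,
            "n_repeats": self.n_repeats,
            "classes": self.classes,
            "dropped_samples": self.dropped_samples,
            "missing_features": self.missing_features,
        }


def build_feature_matrix(
    logcpm: np.ndarray,
    exon_ids: list[str],
    signature: set[str],
    samples: list[SampleInfo],
):
    """Restrict log-CPM to signature exons and split known vs unknown samples.

    Returns (features, labels, known_ids, unknown_features, unknown_ids,
    dropped_ids, missing_exons).  Samples with any non-finite feature value
    are dropped; U samples are returned separately and never labelled.
    """
    if not signature:
        raise ValueError("signature is empty")
    sig_idx = [i for i, e in enumerate(exon_ids) if e in signature]
    missing = sorted(signature - set(exon_ids))
    X_all = np.asarray(logcpm, dtype=float)[sig_idx].T  # samples x features
    finite = np.all(np.isfinite(X_all), axis=1)
    dropped = [s.sample_id for s, ok in zip(samples, finite) if not ok]
    known_mask = np.array([s.group != "U" for s in samples]) & finite
    unknown_mask = np.array([s.group == "U" for s in samples]) & finite
    if not known_mask.any():
        raise ValueError("all labelled samples were dropped")
    features = X_all[known_mask]
    labels = np.array([s.group for s, k in zip(samples, known_mask) if k])
    known_ids = [s.sample_id for s, k in zip(samples, known_mask) if k]
    unknown_features = X_all[unknown_mask]
    unknown_ids = [s.sample_id for s, k in zip(samples, unknown_mask) if k]
    return features, labels, known_ids, unknown_features, unknown_ids, dropped, missing


def _one_split_forest(features, labels, config: RfConfig, seed: int):
    rng = np.random.RandomState(seed)
    for _ in range(100):
        tr_X, te_X, tr_y, te_y = train_test_split(
            features,
            labels,
            train_size=config.train_fraction,
            stratify=labels,
            random_state=rng.randint(2 ** 31 - 1),
        )
        if set(tr_y) == set(labels):
            break
    else:
        raise RuntimeError("could not draw a split containing every class")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(tr_X, tr_y)
    return forest, te_X, te_y


def train_eval_split(features: np.ndarray, labels: np.ndarray, config: RfConfig) -> RfReport:
    """Repeated stratified 70/30 random-forest evaluation."""
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    oobs, accs = [], []
    sens: dict[str, list[float]] = {c: [] for c in classes}
    for r in range(config.n_repeats):
        forest, te_X, te_y = _one_split_forest(features, labels, config, config.seed + r)
        oobs.append(1.0 - forest.oob_score_)
        pred = forest.predict(te_X)
        accs.append(float(np.mean(pred == te_y)))
        for c in classes:
            mask = te_y == c
            if mask.any():
                sens[c].append(float(np.mean(pred[mask] == c)))
    return RfReport(
        oob_error=float(np.mean(oobs)),
        oob_error_sd=float(np.std(oobs)),
        test_accuracy=float(np.mean(accs)),
        test_accuracy_sd=float(np.std(accs)),
        per_class_sensitivity={c: float(np.mean(v)) if v else float("nan") for c, v in sens.items()},
        n_repeats=config.n_repeats,
        classes=classes,
    )


def classify_unknowns(
    features: np.ndarray,
    labels: np.ndarray,
    unknown_features: np.ndarray,
    config: RfConfig,
):
    """Assign unknown samples by mean class probability over repeated forests.

    Each repeat trains an independent forest on the full labelled block; the
    per-sample class probabilities are averaged.  The assigned class is the
    argmax; when the top two mean probabilities differ by less than 0.05 a
    near-tie flag marks the sample as effectively unassignable.
    Returns (mean_probabilities, classes, assigned, near_tie_flags).
    """
    if unknown_features.shape[1] != features.shape[1]:
        raise ValueError(
            f"unknown samples have {unknown_features.shape[1]} features, "
            f"training has {features.shape[1]}"
        )
    classes = sorted(set(labels))
    probs = np.zeros((unknown_features.shape[0], len(classes)))
    for r in range(config.n_repeats):
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.max_features,
            random_state=config.seed + r,
            n_jobs=1,
        )
        forest.fit(features, labels)
        p = forest.predict_proba(unknown_features)
        # align column order to the sorted class list
        col = [list(forest.classes_).index(c) for c in classes]
        probs += p[:, col]
    probs /= config.n_repeats
    assigned = [classes[i] for i in np.argmax(probs, axis=1)]
    top2 = np.sort(probs, axis=1)[:, -2:]
    near_tie = (top2[:, 1] - top2[:, 0]) < NEAR_TIE_MARGIN
    return probs, classes, assigned, near_tie
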