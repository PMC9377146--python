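"""Two-stage random-forest biomarker classifiers.

A preliminary forest (mtry=2, 1001 trees) is trained on all candidate
features; features with a permutation-importance z-score above 2 seed a
refined forest with fewer features.  Accuracy is reported as the
Mann-Whitney AUC on a held-out 40% test split with a stratified-bootstrap
percentile confidence interval.  Candidate features are expected to be
restricted by the caller to taxa significant for the trait of interest,
computed on the training split only so the test set never leaks into
feature selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)


@dataclass
class ClassifierReport:
    preliminary_features: list
    refined_features: list
    importances: pd.Series           # z-scores from the preliminary stage
    auc: float
    ci: tuple[float, float]
    test_scores: pd.Series
    test_labels: pd.Series
    split_seed: int
    fallback_used: bool = False
    oob_score: float | None = None


def stratified_split(
    labels: pd.Series, train_fraction: float = 0.6, seed: int = 0
) -> tuple[list, list]:
    """Deterministic stratified train/test split preserving class proportions."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    train, test = [], []
    for cls in classes:
        ids = list(labels.index[labels == cls])
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        rng.shuffle(ids)
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return sorted(train), sorted(test)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: concordant pairs, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1] if labels.dtype.kind in "biu" else scores[labels == labels.max()]
    neg = scores[labels != 1] if labels.dtype.kind in "biu" else scores[labels != labels.max()]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI of the test AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos_idx = np.where(labels == labels.max())[0]
    neg_idx = np.where(labels != labels.max())[0]
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise ValueError("need at least two members per class")
    if n_boot < 2:
        warnings.warn("n_boot < 2 yields a degenerate interval", stacklevel=2)
    rng = np.random.default_rng(seed)
    aucs = np.empty(max(n_boot, 1))
    redraws = 0
    for b in range(max(n_boot, 1)):
        while True:
            p = rng.choice(pos_idx, size=len(pos_idx), replace=True)
            n = rng.choice(neg_idx, size=len(neg_idx), replace=True)
            idx = np.concatenate([p, n])
            if len(np.unique(labels[idx])) == 2:
                break
            redraws += 1
        aucs[b] = roc_auc(scores[idx], labels[idx])
    if redraws:
        logger.info("bootstrap_auc_ci: %d degenerate resamples redrawn", redraws)
    lo = float(np.quantile(aucs, (1 - level) / 2))
    hi = float(np.quantile(aucs, 1 - (1 - level) / 2))
    return lo, hi


def permutation_importance_z(
    model: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean-decrease-accuracy z-scores: mean drop / standard error over repeats."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    base = (model.predict(X) == y).mean()
    z = np.zeros(X.shape[1])
    for jf in range(X.shape[1]):
        # stack all repeats into one matrix: a single predict call per feature
        stacked = np.tile(X, (n_repeats, 1))
        for r in range(n_repeats):
            stacked[r * n:(r + 1) * n, jf] = rng.permutation(X[:, jf])
        correct = (model.predict(stacked) == np.tile(y, n_repeats))
        drops = base - correct.reshape(n_repeats, n).mean(axis=1)
        se = drops.std(ddof=1) / np.sqrt(n_repeats)
        mean = drops.mean()
        if se == 0:
            z[jf] = np.inf if mean > 0 else 0.0
        else:
            z[jf] = mean / se
    return z


def train_two_stage_rf(
    features: pd.DataFrame,
    labels: pd.Series,
    test_features: pd.DataFrame | None = None,
    test_labels: pd.Series | None = None,
    mtry: int = 2,
    n_trees: int = 1001,
    importance_cut: float = 2.0,
    n_boot: int = 2000,
    importance_repeats: int = 10,
    seed: int = 0,
) -> ClassifierReport:
    """Two-stage random forest: fit, select by importance z > cut, refit.

    ``features`` is samples x features (training split).  If a test split is
    supplied the report carries its AUC and a stratified-bootstrap CI;
    otherwise AUC is computed on out-of-bag votes.  If no feature exceeds
    the importance cut, the refined stage reuses all preliminary features
    (warned).
    """
    X = features.to_numpy(dtype=float)
    y_codes, classes = pd.factorize(labels, sort=True)
    if len(classes) != 2:
        raise ValueError("two-class labels required")
    rng = np.random.default_rng(seed)
    rf_seed = int(rng.integers(0, 2**31 - 1))
    stage1 = RandomForestClassifier(
        n_estimators=n_trees, max_features=min(mtry, X.shape[1]),
        oob_score=True, random_state=rf_seed, n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stage1.fit(X, y_codes)
    z = permutation_importance_z(stage1, X, y_codes, n_repeats=importance_repeats,
                                 seed=int(rng.integers(0, 2**31 - 1)))
    importances = pd.Series(z, index=features.columns, name="importance_z")
    selected = list(features.columns[z > importance_cut])
    fallback = False
    if not selected:
        warnings.warn("no feature exceeded the importance cut; refined stage uses all "
                      "preliminary features", stacklevel=2)
        selected = list(features.columns)
        fallback = True
    stage2 = RandomForestClassifier(
        n_estimators=n_trees, max_features=min(mtry, len(selected)),
        oob_score=True, random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stage2.fit(features[selected].to_numpy(dtype=float), y_codes)

    if test_features is not None and test_labels is not None:
        Xt = test_features[selected].to_numpy(dtype=float)
        yt = pd.factorize(test_labels, sort=True)[0]
        scores = stage2.predict_proba(Xt)[:, 1]
        auc = roc_auc(scores, yt)
        if min((yt == 1).sum(), (yt == 0).sum()) >= 2:
            ci = bootstrap_auc_ci(scores, yt, n_boot=n_boot,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        else:
            warnings.warn("test class with fewer than 2 members; no bootstrap CI",
                          stacklevel=2)
            ci = (float("nan"), float("nan"))
        score_index, label_series = test_features.index, pd.Series(yt, index=test_features.index)
    else:
        scores = stage2.oob_decision_function_[:, 1]
        yt = y_codes
        auc = roc_auc(scores, yt)
        ci = bootstrap_auc_ci(scores, yt, n_boot=n_boot,
                              seed=int(rng.integers(0, 2**31 - 1)))
        score_index, label_series = features.index, pd.Series(yt, index=features.index)
    return ClassifierReport(
        preliminary_features=list(features.columns),
        refined_features=selected,
        importances=importances,
        auc=auc,
        ci=ci,
        test_scores=pd.Series(scores, index=score_index, name="score"),
        test_labels=label_series,
        split_seed=seed,
        fallback_used=fallback,
        oob_score=float(stage1.oob_score_),
    )


def log_relative_features(counts: pd.DataFrame, sf: pd.Series,
                          pseudocount: float = 1e-6) -> pd.DataFrame:
    """Feature transform: size-factor-normalized relative abundance, log10.

    Returns samples x taxa, ready for the classifier.
    """
    norm = counts / sf.loc[counts.columns]
    rel = norm / norm.sum(axis=0)
    return np.log10(rel + pseudocount).T
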