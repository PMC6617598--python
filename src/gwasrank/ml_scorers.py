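"""Machine-learning per-SNP scorers: 1-way MDR, entropy gain, decision trees.

These scorers treat the 0/1/2 genotype as a categorical feature and make no
encoding assumption, which lets them pick up non-additive architectures
(e.g. heterozygote-advantage or overdominant loci) that a fixed encoding
can miss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from gwasrank.genotype_io import MISSING, PHENO_CASE, PHENO_CONTROL

_GENOTYPES = (0, 1, 2)


@dataclass
class RiskModel:
    """Per-genotype high/low risk labels for a 1-way MDR model.

    A genotype is high risk when its case:control ratio strictly exceeds
    the overall case:control ratio of the training data. Ties and
    genotypes unseen in training are labeled low risk.
    """

    labels: dict[int, str]
    n_cases: int
    n_controls: int
    counts: dict[int, tuple[int, int]]

    @classmethod
    def fit(cls, calls: np.ndarray, phenotype: np.ndarray) -> "RiskModel":
        calls = np.asarray(calls)
        pheno = np.asarray(phenotype)
        ok = calls != MISSING
        case = ok & (pheno == PHENO_CASE)
        ctrl = ok & (pheno == PHENO_CONTROL)
        n_cases = int(case.sum())
        n_controls = int(ctrl.sum())
        if n_cases == 0 or n_controls == 0:
            raise ValueError("both phenotype classes required in training data")
        labels: dict[int, str] = {}
        counts: dict[int, tuple[int, int]] = {}
        for g in _GENOTYPES:
            gc = int((case & (calls == g)).sum())
            gn = int((ctrl & (calls == g)).sum())
            if gc + gn == 0:
                continue
            counts[g] = (gc, gn)
            # cross-multiplied comparison: gc/gn > n_cases/n_controls
            labels[g] = "high" if gc * n_controls > gn * n_cases else "low"
        return cls(labels, n_cases, n_controls, counts)

    def predict_case(self, calls: np.ndarray) -> np.ndarray:
        """True where the genotype's risk label is high (unseen -> low)."""
        calls = np.asarray(calls)
        out = np.zeros(calls.shape, dtype=bool)
        for g, label in self.labels.items():
            if label == "high":
                out |= calls == g
        return out


def _stratified_folds(pheno: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold id per sample: per-class seeded shuffle, then round-robin."""
    rng = np.random.default_rng(seed)
    fold_id = np.full(pheno.shape, -1, dtype=int)
    for cls in (PHENO_CASE, PHENO_CONTROL):
        idx = np.flatnonzero(pheno == cls)
        idx = rng.permutation(idx)
        fold_id[idx] = np.arange(len(idx)) % folds
    return fold_id


def _balanced_accuracy(y_true_case: np.ndarray, y_pred_case: np.ndarray) -> float:
    tp = int((y_true_case & y_pred_case).sum())
    fn = int((y_true_case & ~y_pred_case).sum())
    tn = int((~y_true_case & ~y_pred_case).sum())
    fp = int((~y_true_case & y_pred_case).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return 0.5 * (sens + spec)


def mdr_1way(calls: np.ndarray, phenotype: np.ndarray, folds: int = 10,
             seed: int = 0) -> float:
    """Cross-validated balanced accuracy of the 1-way MDR risk model.

    For each fold a :class:`RiskModel` is fit on the training samples and
    used to classify the held-out fold (high-risk genotype -> case); the
    fold's balanced accuracy is (sensitivity + specificity)/2 and the
    returned score is the mean over folds. ``folds=1`` trains and tests on
    the full data (the resubstitution estimate). Folds are stratified by
    phenotype with seed-determined assignment; folds where a phenotype
    class is absent are skipped with a warning.
    """
    calls = np.asarray(calls)
    pheno = np.asarray(phenotype)
    usable = (calls != MISSING) & np.isin(pheno, [PHENO_CASE, PHENO_CONTROL])
    calls = calls[usable]
    pheno = pheno[usable]
    n = len(calls)
    if folds < 1:
        raise ValueError("folds must be >= 1")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n_samples={n}")
    if not ((pheno == PHENO_CASE).any() and (pheno == PHENO_CONTROL).any()):
        raise ValueError("both phenotype classes required")

    if folds == 1:
        model = RiskModel.fit(calls, pheno)
        pred = model.predict_case(calls)
        return _balanced_accuracy(pheno == PHENO_CASE, pred)

    fold_id = _stratified_folds(pheno, folds, seed)
    scores = []
    for f in range(folds):
        test = fold_id == f
        train = ~test
        y_test = pheno[test] == PHENO_CASE
        if not (y_test.any() and (~y_test).any()):
            warnings.warn(f"fold {f}: one phenotype class absent, skipped")
            continue
        try:
            model = RiskModel.fit(calls[train], pheno[train])
        except ValueError:
            warnings.warn(f"fold {f}: degenerate training data, skipped")
            continue
        pred = model.predict_case(calls[test])
        scores.append(_balanced_accuracy(y_test, pred))
    if not scores:
        raise ValueError("no usable folds")
    return float(np.mean(scores))


def entropy_gain(calls: np.ndarray, phenotype: np.ndarray) -> float:
    """Information gain H(Y) - H(Y|G) about the phenotype, in bits.

    Plug-in (empirical) probabilities with the 0*log0 = 0 convention. For a
    binary phenotype this equals the mutual information I(G; Y) and lies in
    [0, 1] bits.
    """
    calls = np.asarray(calls)
    pheno = np.asarray(phenotype)
    usable = (calls != MISSING) & np.isin(pheno, [PHENO_CASE, PHENO_CONTROL])
    calls = calls[usable]
    pheno = pheno[usable]
    n = len(calls)
    if n == 0:
        raise ValueError("no usable samples")
    y = pheno == PHENO_CASE
    if not (y.any() and (~y).any()):
        raise ValueError("both phenotype classes required")

    def entropy_bits(counts: np.ndarray) -> float:
        counts = counts[counts > 0]
        p = counts / counts.sum()
        return float(-(p * np.log2(p)).sum())

    h_y = entropy_bits(np.array([y.sum(), (~y).sum()]))
    h_y_given_g = 0.0
    for g in _GENOTYPES:
        sel = calls == g
        ng = int(sel.sum())
        if ng == 0:
            continue
        h_y_given_g += (ng / n) * entropy_bits(
            np.array([(y & sel).sum(), (~y & sel).sum()])
        )
    return max(0.0, h_y - h_y_given_g)


_TREE_GRID = {
    "criterion": ["gini", "entropy"],
    "min_impurity_decrease": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5],
}


def decision_tree_score(calls: np.ndarray, phenotype: np.ndarray,
                        seed: int = 0) -> float:
    """Held-out score of a single-feature decision tree for one SNP.

    The data is split 75/25 (stratified); hyperparameters (criterion in
    {gini, entropy}, min_impurity_decrease in {0, 0.1, ..., 0.5}) are
    selected by 5-fold cross-validation on the training part with the
    r-squared score on the 0/1 labels as the quality measure; the selected
    tree's classification accuracy on the 25% held-out split is returned.
    If a split leaves a class empty it is re-drawn with an incremented
    seed, at most 5 times.
    """
    from sklearn.model_selection import (
        GridSearchCV,
        StratifiedKFold,
        train_test_split,
    )
    from sklearn.tree import DecisionTreeClassifier

    calls = np.asarray(calls)
    pheno = np.asarray(phenotype)
    usable = (calls != MISSING) & np.isin(pheno, [PHENO_CASE, PHENO_CONTROL])
    X = calls[usable].astype(float)[:, None]
    y = (pheno[usable] == PHENO_CASE).astype(int)
    if len(y) < 8:
        raise ValueError("too few samples for a 75/25 split with 5-fold CV")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both phenotype classes required")

    last_err: Exception | None = None
    for attempt in range(5):
        s = seed + attempt
        try:
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=0.25, stratify=y, random_state=s
            )
            if y_tr.sum() in (0, len(y_tr)) or y_te.sum() in (0, len(y_te)):
                raise ValueError("class absent from a split")
            cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=s)
            search = GridSearchCV(
                DecisionTreeClassifier(random_state=s),
                _TREE_GRID,
                scoring="r2",
                cv=cv,
            )
            search.fit(X_tr, y_tr)
            return float(search.best_estimator_.score(X_te, y_te))
        except ValueError as err:
            last_err = err
    raise ValueError(f"could not form valid splits after 5 attempts: {last_err}")
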