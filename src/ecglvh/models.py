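"""Supervised LVH classification and its evaluation protocol.

Three classifiers — L2 logistic regression, Gaussian-kernel SVM and a
bagged random forest — are trained on the z-scored, class-balanced
training split and evaluated on the untouched 20 % test split with
accuracy, sensitivity, specificity and the rank-statistic AUC, plus
10-fold cross-validated training metrics.  A centre-rotation harness
refits the whole pipeline on geographic-centre partitions of the cohort
as an internal robustness check.

The public surface follows the statsmodels idiom: build an
:class:`LvhClassificationModel` from a cohort dataframe, call ``fit``,
inspect the returned :class:`LvhClassificationResults` (``summary()``,
``metrics``, ``cv_metrics``, ``confusion``...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .features import FeaturePreprocessor, split_and_balance

#: Centre-rotation partitions: (train centres, test centres).
CENTRE_ROTATION = (
    (("Cheadle", "Newcastle"), ("Reading", "Bristol")),
    (("Newcastle", "Reading", "Bristol"), ("Cheadle",)),
    (("Cheadle", "Reading", "Bristol"), ("Newcastle",)),
)

SVM_GRID = {"C": [0.5, 2.0, 8.0], "gamma": ["scale", 0.05, 0.2]}
RF_GRID = {"max_depth": [4, 8, None], "max_features": ["sqrt", 0.5]}
RF_TREES = 200


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann–Whitney rank statistic.

    Equals the fraction of (positive, negative) pairs in which the
    positive scores higher, counting ties as half.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(s)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def classification_metrics(y_true: np.ndarray, scores: np.ndarray,
                           threshold: float = 0.5) -> dict:
    """Accuracy/sensitivity/specificity at a probability threshold + AUC."""
    y = np.asarray(y_true).astype(int)
    pred = (np.asarray(scores) >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
        "auc": rank_auc(y, scores),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }


# ---------------------------------------------------------------------------
# Trainers (sklearn estimators behind a stable surface)
# ---------------------------------------------------------------------------

def _feasible_folds(y: np.ndarray, requested: int) -> int:
    """Largest usable stratified fold count (≤ requested)."""
    counts = np.bincount(np.asarray(y).astype(int))
    m = int(counts[counts > 0].min())
    if m < 2 or len(counts[counts > 0]) < 2:
        raise ValueError(
            "training set needs at least two records of each class")
    return min(requested, m)


def train_logistic(X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Weakly L2-regularised logistic regression on standardised data."""
    clf = LogisticRegression(C=100.0, max_iter=2000, random_state=seed)
    return clf.fit(X, y)


def train_svm(X: np.ndarray, y: np.ndarray, seed: int = 0, cv: int = 3):
    """RBF-kernel SVM; C and gamma from a small CV grid on the training
    folds; Platt-style sigmoid calibration (fitted on training folds)
    turns margins into the probabilities needed for AUC/thresholding."""
    cv = _feasible_folds(y, cv)
    base = SVC(kernel="rbf", random_state=seed)
    search = GridSearchCV(base, SVM_GRID, cv=cv, scoring="roc_auc", n_jobs=1)
    search.fit(X, y)
    calibrated = CalibratedClassifierCV(
        SVC(kernel="rbf", random_state=seed, **search.best_params_),
        method="sigmoid", cv=cv, ensemble=False)
    return calibrated.fit(X, y)


def train_rf(X: np.ndarray, y: np.ndarray, seed: int = 0, cv: int = 3):
    """Bagged random forest; depth and features-per-split tuned by CV."""
    cv = _feasible_folds(y, cv)
    base = RandomForestClassifier(n_estimators=RF_TREES, bootstrap=True,
                                  random_state=seed, n_jobs=1)
    search = GridSearchCV(base, RF_GRID, cv=cv, scoring="roc_auc", n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_


TRAINERS = {"logistic": train_logistic, "svm": train_svm, "rf": train_rf}


def evaluate(clf, X_test: np.ndarray, y_test: np.ndarray) -> dict:
    """Test-set metrics at the 0.5 probability threshold."""
    scores = clf.predict_proba(X_test)[:, 1]
    return classification_metrics(y_test, scores)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class LvhClassificationResults:
    """Fitted-model report: held-out metrics, CV summary, artefacts."""

    method: str
    metrics: dict
    cv_metrics: Optional[pd.DataFrame]
    hyperparameters: dict
    seed: int
    n_train: int
    n_test: int
    features: list[str]
    coefficients: Optional[pd.Series] = None
    ranking: Optional[pd.Series] = None
    estimator: object = field(default=None, repr=False)
    preprocessor: FeaturePreprocessor = field(default=None, repr=False)
    test_scores: Optional[np.ndarray] = field(default=None, repr=False)
    test_labels: Optional[np.ndarray] = field(default=None, repr=False)

    def roc_points(self) -> pd.DataFrame:
        """ROC curve of the held-out scores (threshold, fpr, tpr)."""
        if self.test_scores is None:
            raise ValueError("no stored test scores")
        order = np.argsort(-self.test_scores)
        y = self.test_labels[order]
        tpr = np.concatenate([[0.0], np.cumsum(y) / max(y.sum(), 1)])
        fpr = np.concatenate([[0.0],
                              np.cumsum(1 - y) / max((1 - y).sum(), 1)])
        thr = np.concatenate([[np.inf], self.test_scores[order]])
        return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})

    def plot_roc(self, ax=None):
        """Plot the held-out ROC curve (matplotlib axes returned)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        pts = self.roc_points()
        ax.plot(pts["fpr"], pts["tpr"],
                label=f"{self.method} (AUC {self.auc:.2f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 − specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax

    @property
    def auc(self) -> float:
        return self.metrics["auc"]

    @property
    def confusion(self) -> dict:
        return self.metrics["confusion"]

    def summary(self) -> str:
        lines = [
            f"LVH classification — {self.method}",
            "=" * 44,
            f"train n (balanced): {self.n_train}    test n: {self.n_test}",
            f"features retained:  {len(self.features)}    seed: {self.seed}",
            "-" * 44,
            f"test accuracy:      {self.metrics['accuracy']:.3f}",
            f"test sensitivity:   {self.metrics['sensitivity']:.3f}",
            f"test specificity:   {self.metrics['specificity']:.3f}",
            f"test AUC:           {self.metrics['auc']:.3f}",
        ]
        if self.cv_metrics is not None:
            m = self.cv_metrics.mean()
            lines += ["-" * 44,
                      f"10-fold CV (train): acc {m['accuracy']:.3f}, "
                      f"sens {m['sensitivity']:.3f}, spec {m['specificity']:.3f}, "
                      f"AUC {m['auc']:.3f}"]
        if self.coefficients is not None:
            top = self.coefficients.abs().sort_values(ascending=False).head(5)
            lines += ["-" * 44, "largest |coefficients|:"]
            lines += [f"  {name:24s} {self.coefficients[name]:+.3f}"
                      for name in top.index]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "method": self.method, "seed": self.seed,
            "n_train": self.n_train, "n_test": self.n_test,
            "features": list(self.features),
            "hyperparameters": self.hyperparameters,
            "metrics": {k: v for k, v in self.metrics.items()},
        }
        if self.cv_metrics is not None:
            out["cv_mean"] = self.cv_metrics.mean().to_dict()
        return out


class LvhClassificationModel:
    """Cohort-level LVH classification experiment.

    Parameters
    ----------
    data : DataFrame
        One row per participant, containing the feature columns, the
        binary label column and (optionally) a centre column.
    features : sequence of str
        Feature columns offered to the classifier (before QC).
    label : str
        Binary label column name.
    centre : str, optional
        Centre column used by :meth:`centre_rotation`.
    """

    def __init__(self, data: pd.DataFrame, features: Sequence[str],
                 label: str = "lvh", centre: Optional[str] = "centre"):
        self.data = data.reset_index(drop=True)
        self.features = list(features)
        self.label = label
        self.centre = centre if centre in data.columns else None
        missing = [c for c in self.features if c not in data.columns]
        if missing:
            raise KeyError(f"feature columns absent from data: {missing}")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, features: Sequence[str],
                       label: str = "lvh",
                       centre: Optional[str] = "centre",
                       ) -> "LvhClassificationModel":
        return cls(data, features, label=label, centre=centre)

    # -- fitting ----------------------------------------------------------

    def _fit_on(self, train_idx: pd.Index, test_idx: pd.Index, method: str,
                seed: int, do_cv: bool) -> LvhClassificationResults:
        df = self.data
        y = df[self.label].astype(int)
        prep = FeaturePreprocessor(seed=seed)
        X_tr = prep.fit_transform(df.loc[train_idx, self.features],
                                  y.loc[train_idx])
        X_te = prep.transform(df.loc[test_idx, self.features])
        y_tr = y.loc[X_tr.index].to_numpy()
        y_te = y.loc[test_idx].to_numpy()

        clf = TRAINERS[method](X_tr.to_numpy(), y_tr, seed=seed)
        scores = clf.predict_proba(X_te.to_numpy())[:, 1]
        metrics = classification_metrics(y_te, scores)

        cv_df = None
        if do_cv:
            cv_df = self._cross_validate(X_tr.to_numpy(), y_tr, method, seed)

        coefs = None
        if method == "logistic":
            coefs = pd.Series(clf.coef_[0], index=X_tr.columns)
        hyper = {k.split("__")[-1]: v for k, v in clf.get_params().items()
                 if k.split("__")[-1] in ("C", "gamma", "max_depth",
                                          "max_features", "n_estimators")}
        return LvhClassificationResults(
            method=method, metrics=metrics, cv_metrics=cv_df,
            hyperparameters=hyper, seed=seed,
            n_train=len(X_tr), n_test=len(test_idx),
            features=list(X_tr.columns), coefficients=coefs,
            ranking=prep.ranking_, estimator=clf, preprocessor=prep,
            test_scores=scores, test_labels=y_te,
        )

    @staticmethod
    def _cross_validate(X: np.ndarray, y: np.ndarray, method: str,
                        seed: int, folds: int = 10) -> Optional[pd.DataFrame]:
        # each CV training part still needs >= 2 per class for the
        # trainers' internal grids
        folds = min(folds, int(np.bincount(y).min()) // 2)
        if folds < 2:
            return None
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        rows = []
        for tr, va in skf.split(X, y):
            clf = TRAINERS[method](X[tr], y[tr], seed=seed)
            m = evaluate(clf, X[va], y[va])
            rows.append({k: m[k] for k in
                         ("accuracy", "sensitivity", "specificity", "auc")})
        return pd.DataFrame(rows)

    def fit(self, method: str = "logistic", seed: int = 0,
            do_cv: bool = True) -> LvhClassificationResults:
        """Stratified 80/20 split, balanced training, fit and evaluate."""
        train_idx, test_idx = split_and_balance(self.data, self.label,
                                                seed=seed)
        return self._fit_on(train_idx, test_idx, method, seed, do_cv)

    def fit_all(self, seed: int = 0, do_cv: bool = False,
                ) -> dict[str, LvhClassificationResults]:
        """Fit all three classifiers on the same split."""
        train_idx, test_idx = split_and_balance(self.data, self.label,
                                                seed=seed)
        return {m: self._fit_on(train_idx, test_idx, m, seed, do_cv)
                for m in TRAINERS}

    # -- centre rotation ---------------------------------------------------

    def centre_rotation(self, method: str = "svm", seed: int = 0,
                        rotation=CENTRE_ROTATION) -> pd.DataFrame:
        """Three train/test experiments rotating the imaging centres.

        The full pipeline (QC, selection, standardisation, balancing,
        tuning) is refit within each experiment's training centres; the
        test centres are evaluated untouched.
        """
        if self.centre is None:
            raise ValueError("model was built without a centre column")
        rows = []
        for k, (train_c, test_c) in enumerate(rotation, start=1):
            tr_mask = self.data[self.centre].isin(train_c)
            te_mask = self.data[self.centre].isin(test_c)
            if te_mask.sum() == 0 or tr_mask.sum() == 0:
                raise ValueError(f"empty centre partition in experiment {k}")
            tr_all = self.data.index[tr_mask]
            te_idx = self.data.index[te_mask]
            y_tr = self.data.loc[tr_all, self.label].astype(int)
            # balance within the training centres
            sub = self.data.loc[tr_all]
            rng = np.random.default_rng(seed + k)
            n_min = y_tr.value_counts().min()
            kept = []
            for cls, grp in y_tr.groupby(y_tr):
                idx = grp.index.to_numpy()
                if len(idx) > n_min:
                    idx = np.sort(rng.choice(idx, n_min, replace=False))
                kept.append(idx)
            tr_idx = pd.Index(np.sort(np.concatenate(kept)))
            res = self._fit_on(tr_idx, te_idx, method, seed, do_cv=False)
            rows.append({
                "experiment": k,
                "train_centres": "+".join(train_c),
                "test_centres": "+".join(test_c),
                "train_lvh": int(y_tr.sum()),
                "test_lvh": int(self.data.loc[te_idx, self.label].sum()),
                **{m: res.metrics[m] for m in
                   ("accuracy", "sensitivity", "specificity", "auc")},
            })
            _ = sub  # noqa: F841
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Generative-parameter recovery (diagnostic for the synthetic cohort)
# ---------------------------------------------------------------------------

def recover_logistic_params(df: pd.DataFrame,
                            feature_cols: Sequence[str] = ("qrs_amp_true",
                                                           "sbp_adj_true"),
                            label: str = "lvh") -> pd.DataFrame:
    """Unregularised logistic fit of the label on the latent generative
    features, with 95 % confidence intervals (one row per term)."""
    X = sm.add_constant(df[list(feature_cols)].astype(float))
    fit = sm.Logit(df[label].astype(int), X).fit(disp=0)
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame({
        "estimate": fit.params,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "se": fit.bse,
    })
    return out
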