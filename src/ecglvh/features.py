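"""Leakage-safe assembly of the modelling matrix.

The cleaning chain mirrors common clinical-ML practice: Tukey-fence
outlier masking (1.5 × IQR beyond the quartiles), greedy removal of
highly correlated features (|r| ≥ 0.9, findCorrelation semantics),
chained-equation imputation of features with < 10 % missingness,
z-score standardisation, and chi-square feature ranking on decile-binned
values.  Every statistic is learned on training rows only and applied to
test rows, so test data never leaks into the fitted artefacts; class
imbalance is handled by down-sampling the training majority class to the
minority count after a stratified 80/20 split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

IQR_FACTOR = 1.5
CORR_THRESHOLD = 0.9
MAX_MISSING_FRACTION = 0.10
CHI2_BINS = 10
MICE_CYCLES = 10
TEST_FRACTION = 0.20


# ---------------------------------------------------------------------------
# Individual operations
# ---------------------------------------------------------------------------

def iqr_fences(values: pd.Series) -> tuple[float, float]:
    q1, q3 = values.quantile(0.25), values.quantile(0.75)
    iqr = q3 - q1
    return q1 - IQR_FACTOR * iqr, q3 + IQR_FACTOR * iqr


def iqr_outlier_filter(values: pd.Series,
                       fences: Optional[tuple[float, float]] = None,
                       ) -> pd.Series:
    """Set values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] to missing.

    Boundary values are kept (inclusive fences); with zero IQR all equal
    values survive.  ``fences`` lets a caller apply training-derived
    fences to held-out data.
    """
    lo, hi = fences if fences is not None else iqr_fences(values)
    out = values.copy()
    out[(values < lo) | (values > hi)] = np.nan
    return out


def correlation_filter(df: pd.DataFrame,
                       threshold: float = CORR_THRESHOLD) -> list[str]:
    """Features retained after greedy |r| ≥ threshold elimination.

    While any pair reaches the threshold, the member with the larger
    mean absolute correlation to all other features is dropped.
    """
    cols = [c for c in df.columns if df[c].notna().sum() >= 3]
    corr = df[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    active = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(active, active)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < threshold:
            break
        mean_i = sub[i].mean()
        mean_j = sub[j].mean()
        drop = active[i] if mean_i >= mean_j else active[j]
        active.remove(drop)
        if len(active) < 2:
            break
    return [cols[k] for k in active]


def impute(df: pd.DataFrame, seed: int = 0,
           max_missing: float = MAX_MISSING_FRACTION) -> pd.DataFrame:
    """Chained-equation imputation of features with < ``max_missing``
    missingness; features at or above it are dropped.  Rows with every
    feature missing are dropped (callers can diff the index to count).
    """
    frac = df.isna().mean()
    keep = [c for c in df.columns if frac[c] < max_missing]
    out = df[keep].copy()
    all_missing = out.isna().all(axis=1)
    out = out.loc[~all_missing]
    if out.isna().any().any():
        imp = IterativeImputer(max_iter=MICE_CYCLES, random_state=seed,
                               sample_posterior=False)
        out = pd.DataFrame(imp.fit_transform(out), index=out.index,
                           columns=out.columns)
    return out


def chi2_rank(df: pd.DataFrame, labels: pd.Series,
              bins: int = CHI2_BINS) -> pd.Series:
    """Chi-square association of each feature with the label, descending.

    Continuous features are decile-binned; features with few distinct
    values keep their natural categories.
    """
    scores = {}
    for col in df.columns:
        x = df[col]
        ok = x.notna() & labels.notna()
        x, y = x[ok], labels[ok]
        if x.nunique() > bins:
            x = pd.qcut(x, q=bins, duplicates="drop")
        table = pd.crosstab(x, y)
        if table.shape[0] < 2 or table.shape[1] < 2:
            scores[col] = 0.0
            continue
        stat, _, _, _ = chi2_contingency(table.to_numpy())
        scores[col] = float(stat)
    return pd.Series(scores).sort_values(ascending=False)


def split_and_balance(df: pd.DataFrame, label: str, seed: int = 0,
                      test_fraction: float = TEST_FRACTION,
                      ) -> tuple[pd.Index, pd.Index]:
    """Stratified 80/20 split, then down-sample the training majority
    class to the minority count.  Returns (train_index, test_index);
    the test set is untouched."""
    y = df[label].astype(int)
    train_idx, test_idx = train_test_split(
        df.index, test_size=test_fraction, stratify=y, random_state=seed)
    rng = np.random.default_rng(seed)
    y_tr = y.loc[train_idx]
    counts = y_tr.value_counts()
    minority = counts.idxmin()
    n_min = counts.min()
    kept = []
    for cls, grp in y_tr.groupby(y_tr):
        idx = grp.index.to_numpy()
        if cls != minority and len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        kept.append(pd.Index(idx))
    train_bal = kept[0].append(kept[1:]) if len(kept) > 1 else kept[0]
    # preserve original row order for determinism
    train_bal = pd.Index([i for i in df.index if i in set(train_bal)])
    return train_bal, pd.Index(test_idx)


# ---------------------------------------------------------------------------
# Fitted preprocessing pipeline
# ---------------------------------------------------------------------------

@dataclass
class FeaturePreprocessor:
    """Outlier masking → correlation filter → imputation → z-scoring,
    fitted on training rows and applied to any rows.

    Order within the chain follows the convention of cleaning before
    selection before imputation; the fitted artefacts (fences, retained
    features, imputer, scaler, ranking) depend on the training rows only.
    """

    seed: int = 0
    corr_threshold: float = CORR_THRESHOLD
    max_missing: float = MAX_MISSING_FRACTION
    fences_: dict = field(default_factory=dict, repr=False)
    retained_: list = field(default_factory=list, repr=False)
    ranking_: Optional[pd.Series] = field(default=None, repr=False)

    def fit(self, X: pd.DataFrame, y: Optional[pd.Series] = None,
            ) -> "FeaturePreprocessor":
        self.fences_ = {c: iqr_fences(X[c].dropna()) for c in X.columns}
        masked = self._mask(X)
        frac = masked.isna().mean()
        usable = [c for c in masked.columns if frac[c] < self.max_missing]
        # drop zero-variance features (they carry no signal and break scaling)
        usable = [c for c in usable if masked[c].nunique(dropna=True) > 1]
        self.retained_ = correlation_filter(masked[usable], self.corr_threshold)
        self._imputer = IterativeImputer(max_iter=MICE_CYCLES,
                                         random_state=self.seed,
                                         sample_posterior=False)
        imputed = self._imputer.fit_transform(masked[self.retained_])
        self._scaler = StandardScaler().fit(imputed)
        if y is not None:
            ranked_input = pd.DataFrame(imputed, columns=self.retained_,
                                        index=masked.index)
            self.ranking_ = chi2_rank(ranked_input, y.loc[masked.index])
        return self

    def _mask(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for c in out.columns:
            out[c] = iqr_outlier_filter(out[c], self.fences_[c])
        return out

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        masked = self._mask(X)[self.retained_]
        imputed = self._imputer.transform(masked)
        scaled = self._scaler.transform(imputed)
        return pd.DataFrame(scaled, index=X.index, columns=self.retained_)

    def fit_transform(self, X: pd.DataFrame,
                      y: Optional[pd.Series] = None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
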