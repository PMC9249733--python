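"""Statistical evaluation of projection models.

Spearman rank correlations are always reported; Pearson correlations are
added only when both variables pass a Shapiro–Wilk normality gate
(p >= 0.05), mirroring the convention that parametric correlations require
approximately normal marginals. Group comparisons use Welch's two-sided
t-test. The leave-one-residue-out analysis probes generalization to unseen
mutational space: every training sequence lacking a given residue at a given
CDR site, every test sequence carrying it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .labeling import select_master_dataset


@dataclass
class CorrelationReport:
    n: int
    spearman_rho: float
    spearman_p: float
    pearson_r: float | None = None
    pearson_p: float | None = None
    normality_p: dict | None = None

    @property
    def pearson_reported(self) -> bool:
        return self.pearson_r is not None


def spearman(x, y):
    """Spearman rho with average-rank ties; p from the two-sided t-test.

    t = rho * sqrt((n-2) / (1-rho^2)) against t(n-2). Constant input gives
    (nan, nan) — an undefined, not erroneous, correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_gated(x, y, alpha: float = 0.05) -> CorrelationReport:
    """Spearman always; Pearson only when both variables look normal.

    Shapiro–Wilk is applied to each variable; Pearson r (with its two-sided
    t-test p) is included only when both normality p-values are >= alpha.
    Outside the test's validity range (3 <= n <= 5000) the gate is skipped
    with a warning and Pearson omitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rho, rho_p = spearman(x, y)
    report = CorrelationReport(n=n, spearman_rho=rho, spearman_p=rho_p)
    if not (3 <= n <= 5000):
        warnings.warn(
            f"n={n} outside Shapiro-Wilk validity range; Pearson omitted",
            stacklevel=2,
        )
        return report
    report.normality_p = {
        "x": float(sps.shapiro(x).pvalue),
        "y": float(sps.shapiro(y).pvalue),
    }
    if all(p >= alpha for p in report.normality_p.values()):
        r = sps.pearsonr(x, y)
        report.pearson_r = float(r.statistic)
        report.pearson_p = float(r.pvalue)
    return report


def ttest_two_sided(a, b, paired: bool = False):
    """Two-sided t-test; Welch form for independent groups.

    Zero variance in both groups with equal means returns (0.0, 1.0) by
    convention rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    if paired:
        res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def classification_accuracy(model, X, y) -> float:
    """Fraction of correct binary classifications."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    return float(np.mean(model.predict(X) == y))


@dataclass
class LOOReport:
    site: int
    residue: str
    n_train: int
    n_test: int
    test_accuracy: float
    test_spearman: float | None = None
    test_spearman_p: float | None = None


def leave_one_residue_out(
    dataset: pd.DataFrame,
    site: int,
    residue: str,
    encoder_factory,
    model_factory,
    label_column: str = "antigen_label",
    truth_column: str | None = None,
    train_cap: int | None = 4000,
) -> LOOReport:
    """Hold out every sequence carrying ``residue`` at ``site``.

    The model trains on sequences lacking the residue at the site (capped by
    the master-selection rule when the pool exceeds ``train_cap``) and is
    evaluated on all sequences bearing it, regardless of the other sites.
    Encoders that cannot represent the held-out residue (one-hot) raise at
    transform time — that failure is the expected negative control.
    """
    has_res = dataset["sequence"].str[site] == residue
    test = dataset[has_res]
    train = dataset[~has_res]
    if test.empty:
        raise ValueError(f"no sequence carries {residue!r} at site {site}")
    if train.empty:
        raise ValueError(f"every sequence carries {residue!r} at site {site}")
    if train_cap is not None and len(train) > train_cap:
        try:
            train = select_master_dataset(train, n=train_cap)
        except (ValueError, KeyError):
            train = train.head(train_cap)
    y_col = dataset[label_column]
    to_binary = (
        (lambda s: (s == "positive").astype(int))
        if y_col.dtype == object
        else (lambda s: s.astype(int))
    )
    enc = encoder_factory().fit(list(train["sequence"]))
    X_train = enc.transform(list(train["sequence"]))
    model = model_factory().fit(X_train, to_binary(train[label_column]).to_numpy())
    X_test = enc.transform(list(test["sequence"]))  # may raise: unsupported encoder
    y_test = to_binary(test[label_column]).to_numpy()
    acc = float(np.mean(model.predict(X_test) == y_test))
    report = LOOReport(site, residue, len(train), len(test), acc)
    if truth_column is not None and len(test) >= 3:
        rho, p = spearman(model.project(X_test), test[truth_column])
        report.test_spearman = rho
        report.test_spearman_p = p
    return report
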