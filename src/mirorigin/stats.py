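"""Relationship statistics between origin-mode sets.

Monte Carlo intersection test: two label sets of sizes m and n are redrawn
without replacement from the M miRNA genes and their intersection counted,
100,000 times by default.  The default empirical tail is the standard
one-sided convention (P(sim >= N) when enriched, P(sim <= N) when
depleted), which agrees with the exact hypergeometric tail; the published
sentence describing the opposite tail is available as ``paper_literal``.

Classification-accuracy similarity: six discriminative models (naive
Bayes, k-NN, two decision-tree variants, SVM, random forest) under
stratified 5-fold cross-validation; the mean accuracy over the six models
is the similarity score (high accuracy = dissimilar sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "IntersectionTest",
    "SimilarityResult",
    "monte_carlo_intersection",
    "cv_similarity",
    "chi_square_2x2",
    "welch_t",
]


@dataclass
class IntersectionTest:
    M: int
    m: int
    n: int
    N: int
    expected: float
    mean_simulated: float
    reps: int
    p_empirical: float
    p_analytic: float
    direction: str  # enriched | depleted


def monte_carlo_intersection(
    M: int,
    m: int,
    n: int,
    N: int,
    reps: int = 100_000,
    seed: int = 0,
    paper_literal: bool = False,
) -> IntersectionTest:
    """Monte Carlo + exact hypergeometric intersection test.

    Draws two independent subsets (sizes m and n) without replacement from
    M items per repetition and counts their intersection.
    """
    if not (0 <= m <= M and 0 <= n <= M):
        raise ValueError("need 0 <= m, n <= M")
    lo, hi = max(0, m + n - M), min(m, n)
    if not lo <= N <= hi:
        raise ValueError(f"infeasible N={N}: must lie in [{lo}, {hi}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    rng = np.random.default_rng(seed)
    expected = m * n / M if M else 0.0

    total_ge = 0  # simulated intersections >= N
    total_le = 0
    total_sum = 0
    chunk = max(1, min(reps, int(2e6 // max(M, 1))))
    done = 0
    while done < reps:
        c = min(chunk, reps - done)
        u1 = rng.random((c, M))
        u2 = rng.random((c, M))
        in1 = np.zeros((c, M), dtype=bool)
        in2 = np.zeros((c, M), dtype=bool)
        np.put_along_axis(in1, np.argsort(u1, axis=1)[:, :m], True, axis=1)
        np.put_along_axis(in2, np.argsort(u2, axis=1)[:, :n], True, axis=1)
        inter = (in1 & in2).sum(axis=1)
        total_ge += int((inter >= N).sum())
        total_le += int((inter <= N).sum())
        total_sum += int(inter.sum())
        done += c

    enriched = N > expected
    if paper_literal:
        # published wording: frequency of intersections *smaller* than N
        # when N exceeds the random value, otherwise *larger* than N
        frac = (reps - total_ge) / reps if enriched else (reps - total_le) / reps
    else:
        frac = total_ge / reps if enriched else total_le / reps
    p_emp = max(frac, 1.0 / reps)

    if enriched:
        p_ana = float(sps.hypergeom.sf(N - 1, M, m, n))
    else:
        p_ana = float(sps.hypergeom.cdf(N, M, m, n))

    return IntersectionTest(
        M=M,
        m=m,
        n=n,
        N=N,
        expected=expected,
        mean_simulated=total_sum / reps,
        reps=reps,
        p_empirical=p_emp,
        p_analytic=min(p_ana, 1.0),
        direction="enriched" if enriched else "depleted",
    )


@dataclass
class SimilarityResult:
    accuracy_per_classifier: dict[str, float]
    mean_accuracy: float
    folds: int = 5


def _classifier_suite(seed: int):
    return {
        "naive_bayes": GaussianNB(),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5)),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "c45_tree": DecisionTreeClassifier(criterion="entropy", random_state=seed),
        "svm": make_pipeline(StandardScaler(), SVC(random_state=seed)),
        "random_forest": RandomForestClassifier(n_estimators=60, random_state=seed),
    }


def cv_similarity(
    features_set1: np.ndarray, features_set2: np.ndarray, seed: int = 0
) -> SimilarityResult:
    """Mean 5-fold CV accuracy of six classifiers separating the two sets."""
    X1 = np.asarray(features_set1, dtype=float)
    X2 = np.asarray(features_set2, dtype=float)
    if X1.ndim == 1:
        X1 = X1[:, None]
    if X2.ndim == 1:
        X2 = X2[:, None]
    if min(len(X1), len(X2)) < 5:
        raise ValueError("each set needs >= 5 members for stratified 5-fold CV")
    X = np.vstack([X1, X2])
    y = np.concatenate([np.zeros(len(X1)), np.ones(len(X2))])
    # NaN-tolerant: impute with column means, drop all-NaN columns
    col_ok = ~np.all(np.isnan(X), axis=0)
    X = X[:, col_ok]
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])

    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    accs = {}
    for name, clf in _classifier_suite(seed).items():
        correct = 0
        for train, test in splits:
            clf.fit(X[train], y[train])
            correct += int((clf.predict(X[test]) == y[test]).sum())
        accs[name] = correct / len(y)
    return SimilarityResult(
        accuracy_per_classifier=accs,
        mean_accuracy=float(np.mean(list(accs.values()))),
    )


def chi_square_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> tuple[float, float]:
    """Chi-square test on a 2x2 table [[a, b], [c, d]] (no continuity
    correction by default)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        raise ValueError("degenerate 2x2 table")
    stat, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def welch_t(group1, group2) -> tuple[float, float]:
    """Welch's unequal-variance t-test."""
    x, y = np.asarray(group1, dtype=float), np.asarray(group2, dtype=float)
    if np.array_equal(x, y):
        return 0.0, 1.0
    stat, p = sps.ttest_ind(x, y, equal_var=False)
    return float(stat), float(p)
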