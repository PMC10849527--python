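"""Environmental separability of taxa: LDA confusion tables and the gap statistic.

Two complementary questions about named taxa in environmental space: (i) how
well can a linear discriminant classifier re-assign individuals to their
taxon from environmental values alone (confusion tables of predicted shares,
in percent); and (ii) how many environmental clusters ("ecospecies" /
"ecopopulations") do the data actually support, estimated by the gap
statistic on k-means partitions against uniform reference data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, cross_val_predict


@dataclass
class ConfusionTable:
    """Row-stochastic table of predicted-group shares per true group (percent)."""

    labels: list
    percent: pd.DataFrame  # rows = true group, columns = predicted group

    def __post_init__(self):
        if self.percent.shape[0] != self.percent.shape[1]:
            raise ValueError("confusion table must be square")
        rowsum = self.percent.to_numpy().sum(axis=1)
        if not np.allclose(rowsum, 100.0, atol=1e-6):
            raise ValueError("confusion table rows must sum to 100")

    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.percent.to_numpy()), index=self.labels)

    def rounded(self) -> pd.DataFrame:
        return self.percent.round(0).astype(int)


def lda_confusion(matrix: pd.DataFrame, labels, mode: str = "resubstitution") -> ConfusionTable:
    """Linear-discriminant confusion table of taxa in environmental space.

    Fits an LDA classifier (priors proportional to group sizes) on the
    environmental matrix and tabulates, for each true group, the percent of
    its points predicted into each group. ``mode``: "resubstitution"
    (predict the training points, the default) or "loo" (leave-one-out
    cross-validated predictions).
    """
    X = matrix.to_numpy(dtype=float)
    y = np.asarray(labels)
    groups = sorted(pd.unique(y))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_vars = X.shape[1]
    counts = pd.Series(y).value_counts()
    too_small = [g for g in groups if counts[g] < n_vars + 1]
    if too_small:
        raise ValueError(f"groups with fewer than n_vars+1 points: {too_small}")
    clf = LinearDiscriminantAnalysis()
    try:
        if mode == "resubstitution":
            clf.fit(X, y)
            pred = clf.predict(X)
        elif mode == "loo":
            pred = cross_val_predict(clf, X, y, cv=LeaveOneOut())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError(
            "singular pooled covariance; reduce or decorrelate variables") from err
    table = pd.DataFrame(0.0, index=groups, columns=groups)
    for g in groups:
        sel = y == g
        shares = pd.Series(pred[sel]).value_counts(normalize=True) * 100.0
        for h, v in shares.items():
            table.loc[g, h] = v
    return ConfusionTable(groups, table)


@dataclass
class GapResult:
    """Gap-statistic curve and the selected number of clusters."""

    k_range: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    log_w: np.ndarray
    k_best: int
    b_refs: int
    seed: int | None

    def __post_init__(self):
        if not (len(self.k_range) == len(self.gap) == len(self.se) == len(self.log_w)):
            raise ValueError("gap curve arrays must have equal length")
        if self.k_best not in self.k_range:
            raise ValueError("k_best must lie in k_range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_range, "gap": self.gap, "se": self.se,
                             "log_w": self.log_w})


def within_dispersion(X: np.ndarray, assign: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to cluster centroids."""
    w = 0.0
    for k in np.unique(assign):
        pts = X[assign == k]
        w += float(((pts - pts.mean(axis=0))**2).sum())
    return w


def _kmeans_w(X: np.ndarray, k: int, rng: np.random.Generator, n_restarts: int) -> float:
    if k == 1:
        return within_dispersion(X, np.zeros(len(X), dtype=int))
    km = KMeans(n_clusters=k, n_init=n_restarts,
                random_state=int(rng.integers(0, 2**31 - 1)))
    km.fit(X)
    return float(km.inertia_)


def gap_statistic(matrix: pd.DataFrame, k_max: int, b_refs: int = 50, seed=None,
                  n_restarts: int = 25) -> GapResult:
    """Gap statistic for the number of k-means clusters.

    Gap(k) = mean_b log(W*_kb) - log(W_k), with W_k the within-cluster
    dispersion of the k-means partition and W*_kb the same under B reference
    datasets drawn uniform over the variable-wise range box. The standard
    error s_k = sd_b * sqrt(1 + 1/B), and the selected k is the smallest k
    with Gap(k) >= Gap(k+1) - s_{k+1} (first-SE-max rule); if no k
    qualifies, k_max is returned.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    n = len(X)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the number of points ({n})")
    if b_refs < 10:
        raise ValueError("b_refs must be >= 10")
    rng = np.random.default_rng(seed)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    ks = np.arange(1, k_max + 1)
    log_w = np.array([np.log(_kmeans_w(X, k, rng, n_restarts)) for k in ks])
    ref_log_w = np.empty((b_refs, k_max))
    for b in range(b_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        for i, k in enumerate(ks):
            ref_log_w[b, i] = np.log(_kmeans_w(ref, k, rng, n_restarts))
    gap = ref_log_w.mean(axis=0) - log_w
    sd = ref_log_w.std(axis=0)
    se = sd * np.sqrt(1.0 + 1.0 / b_refs)
    k_best = int(ks[-1])
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            k_best = int(ks[i])
            break
    return GapResult(ks, gap, se, log_w, k_best, b_refs,
                     None if seed is None else int(seed))
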