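"""Ellipsoid niche models: minimum-volume-ellipsoid fit, distance thresholds, projection.

The niche of a taxon is modeled as an ellipsoid in environmental space: the
minimum volume ellipsoid (MVE) covering 90% of the fitting points, a robust
estimate that discounts stray records. Suitability of any environmental
vector is then a decreasing function of its Mahalanobis distance from the
ellipsoid centroid. A parametric distribution (Gaussian by default) is fitted
by maximum likelihood to the fitting points' distances, and its percentiles
at the 75/85/90/95/99% inclusion levels give nested presence/absence
thresholds; the continuous suitability surface is 1 - F(d), the upper tail of
the fitted distance distribution.

The MVE search follows the classical elemental-set resampling scheme: draw
many (p+1)-point subsets, inflate each subset's ellipsoid to cover
h = ceil(inclusion * n) points, keep the candidate of minimal volume, and
report the mean and (consistency-scaled) covariance of its h-point subset.
When the number of elemental sets is small the search is exhaustive, which
tests exploit as a brute-force oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .env_layers import EnvStack
from .occurrence_prep import AccessibleArea

DEFAULT_LEVELS = (75, 85, 90, 95, 99)
EXHAUSTIVE_LIMIT = 10_000  # enumerate all elemental sets when C(n, p+1) <= this

_FAMILIES = {
    "gaussian": stats.norm,
    "halfnormal": stats.halfnorm,
    "lognormal": stats.lognorm,
    "gamma": stats.gamma,
}


@dataclass
class Ellipsoid:
    """Fitted niche ellipsoid: centroid and covariance in environmental units."""

    centroid: np.ndarray
    covariance: np.ndarray
    inclusion: float = 0.9
    n_fit: int = 0
    seed: int | None = None
    variables: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not (0 < self.inclusion <= 1):
            raise ValueError("inclusion must lie in (0, 1]")
        if self.covariance.shape != (self.centroid.size,) * 2:
            raise ValueError("covariance shape does not match centroid")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("covariance must be positive definite")

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.covariance)

    def to_dict(self) -> dict:
        return {
            "centroid": self.centroid.tolist(),
            "covariance": self.covariance.tolist(),
            "inclusion": self.inclusion,
            "n_fit": self.n_fit,
            "seed": self.seed,
            "variables": self.variables,
        }


@dataclass
class DistanceModel:
    """Parametric model of the Mahalanobis distance distribution with cutoffs.

    ``cutoffs[L]`` is the fitted distribution's L-th percentile (floored at
    0): the distance threshold below which a cell is scored present at
    inclusion level L percent. Cutoffs are strictly increasing with level.
    """

    family: str
    params: tuple
    levels: tuple = DEFAULT_LEVELS
    cutoffs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {sorted(_FAMILIES)}")
        vals = [self.cutoffs[L] for L in self.levels]
        if any(v < 0 for v in vals):
            raise ValueError("cutoffs must be non-negative")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("cutoffs must be non-decreasing with level")

    def cdf(self, d):
        return _FAMILIES[self.family].cdf(d, *self.params)

    def suitability(self, d):
        """Continuous suitability 1 - F(d), clipped to [0, 1]."""
        return np.clip(1.0 - self.cdf(d), 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": list(self.params),
            "levels": list(self.levels),
            "cutoffs": {str(k): v for k, v in self.cutoffs.items()},
        }


def save_model(path, ellipsoid: Ellipsoid, dmodel: DistanceModel) -> None:
    with open(path, "w") as fh:
        json.dump({"ellipsoid": ellipsoid.to_dict(), "distance_model": dmodel.to_dict()}, fh, indent=2)


def load_model(path) -> tuple[Ellipsoid, DistanceModel]:
    with open(path) as fh:
        blob = json.load(fh)
    e = blob["ellipsoid"]
    d = blob["distance_model"]
    ellipsoid = Ellipsoid(np.array(e["centroid"]), np.array(e["covariance"]),
                          e["inclusion"], e["n_fit"], e["seed"], e.get("variables", []))
    dmodel = DistanceModel(d["family"], tuple(d["params"]), tuple(d["levels"]),
                           {int(float(k)): v for k, v in d["cutoffs"].items()})
    return ellipsoid, dmodel


# ---------------------------------------------------------------------------
# MVE fitting
# ---------------------------------------------------------------------------


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float)
    return np.asarray(matrix, dtype=float)


def _candidate_log_volumes(X: np.ndarray, subsets: np.ndarray, h: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-volume of each elemental candidate, inflated to cover h points.

    For a subset S with mean m and covariance C, the covering ellipsoid's
    volume is proportional to sqrt(det C) * r^p where r^2 is the h-th
    smallest squared Mahalanobis distance of the data under (m, C). Returns
    (log_volumes, r2) with +inf for irreparably singular candidates.
    """
    n, p = X.shape
    T = len(subsets)
    pts = X[subsets]                              # (T, p+1, p)
    means = pts.mean(axis=1)                      # (T, p)
    dev = pts - means[:, None, :]
    cov = np.einsum("tkp,tkq->tpq", dev, dev) / p  # ddof=1 over p+1 points
    # regularize singular candidates: eps * mean diagonal on the diagonal
    diag_mean = np.einsum("tpp->t", cov) / p
    eps = 1e-8 * np.where(diag_mean > 0, diag_mean, 1.0)
    cov = cov + eps[:, None, None] * np.eye(p)
    sign, logdet = np.linalg.slogdet(cov)
    ok = sign > 0
    inv = np.full_like(cov, np.nan)
    if ok.any():
        inv[ok] = np.linalg.inv(cov[ok])
    r2 = np.full(T, np.inf)
    logvol = np.full(T, np.inf)
    if ok.any():
        diff = X[None, :, :] - means[:, None, :]       # (T, n, p)
        d2 = np.einsum("tnp,tpq,tnq->tn", diff[ok], inv[ok], diff[ok])
        r2_ok = np.partition(d2, h - 1, axis=1)[:, h - 1]
        r2[ok] = r2_ok
        logvol[ok] = 0.5 * logdet[ok] + 0.5 * p * np.log(np.maximum(r2_ok, 1e-300))
    return logvol, r2


def mve_consistency_factor(inclusion: float, p: int) -> float:
    """Scale making the h-subset covariance consistent for a Gaussian sample."""
    q = stats.chi2.ppf(inclusion, p)
    return inclusion / stats.chi2.cdf(q, p + 2)


def fit_mve(matrix, inclusion: float = 0.9, seed=None, n_trials: int = 10_000,
            variables=None) -> Ellipsoid:
    """Minimum volume ellipsoid covering ``inclusion`` of the points.

    Seeded elemental-set resampling with an exhaustive search whenever
    C(n, p+1) <= 10,000. The returned ellipsoid carries the mean and the
    consistency-scaled covariance of the optimal h-point subset
    (h = ceil(inclusion * n)).
    """
    X = _as_array(matrix)
    if variables is None and isinstance(matrix, pd.DataFrame):
        variables = list(matrix.columns)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} points, got {n}")
    h = math.ceil(inclusion * n)
    h = max(h, p + 1)

    n_elemental = math.comb(n, p + 1)
    if n_elemental <= EXHAUSTIVE_LIMIT:
        subsets = np.array(list(combinations(range(n), p + 1)), dtype=np.intp)
    else:
        rng = np.random.default_rng(seed)
        # vectorized sampling without replacement: smallest p+1 of n uniforms
        keys = rng.random((n_trials, n))
        subsets = np.argpartition(keys, p + 1, axis=1)[:, :p + 1].astype(np.intp)

    best_logvol = np.inf
    best = None
    chunk = max(1, int(1_000_000 / max(n, 1)))
    for start in range(0, len(subsets), chunk):
        sub = subsets[start:start + chunk]
        logvol, r2 = _candidate_log_volumes(X, sub, h)
        i = int(np.argmin(logvol))
        if logvol[i] < best_logvol:
            best_logvol = logvol[i]
            best = sub[i]
    if best is None or not np.isfinite(best_logvol):
        raise ValueError("all elemental candidates were singular; add points or drop variables")

    # recover the h-subset of the winning candidate
    pts = X[best]
    m = pts.mean(axis=0)
    C = np.cov(pts, rowvar=False)
    diag_mean = np.trace(C) / p
    C = C + 1e-8 * (diag_mean if diag_mean > 0 else 1.0) * np.eye(p)
    inv = np.linalg.inv(C)
    diff = X - m
    d2 = np.einsum("np,pq,nq->n", diff, inv, diff)
    h_idx = np.argsort(d2, kind="stable")[:h]
    sub = X[h_idx]
    centroid = sub.mean(axis=0)
    cov = np.cov(sub, rowvar=False)
    # guard degenerate subsets (e.g. all points in one raster cell): floor the
    # spectrum at a scale-relative jitter so the ellipsoid stays invertible
    scale = max(np.trace(cov) / p, 1.0)
    if np.linalg.eigvalsh(cov).min() <= 1e-12 * scale:
        cov = cov + 1e-8 * scale * np.eye(p)
    cov = cov * mve_consistency_factor(inclusion, p)
    ell = Ellipsoid(centroid, cov, inclusion, n, None if seed is None else int(seed),
                    list(variables) if variables is not None else [])
    # achieved elemental-candidate objective, comparable to mve_best_log_volume
    ell.log_volume = float(best_logvol)
    return ell


def mve_best_log_volume(matrix, inclusion: float = 0.9) -> float:
    """Brute-force minimum log-volume over all elemental sets (test oracle)."""
    X = _as_array(matrix)
    n, p = X.shape
    h = max(math.ceil(inclusion * n), p + 1)
    subsets = np.array(list(combinations(range(n), p + 1)), dtype=np.intp)
    logvol, _ = _candidate_log_volumes(X, subsets, h)
    return float(np.min(logvol))


def mahalanobis(ellipsoid: Ellipsoid, matrix) -> np.ndarray:
    """Mahalanobis distance of each row from the ellipsoid centroid."""
    X = _as_array(matrix)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != ellipsoid.centroid.size:
        raise ValueError("dimension mismatch between matrix and ellipsoid")
    diff = X - ellipsoid.centroid
    d2 = np.einsum("np,pq,nq->n", diff, ellipsoid.precision, diff)
    return np.sqrt(np.maximum(d2, 0.0))


# ---------------------------------------------------------------------------
# distance-distribution thresholding
# ---------------------------------------------------------------------------


def fit_distance_model(distances, family: str = "gaussian",
                       levels=DEFAULT_LEVELS) -> DistanceModel:
    """Maximum-likelihood fit of a distribution to the fitted points' distances.

    The cutoff for inclusion level L is the fitted distribution's L-th
    percentile, floored at 0 (a Gaussian fitted to small distances can put
    mass below zero). Degenerate samples (all distances equal) collapse to a
    point mass guarded at sigma = 1e-12.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 10:
        raise ValueError("need at least 10 distances to fit a distance model")
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_FAMILIES)}")
    dist = _FAMILIES[family]
    if family == "gaussian":
        mu, sigma = float(np.mean(d)), float(np.std(d))
        params = (mu, max(sigma, 1e-12))
    elif family == "halfnormal":
        params = dist.fit(d, floc=0.0)
    else:
        params = dist.fit(d, floc=0.0)
    if not all(np.isfinite(params)):
        raise ValueError(f"non-finite MLE for family {family!r}; try another family")
    levels = tuple(levels)
    cutoffs = {}
    for L in levels:
        q = float(dist.ppf(L / 100.0, *params))
        cutoffs[L] = max(q, 0.0)
    return DistanceModel(family, tuple(float(x) for x in params), levels, cutoffs)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


@dataclass
class SuitabilityMap:
    """Projected niche model on a raster grid.

    ``values`` is the continuous suitability 1 - F(d) in [0, 1] (NaN outside
    the analysis extent); ``binary[L]`` the presence mask at inclusion level
    L (nested across levels); ``normalized`` the suitability rescaled to sum
    to 1 over the extent.
    """

    grid: object
    extent_mask: np.ndarray
    values: np.ndarray
    binary: dict
    normalized: np.ndarray

    def extent_values(self) -> np.ndarray:
        return self.values[self.extent_mask]

    def extent_normalized(self) -> np.ndarray:
        return self.normalized[self.extent_mask]


def project(ellipsoid: Ellipsoid, dmodel: DistanceModel, stack: EnvStack,
            extent: AccessibleArea | np.ndarray | None = None) -> SuitabilityMap:
    """Project a fitted niche model over a raster stack.

    ``extent`` restricts the analysis region: an accessible area (or
    pre-rasterized boolean mask); None uses every unmasked cell. Per cell the
    Mahalanobis distance d is computed from the cell's environmental vector,
    the continuous surface is 1 - F(d), binary masks threshold d at each
    level's cutoff, and the normalized surface divides by the extent sum.
    """
    if ellipsoid.variables and list(stack.variables) != list(ellipsoid.variables):
        raise ValueError(
            f"stack variables {stack.variables} do not match fit variables {ellipsoid.variables}")
    if extent is None:
        emask = stack.mask.copy()
    elif isinstance(extent, AccessibleArea):
        emask = stack.area_mask(extent)
    else:
        emask = np.asarray(extent, dtype=bool) & stack.mask
    if not emask.any():
        raise ValueError("empty analysis extent")
    rows, cols = np.nonzero(emask)
    vec = stack.data[:, rows, cols].T
    d = mahalanobis(ellipsoid, vec)
    s = dmodel.suitability(d)
    values = np.full(emask.shape, np.nan)
    values[rows, cols] = s
    binary = {}
    for L in dmodel.levels:
        mask_l = np.zeros(emask.shape, dtype=bool)
        mask_l[rows, cols] = d <= dmodel.cutoffs[L]
        binary[L] = mask_l
    total = s.sum()
    normalized = np.full(emask.shape, np.nan)
    if total > 0:
        normalized[rows, cols] = s / total
    else:
        # degenerate all-zero surface: fall back to uniform over the extent
        normalized[rows, cols] = 1.0 / len(rows)
    return SuitabilityMap(stack.grid, emask, values, binary, normalized)


def fit_niche_model(matrix, inclusion: float = 0.9, seed=None,
                    family: str = "gaussian", levels=DEFAULT_LEVELS,
                    n_trials: int = 10_000) -> tuple[Ellipsoid, DistanceModel]:
    """Convenience: fit_mve then fit_distance_model on the fitting points."""
    ell = fit_mve(matrix, inclusion=inclusion, seed=seed, n_trials=n_trials)
    d = mahalanobis(ell, matrix)
    dmodel = fit_distance_model(d, family=family, levels=levels)
    return ell, dmodel
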