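"""Niche overlap and the background similarity test with a -2..+2 decision score.

Overlap between two projected niche models is Schoener's D: both suitability
surfaces are normalized to sum to 1 over a shared analysis extent and
D = 1 - 0.5 * sum |p_i - q_i|, ranging from 0 (disjoint) to 1 (identical).

The similarity (background) test asks whether the observed overlap between
taxa A and B could have arisen from the available environments alone: the
observed D between the two real models is compared against two null
distributions, each built from models fitted to random background points
drawn from the *other* taxon's accessible area (real-A vs. 100 random-B
models, and vice versa). Against each null the observed D is scored +1 if it
exceeds the upper tail (97.5th percentile), -1 if below the lower tail
(2.5th), else 0; the two marks sum to a score in {-2..+2}. Only -2 counts as
significant niche divergence; +2 is extreme conservatism.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .ellipsoid_niche import (
    DEFAULT_LEVELS,
    SuitabilityMap,
    fit_niche_model,
    project,
)
from .env_layers import EnvStack, sample_background
from .occurrence_prep import AccessibleArea


@dataclass
class TestConfig:
    """Knobs of the background similarity test.

    ``n_random`` (points per null model) defaults to the focal taxon's
    occurrence count. ``surface`` selects the compared layer: "continuous"
    (1 - F(d), the default) or "binary@L" for the presence mask at level L.
    ``mve_trials`` caps the elemental resamples per null-model MVE fit.
    """

    reps: int = 100
    tails: tuple = (2.5, 97.5)
    n_random: int | None = None
    seed: int = 0
    surface: str = "continuous"
    inclusion: float = 0.9
    family: str = "gaussian"
    levels: tuple = DEFAULT_LEVELS
    mve_trials: int = 2000
    extent_mode: str = "union"  # union | intersection | full
    max_failure_fraction: float = 0.1

    def __post_init__(self):
        if self.reps < 20:
            raise ValueError("reps must be >= 20")
        lo, hi = self.tails
        if not (0 < lo < hi < 100):
            raise ValueError("tails must satisfy 0 < lower < upper < 100")
        if self.surface != "continuous" and not self.surface.startswith("binary@"):
            raise ValueError("surface must be 'continuous' or 'binary@LEVEL'")


@dataclass
class OverlapResult:
    """Observed Schoener's D, the two null distributions, and the decision score."""

    taxon_a: str
    taxon_b: str
    d_obs: float
    null_ab: np.ndarray  # D of real-A vs. models from random points in M_B
    null_ba: np.ndarray  # D of real-B vs. models from random points in M_A
    score: int
    extent_mode: str = "union"

    def __post_init__(self):
        self.null_ab = np.asarray(self.null_ab, dtype=float)
        self.null_ba = np.asarray(self.null_ba, dtype=float)
        for arr in (self.null_ab, self.null_ba, np.array([self.d_obs])):
            if ((arr < -1e-12) | (arr > 1 + 1e-12)).any():
                raise ValueError("Schoener's D values must lie in [0, 1]")
        if self.score not in {-2, -1, 0, 1, 2}:
            raise ValueError("score must lie in {-2..+2}")

    def to_dict(self) -> dict:
        return {
            "taxon_a": self.taxon_a,
            "taxon_b": self.taxon_b,
            "d_obs": self.d_obs,
            "score": self.score,
            "extent_mode": self.extent_mode,
            "null_ab": self.null_ab.tolist(),
            "null_ba": self.null_ba.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def _surface_values(smap: SuitabilityMap, extent_mask: np.ndarray, surface: str) -> np.ndarray:
    if surface == "continuous":
        vals = np.where(np.isfinite(smap.values), smap.values, 0.0)
    else:
        level = int(surface.split("@", 1)[1])
        vals = smap.binary[level].astype(float)
    return vals[extent_mask]


def schoeners_d(map_a: SuitabilityMap, map_b: SuitabilityMap,
                extent_mask: np.ndarray | None = None,
                surface: str = "continuous") -> float:
    """Schoener's D between two suitability maps over a shared extent.

    Each map's surface is restricted to the extent and normalized to sum to
    1; D = 1 - 0.5 * sum |p - q|. Symmetric, in [0, 1]; an all-zero surface
    on the extent is an error (normalization undefined).
    """
    if map_a.grid != map_b.grid:
        raise ValueError("maps must share the grid")
    if extent_mask is None:
        extent_mask = map_a.extent_mask | map_b.extent_mask
    p = _surface_values(map_a, extent_mask, surface)
    q = _surface_values(map_b, extent_mask, surface)
    sp, sq = p.sum(), q.sum()
    if sp <= 0 or sq <= 0:
        raise ValueError("a surface is all-zero on the extent; D undefined")
    p = p / sp
    q = q / sq
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def comparison_extent(stack: EnvStack, m_a: AccessibleArea, m_b: AccessibleArea,
                      mode: str = "union") -> np.ndarray:
    """Rasterized analysis extent for a pairwise comparison."""
    a = stack.area_mask(m_a)
    b = stack.area_mask(m_b)
    if mode == "union":
        return a | b
    if mode == "intersection":
        return a & b
    if mode == "full":
        return stack.mask.copy()
    raise ValueError(f"unknown extent mode {mode!r}")


def build_null_models(m: AccessibleArea, stack: EnvStack, config: TestConfig,
                      n_random: int, extent_mask: np.ndarray, seed_seq) -> list:
    """reps niche models fitted to random background points from M.

    Each rep draws ``n_random`` cell-uniform points from M, runs the full
    fit (MVE -> distance model -> projection onto ``extent_mask``) under a
    per-rep seed derived from the master seed. Reps whose fit fails are
    skipped; more than ``max_failure_fraction`` failures aborts.
    """
    maps = []
    failures = 0
    child_seqs = seed_seq.spawn(config.reps)
    for ss in child_seqs:
        rng = np.random.default_rng(ss)
        bg_seed = int(rng.integers(0, 2**31 - 1))
        fit_seed = int(rng.integers(0, 2**31 - 1))
        try:
            bg = sample_background(stack, m, n_random, bg_seed)
            ell, dmodel = fit_niche_model(
                bg, inclusion=config.inclusion, seed=fit_seed,
                family=config.family, levels=config.levels, n_trials=config.mve_trials)
            maps.append(project(ell, dmodel, stack, extent_mask))
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            if failures > config.max_failure_fraction * config.reps:
                raise RuntimeError(
                    f"more than {config.max_failure_fraction:.0%} of null-model fits failed")
    return maps


def score_decision(d_obs: float, null_ab, null_ba, tails=(2.5, 97.5)) -> int:
    """Sum of per-null marks: +1 above the upper percentile, -1 below the lower.

    Percentiles are empirical with linear interpolation; a d_obs exactly
    equal to a percentile counts as 0 for that null.
    """
    lo, hi = tails
    score = 0
    for null in (np.asarray(null_ab, float), np.asarray(null_ba, float)):
        if null.size == 0:
            raise ValueError("empty null distribution")
        lower = np.percentile(null, lo)
        upper = np.percentile(null, hi)
        if d_obs > upper:
            score += 1
        elif d_obs < lower:
            score -= 1
    return score


def similarity_test(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                    m_a: AccessibleArea, m_b: AccessibleArea, stack: EnvStack,
                    config: TestConfig, taxon_a: str = "A", taxon_b: str = "B"
                    ) -> OverlapResult:
    """Two-sided background similarity test between taxa A and B.

    Fits the two real models from the taxa's environmental matrices,
    computes the observed D over the comparison extent, builds the two null
    distributions (real-A vs. random-from-M_B models and vice versa), and
    scores the observed D against both tails.
    """
    master = np.random.SeedSequence([config.seed, 101])
    s_null_b, s_null_a = master.spawn(2)
    extent = comparison_extent(stack, m_a, m_b, config.extent_mode)
    if not extent.any():
        raise ValueError("empty comparison extent")

    # fit seeds keyed by taxon label: a taxon compared to itself gets the
    # identical model on both sides, so D(A, A) = 1 exactly
    def _fit_seed(label: str) -> int:
        return (config.seed * 2654435761 + zlib.crc32(label.encode())) % (2**31 - 1)

    ell_a, dm_a = fit_niche_model(
        matrix_a, inclusion=config.inclusion, seed=_fit_seed(taxon_a),
        family=config.family, levels=config.levels, n_trials=config.mve_trials)
    ell_b, dm_b = fit_niche_model(
        matrix_b, inclusion=config.inclusion, seed=_fit_seed(taxon_b),
        family=config.family, levels=config.levels, n_trials=config.mve_trials)
    map_a = project(ell_a, dm_a, stack, extent)
    map_b = project(ell_b, dm_b, stack, extent)
    d_obs = schoeners_d(map_a, map_b, extent, config.surface)

    n_rand_b = config.n_random if config.n_random is not None else len(matrix_b)
    n_rand_a = config.n_random if config.n_random is not None else len(matrix_a)
    nulls_from_b = build_null_models(m_b, stack, config, n_rand_b, extent, s_null_b)
    nulls_from_a = build_null_models(m_a, stack, config, n_rand_a, extent, s_null_a)
    null_ab = np.array([schoeners_d(map_a, nm, extent, config.surface) for nm in nulls_from_b])
    null_ba = np.array([schoeners_d(map_b, nm, extent, config.surface) for nm in nulls_from_a])
    score = score_decision(d_obs, null_ab, null_ba, config.tails)
    return OverlapResult(taxon_a, taxon_b, d_obs, null_ab, null_ba, score,
                         config.extent_mode)


def pairwise_scores(matrices: dict, ms: dict, stack: EnvStack, config: TestConfig
                    ) -> tuple[pd.DataFrame, list]:
    """All k(k-1)/2 unordered pairwise similarity tests.

    Returns (lower-triangle score matrix, list of OverlapResult). Each pair
    gets an independent seed stream derived from the master seed and the
    pair's rank, so results do not depend on evaluation order.
    """
    taxa = sorted(matrices)
    results = []
    scores = pd.DataFrame(np.nan, index=taxa, columns=taxa)
    for rank, (a, b) in enumerate(combinations(taxa, 2)):
        pair_cfg = TestConfig(**{**config.__dict__, "seed": config.seed + 7919 * (rank + 1)})
        res = similarity_test(matrices[a], matrices[b], ms[a], ms[b], stack,
                              pair_cfg, taxon_a=a, taxon_b=b)
        results.append(res)
        scores.loc[b, a] = res.score
    return scores, results


def n_pairs(k: int) -> int:
    """Number of unordered taxon pairs among k taxa."""
    return k * (k - 1) // 2
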