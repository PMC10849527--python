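"""Synthetic study systems: environments, accessible areas, niches on a tree, occurrences.

Emulates the data regime of a comparative niche-evolution study of a small
bird genus: a stack of smooth continuous environmental variables on a
lon/lat grid, per-taxon accessible areas (M), "true" ellipsoidal niches
evolved along a 9-tip phylogeny under per-branch modes — ``conserve`` (child
keeps the parent niche), ``partition`` (child occupies a proper sub-region
of the parent's 95% ellipsoid), ``shift`` (child centroid moves outside the
parent's 95% ellipsoid) — and occurrence records sampled within M with
probability decaying as a Gaussian in Mahalanobis distance from the niche
centroid. Records receive breeding-season dates for their hemisphere, plus
configurable fractions of out-of-season dates and out-of-M "vagrant" points
so the cleaning stage has something to do.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from scipy import stats
from shapely.geometry import box

from .env_layers import EnvStack, GridSpec
from .occurrence_prep import (
    NORTH_BREEDING_MONTHS,
    SOUTH_BREEDING_MONTHS,
    AccessibleArea,
    OccurrenceSet,
    write_accessible_areas,
)

#: 9-tip ultrametric tree (depth 1.0) with labeled internal nodes
DEFAULT_TREE = (
    "((sp1:0.5,(sp2:0.3,sp3:0.3)n2:0.2)n1:0.5,"
    "((sp4:0.4,(sp5:0.2,sp6:0.2)n5:0.2)n4:0.3,"
    "(sp7:0.35,(sp8:0.15,sp9:0.15)n7:0.2)n6:0.35)n3:0.3)root;"
)


def read_tree(source: str) -> dendropy.Tree:
    """Parse a rooted Newick tree from a string or file path."""
    if Path(str(source)).exists() if len(str(source)) < 500 else False:
        return dendropy.Tree.get(path=str(source), schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(data=str(source), schema="newick",
                             preserve_underscores=True)


def node_label(node: dendropy.Node) -> str | None:
    return node.taxon.label if node.taxon is not None else node.label


@dataclass
class TrueNiche:
    """Ground-truth ellipsoidal niche: centroid + SPD covariance (env units)."""

    taxon: str
    centroid: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (self.centroid.size,) * 2:
            raise ValueError("covariance shape does not match centroid")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("covariance must be positive definite")

    @property
    def n_vars(self) -> int:
        return self.centroid.size

    def mahalanobis(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        diff = X - self.centroid
        inv = np.linalg.inv(self.covariance)
        return np.sqrt(np.maximum(np.einsum("np,pq,nq->n", diff, inv, diff), 0.0))

    def radius(self, level: float = 0.95) -> float:
        """Mahalanobis radius of the ``level`` probability ellipsoid."""
        return float(np.sqrt(stats.chi2.ppf(level, self.n_vars)))


@dataclass
class SimConfig:
    """Study-system parameters for the synthetic generators.

    ``extent`` is (west, east, south, north) in decimal degrees;
    ``branch_modes`` maps a child node label (tip or internal) to its branch
    mode — a string in {conserve, partition, shift} or a dict with keys
    ``mode`` and optionally ``shrink``/``factor``/``direction``. Branches
    not listed are conserved. A fixed ``seed`` makes every generator
    bit-reproducible.
    """

    extent: tuple = (-80.0, -40.0, -30.0, 10.0)
    resolution: float = 1.0
    n_vars: int = 3
    tree: str = DEFAULT_TREE
    branch_modes: dict = field(default_factory=dict)
    n_occurrences: int = 200
    seed: int = 0
    noise_sd: float = 0.25
    mask_fraction: float = 0.02
    vagrant_fraction: float = 0.05
    out_of_window_fraction: float = 0.1
    partition_shrink: float = 0.5
    shift_factor: float = 1.6
    m_layout: str = "tiled"  # or "shared"

    def __post_init__(self):
        west, east, south, north = self.extent
        if not (east > west and north > south):
            raise ValueError("degenerate extent: east must exceed west and north exceed south")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_vars < 2:
            raise ValueError("n_vars must be >= 2")
        for label, mode in self.branch_modes.items():
            name = mode["mode"] if isinstance(mode, dict) else mode
            if name not in {"conserve", "partition", "shift"}:
                raise ValueError(f"unknown branch mode {name!r} for {label!r}")

    @property
    def grid(self) -> GridSpec:
        west, east, south, north = self.extent
        ncols = int(round((east - west) / self.resolution))
        nrows = int(round((north - south) / self.resolution))
        return GridSpec(west=west, south=south, resolution=self.resolution,
                        nrows=nrows, ncols=ncols)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "extent" in raw:
            raw["extent"] = tuple(raw["extent"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def make_env_stack(config: SimConfig) -> EnvStack:
    """Smooth multi-variable environmental grid with noise and a nodata mask.

    Each layer is a quadratic polynomial trend in (lon, lat) — coefficients
    drawn once from the seeded RNG — plus iid Gaussian noise of standard
    deviation ``noise_sd``. A random ``mask_fraction`` of cells is marked
    nodata in all layers.
    """
    grid = config.grid
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    lon = grid.lon_centers()
    lat = grid.lat_centers()
    # normalized coordinates in [-1, 1]
    x = 2 * (lon - lon.min()) / max(lon.max() - lon.min(), 1e-12) - 1
    y = 2 * (lat - lat.min()) / max(lat.max() - lat.min(), 1e-12) - 1
    X, Y = np.meshgrid(x, y)
    layers = []
    for _ in range(config.n_vars):
        coef = rng.normal(0.0, 1.0, size=6)
        trend = (coef[0] + 2.0 * coef[1] * X + 2.0 * coef[2] * Y
                 + coef[3] * X**2 + coef[4] * X * Y + coef[5] * Y**2)
        noise = rng.normal(0.0, config.noise_sd, size=trend.shape) if config.noise_sd > 0 else 0.0
        layers.append(trend + noise)
    data = np.stack(layers)
    mask = np.ones((grid.nrows, grid.ncols), dtype=bool)
    if config.mask_fraction > 0:
        n_cells = grid.nrows * grid.ncols
        n_masked = int(round(config.mask_fraction * n_cells))
        if n_masked:
            flat = rng.choice(n_cells, size=n_masked, replace=False)
            mask.ravel()[flat] = False
    names = [f"env{i + 1}" for i in range(config.n_vars)]
    return EnvStack(names, grid, data, mask)


# ---------------------------------------------------------------------------
# niche evolution along the tree
# ---------------------------------------------------------------------------


def _mode_spec(config: SimConfig, label: str | None) -> dict:
    raw = config.branch_modes.get(label, "conserve") if label is not None else "conserve"
    if isinstance(raw, str):
        raw = {"mode": raw}
    out = {"mode": raw.get("mode", "conserve"),
           "shrink": float(raw.get("shrink", config.partition_shrink)),
           "factor": float(raw.get("factor", config.shift_factor)),
           "direction": raw.get("direction")}
    return out


def evolve_niches(config: SimConfig, root: TrueNiche) -> dict:
    """Propagate the root niche down the tree under per-branch modes.

    conserve: child = parent. partition: covariance shrunk by shrink^2 and
    centroid displaced inside the parent ellipsoid so the child's 95% region
    is contained in the parent's. shift: centroid displaced to
    ``factor`` x the parent's 95% Mahalanobis radius (outside the parent
    region), covariance unchanged. Returns tip label -> TrueNiche (internal
    node niches are available under their labels too).
    """
    tree = read_tree(config.tree)
    p = root.n_vars
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    niches: dict[str, TrueNiche] = {}
    parent_niche = {tree.seed_node: root}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            label = node_label(node) or "root"
            niches[label] = root
            continue
        parent = parent_niche[node.parent_node]
        spec = _mode_spec(config, node_label(node))
        mode = spec["mode"]
        L = np.linalg.cholesky(parent.covariance)
        # a deterministic draw per node keeps seeds reproducible across modes
        raw_dir = rng.normal(size=p)
        if spec["direction"] is not None:
            # explicit env-space direction, normalized to unit Mahalanobis length
            v = np.asarray(spec["direction"], dtype=float)
            mnorm = float(np.sqrt(v @ np.linalg.inv(parent.covariance) @ v))
            step = v / mnorm
        else:
            # random direction, uniform on the Mahalanobis unit sphere
            unit = raw_dir / np.linalg.norm(raw_dir)
            step = L @ unit
        r95 = parent.radius(0.95)
        label = node_label(node) or f"node{id(node)}"
        if mode == "conserve":
            child = TrueNiche(label, parent.centroid, parent.covariance)
        elif mode == "partition":
            shrink = spec["shrink"]
            if shrink >= 1:
                raise ValueError(f"partition shrink must be < 1, got {shrink}")
            # centroid at 0.9 of the slack so the child 95% region stays inside
            d = 0.9 * (1.0 - shrink) * r95
            centroid = parent.centroid + d * step
            child = TrueNiche(label, centroid, shrink**2 * parent.covariance)
        else:  # shift
            d = spec["factor"] * r95
            centroid = parent.centroid + d * step
            child = TrueNiche(label, centroid, parent.covariance.copy())
        niches[label] = child
        parent_niche[node] = child
    tips = {leaf.taxon.label: niches[leaf.taxon.label] for leaf in tree.leaf_node_iter()}
    tips.update({k: v for k, v in niches.items() if k not in tips})
    return tips


# ---------------------------------------------------------------------------
# accessible areas
# ---------------------------------------------------------------------------


def make_accessible_areas(config: SimConfig) -> dict:
    """Per-tip M polygons over the grid.

    ``tiled``: tips are laid out round-robin on a 3x3 grid of boxes, each
    inflated by 25% so neighbouring Ms overlap (allopatric-to-parapatric
    mosaic). ``shared``: every tip's M is the full grid extent.
    """
    tree = read_tree(config.tree)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    west, east, south, north = config.extent
    areas = {}
    if config.m_layout == "shared":
        poly = box(west, south, east, north)
        for t in tips:
            areas[t] = AccessibleArea(t, (poly,))
        return areas
    nx = ny = 3
    dx = (east - west) / nx
    dy = (north - south) / ny
    for i, t in enumerate(tips):
        cx = i % nx
        cy = (i // nx) % ny
        w = west + cx * dx - 0.25 * dx
        e = west + (cx + 1) * dx + 0.25 * dx
        s = south + cy * dy - 0.25 * dy
        n = south + (cy + 1) * dy + 0.25 * dy
        poly = box(max(w, west), max(s, south), min(e, east), min(n, north))
        areas[t] = AccessibleArea(t, (poly,))
    return areas


# ---------------------------------------------------------------------------
# occurrence sampling
# ---------------------------------------------------------------------------


def _breeding_months(hemisphere: str) -> list:
    return sorted(NORTH_BREEDING_MONTHS) if hemisphere == "north" else sorted(SOUTH_BREEDING_MONTHS)


def sample_occurrences(niche: TrueNiche, m: AccessibleArea, stack: EnvStack,
                       n: int, seed, vagrant_fraction: float = 0.0,
                       out_of_window_fraction: float = 0.0,
                       hemisphere: str | None = None) -> OccurrenceSet:
    """Occurrence records drawn from an ellipsoidal niche within M.

    Cells inside M are sampled with probability proportional to
    exp(-d^2 / 2), d the Mahalanobis distance of the cell's environmental
    vector under the niche; point coordinates are jittered uniformly within
    the cell. A ``vagrant_fraction`` of extra points is drawn uniformly from
    unmasked cells outside M, and an ``out_of_window_fraction`` of records
    receives a month outside the hemisphere's breeding window.
    """
    rng = np.random.default_rng(seed)
    rows, cols = stack.cells_in_area(m)
    if len(rows) == 0:
        raise ValueError(f"M for {m.taxon!r} contains no unmasked cell")
    vec = stack.data[:, rows, cols].T
    d = niche.mahalanobis(vec)
    logw = -0.5 * d**2
    w = np.exp(logw - logw.max())
    w /= w.sum()
    if n > len(rows):
        warnings.warn(
            f"requested {n} occurrences but only {len(rows)} cells in M; sampling with replacement")
    pick = rng.choice(len(rows), size=n, replace=True, p=w)
    clon, clat = stack.cell_lonlat(rows[pick], cols[pick])
    res = stack.grid.resolution
    lon = clon + rng.uniform(-0.5, 0.5, size=n) * res
    lat = clat + rng.uniform(-0.5, 0.5, size=n) * res
    # jitter must not push a within-M point across the M boundary
    outside = ~m.covers_xy(lon, lat)
    lon[outside] = clon[outside]
    lat[outside] = clat[outside]

    n_vagrant = int(round(vagrant_fraction * n))
    if n_vagrant:
        vrows, vcols = np.nonzero(stack.mask & ~stack.area_mask(m))
        if len(vrows):
            vpick = rng.integers(0, len(vrows), size=n_vagrant)
            vlon, vlat = stack.cell_lonlat(vrows[vpick], vcols[vpick])
            vlon = vlon + rng.uniform(-0.45, 0.45, size=n_vagrant) * res
            vlat = vlat + rng.uniform(-0.45, 0.45, size=n_vagrant) * res
            lon = np.concatenate([lon, vlon])
            lat = np.concatenate([lat, vlat])

    total = len(lon)
    if hemisphere is None:
        hemisphere = "north" if m.geometry.centroid.y >= 0 else "south"
    months_in = _breeding_months(hemisphere)
    months_out = sorted(set(range(1, 13)) - set(months_in))
    month = rng.choice(months_in, size=total)
    n_out = int(round(out_of_window_fraction * total))
    if n_out:
        which = rng.choice(total, size=n_out, replace=False)
        month[which] = rng.choice(months_out, size=n_out)
    records = pd.DataFrame({
        "lon": lon,
        "lat": lat,
        "year": rng.integers(2015, 2022, size=total),
        "month": month,
        "day": rng.integers(1, 29, size=total),
        "source_id": [f"{niche.taxon}-{i}" for i in range(total)],
    })
    prov = [{"step": "simulate", "n_in": 0, "n_out": total, "seed": int(seed) if np.isscalar(seed) else None,
             "n_vagrant": n_vagrant, "n_out_of_window": n_out}]
    return OccurrenceSet(niche.taxon, records, prov)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimConfig
    stack: EnvStack
    tree: str
    niches: dict           # label -> TrueNiche (tips and internal nodes)
    areas: dict            # tip -> AccessibleArea
    occurrences: dict      # tip -> OccurrenceSet


def default_root_niche(config: SimConfig, stack: EnvStack) -> TrueNiche:
    """Root niche centered on the grid-median environment, moderately broad.

    The covariance is diagonal at (0.6 x layer SD)^2, so the ancestral 95%
    ellipsoid spans a substantial but proper subset of available conditions.
    """
    _, _, vec = stack.valid_cell_vectors()
    centroid = np.median(vec, axis=0)
    sd = vec.std(axis=0, ddof=1)
    cov = np.diag((0.6 * sd)**2)
    return TrueNiche("root", centroid, cov)


def simulate_dataset(config: SimConfig, root: TrueNiche | None = None) -> SimulatedDataset:
    """End-to-end synthetic study system for the full pipeline."""
    stack = make_env_stack(config)
    if root is None:
        root = default_root_niche(config, stack)
    niches = evolve_niches(config, root)
    areas = make_accessible_areas(config)
    seeds = np.random.SeedSequence([config.seed, 37]).spawn(len(areas))
    occurrences = {}
    for (tip, m), ss in zip(sorted(areas.items()), seeds):
        occurrences[tip] = sample_occurrences(
            niches[tip], m, stack, config.n_occurrences, ss,
            vagrant_fraction=config.vagrant_fraction,
            out_of_window_fraction=config.out_of_window_fraction,
        )
    return SimulatedDataset(config, stack, config.tree, niches, areas, occurrences)


#: two-tip tree used by pairwise calibration scenarios
PAIR_TREE = "(spA:1.0,spB:1.0)root;"


def make_pair_scenario(kind: str, seed: int, n_occurrences: int = 200,
                       n_vars: int = 3, shift_factor: float = 2.5):
    """Two-taxon study system for calibrating the background similarity test.

    ``kind="conserve"``: both tips inherit the root niche unchanged and share
    an identical M spanning the full grid — the null regime of the test, under
    which a -2 (divergence) verdict is a false positive.

    ``kind="shift"``: the tips' Ms are disjoint west/east thirds of the grid
    and spB's niche centroid sits at the mean environment of M_B, placed
    ``shift_factor`` x the root's 95% Mahalanobis radius away from the root
    centroid (the mean environment of M_A). With ``shift_factor`` > 2 the two
    95% ellipsoids cannot intersect, i.e. the taxa occupy non-overlapping
    environments, the regime where the test should report divergence. The
    root covariance scale is solved from that displacement, so the scenario
    adapts to however strong the simulated gradient happens to be.

    Returns (stack, areas, matrices): per-taxon accessible areas and
    occurrence environmental matrices ready for ``similarity_test``.
    """
    from .env_layers import extract  # local import to avoid cycles at module load

    west, east, south, north = SimConfig().extent
    if kind == "conserve":
        cfg = SimConfig(tree=PAIR_TREE, n_vars=n_vars, seed=seed,
                        n_occurrences=n_occurrences, m_layout="shared",
                        vagrant_fraction=0.0, out_of_window_fraction=0.0)
        stack = make_env_stack(cfg)
        root = default_root_niche(cfg, stack)
        niches = evolve_niches(cfg, root)
        poly = box(west, south, east, north)
        areas = {t: AccessibleArea(t, (poly,)) for t in ("spA", "spB")}
    elif kind == "shift":
        third = (east - west) / 3.0
        areas = {
            "spA": AccessibleArea("spA", (box(west, south, west + third, north),)),
            "spB": AccessibleArea("spB", (box(east - third, south, east, north),)),
        }
        cfg = SimConfig(tree=PAIR_TREE, n_vars=n_vars, seed=seed,
                        n_occurrences=n_occurrences,
                        vagrant_fraction=0.0, out_of_window_fraction=0.0)
        stack = make_env_stack(cfg)
        mean_env = {}
        for t, m in areas.items():
            rows, cols = stack.cells_in_area(m)
            mean_env[t] = stack.data[:, rows, cols].mean(axis=1)
        delta = mean_env["spB"] - mean_env["spA"]
        _, _, vec = stack.valid_cell_vectors()
        sd = vec.std(axis=0, ddof=1)
        r95 = float(np.sqrt(stats.chi2.ppf(0.95, n_vars)))
        # diagonal covariance (s * sd)^2 with s solved so that the Mahalanobis
        # distance of mean_env[spB] from the root equals shift_factor * r95
        s = float(np.linalg.norm(delta / sd)) / (shift_factor * r95)
        root = TrueNiche("root", mean_env["spA"], np.diag((s * sd) ** 2))
        cfg.branch_modes = {"spB": {"mode": "shift", "factor": shift_factor,
                                    "direction": delta.tolist()}}
        niches = evolve_niches(cfg, root)
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")

    seeds = np.random.SeedSequence([seed, 53]).spawn(2)
    matrices = {}
    for (t, ss) in zip(("spA", "spB"), seeds):
        occ = sample_occurrences(niches[t], areas[t], stack, n_occurrences, ss)
        matrices[t], _ = extract(stack, occ.records["lon"], occ.records["lat"])
    return stack, areas, matrices


def write_dataset(ds: SimulatedDataset, directory) -> None:
    """Write occurrences (CSV), env layers (.asc), Ms (GeoJSON), tree (Newick)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = []
    for tip, occ in sorted(ds.occurrences.items()):
        df = occ.records.rename(columns={"lon": "decimalLongitude", "lat": "decimalLatitude"})
        df.insert(0, "taxon", tip)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(directory / "occurrences.csv", index=False)
    ds.stack.write_ascii(directory / "env")
    write_accessible_areas([ds.areas[t] for t in sorted(ds.areas)], directory / "ms.geojson")
    with open(directory / "tree.nwk", "w") as fh:
        fh.write(ds.tree if ds.tree.endswith("\n") else ds.tree + "\n")
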