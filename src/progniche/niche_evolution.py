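"""Binned niche characters and ancestral reconstruction on a phylogeny.

Each environmental variable's pooled range is partitioned into equal-width
bins, and each taxon is coded per bin as ``present`` (an occurrence value
falls in the bin), ``absent`` (no occurrence, but the bin's conditions occur
in the taxon's accessible area M), or ``uncertain`` (the bin's conditions do
not occur within M, so the taxon never had access to them). These
present/absent/uncertain characters are reconstructed over the phylogeny
with Fitch parsimony (uncertain tips are compatible with both states;
internal nodes whose minimum-change state set contains both states are
reported ambiguous), and per-branch summaries count bins gained
(absent -> present, niche expansion) and lost (present -> absent,
contraction).

Also provides the tree surgery used when a study tree lacks a taxon: a new
tip can be inserted as sister to an existing tip, splitting the sister's
terminal branch at a chosen fraction of its length, preserving
ultrametricity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .synthetic_data import node_label, read_tree

PRESENT, ABSENT, UNCERTAIN = "present", "absent", "uncertain"
_STATE_CODE = {PRESENT: 0, ABSENT: 1}


# ---------------------------------------------------------------------------
# tree surgery
# ---------------------------------------------------------------------------


def insert_tip(tree: dendropy.Tree, new_tip: str, sister: str,
               fraction: float = 0.5) -> dendropy.Tree:
    """Attach ``new_tip`` as sister to an existing tip.

    The sister's terminal branch is split at ``fraction`` x its length from
    the parent node; the new tip hangs from the created node with a terminal
    branch equal to the remaining (1 - fraction) share, so an ultrametric
    input stays ultrametric. Returns a new tree; the input is not modified.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie strictly between 0 and 1")
    tree = tree.clone(depth=1)
    leaf = None
    for node in tree.leaf_node_iter():
        if node.taxon is not None and node.taxon.label == sister:
            leaf = node
            break
    if leaf is None:
        raise KeyError(f"sister tip {sister!r} not found in tree")
    L = leaf.edge.length
    if L is None or L <= 0:
        raise ValueError(f"sister tip {sister!r} has no positive branch length")
    parent = leaf.parent_node
    parent.remove_child(leaf)
    mid = parent.new_child(edge_length=fraction * L)
    mid.add_child(leaf)
    leaf.edge.length = (1.0 - fraction) * L
    taxon = tree.taxon_namespace.require_taxon(label=new_tip)
    mid.new_child(taxon=taxon, edge_length=(1.0 - fraction) * L)
    return tree


def prune_tip(tree: dendropy.Tree, tip: str) -> dendropy.Tree:
    """Remove a tip and merge the unifurcation it leaves behind."""
    tree = tree.clone(depth=1)
    tree.prune_taxa_with_labels([tip], suppress_unifurcations=True)
    tree.purge_taxon_namespace()
    return tree


def tip_depths(tree: dendropy.Tree) -> dict:
    """Root-to-tip path lengths keyed by tip label."""
    depths = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


# ---------------------------------------------------------------------------
# character construction
# ---------------------------------------------------------------------------


@dataclass
class NicheCharacterTable:
    """Per-variable bin x taxon occupancy states for ancestral reconstruction."""

    variable: str
    bin_edges: np.ndarray          # length n_bins + 1, strictly increasing
    states: pd.DataFrame           # rows = bins, columns = taxa, entries P/A/U

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.bin_edges) != len(self.states) + 1:
            raise ValueError("edges must be one longer than the bin count")
        bad = ~self.states.isin([PRESENT, ABSENT, UNCERTAIN]).all()
        if bad.any():
            raise ValueError(f"invalid states in columns {list(self.states.columns[bad])}")
        no_present = [t for t in self.states.columns
                      if not (self.states[t] == PRESENT).any()]
        if no_present:
            raise ValueError(f"taxa with no present bin for {self.variable!r}: {no_present}")

    @property
    def n_bins(self) -> int:
        return len(self.states)

    def to_frame(self) -> pd.DataFrame:
        out = self.states.copy()
        out.insert(0, "bin_lo", self.bin_edges[:-1])
        out.insert(1, "bin_hi", self.bin_edges[1:])
        out.insert(0, "variable", self.variable)
        return out


def _bin_membership(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Boolean bin x 1 occupancy: lo <= x < hi, last bin closed above."""
    idx = np.digitize(values, edges[1:-1])
    out = np.zeros(len(edges) - 1, dtype=bool)
    out[np.unique(idx)] = True
    return out


def build_characters(occ: dict, bg: dict, n_bins: int = 10, variables=None,
                     trim_percent: float = 5.0, interval: bool = True) -> list:
    """Binned occupancy characters for every environmental variable.

    ``occ`` and ``bg`` map taxon -> EnvMatrix (occurrence and M-background
    environmental values on the same variable set). Per variable, the pooled
    range over all taxa's background (extended by any occurrence values, so
    every record is classifiable) is split into ``n_bins`` equal-width bins;
    state(taxon, bin) = present if the bin intersects the taxon's occupied
    interval on that variable, absent if not but background values fall in
    the bin, uncertain if the bin lies outside the taxon's accessible
    environments.

    The occupied interval is the span between the taxon's occurrence
    quantiles at ``trim_percent / 2`` and ``100 - trim_percent / 2``: a
    realized niche on a continuous axis is an interval, so interior bins
    that happen to catch no sample are not coded as holes, and trimming the
    extreme tails keeps single stray records from extending the span — the
    conventional guard in bin-based niche coding. ``trim_percent=0`` with
    discrete membership semantics is available via ``interval=False``,
    which codes a bin present only when an occurrence value falls in it.
    """
    taxa = sorted(occ)
    if sorted(bg) != taxa:
        raise ValueError("occ and bg must cover the same taxa")
    for t in taxa:
        if len(occ[t]) == 0:
            raise ValueError(f"taxon {t!r} has zero occurrences")
        if list(occ[t].columns) != list(occ[taxa[0]].columns):
            raise ValueError("all taxa must share one variable set")
    if variables is None:
        variables = list(occ[taxa[0]].columns)
    tables = []
    for var in variables:
        pooled = np.concatenate(
            [bg[t][var].to_numpy() for t in taxa] + [occ[t][var].to_numpy() for t in taxa])
        lo, hi = float(pooled.min()), float(pooled.max())
        if hi <= lo:
            warnings.warn(f"variable {var!r} is constant across taxa; skipped")
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        states = pd.DataFrame(UNCERTAIN, index=range(n_bins), columns=taxa)
        for t in taxa:
            vals = occ[t][var].to_numpy()
            if trim_percent > 0 and len(vals) > 2:
                q_lo, q_hi = np.percentile(vals, [trim_percent / 2, 100 - trim_percent / 2])
                vals = vals[(vals >= q_lo) & (vals <= q_hi)]
            if interval and len(vals) > 0:
                # occupied span: every bin intersecting [min, max] is present
                lo_bin = int(np.digitize(vals.min(), edges[1:-1]))
                hi_bin = int(np.digitize(vals.max(), edges[1:-1]))
                occ_bins = np.zeros(n_bins, dtype=bool)
                occ_bins[lo_bin:hi_bin + 1] = True
            else:
                occ_bins = _bin_membership(vals, edges)
            bg_bins = _bin_membership(bg[t][var].to_numpy(), edges)
            states[t] = np.where(occ_bins, PRESENT, np.where(bg_bins, ABSENT, UNCERTAIN))
        tables.append(NicheCharacterTable(var, edges, states))
    return tables


# ---------------------------------------------------------------------------
# ancestral reconstruction (Fitch / two-state Sankoff)
# ---------------------------------------------------------------------------


@dataclass
class AncestralStates:
    """Per-node, per-bin reconstructed states for one variable.

    ``states`` rows are bins, columns node labels (tips and internal);
    entries in {present, absent, uncertain} with ``uncertain`` meaning the
    minimum-change set contains both states (ambiguous) or no tip carried
    information. ``score`` is the parsimony change count per bin.
    """

    variable: str
    states: pd.DataFrame
    score: np.ndarray
    root_label: str
    method: str = "fitch"


def _ensure_labels(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node_label(node) is None:
            node.label = f"node{i}"
        i += 1


def reconstruct(tree: dendropy.Tree | str, table: NicheCharacterTable,
                method: str = "fitch") -> AncestralStates:
    """Minimum-change ancestral occupancy per bin over the tree.

    Two-state (present/absent) parsimony via the Sankoff dynamic program,
    which for unit costs reproduces Fitch counts; ``uncertain`` tips carry
    zero cost for both states. A node's reported state is the one present in
    *every* minimum-change labeling's state set at that node; nodes whose
    minimum-change set holds both states are reported ``uncertain``
    (ambiguous). Bins with no informative tip yield an uncertain root and a
    warning. Branch lengths are ignored (unweighted parsimony).
    """
    if method != "fitch":
        raise NotImplementedError("only Fitch/unweighted parsimony is implemented")
    if isinstance(tree, str):
        tree = read_tree(tree)
    tree = tree.clone(depth=1)
    _ensure_labels(tree)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(table.states.columns)
    if missing:
        raise ValueError(f"character table lacks tip columns: {sorted(missing)}")

    nodes = list(tree.postorder_node_iter())
    labels = [node_label(n) for n in nodes]
    n_bins = table.n_bins
    INF = float("inf")
    out = pd.DataFrame(UNCERTAIN, index=range(n_bins), columns=labels)
    scores = np.zeros(n_bins)

    for b in range(n_bins):
        informative = False
        cost = {}
        # leaf-to-root pass: cost[v][s] = min changes in v's subtree with v = s
        for node in nodes:
            if node.is_leaf():
                state = table.states.loc[b, node.taxon.label]
                if state == UNCERTAIN:
                    cost[node] = np.zeros(2)
                else:
                    informative = True
                    c = np.full(2, INF)
                    c[_STATE_CODE[state]] = 0.0
                    cost[node] = c
            else:
                c = np.zeros(2)
                for child in node.child_nodes():
                    cc = cost[child]
                    c = c + np.minimum(cc, cc[::-1] + 1.0)
                cost[node] = c
        root = nodes[-1]
        if not informative:
            warnings.warn(f"bin {b} of {table.variable!r}: all tips uncertain")
            continue
        scores[b] = float(cost[root].min())
        # root-to-leaf pass: above[v][s] = min changes outside v's subtree with v = s
        above = {root: np.zeros(2)}
        for node in reversed(nodes):  # preorder
            if node.is_leaf():
                continue
            for child in node.child_nodes():
                # contribution of the other children plus the cost from above
                rest = above[node].copy()
                for sib in node.child_nodes():
                    if sib is child:
                        continue
                    sc = cost[sib]
                    rest = rest + np.minimum(sc, sc[::-1] + 1.0)
                cc = np.minimum(rest, rest[::-1] + 1.0)
                above[child] = cc
        total_min = scores[b]
        for node, label in zip(nodes, labels):
            if node.is_leaf():
                out.loc[b, label] = table.states.loc[b, node.taxon.label]
                continue
            tot = cost[node] + above[node]
            mpr = np.flatnonzero(tot <= total_min + 1e-9)
            if len(mpr) == 1:
                out.loc[b, label] = PRESENT if mpr[0] == 0 else ABSENT
            else:
                out.loc[b, label] = UNCERTAIN
    root_label = node_label(nodes[-1])
    return AncestralStates(table.variable, out, scores, root_label)


def parsimony_score_bruteforce(tree: dendropy.Tree | str,
                               tip_states: dict) -> tuple[float, set]:
    """Exhaustive minimum-change search over all internal labelings (oracle).

    ``tip_states`` maps tip label -> state in {present, absent, uncertain}.
    Returns (minimum change count, set of root states attaining it). Only
    feasible for small trees (<= ~10 internal nodes).
    """
    import itertools

    if isinstance(tree, str):
        tree = read_tree(tree)
    tree = tree.clone(depth=1)
    _ensure_labels(tree)
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = float("inf")
    root_states = set()
    for assign in itertools.product([0, 1], repeat=len(internals)):
        lab = dict(zip(internals, assign))
        changes = 0
        for node, s in lab.items():
            if node.parent_node is not None and s != lab[node.parent_node]:
                changes += 1
        # a leaf contributes 0 if its allowed set contains the parent state
        for node in internals:
            for child in node.child_nodes():
                if child.is_leaf():
                    s = tip_states[child.taxon.label]
                    if s != UNCERTAIN and _STATE_CODE[s] != lab[node]:
                        changes += 1
        if changes < best:
            best = changes
            root_states = {assign[0]}
        elif changes == best:
            root_states.add(assign[0])
    names = {0: PRESENT, 1: ABSENT}
    return best, {names[s] for s in root_states}


# ---------------------------------------------------------------------------
# branch-change classification
# ---------------------------------------------------------------------------


def classify_changes(states: AncestralStates, tree: dendropy.Tree | str) -> pd.DataFrame:
    """Per-branch counts of bins gained and lost along the tree.

    For each branch (parent -> child) counts bins changing absent ->
    present (expansion) and present -> absent (contraction); bins where
    either endpoint is uncertain/ambiguous are excluded from both counts and
    tallied under ``ambiguous``.
    """
    if isinstance(tree, str):
        tree = read_tree(tree)
    tree = tree.clone(depth=1)
    _ensure_labels(tree)
    rows = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child = node_label(node)
        parent = node_label(node.parent_node)
        ps = states.states[parent]
        cs = states.states[child]
        informative = (ps != UNCERTAIN) & (cs != UNCERTAIN)
        rows.append({
            "variable": states.variable,
            "parent": parent,
            "child": child,
            "expansion": int(((ps == ABSENT) & (cs == PRESENT) & informative).sum()),
            "contraction": int(((ps == PRESENT) & (cs == ABSENT) & informative).sum()),
            "ambiguous": int((~informative).sum()),
        })
    return pd.DataFrame(rows)


def write_reconstruction(states: AncestralStates, path) -> None:
    """CSV of per-node states, bins as rows, node labels as columns."""
    out = states.states.copy()
    out.insert(0, "bin", range(len(out)))
    out.insert(0, "variable", states.variable)
    out.to_csv(path, index=False)
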