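"""Supertree pool construction for fossil taxa.

Source topologies (literature hypotheses on overlapping taxon sets) are
combined by matrix representation with parsimony (MRP): every internal
edge of every source tree becomes a binary character (Baum-Ragan coding:
clade members 1, other taxa of that source 0, absent taxa '?'), and
heuristic parsimony search over the full taxon set yields supertrees.
Each supertree topology is then stochastically time calibrated: tip ages
are drawn uniformly within each taxon's stratigraphic first-appearance
interval, node ages propagate upwards with a minimum branch length, and
named clades can carry minimum-age constraints.  Repeating the
calibration yields a pool of trees expressing both phylogenetic and
temporal uncertainty.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._phylo import topology_hash
from .errors import InputError

__all__ = [
    "SourceTopology",
    "MRPMatrix",
    "StratRange",
    "NodeConstraint",
    "CHRONOSTRAT_UNITS",
    "unit_bounds",
    "build_mrp_matrix",
    "fitch_length",
    "mrp_supertrees",
    "time_calibrate",
    "build_pool",
]

logger = logging.getLogger(__name__)

SourceTopology = dendropy.Tree  # alias: a source tree without branch lengths


@dataclass(frozen=True)
class StratRange:
    """Stratigraphic first-appearance interval of a taxon (Ma, older >= younger)."""

    taxon: str
    oldest: float
    youngest: float

    def __post_init__(self):
        if not (self.oldest >= self.youngest > 0):
            raise InputError(
                f"invalid stratigraphic range for {self.taxon}: {self.oldest}-{self.youngest}"
            )


@dataclass(frozen=True)
class NodeConstraint:
    """Minimum age (Ma) for the MRCA of a taxon set."""

    clade: frozenset
    min_age: float

    @staticmethod
    def of(taxa: Iterable[str], min_age: float) -> "NodeConstraint":
        return NodeConstraint(clade=frozenset(taxa), min_age=float(min_age))


#: Chronostratigraphic unit boundaries (Ma), ICS chart 2022 values, for the
#: units relevant to early-vertebrate first appearances.
CHRONOSTRAT_UNITS: dict[str, tuple[float, float]] = {
    # Cambrian
    "Furongian": (497.0, 485.4),
    # Ordovician
    "Tremadocian": (485.4, 477.7),
    "Floian": (477.7, 470.0),
    "Dapingian": (470.0, 467.3),
    "Darriwilian": (467.3, 458.4),
    "Sandbian": (458.4, 453.0),
    "Katian": (453.0, 445.2),
    "Hirnantian": (445.2, 443.8),
    # Silurian
    "Llandovery": (443.8, 433.4),
    "Rhuddanian": (443.8, 440.8),
    "Aeronian": (440.8, 438.5),
    "Telychian": (438.5, 433.4),
    "Wenlock": (433.4, 427.4),
    "Ludlow": (427.4, 423.0),
    "Pridoli": (423.0, 419.2),
    # Devonian
    "Lochkovian": (419.2, 410.8),
    "Pragian": (410.8, 407.6),
    "Emsian": (407.6, 393.3),
    "Eifelian": (393.3, 387.7),
    "Givetian": (387.7, 382.7),
    "Frasnian": (382.7, 372.2),
    "Famennian": (372.2, 358.9),
}


def unit_bounds(name: str) -> tuple[float, float]:
    """(oldest, youngest) boundary ages of a chronostratigraphic unit.

    Hyphenated spans like ``"Darriwilian-Sandbian"`` cover the union of
    the named units.
    """
    parts = [p.strip() for p in name.replace("–", "-").split("-")]
    try:
        bounds = [CHRONOSTRAT_UNITS[p] for p in parts]
    except KeyError as exc:
        raise InputError(f"unknown chronostratigraphic unit in {name!r}") from exc
    return max(b[0] for b in bounds), min(b[1] for b in bounds)


# ---------------------------------------------------------------------------
# MRP matrix


class MRPMatrix:
    """Taxa-by-characters matrix with values 1 (in clade), 0 (out), -1 ('?')."""

    def __init__(self, taxa: Sequence[str], data: np.ndarray):
        self.taxa = list(taxa)
        self.data = np.asarray(data, dtype=np.int8)
        if self.data.shape[0] != len(self.taxa):
            raise InputError("matrix row count does not match taxa")

    @property
    def n_characters(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, index=self.taxa)
        return df.replace(-1, "?")


def build_mrp_matrix(sources: Sequence[dendropy.Tree], master_taxa: Sequence[str] | None = None) -> MRPMatrix:
    """Baum-Ragan matrix representation of a set of source topologies.

    One character per non-trivial internal edge (clade) per source tree:
    clade members score 1, other taxa present in that source 0, taxa
    absent from the source '?'.
    """
    if len(sources) < 1:
        raise InputError("need at least one source topology")
    if master_taxa is None:
        seen: dict[str, None] = {}
        for src in sources:
            for leaf in src.leaf_node_iter():
                if leaf.taxon is None:
                    raise InputError("source tree has unlabeled tips")
                seen.setdefault(leaf.taxon.label)
        master_taxa = list(seen)
    index = {t: i for i, t in enumerate(master_taxa)}
    columns = []
    for src in sources:
        labels = []
        for leaf in src.leaf_node_iter():
            if leaf.taxon is None:
                raise InputError("source tree has unlabeled tips")
            labels.append(leaf.taxon.label)
        present = set(labels)
        extra = present - set(index)
        if extra:
            raise InputError(f"source taxa missing from master list: {sorted(extra)}")
        n_src = len(present)
        for node in src.postorder_internal_node_iter():
            clade = {l.taxon.label for l in node.leaf_iter()}
            if len(clade) < 2 or len(clade) >= n_src:
                continue
            col = np.full(len(index), -1, dtype=np.int8)
            for t in present:
                col[index[t]] = 0
            for t in clade:
                col[index[t]] = 1
            columns.append(col)
    data = np.column_stack(columns) if columns else np.zeros((len(index), 0), dtype=np.int8)
    return MRPMatrix(list(master_taxa), data)


# ---------------------------------------------------------------------------
# Fitch parsimony on an internal lightweight tree representation
#
# A topology is a dict {node_id: (child_a, child_b)}; leaves are ids in
# [0, n_taxa) equal to the row index of the taxon in the matrix, internal
# nodes get ids >= n_taxa, and the root is the largest id.  State sets are
# 2-bit masks per character: 1 = state 0, 2 = state 1, 3 = {0, 1} ('?').


def _charmatrix_to_masks(matrix: MRPMatrix) -> np.ndarray:
    masks = np.where(matrix.data == -1, 3, np.where(matrix.data == 1, 2, 1))
    return masks.astype(np.uint8)


def _postorder(children: dict, root: int) -> list[int]:
    order = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        if node in children:
            stack.extend(children[node])
    order.reverse()
    return order


def _fitch_score(children: dict, root: int, masks: np.ndarray, weights=None) -> int:
    state = {}
    steps = 0 if weights is None else 0.0
    for node in _postorder(children, root):
        if node not in children:
            state[node] = masks[node]
            continue
        a, b = children[node]
        sa, sb = state.pop(a), state.pop(b)
        inter = sa & sb
        empty = inter == 0
        if weights is None:
            steps += int(empty.sum())
        else:
            steps += float(weights[empty].sum())
        state[node] = np.where(empty, sa | sb, inter)
    return steps


def fitch_length(tree: dendropy.Tree, matrix: MRPMatrix) -> int:
    """Parsimony length of a tree under Fitch counting with '?' as missing.

    Polytomies are resolved arbitrarily before scoring (the score of any
    resolution upper-bounds the polytomy score; search trees are binary).
    """
    children, root, _ = _dendropy_to_internal(tree, matrix.taxa)
    return int(_fitch_score(children, root, _charmatrix_to_masks(matrix)))


def _dendropy_to_internal(tree: dendropy.Tree, taxa: Sequence[str]):
    index = {t: i for i, t in enumerate(taxa)}
    next_id = len(taxa)
    children: dict[int, tuple[int, int]] = {}

    def convert(node) -> int:
        nonlocal next_id
        if node.is_leaf():
            lbl = node.taxon.label if node.taxon else None
            if lbl not in index:
                raise InputError(f"tree tip {lbl!r} not in matrix taxa")
            return index[lbl]
        kids = [convert(ch) for ch in node.child_nodes()]
        while len(kids) > 1:  # arbitrary resolution of polytomies
            b = kids.pop()
            a = kids.pop()
            children[next_id] = (a, b)
            kids.append(next_id)
            next_id += 1
        return kids[0]

    root = convert(tree.seed_node)
    return children, root, next_id


def _internal_to_dendropy(children: dict, root: int, taxa: Sequence[str]) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(node_id):
        node = dendropy.Node()
        if node_id in children:
            for ch in children[node_id]:
                node.add_child(build(ch))
        else:
            node.taxon = ns.new_taxon(label=taxa[node_id])
        return node

    tree.seed_node = build(root)
    tree.is_rooted = True
    return tree


# -- heuristic search -------------------------------------------------------


def _random_addition_tree(n_taxa: int, masks: np.ndarray, rng) -> tuple[dict, int, int]:
    """Greedy stepwise addition in random taxon order."""
    order = list(rng.permutation(n_taxa))
    next_id = n_taxa
    a, b = order[0], order[1]
    children = {next_id: (a, b)}
    root = next_id
    next_id += 1
    for taxon in order[2:]:
        best = None
        edges = _edges(children, root)
        for parent, child in edges:
            cand = {k: v for k, v in children.items()}
            new_internal = next_id
            if parent is None:  # insert above the root
                cand[new_internal] = (child, taxon)
                cand_root = new_internal
            else:
                kids = list(cand[parent])
                kids[kids.index(child)] = new_internal
                cand[parent] = tuple(kids)
                cand[new_internal] = (child, taxon)
                cand_root = root
            score = _fitch_score(cand, cand_root, masks)
            if best is None or score < best[0]:
                best = (score, cand, cand_root)
        _, children, root = best
        next_id += 1
    return children, root, next_id


def _edges(children: dict, root: int):
    """All (parent, child) edges plus the virtual (None, root) edge."""
    out = [(None, root)]
    for parent, kids in children.items():
        for ch in kids:
            out.append((parent, ch))
    return out


def _nni_neighbors(children: dict, root: int):
    """Nearest-neighbour-interchange neighbours of a rooted binary tree."""
    parent_of = {}
    for p, kids in children.items():
        for ch in kids:
            parent_of[ch] = p
    for v, (x, y) in list(children.items()):
        if v == root:
            continue
        p = parent_of[v]
        sibs = [s for s in children[p] if s != v]
        if not sibs:
            continue
        s = sibs[0]
        for keep, move in ((x, y), (y, x)):
            cand = dict(children)
            cand[v] = (keep, s)
            kids_p = list(cand[p])
            kids_p[kids_p.index(s)] = move
            cand[p] = tuple(kids_p)
            yield cand, root


def _spr_neighbors(children: dict, root: int):
    """Subtree-prune-and-regraft neighbours (rooted representation)."""
    parent_of = {}
    for p, kids in children.items():
        for ch in kids:
            parent_of[ch] = p

    def subtree_nodes(node):
        out = {node}
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur in children:
                for ch in children[cur]:
                    out.add(ch)
                    stack.append(ch)
        return out

    for prune in list(parent_of):
        p = parent_of[prune]
        sibs = [s for s in children[p] if s != prune]
        if not sibs:
            continue
        sib = sibs[0]
        forbidden = subtree_nodes(prune) | {p}
        # remove prune: splice sib into p's place
        base = dict(children)
        del base[p]
        if p == root:
            new_root = sib
        else:
            gp = parent_of[p]
            kids_gp = list(base[gp])
            kids_gp[kids_gp.index(p)] = sib
            base[gp] = tuple(kids_gp)
            new_root = root
        for parent, child in _edges(base, new_root):
            if child in forbidden or child == sib and parent is None:
                continue
            cand = dict(base)
            if parent is None:
                cand[p] = (child, prune)
                yield cand, p
            else:
                kids = list(cand[parent])
                kids[kids.index(child)] = p
                cand[parent] = tuple(kids)
                cand[p] = (child, prune)
                yield cand, new_root


def mrp_supertrees(
    matrix: MRPMatrix,
    n_trees: int,
    seed: int = 0,
    search: str = "nni",
    max_equally_parsimonious: int | None = None,
    n_starts: int | None = None,
    outgroup: str | None = None,
) -> list[dendropy.Tree]:
    """Heuristic MRP search: random-addition starts + hill climbing.

    Collects the best (lowest Fitch length) trees found across all
    starts, deduplicates by unrooted topology, and returns up to
    ``n_trees`` of them; if fewer distinct optima are found, trees are
    repeated (with a log message) so the pool size is honoured.
    Deterministic given ``seed``.
    """
    if len(matrix.taxa) < 4:
        raise InputError("MRP search needs at least 4 taxa")
    if search not in ("nni", "spr"):
        raise InputError(f"unknown search strategy {search!r}")
    masks = _charmatrix_to_masks(matrix)
    rng = np.random.default_rng(seed)
    n_starts = n_starts or max(n_trees, 8)
    cap = max_equally_parsimonious or n_trees
    neighbor_fn = _nni_neighbors if search == "nni" else _spr_neighbors

    best_score = None
    found: dict[frozenset, tuple[dict, int]] = {}
    for _ in range(n_starts):
        children, root, _ = _random_addition_tree(len(matrix.taxa), masks, rng)
        score = _fitch_score(children, root, masks)
        improved = True
        while improved:
            improved = False
            for cand, cand_root in neighbor_fn(children, root):
                s = _fitch_score(cand, cand_root, masks)
                if s < score:
                    children, root, score = cand, cand_root, s
                    improved = True
                    break
        if best_score is None or score < best_score:
            best_score = score
            found = {}
        if score == best_score and len(found) < cap:
            tree = _internal_to_dendropy(children, root, matrix.taxa)
            key = topology_hash(tree)
            found.setdefault(key, (children, root))

    trees = [_internal_to_dendropy(ch, rt, matrix.taxa) for ch, rt in found.values()]
    if len(trees) < n_trees:
        logger.info(
            "found %d distinct equally parsimonious trees; sampling with replacement to %d",
            len(trees), n_trees,
        )
        idx = rng.integers(0, len(trees), size=n_trees - len(trees))
        trees = trees + [trees[i].clone(depth=1) for i in idx]
    trees = trees[:n_trees]
    if outgroup is not None:
        trees = [_root_on_outgroup(t, outgroup) for t in trees]
    for t in trees:
        t.score = best_score  # reported parsimony length
    return trees


def _root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon and leaf.taxon.label == outgroup:
            node = leaf
            break
    if node is None:
        raise InputError(f"outgroup {outgroup!r} not in tree")
    tree.reroot_at_edge(node.edge, update_bipartitions=False)
    return tree


def exhaustive_parsimony(matrix: MRPMatrix) -> tuple[int, list[dendropy.Tree]]:
    """Exhaustive search over all unrooted topologies (small taxon sets only).

    Enumerates topologies by stepwise insertion; intended as an oracle for
    testing the heuristic search on <= 8 taxa.
    """
    n = len(matrix.taxa)
    if n > 8:
        raise InputError("exhaustive search limited to 8 taxa")
    masks = _charmatrix_to_masks(matrix)
    best = [None, []]

    # The growing tree is kept rooted on the edge adjacent to taxon 0
    # (root children are (0, rest)); skipping insertions on the virtual
    # root edge and on (root, 0) enumerates each unrooted topology once:
    # 1 * 3 * 5 * ... * (2n-5) rooted layouts for n taxa.
    def recurse(children: dict, root: int, next_id: int, next_taxon: int):
        if next_taxon == n:
            score = _fitch_score(children, root, masks)
            if best[0] is None or score < best[0]:
                best[0], best[1] = score, [(dict(children), root)]
            elif score == best[0]:
                best[1].append((dict(children), root))
            return
        for parent, child in _edges(children, root):
            if parent is None or (parent == root and child == 0):
                continue
            cand = dict(children)
            kids = list(cand[parent])
            kids[kids.index(child)] = next_id
            cand[parent] = tuple(kids)
            cand[next_id] = (child, next_taxon)
            recurse(cand, root, next_id + 1, next_taxon + 1)

    recurse({n: (0, 1)}, n, n + 1, 2)
    trees = [_internal_to_dendropy(ch, rt, matrix.taxa) for ch, rt in best[1]]
    return int(best[0]), trees


# ---------------------------------------------------------------------------
# time calibration


def time_calibrate(
    topology: dendropy.Tree,
    ranges: Sequence[StratRange],
    constraints: Sequence[NodeConstraint] = (),
    seed: int = 0,
    min_branch: float = 1.0,
) -> dendropy.Tree:
    """Stochastic time calibration of a topology against tip-age ranges.

    Tip ages are sampled uniformly within each taxon's stratigraphic
    interval; each internal node's age is the oldest of its children's
    ages (and any applicable minimum-age constraint) plus ``min_branch``,
    so every branch has length >= ``min_branch`` and parents are strictly
    older than children.  Constraints on non-monophyletic taxon sets, and
    constraints already satisfied by sampled tip ages, are skipped or
    inactive with a log message.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    tree = topology.clone(depth=1)
    by_taxon = {r.taxon: r for r in ranges}
    ages: dict = {}
    for leaf in tree.leaf_node_iter():
        lbl = leaf.taxon.label
        if lbl not in by_taxon:
            raise InputError(f"no stratigraphic range for tip {lbl!r}")
        r = by_taxon[lbl]
        ages[leaf] = float(rng.uniform(r.youngest, r.oldest))

    constraint_nodes: dict = {}
    all_tips = {l.taxon.label for l in tree.leaf_node_iter()}
    for con in constraints:
        taxa = set(con.clade)
        if not taxa <= all_tips:
            logger.warning("constraint clade has taxa outside tree; skipped: %s", sorted(taxa)[:4])
            continue
        mrca = tree.mrca(taxon_labels=list(taxa))
        below = {l.taxon.label for l in mrca.leaf_iter()}
        if below != taxa:
            logger.warning("constraint clade not monophyletic; skipped: %s", sorted(taxa)[:4])
            continue
        constraint_nodes[mrca] = max(constraint_nodes.get(mrca, 0.0), con.min_age)

    for node in tree.postorder_internal_node_iter():
        candidate = max(ages[ch] for ch in node.child_nodes())
        if node in constraint_nodes:
            m = constraint_nodes[node]
            if m < candidate:
                logger.info("min-age constraint %.1f Ma inactive (children older)", m)
            candidate = max(candidate, m)
        ages[node] = candidate + min_branch

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        node.edge.length = ages[node.parent_node] - ages[node]
    for leaf in tree.leaf_node_iter():
        leaf.age_ma = ages[leaf]
    tree.root_age = ages[tree.seed_node]
    return tree


def build_pool(
    sources: Sequence[dendropy.Tree],
    ranges: Sequence[StratRange],
    constraints: Sequence[NodeConstraint] = (),
    n_topologies: int = 45,
    n_calibrations: int = 100,
    seed: int = 0,
    search: str = "nni",
    outgroup: str | None = None,
    min_branch: float = 1.0,
    n_starts: int | None = None,
) -> tuple[list[dendropy.Tree], list[dict]]:
    """MRP supertrees x stochastic calibrations -> pool of dated trees.

    Returns ``(pool, manifest)`` with ``n_topologies * n_calibrations``
    trees and one manifest entry (topology id, calibration id, seed) per
    tree.  Fully reproducible from ``seed``.
    """
    if n_topologies * n_calibrations < 1:
        raise InputError("pool must contain at least one tree")
    matrix = build_mrp_matrix(sources)
    topologies = mrp_supertrees(
        matrix, n_topologies, seed=seed, search=search, outgroup=outgroup, n_starts=n_starts
    )
    pool = []
    manifest = []
    for i, topo in enumerate(topologies):
        for j in range(n_calibrations):
            sub_seed = (seed + 100003 * i + 17 * j) % (2**31 - 1)
            tree = time_calibrate(topo, ranges, constraints, seed=sub_seed, min_branch=min_branch)
            pool.append(tree)
            manifest.append({"topology": i, "calibration": j, "seed": sub_seed})
    return pool, manifest
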