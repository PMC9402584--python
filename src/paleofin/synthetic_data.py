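"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: an extant
swimming-speed dataset (records + ultrametric phylogeny) drawn from a
known PGLS model, parametric caudal-fin outlines with controllable lobe
geometry, and a complete fossil study (true dated tree, overlapping
source topologies, stratigraphic tip ranges, node constraints and fin
outlines whose shape metrics evolve by Brownian motion on the true
tree).  Ground-truth parameters are returned alongside the data so every
stage of the pipeline can be checked for parameter recovery.

All generators are deterministic given the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._phylo import node_depths
from .errors import GeometryError, InputError
from .fin_geometry import FinOutline, compute_metrics, is_simple
from .pgls_speed import (
    BEST_FORMULA,
    build_design,
    record_tip_labels,
    resolve_record_polytomies,
)
from .tree_assembly import NodeConstraint, StratRange

__all__ = [
    "SimConfig",
    "simulate_fin_outline",
    "simulate_extant_dataset",
    "simulate_fossil_study",
    "FossilStudy",
    "simulate_bm_on_tree",
    "yule_tree",
    "fossil_birth_death_tree",
]


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults mirror the structure of the empirical datasets the pipeline
    targets: 160 speed records over 61 extant species with body lengths
    4-105 cm, 41 fossil taxa and 37 partially overlapping source
    topologies.
    """

    seed: int = 0
    n_species: int = 61
    n_records: int = 160
    length_range_cm: tuple[float, float] = (4.0, 105.0)
    #: generating coefficients of Speed ~ Length + Mode + HeWiCF + Cond
    true_beta: dict = field(
        default_factory=lambda: {
            "Intercept": 5.0,
            "Length": -0.02,
            "Mode[cruising]": -1.5,
            "HeWiCF": 0.5,
            "Cond[non-free]": -0.4,
        }
    )
    true_sigma2: float = 0.002  # BM rate of the phylogenetic residual, (BL/s)^2/Myr
    #: iid within-record noise (BL/s).  The regression model this package
    #: fits (zero-length record polytomies, pure BM residuals) contains no
    #: such term, so the default generator matches it exactly; raise this
    #: to probe robustness to model misspecification.
    noise_scale: float = 0.0
    tree_depth: float = 100.0  # extant tree root-to-tip depth, Myr
    n_fossils: int = 41
    n_sources: int = 37
    drift_mu: float = 0.0  # trend in fossil speeds, BL/s per Myr
    birth: float = 1.0  # birth-death rates per lineage per unit time
    death: float = 0.5
    fossil_root_age: float = 520.0  # Ma
    fossil_span: float = 150.0  # Myr from root to youngest fossil tip
    #: BM rates of the fossil fin-shape parameters (per Myr)
    shape_sigma2: dict = field(
        default_factory=lambda: {"he_wi": 6e-4, "chord": 2e-3, "asym": 5e-5, "log_length": 1e-3}
    )

    def __post_init__(self):
        if self.n_records < self.n_species:
            raise InputError("n_records must be >= n_species")
        lo, hi = self.length_range_cm
        if not (0 < lo < hi):
            raise InputError("length range must be positive and increasing")


# ---------------------------------------------------------------------------
# tree simulators


def yule_tree(n_tips: int, rng, depth: float = 100.0, prefix: str = "sp") -> dendropy.Tree:
    """Pure-birth ultrametric tree on ``n_tips``, rescaled to ``depth`` Myr."""
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    t = 0.0
    root = tree.seed_node
    birth_time = {root: 0.0}
    active = [root]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / max(len(active), 1))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.edge.length = t - birth_time.pop(node)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth_time[child] = t
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    for k, node in enumerate(active):
        node.edge.length = t - birth_time.pop(node)
        node.taxon = ns.new_taxon(label=f"{prefix}{k:03d}")
    scale = depth / t
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    tree.seed_node.edge.length = None
    return tree


def fossil_birth_death_tree(
    n_fossils: int, rng, birth: float = 1.0, death: float = 0.5,
    prefix: str = "fos", max_tries: int = 200,
) -> dendropy.Tree:
    """Birth-death tree pruned to its first ``n_fossils`` extinct tips.

    Forward simulation; extinct lineages become the fossil tips, so tip
    depths vary (the tree is non-ultrametric by construction).  Branch
    lengths are in simulation time units; callers rescale.
    """
    for _ in range(max_tries):
        ns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=ns)
        tree.is_rooted = True
        t = 0.0
        birth_time = {tree.seed_node: 0.0}
        active = [tree.seed_node]
        dead = 0
        while active and dead < n_fossils:
            rate = len(active) * (birth + death)
            t += rng.exponential(1.0 / rate)
            i = int(rng.integers(len(active)))
            node = active.pop(i)
            node.edge.length = t - birth_time.pop(node)
            if rng.random() < birth / (birth + death):
                for _ in range(2):
                    child = dendropy.Node()
                    node.add_child(child)
                    birth_time[child] = t
                    active.append(child)
            else:
                node.taxon = ns.new_taxon(label=f"{prefix}{dead:03d}")
                dead += 1
        if dead < n_fossils:
            continue
        for k, node in enumerate(active):  # survivors at stop time: label & prune
            node.edge.length = t - birth_time.pop(node)
            node.taxon = ns.new_taxon(label=f"alive{k:04d}")
        fossil_labels = [f"{prefix}{i:03d}" for i in range(n_fossils)]
        if active:
            tree.retain_taxa_with_labels(fossil_labels)
        if len(list(tree.leaf_node_iter())) == n_fossils:
            tree.seed_node.edge.length = None
            return tree
    raise InputError("birth-death simulation failed to yield enough fossil tips")


def simulate_bm_on_tree(
    tree: dendropy.Tree, sigma2: float, rng, root_value: float = 0.0,
    drift: float = 0.0,
) -> dict:
    """One BM (optionally drifting) realization; maps node -> value."""
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = root_value
            continue
        bl = node.edge.length or 0.0
        step = rng.normal(drift * bl, math.sqrt(max(sigma2 * bl, 0.0)))
        values[node] = values[node.parent_node] + step
    return values


# ---------------------------------------------------------------------------
# parametric fin outlines

_STYLES = {
    "symmetric": dict(asym=0.5, fork_depth=0.0),
    "forked": dict(asym=0.5, fork_depth=0.5),
    "epicercal": dict(asym=2.0 / 3.0, fork_depth=0.25),
    "hypocercal": dict(asym=1.0 / 3.0, fork_depth=0.25),
}


def _build_outline(
    span_dorsal: float,
    span_ventral: float,
    chord: float,
    base_height: float | None = None,
    fork_depth: float = 0.0,
    sharpness: float = 1.0,
    n_arc: int = 61,
    source_id: str = "",
) -> FinOutline:
    """Two sine-arch lobes over a shared chord, closed by the base edge.

    The dorsal (ventral) margin rises from the base corner to ``span``
    above (below) the chord axis and returns; the trailing edge is
    optionally notched inward by ``fork_depth`` of the chord.  Bounding
    extents are exactly ``span_dorsal + span_ventral`` (height) and
    ``chord`` (width), which gives closed forms for he_wi.
    """
    if min(span_dorsal, span_ventral, chord) <= 0:
        raise GeometryError("outline spans and chord must be positive")
    if base_height is None:
        base_height = 0.6 * min(span_dorsal, span_ventral)
    n_arc = int(n_arc) | 1  # odd: include the mid-chord sample so extents are exact
    b2 = base_height / 2.0
    if b2 >= min(span_dorsal, span_ventral):
        raise GeometryError("base height exceeds a lobe span")
    xs = np.linspace(0.0, chord, n_arc)
    upper = np.column_stack(
        [xs, b2 + (span_dorsal - b2) * np.sin(np.pi * xs / chord) ** sharpness]
    )
    lower = np.column_stack(
        [xs, -b2 - (span_ventral - b2) * np.sin(np.pi * xs / chord) ** sharpness]
    )[::-1]
    fork_depth = float(np.clip(fork_depth, 0.0, 0.9))
    notch_x = chord * (1.0 - fork_depth) if fork_depth > 0 else chord
    trailing = np.array([[notch_x, 0.0]])
    pts = np.vstack([upper, trailing, lower])
    out = FinOutline(pts, dorsal_base=0, ventral_base=len(pts) - 1, source_id=source_id)
    return out


def simulate_fin_outline(style: str, params: Mapping | None = None, seed: int = 0) -> FinOutline:
    """Parametric caudal-fin outline of a given style.

    ``params`` may override ``span`` (total height), ``chord`` (width),
    ``asym`` (dorsal share of the span: > 0.5 epicercal, < 0.5
    hypocercal), ``fork_depth``, ``sharpness`` and ``base_height``.
    Parameter combinations that self-intersect are retried with a small
    jitter before giving up.
    """
    if style not in _STYLES:
        raise GeometryError(f"unknown outline style {style!r}")
    p = dict(span=2.0, chord=2.0, sharpness=1.0, base_height=None, n_arc=61)
    p.update(_STYLES[style])
    p.update(params or {})
    rng = np.random.default_rng(seed)
    span, asym = float(p["span"]), float(p["asym"])
    for attempt in range(5):
        out = _build_outline(
            span_dorsal=span * asym,
            span_ventral=span * (1.0 - asym),
            chord=float(p["chord"]),
            base_height=p["base_height"],
            fork_depth=float(p["fork_depth"]),
            sharpness=float(p["sharpness"]),
            n_arc=int(p["n_arc"]),
            source_id=style,
        )
        if is_simple(out):
            return out
        span *= 1.0 + 0.01 * rng.random()  # jitter and retry
    raise GeometryError(f"could not build a simple outline for style {style!r}")


# ---------------------------------------------------------------------------
# extant dataset

_LOCTYPES = ("anguilliform", "carangiform", "median/paired fin", "thunniform")


def simulate_extant_dataset(cfg: SimConfig):
    """Synthetic extant swimming-speed dataset drawn from a known model.

    Returns ``(records, tree, truth)``: a records DataFrame (one row per
    speed record), the ultrametric species tree, and a ``truth`` dict
    holding the generating coefficients, BM rate, the resolved record
    tree and the per-record phylogenetic residuals.

    Speeds follow ``Speed ~ Length + Mode + HeWiCF + Cond`` with a BM
    residual simulated on the record tree (multi-record species resolved
    as zero-length polytomies, exactly as the fitting step assumes) plus
    iid noise of scale ``cfg.noise_scale``.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = yule_tree(cfg.n_species, rng, depth=cfg.tree_depth)
    species = [l.taxon.label for l in tree.leaf_node_iter()]

    # species-level attributes: group from the two root clades, one fin per species
    root_kids = tree.seed_node.child_nodes()
    chond = {l.taxon.label for l in root_kids[0].leaf_iter()} if len(root_kids) > 1 else set()
    sp_attr = {}
    for sp in species:
        style = rng.choice(["symmetric", "forked", "epicercal", "hypocercal"])
        span = float(np.exp(rng.normal(math.log(2.0), 0.3)))
        chord_v = float(np.exp(rng.normal(math.log(2.0), 0.3)))
        outline = simulate_fin_outline(
            str(style), {"span": span, "chord": chord_v}, seed=int(rng.integers(2**31 - 1))
        )
        metrics = compute_metrics(outline)
        lo, hi = cfg.length_range_cm
        length = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        sp_attr[sp] = dict(
            metrics=metrics,
            length=length,
            loc_type=str(rng.choice(_LOCTYPES)),
            group="chondrichthyan" if sp in chond else "osteichthyan",
        )

    rows = []
    assignment = list(species) + [species[int(rng.integers(cfg.n_species))]
                                  for _ in range(cfg.n_records - cfg.n_species)]
    for sp in assignment:
        a = sp_attr[sp]
        m = a["metrics"]
        rows.append(
            {
                "species": sp,
                "speed": np.nan,
                "Length": a["length"] * float(np.exp(rng.normal(0.0, 0.05))),
                "Mode": "cruising" if rng.random() < 0.5 else "burst",
                "Cond": "non-free" if rng.random() < 0.4 else "free",
                "LocType": a["loc_type"],
                "Group": a["group"],
                "HeWiCF": m.he_wi,
                "CircCF": m.circ,
                "RoundCF": m.round,
                "SolCF": m.sol,
                "AR": m.ar,
            }
        )
    df = pd.DataFrame(rows)

    rec_seed = int(rng.integers(2**31 - 1))
    rtree = resolve_record_polytomies(tree, df, seed=rec_seed)
    labels = record_tip_labels(df)
    X, names, _, _ = build_design(df, BEST_FORMULA)
    beta = np.array([cfg.true_beta[name] for name in names])
    mean = X @ beta

    for _ in range(200):
        bm = simulate_bm_on_tree(rtree, cfg.true_sigma2, rng)
        by_label = {l.taxon.label: bm[l] for l in rtree.leaf_node_iter()}
        resid = np.array([by_label[lbl] for lbl in labels])
        noise = rng.normal(0.0, cfg.noise_scale, size=len(df)) if cfg.noise_scale > 0 else 0.0
        speed = mean + resid + noise
        if speed.min() > 0.05:
            break
    else:
        raise InputError("could not generate strictly positive speeds; adjust parameters")
    df["speed"] = speed

    truth = {
        "formula": BEST_FORMULA,
        "beta": pd.Series(beta, index=names),
        "sigma2": cfg.true_sigma2,
        "noise_scale": cfg.noise_scale,
        "record_tree": rtree,
        "record_seed": rec_seed,
        "phylo_residuals": resid,
    }
    return df, tree, truth


# ---------------------------------------------------------------------------
# fossil study


@dataclass
class FossilStudy:
    """A complete synthetic fossil dataset with retained ground truth."""

    taxa: list
    true_tree: dendropy.Tree  # dated; tip ages on leaves (age_ma)
    tip_ages: dict  # taxon -> true age (Ma)
    outlines: dict  # taxon -> FinOutline
    max_lengths_cm: dict  # taxon -> float
    sources: list  # source topologies (no branch lengths)
    ranges: list  # StratRange per taxon
    constraints: list  # NodeConstraint
    clades: dict  # clade name -> taxon set (true clades)
    true_tip_params: dict  # taxon -> shape parameter dict
    true_node_params: dict  # frozenset(descendant taxa) -> shape parameter dict
    cfg: SimConfig


def _params_to_outline(p: Mapping, source_id: str = "") -> FinOutline:
    he_wi = max(float(p["he_wi"]), 0.2)
    chord = max(float(p["chord"]), 0.5)
    asym = float(np.clip(p["asym"], 0.15, 0.85))
    span = he_wi * chord
    return _build_outline(
        span_dorsal=span * asym,
        span_ventral=span * (1.0 - asym),
        chord=chord,
        fork_depth=float(p.get("fork_depth", 0.25)),
        source_id=source_id,
    )


def simulate_fossil_study(cfg: SimConfig) -> FossilStudy:
    """Synthetic fossil dataset: dated tree, sources, ranges, outlines.

    Fin-shape parameters (height-to-width ratio, chord, dorsal/ventral
    asymmetry) and log body length evolve by BM on the true tree (the
    he_wi parameter optionally with a drift so derived speeds trend at
    about ``cfg.drift_mu``); source topologies are induced subtrees of
    the true topology covering every taxon; stratigraphic ranges contain
    the true tip ages; constraints sit on true clades with minimum ages
    at or below the true node ages.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    tree = fossil_birth_death_tree(cfg.n_fossils, rng, cfg.birth, cfg.death)
    depths = node_depths(tree)
    max_depth = max(depths[l] for l in tree.leaf_node_iter())
    scale = cfg.fossil_span / max_depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    depths = node_depths(tree)
    taxa = [l.taxon.label for l in tree.leaf_node_iter()]
    tip_ages = {l.taxon.label: cfg.fossil_root_age - depths[l] for l in tree.leaf_node_iter()}
    for leaf in tree.leaf_node_iter():
        leaf.age_ma = tip_ages[leaf.taxon.label]
    tree.root_age = cfg.fossil_root_age

    # shape parameters by BM; drift on he_wi converts to a speed trend via
    # the generating HeWiCF coefficient
    beta_hewi = cfg.true_beta.get("HeWiCF", 0.5)
    hewi_drift = cfg.drift_mu / beta_hewi if beta_hewi else 0.0
    sims = {
        "he_wi": simulate_bm_on_tree(tree, cfg.shape_sigma2["he_wi"], rng, 1.2, drift=hewi_drift),
        "chord": simulate_bm_on_tree(tree, cfg.shape_sigma2["chord"], rng, 2.0),
        "asym": simulate_bm_on_tree(tree, cfg.shape_sigma2["asym"], rng, 0.5),
        "log_length": simulate_bm_on_tree(tree, cfg.shape_sigma2["log_length"], rng, math.log(20.0)),
    }

    def node_params(node) -> dict:
        return {k: float(v[node]) for k, v in sims.items()}

    true_tip_params, outlines, max_lengths = {}, {}, {}
    for leaf in tree.leaf_node_iter():
        t = leaf.taxon.label
        p = node_params(leaf)
        true_tip_params[t] = p
        outlines[t] = _params_to_outline(p, source_id=t)
        max_lengths[t] = float(np.clip(np.exp(p["log_length"]), *cfg.length_range_cm))
    true_node_params = {}
    for node in tree.preorder_internal_node_iter():
        key = frozenset(l.taxon.label for l in node.leaf_iter())
        true_node_params[key] = node_params(node)

    # stratigraphic ranges containing the true ages
    ranges = []
    for t in taxa:
        pad_old = float(rng.uniform(1.0, 8.0))
        pad_young = float(rng.uniform(1.0, 8.0))
        ranges.append(StratRange(t, tip_ages[t] + pad_old, max(tip_ages[t] - pad_young, 1.0)))

    # overlapping source topologies covering all taxa
    n = len(taxa)
    sources = []
    subsets = []
    for _ in range(cfg.n_sources):
        size = int(rng.integers(max(4, int(0.3 * n)), max(5, int(0.8 * n)) + 1))
        subsets.append(set(rng.choice(taxa, size=size, replace=False)))
    covered = set().union(*subsets)
    for t in set(taxa) - covered:
        subsets[int(rng.integers(len(subsets)))].add(t)
    for sub in subsets:
        src = tree.clone(depth=1)
        src.retain_taxa_with_labels(list(sub))
        for edge in src.preorder_edge_iter():
            edge.length = None
        sources.append(src)

    # minimum-age constraints on true clades (consistent with true ages)
    internal = [nd for nd in tree.preorder_internal_node_iter()
                if nd.parent_node is not None and sum(1 for _ in nd.leaf_iter()) >= 4]
    rng.shuffle(internal)
    constraints = []
    clades = {}
    for i, node in enumerate(internal[:3]):
        members = frozenset(l.taxon.label for l in node.leaf_iter())
        age = cfg.fossil_root_age - depths[node]
        constraints.append(NodeConstraint(members, max(age - float(rng.uniform(2.0, 10.0)), 1.0)))
        clades[f"clade{i}"] = set(members)

    return FossilStudy(
        taxa=taxa,
        true_tree=tree,
        tip_ages=tip_ages,
        outlines=outlines,
        max_lengths_cm=max_lengths,
        sources=sources,
        ranges=ranges,
        constraints=constraints,
        clades=clades,
        true_tip_params=true_tip_params,
        true_node_params=true_node_params,
        cfg=cfg,
    )


def true_speed(params: Mapping, beta: pd.Series, length_cm: float | None = None) -> float:
    """Ground-truth speed implied by shape parameters and the generating model.

    Builds the outline the parameters describe, measures its metrics, and
    applies the generating coefficients for a free-swimming cruiser.
    ``length_cm`` defaults to the parameter set's own body length.
    """
    outline = _params_to_outline(params)
    m = compute_metrics(outline)
    if length_cm is None:
        length_cm = float(np.exp(params["log_length"]))
    val = beta.get("Intercept", 0.0)
    val += beta.get("Length", 0.0) * length_cm
    val += beta.get("Mode[cruising]", 0.0)  # cruising
    val += beta.get("HeWiCF", 0.0) * m.he_wi
    # free swimming: Cond[non-free] dummy is 0
    for name, col in (("CircCF", m.circ), ("RoundCF", m.round), ("SolCF", m.sol), ("AR", m.ar)):
        val += beta.get(name, 0.0) * col
    return float(val)


# ---------------------------------------------------------------------------
# on-disk round trips


def write_extant_dataset(df: pd.DataFrame, tree: dendropy.Tree, outdir) -> dict:
    from .io import write_newick, write_records_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_records_csv(df, outdir / "records.csv")
    write_newick(tree, outdir / "extant_tree.nwk")
    return {"records": str(outdir / "records.csv"), "tree": str(outdir / "extant_tree.nwk")}


def write_fossil_study(study: FossilStudy, outdir) -> dict:
    import json

    from .io import write_newick_pool

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_newick_pool(study.sources, outdir / "sources.nwk")
    pd.DataFrame(
        [{"taxon": r.taxon, "oldest": r.oldest, "youngest": r.youngest} for r in study.ranges]
    ).to_csv(outdir / "ranges.csv", index=False)
    pd.DataFrame(
        [{"clade": ";".join(sorted(c.clade)), "min_age": c.min_age} for c in study.constraints]
    ).to_csv(outdir / "constraints.csv", index=False)
    pd.DataFrame(
        [{"taxon": t, "max_length_cm": l} for t, l in sorted(study.max_lengths_cm.items())]
    ).to_csv(outdir / "lengths.csv", index=False)
    odir = outdir / "outlines"
    odir.mkdir(exist_ok=True)
    from .fin_geometry import write_outline_csv

    for taxon, outline in study.outlines.items():
        write_outline_csv(outline, odir / f"{taxon}.csv")
    (outdir / "clades.json").write_text(
        json.dumps({k: sorted(v) for k, v in study.clades.items()}, indent=1)
    )
    return {
        "sources": str(outdir / "sources.nwk"),
        "ranges": str(outdir / "ranges.csv"),
        "constraints": str(outdir / "constraints.csv"),
        "lengths": str(outdir / "lengths.csv"),
        "outlines": str(odir),
        "clades": str(outdir / "clades.json"),
    }
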