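"""Geometric morphometrics of caudal-fin outlines and ancestral shapes.

Each fin is reduced to a configuration of 102 landmarks: the two
anatomical (type I) fin-base points plus 100 semilandmarks (type III)
equally spaced by arc length along the fin margin from the dorsal to the
ventral base.  Configurations are superimposed by generalized Procrustes
analysis (translation, scale, rotation removed; reflections forbidden),
ancestral configurations are reconstructed coordinate-wise under Brownian
motion on each tree of a pool, and reconstructed shapes are converted
back into fin metrics and swimming-speed predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .ancestral_inference import _asr_bm_system
from .errors import ConvergenceError, GeometryError, GeometryWarning
from .fin_geometry import FinMetrics, FinOutline, compute_metrics, is_simple

__all__ = [
    "LandmarkConfig",
    "ProcrustesSet",
    "interpolate_semilandmarks",
    "gpa",
    "asr_shapes",
    "shape_to_speed",
    "mean_shape",
]

logger = logging.getLogger(__name__)

N_SEMILANDMARKS = 100  # default; total configuration size is n + 2


@dataclass
class LandmarkConfig:
    """Ordered 2-D landmark configuration of a caudal fin.

    Point 0 is the dorsal fin-base (type I), the last point the ventral
    fin-base (type I); intermediate points are outline semilandmarks.
    """

    points: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise GeometryError("landmark configuration must be (n, 2)")
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("landmark configuration has non-finite coordinates")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def centroid_size(self) -> float:
        return float(np.sqrt(np.sum((self.points - self.centroid) ** 2)))

    def closed_outline(self) -> FinOutline:
        """Close the configuration through the base edge (last -> first)."""
        return FinOutline(self.points.copy(), dorsal_base=0, ventral_base=self.n_points - 1)


@dataclass
class ProcrustesSet:
    """Result of a generalized Procrustes superimposition."""

    aligned: list[LandmarkConfig]
    consensus: np.ndarray
    distances: np.ndarray  # per-config Procrustes distance to consensus
    n_iterations: int
    objective_trace: list[float]


# ---------------------------------------------------------------------------
# semilandmark interpolation


def interpolate_semilandmarks(outline: FinOutline, n: int = N_SEMILANDMARKS) -> LandmarkConfig:
    """Equal-arc-length semilandmarks along the fin margin.

    The margin runs from the dorsal base point, around the fin (following
    the outline's vertex order, wrapping), to the ventral base point; the
    direct base edge is excluded.  ``n`` interior semilandmarks are placed
    at arc positions ``k * L / (n + 1)``; the two base points bound the
    configuration, giving ``n + 2`` landmarks in total.
    """
    if outline.dorsal_base is None or outline.ventral_base is None:
        raise GeometryError("fin-base landmarks must be set before interpolation")
    if n < 3:
        raise GeometryError("need at least 3 semilandmarks")
    pts = outline.points
    m = len(pts)
    i, j = outline.dorsal_base % m, outline.ventral_base % m
    order = [(i + k) % m for k in range((j - i) % m + 1)]
    path = pts[order]
    seg = np.hypot(*np.diff(path, axis=0).T)
    total = float(seg.sum())
    if total <= 0:
        raise GeometryError("fin margin path has zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(1, n + 1) * total / (n + 1)
    xs = np.interp(targets, cum, path[:, 0])
    ys = np.interp(targets, cum, path[:, 1])
    config = np.vstack([path[0], np.column_stack([xs, ys]), path[-1]])
    return LandmarkConfig(config, label=outline.source_id)


# ---------------------------------------------------------------------------
# Procrustes superimposition


def _center_scale(pts: np.ndarray) -> np.ndarray:
    c = pts - pts.mean(axis=0)
    size = np.sqrt(np.sum(c**2))
    if size == 0:
        raise GeometryError("degenerate configuration (zero centroid size)")
    return c / size


def _rotate_onto(pts: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (det +1, no reflection) of ``pts`` onto ``target``."""
    u, _, vt = np.linalg.svd(target.T @ pts)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    rot = u @ s @ vt
    return pts @ rot.T


def gpa(
    configs: Sequence[LandmarkConfig],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ProcrustesSet:
    """Generalized Procrustes analysis of equal-sized configurations.

    Iteratively centers, scales to unit centroid size, rotates every
    configuration onto the running consensus and updates the consensus
    until its displacement falls below ``tol`` (tight enough that the
    aligned set is a fixed point to ~1e-9).  The summed squared
    Procrustes distance to the consensus is non-increasing across
    iterations.  Raises :class:`ConvergenceError` (with the objective
    trace) if ``max_iter`` is exhausted.
    """
    if len(configs) < 2:
        raise GeometryError("GPA needs at least 2 configurations")
    k = configs[0].n_points
    if any(c.n_points != k for c in configs):
        raise GeometryError("configurations have unequal landmark counts")
    shapes = [_center_scale(c.points) for c in configs]
    # initialize from the mean: on already-aligned input the first sweep is
    # then a no-op, making the superimposition idempotent
    try:
        consensus = _center_scale(np.mean(shapes, axis=0))
    except GeometryError:
        consensus = shapes[0].copy()
    trace = []
    for it in range(1, max_iter + 1):
        shapes = [_rotate_onto(s, consensus) for s in shapes]
        new_consensus = _center_scale(np.mean(shapes, axis=0))
        obj = float(sum(np.sum((s - new_consensus) ** 2) for s in shapes))
        trace.append(obj)
        delta = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if delta < tol:
            break
    else:
        raise ConvergenceError(f"GPA did not converge in {max_iter} iterations", trace)
    aligned = [
        LandmarkConfig(s, label=c.label) for s, c in zip(shapes, configs)
    ]
    dists = np.array([np.sqrt(np.sum((s - consensus) ** 2)) for s in shapes])
    return ProcrustesSet(
        aligned=aligned,
        consensus=consensus,
        distances=dists,
        n_iterations=it,
        objective_trace=trace,
    )


def opa_distance(a: LandmarkConfig, b: LandmarkConfig) -> float:
    """Two-configuration (ordinary) Procrustes distance, rotation det +1."""
    sa, sb = _center_scale(a.points), _center_scale(b.points)
    sb = _rotate_onto(sb, sa)
    return float(np.sqrt(np.sum((sa - sb) ** 2)))


# ---------------------------------------------------------------------------
# ancestral shapes


def asr_shapes(
    pool_subset: Sequence[dendropy.Tree],
    aligned: Mapping[str, LandmarkConfig] | ProcrustesSet,
    taxa: Sequence[str] | None = None,
) -> list[dict]:
    """Coordinate-wise BM ancestral reconstruction of aligned shapes.

    Each of the 2k coordinates is reconstructed independently under BM on
    every tree (one sparse solve with 2k right-hand sides per tree).
    Returns one ``{node: LandmarkConfig}`` mapping per tree, keyed by
    dendropy node objects; tips map to their observed configurations.
    """
    if isinstance(aligned, ProcrustesSet):
        aligned = {c.label: c for c in aligned.aligned}
    labels = list(aligned)
    if taxa is not None:
        labels = list(taxa)
    k = aligned[labels[0]].n_points
    flat = {t: aligned[t].points.reshape(-1) for t in labels}
    results = []
    for tree in pool_subset:
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        missing = [t for t in tips if t not in flat]
        if missing:
            raise GeometryError(f"no aligned configuration for taxa: {missing[:5]}")
        X = np.array([flat[t] for t in tips])
        tip_index = {t: i for i, t in enumerate(tips)}
        internal, _, est = _asr_bm_system(tree, X, tip_index)
        per_node = {}
        for node, row in zip(internal, est):
            per_node[node] = LandmarkConfig(row.reshape(k, 2))
        for leaf in tree.leaf_node_iter():
            per_node[leaf] = aligned[leaf.taxon.label]
        results.append(per_node)
    return results


def mean_shape(shapes: Sequence[LandmarkConfig]) -> LandmarkConfig:
    """Coordinate-wise mean of (already aligned) configurations."""
    if len(shapes) < 1:
        raise GeometryError("mean_shape needs at least one configuration")
    k = shapes[0].n_points
    if any(s.n_points != k for s in shapes):
        raise GeometryError("configurations have unequal landmark counts")
    mean = np.mean([s.points for s in shapes], axis=0)
    cfg = LandmarkConfig(mean, label="mean")
    if cfg.centroid_size < 1e-12:
        warnings.warn("mean shape is degenerate (zero centroid size)", GeometryWarning)
    return cfg


def shape_to_speed(
    ancestor: LandmarkConfig,
    fit,
    reference_length_m: float = 0.1,
) -> float:
    """Predicted cruising speed of a reconstructed fin shape.

    The configuration is closed through the base edge, the five fin
    metrics are measured on the resulting polygon, and the fitted PGLS
    model predicts speed for a free-swimming cruiser of the reference
    body length (metres).  A self-intersecting reconstruction raises a
    :class:`GeometryWarning` but the metrics are still computed on the
    polygon as given.
    """
    from .pgls_speed import predict_speed

    outline = ancestor.closed_outline()
    if not is_simple(outline):
        warnings.warn(
            "reconstructed shape polygon self-intersects; metrics computed as-is",
            GeometryWarning,
        )
    metrics = compute_metrics(outline)
    return predict_speed(
        fit,
        {
            "total_length": reference_length_m * 100.0,
            "metrics": metrics,
            "mode": "cruising",
            "condition": "free",
            "loc_type": None,
            "group": None,
        },
    )
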