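"""Maximum-likelihood ancestral state reconstruction under Brownian motion.

For a continuous trait evolving by BM on a tree with branch lengths in
Myr, the joint ML estimates of all internal-node states minimize the sum
of squared, branch-length-weighted changes along edges.  This is a sparse
linear system (the grounded graph Laplacian of the tree with edge weights
1/length), and its solution at each node coincides with the GLS mean of
the tips computed on the tree re-rooted at that node — the classic
"fastAnc"-style estimator.  Per-node variances are the diagonal of the
inverse grounded Laplacian scaled by the ML rate estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._phylo import bm_covariance_matrix, is_monophyletic, mrca_node
from .errors import CladeError, InputError, SingularCovarianceError

__all__ = [
    "TipTrait",
    "AsrResult",
    "asr_bm",
    "pool_asr",
    "pool_root_reconstruction",
    "pooled_root_sd",
    "size_normalize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TipTrait:
    taxon: str
    value: float  # BL/s

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise InputError(f"non-finite trait value for {self.taxon}")


def _traits_to_dict(traits) -> dict[str, float]:
    if isinstance(traits, Mapping):
        return {str(k): float(v) for k, v in traits.items()}
    return {t.taxon: t.value for t in traits}


@dataclass
class AsrResult:
    """Ancestral estimates for one tree.

    ``estimates``/``variances`` map node objects (tips included) to the
    reconstructed state and its variance; tip estimates equal the observed
    values with zero variance.
    """

    tree: dendropy.Tree
    estimates: dict
    variances: dict
    sigma2: float
    root_estimate: float
    root_variance: float

    def clade_estimate(self, taxa: set[str], strict: bool = True):
        """Estimate at the MRCA of ``taxa``; None if absent or (when
        ``strict``) non-monophyletic."""
        node = mrca_node(self.tree, taxa)
        if node is None:
            return None
        if strict:
            below = {l.taxon.label for l in node.leaf_iter()}
            if below != set(taxa):
                return None
        return self.estimates[node]


def _asr_bm_system(tree: dendropy.Tree, X: np.ndarray, tip_index: dict):
    """Joint-ML solve for (possibly multivariate) tip data.

    ``X`` is (n_tips, m); returns (internal_nodes, A_inv, estimates
    (n_int, m)).  Edge weights are 1/branch-length; all branch lengths
    must be positive.
    """
    internal = list(tree.preorder_internal_node_iter())
    idx = {node: i for i, node in enumerate(internal)}
    n_int, m = len(internal), X.shape[1]
    A = np.zeros((n_int, n_int))
    B = np.zeros((n_int, m))
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        bl = node.edge.length
        if bl is None or bl <= 0:
            raise InputError("ASR requires strictly positive branch lengths")
        w = 1.0 / bl
        p = idx[parent]
        if node.is_leaf():
            t = tip_index[node.taxon.label]
            A[p, p] += w
            B[p] += w * X[t]
        else:
            c = idx[node]
            A[p, p] += w
            A[c, c] += w
            A[p, c] -= w
            A[c, p] -= w
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("singular ASR system") from exc
    est = A_inv @ B
    return internal, A_inv, est


def asr_bm(tree: dendropy.Tree, traits) -> AsrResult:
    """ML ancestral states of a single trait on one tree.

    ``traits`` is a mapping or list of :class:`TipTrait`; every tip must
    be measured.  The ML rate ``sigma2 = r' C^-1 r / n`` (GLS residuals at
    the root) scales the reported per-node variances.
    """
    values = _traits_to_dict(traits)
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in values]
    if missing:
        raise InputError(f"traits missing for tips: {missing[:5]}")
    x = np.array([[values[t]] for t in tips])
    tip_index = {t: i for i, t in enumerate(tips)}
    internal, A_inv, est = _asr_bm_system(tree, x, tip_index)

    C = bm_covariance_matrix(tree, tips)
    Ci = np.linalg.inv(C)
    one = np.ones(len(tips))
    mu = float(one @ Ci @ x[:, 0] / (one @ Ci @ one))
    resid = x[:, 0] - mu
    sigma2 = float(resid @ Ci @ resid / len(tips))

    estimates, variances = {}, {}
    for node, e, v in zip(internal, est[:, 0], np.diag(A_inv)):
        estimates[node] = float(e)
        variances[node] = float(sigma2 * v)
    for leaf in tree.leaf_node_iter():
        estimates[leaf] = values[leaf.taxon.label]
        variances[leaf] = 0.0
    root = tree.seed_node
    return AsrResult(
        tree=tree,
        estimates=estimates,
        variances=variances,
        sigma2=sigma2,
        root_estimate=estimates[root],
        root_variance=variances[root],
    )


def pool_asr(
    pool: Sequence[dendropy.Tree],
    traits,
    clade_definitions: Mapping[str, Sequence[str]],
    include_root: bool = True,
    strict_clades: bool = True,
) -> dict[str, np.ndarray]:
    """Per-clade distributions of ancestral estimates across a tree pool.

    ``clade_definitions`` maps clade names to taxon sets; for each tree
    the estimate at the clade's MRCA is collected when the clade is
    monophyletic there (skipped with a warning otherwise).  The special
    key ``"root"`` (added when ``include_root``) collects the root state.
    A clade absent from every tree raises :class:`CladeError` when
    ``strict_clades`` (default), otherwise it is dropped with a warning.
    """
    values = _traits_to_dict(traits)
    out: dict[str, list] = {name: [] for name in clade_definitions}
    if include_root:
        out.setdefault("root", [])
    for k, tree in enumerate(pool):
        res = asr_bm(tree, values)
        if include_root:
            out["root"].append(res.root_estimate)
        for name, taxa in clade_definitions.items():
            est = res.clade_estimate(set(taxa))
            if est is None:
                logger.warning("clade %s not monophyletic in tree %d; skipped", name, k)
            else:
                out[name].append(est)
    for name in list(out):
        if name != "root" and not out[name]:
            if strict_clades:
                raise CladeError(f"clade {name!r} absent or never monophyletic in the pool")
            logger.warning("clade %r never monophyletic in the pool; dropped", name)
            del out[name]
    return {name: np.asarray(vals) for name, vals in out.items()}


def pool_root_reconstruction(pool: Sequence[dendropy.Tree], traits) -> pd.DataFrame:
    """Root-state estimate and reconstruction variance for every tree.

    Returns a DataFrame with ``tree_id``, ``estimate`` and ``variance``
    columns.  The pooled uncertainty of the root state combines the
    between-tree spread of the estimates with the mean within-tree
    reconstruction variance:
    ``pooled_sd = sqrt(var(estimates) + mean(variances))``.
    """
    values = _traits_to_dict(traits)
    rows = []
    for k, tree in enumerate(pool):
        res = asr_bm(tree, values)
        rows.append({"tree_id": k, "estimate": res.root_estimate, "variance": res.root_variance})
    return pd.DataFrame(rows)


def pooled_root_sd(recon: pd.DataFrame) -> float:
    """Total SD of the pooled root estimate (tree spread + ASR variance)."""
    between = float(np.var(recon["estimate"], ddof=1)) if len(recon) > 1 else 0.0
    within = float(np.mean(recon["variance"]))
    return math.sqrt(between + within)


def summarize_pool(distributions: Mapping[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, vals in distributions.items():
        rows.append(
            {"clade": name, "n_trees": len(vals), "mean": float(np.mean(vals)),
             "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
        )
    return pd.DataFrame(rows)


def size_normalize(
    fit,
    taxa_predictors: Mapping[str, Mapping],
    reference_length_m: float = 0.1,
) -> dict[str, float]:
    """Re-predict every taxon's speed at a common body length.

    ``taxa_predictors`` maps taxon -> prediction inputs (as accepted by
    :func:`paleofin.pgls_speed.predict_speed`); each taxon's
    ``total_length`` is replaced by ``reference_length_m`` (in metres,
    converted to the model's cm scale).  Taxa differing only in body
    length therefore collapse onto identical normalized speeds.
    """
    from .pgls_speed import predict_speed

    ref_cm = reference_length_m * 100.0
    out = {}
    for taxon, obs in taxa_predictors.items():
        obs = dict(obs)
        obs["total_length"] = ref_cm
        out[taxon] = predict_speed(fit, obs)
    return out
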