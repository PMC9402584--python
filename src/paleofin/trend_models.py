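"""Brownian-motion and drift ("trend") models of trait evolution.

Under BM the tip trait vector is ``x ~ MVN(theta * 1, sigma2 * C)``; the
drift model adds a deterministic change of the mean with time,
``x ~ MVN(theta * 1 + mu * T, sigma2 * C)`` where ``T`` is the vector of
root-to-tip depths.  On an ultrametric tree ``T`` is constant and the
drift term is confounded with the root mean, so the drift model is only
identifiable on trees with fossil (non-contemporaneous) tips.  Both
models are fitted by maximum likelihood in closed form (GLS mean
parameters, ML variance) and compared by AIC; by convention
``dAIC = AIC_BM - AIC_drift`` so negative values favour BM.  Because BM
is nested in the drift model at ``mu = 0``, ``dAIC >= -2`` always.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._phylo import bm_covariance_matrix, tip_depth_vector
from .errors import IdentifiabilityError, SingularCovarianceError

__all__ = ["EvoModelFit", "fit_bm", "fit_drift", "compare_models"]

logger = logging.getLogger(__name__)

SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class EvoModelFit:
    """A fitted single-rate evolutionary model on one tree."""

    model: str  # "BM" | "drift"
    sigma2: float  # (BL/s)^2 / Myr
    theta: float  # root trait mean, BL/s
    drift: float | None  # BL/s per Myr; None for BM
    logL: float
    aic: float
    tree_id: int | None = None


def _traits_vector(tree, traits) -> tuple[list[str], np.ndarray]:
    if isinstance(traits, Mapping):
        values = {str(k): float(v) for k, v in traits.items()}
    else:
        values = {t.taxon: t.value for t in traits}
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in values]
    if missing:
        raise SingularCovarianceError(f"traits missing for tips: {missing[:5]}")
    return tips, np.array([values[t] for t in tips])


def _gls_evo(tree, traits, design_cols: int):
    tips, x = _traits_vector(tree, traits)
    C = bm_covariance_matrix(tree, tips)
    T = tip_depth_vector(tree, tips)
    n = len(tips)
    X = np.ones((n, 1)) if design_cols == 1 else np.column_stack([np.ones(n), T])
    L = np.linalg.cholesky(C)
    from scipy.linalg import solve_triangular

    Xw = solve_triangular(L, X, lower=True)
    xw = solve_triangular(L, x, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, xw, rcond=None)
    resid = xw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    floored = False
    if sigma2 < SIGMA2_FLOOR:
        warnings.warn("degenerate trait data: sigma2 floored at 1e-12")
        sigma2 = SIGMA2_FLOOR
        floored = True
    logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
    if floored:
        logL = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdetC + rss / sigma2)
    else:
        logL = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdetC + n)
    return beta, sigma2, logL, T


def fit_bm(tree: dendropy.Tree, traits, tree_id: int | None = None) -> EvoModelFit:
    """ML fit of the Brownian-motion model (k = 2 parameters)."""
    beta, sigma2, logL, _ = _gls_evo(tree, traits, design_cols=1)
    k = 2
    return EvoModelFit(
        model="BM", sigma2=sigma2, theta=float(beta[0]), drift=None,
        logL=logL, aic=2 * k - 2 * logL, tree_id=tree_id,
    )


def fit_drift(tree: dendropy.Tree, traits, tree_id: int | None = None) -> EvoModelFit:
    """ML fit of the drift/trend model (k = 3 parameters).

    Raises :class:`IdentifiabilityError` on (effectively) ultrametric
    trees, where root-to-tip depths do not vary and the drift rate is
    confounded with the root mean.
    """
    tips, _ = _traits_vector(tree, traits)
    T = tip_depth_vector(tree, tips)
    if np.var(T) < 1e-10 * np.mean(T) ** 2:
        raise IdentifiabilityError(
            "drift model unidentifiable: tree is ultrametric (equal root-to-tip depths)"
        )
    beta, sigma2, logL, _ = _gls_evo(tree, traits, design_cols=2)
    k = 3
    return EvoModelFit(
        model="drift", sigma2=sigma2, theta=float(beta[0]), drift=float(beta[1]),
        logL=logL, aic=2 * k - 2 * logL, tree_id=tree_id,
    )


def compare_models(pool: Sequence[dendropy.Tree], traits) -> pd.DataFrame:
    """Fit BM and drift on every tree; tabulate parameters and dAIC.

    Returns a long DataFrame with one row per successfully fitted tree:
    parameter estimates for both models, ``dAIC = AIC_BM - AIC_drift``
    and an ``equally_supported`` flag for |dAIC| < 2.  Per-tree failures
    are logged and excluded.
    """
    rows = []
    for i, tree in enumerate(pool):
        try:
            bm = fit_bm(tree, traits, tree_id=i)
            dr = fit_drift(tree, traits, tree_id=i)
        except Exception as exc:
            logger.warning("model fits failed on tree %d: %s", i, exc)
            continue
        daic = bm.aic - dr.aic
        rows.append(
            {
                "tree_id": i,
                "sigma2_bm": bm.sigma2,
                "theta_bm": bm.theta,
                "logL_bm": bm.logL,
                "aic_bm": bm.aic,
                "sigma2_drift": dr.sigma2,
                "theta_drift": dr.theta,
                "drift": dr.drift,
                "logL_drift": dr.logL,
                "aic_drift": dr.aic,
                "dAIC": daic,
                "equally_supported": abs(daic) < 2.0,
            }
        )
    if not rows:
        raise SingularCovarianceError("no tree could be fitted by both models")
    return pd.DataFrame(rows)


def summarize_comparison(table: pd.DataFrame) -> dict:
    """Mean +/- SD of the fitted parameters and dAIC over the pool."""
    cols = ["sigma2_bm", "theta_bm", "sigma2_drift", "theta_drift", "drift", "dAIC"]
    out = {}
    for c in cols:
        out[c] = {"mean": float(table[c].mean()), "sd": float(table[c].std(ddof=1)) if len(table) > 1 else 0.0}
    out["n_trees"] = int(len(table))
    out["prop_bm_preferred"] = float((table["dAIC"] < 0).mean())
    return out
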