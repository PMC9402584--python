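"""Phylogenetic generalized least squares (PGLS) models of swimming speed.

Swimming speed (in body lengths per second, BL/s) is regressed on body
length, caudal-fin shape metrics and categorical locomotion descriptors,
with residuals correlated according to shared ancestry under Brownian
motion: ``y = X b + e``, ``e ~ MVN(0, sigma2 * C)`` where ``C[i, j]`` is
the shared root-to-MRCA path length of tips i and j.  Estimation is by
maximum likelihood (GLS coefficients, ML ``sigma2``) so that AIC values
are comparable across candidate fixed-effect structures.

Species contributing several speed records enter the tree as randomly
resolved polytomies with zero-length internal branches; a small terminal
jitter keeps the covariance matrix invertible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from ._phylo import bm_covariance_matrix, clone_tree, node_depths
from .errors import (
    DesignError,
    PredictionError,
    SingularCovarianceError,
)
from .fin_geometry import FinMetrics

__all__ = [
    "SpeedRecord",
    "PglsFit",
    "DEFAULT_CANDIDATE_FORMULAS",
    "records_to_frame",
    "bm_covariance",
    "resolve_record_polytomies",
    "fit_pgls",
    "select_models",
    "gvif",
    "loo_cross_validate",
    "predict_speed",
    "prediction_se",
]

logger = logging.getLogger(__name__)

#: continuous model terms and the record-table column each reads
CONTINUOUS_TERMS = ("Length", "HeWiCF", "CircCF", "RoundCF", "SolCF", "AR")
#: categorical terms (dummy coded, alphabetically first level = reference)
CATEGORICAL_TERMS = ("Mode", "Cond", "LocType", "Group")

MODE_LEVELS = ("burst", "cruising")
COND_LEVELS = ("free", "non-free")
LOCTYPE_LEVELS = ("anguilliform", "carangiform", "median/paired fin", "thunniform")
GROUP_LEVELS = ("chondrichthyan", "osteichthyan")

_LEVEL_SETS = {
    "Mode": set(MODE_LEVELS),
    "Cond": set(COND_LEVELS),
    "LocType": set(LOCTYPE_LEVELS),
    "Group": set(GROUP_LEVELS),
}

#: the default candidate model set (23 fixed-effect structures)
DEFAULT_CANDIDATE_FORMULAS: tuple[tuple[str, ...], ...] = (
    ("Length",),
    ("Length", "Mode"),
    ("Length", "Mode", "LocType"),
    ("Length", "Mode", "AR"),
    ("Length", "Mode", "CircCF"),
    ("Length", "Mode", "RoundCF"),
    ("Length", "Mode", "SolCF"),
    ("Length", "Mode", "HeWiCF"),
    ("Length", "Mode", "HeWiCF", "SolCF", "RoundCF", "CircCF", "AR"),
    ("Length", "Mode", "HeWiCF", "AR"),
    ("Length", "Mode", "LocType", "AR"),
    ("Length", "Mode", "LocType", "CircCF"),
    ("Length", "Mode", "LocType", "RoundCF"),
    ("Length", "Mode", "LocType", "SolCF"),
    ("Length", "Mode", "LocType", "HeWiCF"),
    ("Length", "Mode", "LocType", "HeWiCF", "SolCF", "RoundCF", "CircCF", "AR"),
    ("Length", "Mode", "LocType", "HeWiCF", "AR"),
    ("Length", "Mode", "HeWiCF", "Group"),
    ("Length", "Mode", "HeWiCF", "Cond"),
    ("Length", "Mode", "HeWiCF", "Group", "Cond"),
    ("Length", "Mode", "LocType", "HeWiCF", "Group"),
    ("Length", "Mode", "LocType", "HeWiCF", "Cond"),
    ("Length", "Mode", "LocType", "HeWiCF", "Group", "Cond"),
)

#: the fixed-effect structure the model-selection step typically prefers
BEST_FORMULA = ("Length", "Mode", "HeWiCF", "Cond")


@dataclass
class SpeedRecord:
    """One literature swimming-speed observation with its predictors."""

    species: str
    speed: float  # BL/s
    total_length: float  # cm
    mode: str  # burst | cruising
    condition: str  # free | non-free
    loc_type: str  # anguilliform | carangiform | median/paired fin | thunniform
    metrics: FinMetrics
    group: str = "osteichthyan"  # chondrichthyan | osteichthyan

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError(f"speed must be > 0, got {self.speed}")
        if self.total_length <= 0:
            raise ValueError(f"total_length must be > 0, got {self.total_length}")
        for term, val in (("Mode", self.mode), ("Cond", self.condition),
                          ("LocType", self.loc_type), ("Group", self.group)):
            if val not in _LEVEL_SETS[term]:
                raise ValueError(f"unknown {term} level {val!r}")


def records_to_frame(records) -> pd.DataFrame:
    """Normalize a list of :class:`SpeedRecord` (or a DataFrame) to a frame."""
    if isinstance(records, pd.DataFrame):
        return records.reset_index(drop=True)
    rows = []
    for r in records:
        row = {
            "species": r.species,
            "speed": r.speed,
            "Length": r.total_length,
            "Mode": r.mode,
            "Cond": r.condition,
            "LocType": r.loc_type,
            "Group": r.group,
        }
        for col, attr in (("HeWiCF", "he_wi"), ("CircCF", "circ"),
                          ("RoundCF", "round"), ("SolCF", "sol"), ("AR", "ar")):
            row[col] = getattr(r.metrics, attr)
        rows.append(row)
    return pd.DataFrame(rows)


def record_tip_labels(df: pd.DataFrame) -> list[str]:
    """Unique tip label per record: the species name, suffixed when a
    species contributes several records."""
    counts = df["species"].value_counts()
    seen: dict[str, int] = {}
    labels = []
    for sp in df["species"]:
        if counts[sp] == 1:
            labels.append(sp)
        else:
            k = seen.get(sp, 0)
            seen[sp] = k + 1
            labels.append(f"{sp}__r{k}")
    return labels


# ---------------------------------------------------------------------------
# covariance and polytomy handling


def bm_covariance(tree: dendropy.Tree, tips: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance matrix of ``tips`` (Myr units)."""
    return bm_covariance_matrix(tree, list(tips))


def resolve_record_polytomies(
    tree: dendropy.Tree,
    records,
    seed: int = 0,
    epsilon: float | None = None,
) -> dendropy.Tree:
    """Expand multi-record species into randomly resolved zero-length clades.

    Each species with k > 1 records becomes a randomly resolved binary
    subtree of k tips (labels ``species__r0`` ...), internal branches of
    length 0 and terminal branches of length ``epsilon`` (default
    ``1e-6 * tree depth``) so the BM covariance stays invertible.
    Deterministic given ``seed``.
    """
    df = records_to_frame(records)
    rng = np.random.default_rng(seed)
    out = clone_tree(tree)
    if epsilon is None:
        depth = max(node_depths(out).values())
        epsilon = 1e-6 * depth
    counts = df["species"].value_counts()
    taxon_ns = out.taxon_namespace
    leaf_by_label = {l.taxon.label: l for l in out.leaf_node_iter()}
    for sp, k in counts.items():
        if k < 2:
            continue
        if sp not in leaf_by_label:
            raise SingularCovarianceError(f"species {sp!r} not found in tree")
        node = leaf_by_label[sp]
        node.taxon = None
        # build a randomly resolved binary subtree over the k record tips
        items = []
        for i in range(k):
            leaf = dendropy.Node(edge_length=float(epsilon))
            leaf.taxon = taxon_ns.new_taxon(label=f"{sp}__r{i}")
            items.append(leaf)
        while len(items) > 1:
            i, j = sorted(rng.choice(len(items), size=2, replace=False))
            b = items.pop(j)
            a = items.pop(i)
            if len(items) == 0:
                parent = node  # attach final pair directly to the species node
            else:
                parent = dendropy.Node(edge_length=0.0)
                items.append(parent)
            parent.add_child(a)
            parent.add_child(b)
    out.update_taxon_namespace()
    return out


def _prepare(records, tree, seed, epsilon):
    """Records frame, tip labels, record tree pruned to the records, C."""
    df = records_to_frame(records)
    labels = record_tip_labels(df)
    rtree = resolve_record_polytomies(tree, df, seed=seed, epsilon=epsilon)
    present = {l.taxon.label for l in rtree.leaf_node_iter()}
    needed = set(labels)
    if not needed <= present:
        raise SingularCovarianceError(f"records missing from tree: {sorted(needed - present)[:5]}")
    if present - needed:
        rtree.retain_taxa_with_labels(list(needed))
    C = bm_covariance_matrix(rtree, labels)
    return df, labels, rtree, C


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    df: pd.DataFrame,
    terms: Sequence[str],
    levels: Mapping[str, Sequence[str]] | None = None,
):
    """Design matrix with intercept; dummy coding for categorical terms.

    Returns ``(X, names, levels, term_columns)`` where ``term_columns``
    maps each term to its column indices (used by the GVIF computation).
    """
    fixed = levels is not None
    levels = dict(levels) if levels else {}
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    term_columns: dict[str, list[int]] = {}
    for term in terms:
        idx0 = len(names)
        if term in CONTINUOUS_TERMS:
            if term not in df.columns:
                raise DesignError(f"records table lacks column {term!r}")
            cols.append(df[term].to_numpy(dtype=float))
            names.append(term)
        elif term in CATEGORICAL_TERMS:
            vals = df[term].astype(str)
            if fixed:
                lv = list(levels[term])
                unknown = set(vals) - set(lv)
                if unknown:
                    raise PredictionError(f"unknown {term} level(s): {sorted(unknown)}")
            else:
                lv = sorted(vals.unique())
                levels[term] = lv
            for level in lv[1:]:  # first (alphabetical) level is the reference
                cols.append((vals == level).to_numpy(dtype=float))
                names.append(f"{term}[{level}]")
        else:
            raise DesignError(f"unknown model term {term!r}")
        term_columns[term] = list(range(idx0, len(names)))
    X = np.column_stack(cols)
    return X, names, levels, term_columns


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PglsFit:
    """A fitted PGLS model."""

    formula: tuple[str, ...]
    coef_names: list[str]
    beta: np.ndarray
    levels: dict
    sigma2: float
    logL: float
    aic: float
    r2: float
    n: int
    k: int
    log10_response: bool = False
    delta_aic: float | None = None
    waic: float | None = None
    coef_cov: np.ndarray | None = None  # sigma2-scaled (X' C^-1 X)^-1

    @property
    def formula_string(self) -> str:
        rhs = " + ".join(self.formula) if self.formula else "1"
        return f"Speed ~ {rhs}"

    def coef_series(self) -> pd.Series:
        return pd.Series(self.beta, index=self.coef_names)


def _gls(X: np.ndarray, y: np.ndarray, C: np.ndarray):
    """ML GLS fit: returns (beta, rss, sigma2, logL) for known C shape."""
    n, p = X.shape
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("covariance not positive definite") from exc
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    q, r = np.linalg.qr(Xw)
    if np.linalg.matrix_rank(r) < p:
        raise DesignError("rank-deficient design matrix")
    beta = linalg.solve_triangular(r, q.T @ yw)
    r_inv = linalg.solve_triangular(r, np.eye(p))
    xtcix_inv = r_inv @ r_inv.T
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 <= 0:
        sigma2 = 1e-300
    logL = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdetC + n)
    return beta, rss, sigma2, logL, xtcix_inv


def fit_pgls(
    records,
    tree: dendropy.Tree,
    formula: Sequence[str],
    *,
    seed: int = 0,
    epsilon: float | None = None,
    log10_response: bool = False,
) -> PglsFit:
    """Fit a PGLS regression of speed on the given terms.

    ``formula`` is an ordered list of term names drawn from
    ``CONTINUOUS_TERMS`` and ``CATEGORICAL_TERMS``.  The model always
    includes an intercept.  ``k = p + 1`` counts the ML variance.
    """
    df, labels, rtree, C = _prepare(records, tree, seed, epsilon)
    return _fit_on_prepared(df, C, tuple(formula), log10_response)


def _fit_on_prepared(df, C, formula, log10_response=False) -> PglsFit:
    y = df["speed"].to_numpy(dtype=float)
    if log10_response:
        y = np.log10(y)
    X, names, levels, _ = build_design(df, formula)
    beta, rss, sigma2, logL, xtcix_inv = _gls(X, y, C)
    X0 = np.ones((len(y), 1))
    _, rss0, _, _, _ = _gls(X0, y, C)
    r2 = 1.0 - rss / rss0 if rss0 > 0 else 1.0
    k = X.shape[1] + 1
    return PglsFit(
        formula=tuple(formula),
        coef_names=names,
        beta=beta,
        levels=levels,
        sigma2=sigma2,
        logL=logL,
        aic=2 * k - 2 * logL,
        r2=r2,
        n=len(y),
        k=k,
        log10_response=log10_response,
        coef_cov=sigma2 * xtcix_inv,
    )


def select_models(
    records,
    tree: dendropy.Tree,
    candidate_formulas: Sequence[Sequence[str]] = DEFAULT_CANDIDATE_FORMULAS,
    *,
    seed: int = 0,
    epsilon: float | None = None,
    log10_response: bool = False,
) -> list[PglsFit]:
    """Fit all candidates and rank them by AIC with Akaike weights.

    Candidates whose fit fails (rank deficiency etc.) are excluded with a
    logged warning.  Akaike weights are normalized over the successful
    fits and sum to 1.
    """
    if len(candidate_formulas) < 2:
        raise DesignError("model selection needs at least 2 candidate formulas")
    df, labels, rtree, C = _prepare(records, tree, seed, epsilon)
    fits: list[PglsFit] = []
    for formula in candidate_formulas:
        try:
            fits.append(_fit_on_prepared(df, C, tuple(formula), log10_response))
        except Exception as exc:
            logger.warning("candidate %s failed: %s", " + ".join(formula), exc)
    if not fits:
        raise DesignError("no candidate model could be fitted")
    best = min(f.aic for f in fits)
    rel = np.array([math.exp(-(f.aic - best) / 2.0) for f in fits])
    w = rel / rel.sum()
    for f, dw, wa in zip(fits, (f.aic - best for f in fits), w):
        f.delta_aic = dw
        f.waic = float(wa)
    fits.sort(key=lambda f: f.aic)
    return fits


def model_table(fits: Sequence[PglsFit]) -> pd.DataFrame:
    """Model-selection summary (formula, R2, AIC, dAIC, wAIC)."""
    return pd.DataFrame(
        {
            "formula": [f.formula_string for f in fits],
            "R2": [f.r2 for f in fits],
            "AIC": [f.aic for f in fits],
            "dAIC": [f.delta_aic for f in fits],
            "wAIC": [f.waic for f in fits],
        }
    )


# ---------------------------------------------------------------------------
# collinearity


def gvif(records, formula: Sequence[str]) -> pd.DataFrame:
    """Generalized variance-inflation factors (Fox & Monette).

    For each term with Df dummy columns, ``GVIF = det(R11) * det(R22) /
    det(R)`` computed on the correlation matrix of the intercept-free
    design; the returned table also carries ``GVIF^(1/(2 Df))``, which is
    compared against the conventional threshold of 2.
    """
    formula = tuple(formula)
    if len(formula) < 2:
        raise DesignError("GVIF needs at least 2 model terms")
    df = records_to_frame(records)
    X, names, _, term_columns = build_design(df, formula)
    Z = X[:, 1:]  # drop intercept
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DesignError("constant column in design; correlation matrix singular")
    Zs = (Z - Z.mean(axis=0)) / sd
    R = np.corrcoef(Zs, rowvar=False)
    detR = np.linalg.det(R)
    if detR < 1e-12:
        raise DesignError("exactly collinear predictors (singular correlation matrix)")
    rows = []
    for term in formula:
        idx = [i - 1 for i in term_columns[term]]
        other = [i for i in range(R.shape[0]) if i not in idx]
        det11 = np.linalg.det(R[np.ix_(idx, idx)])
        det22 = np.linalg.det(R[np.ix_(other, other)]) if other else 1.0
        g = det11 * det22 / detR
        dfree = len(idx)
        rows.append(
            {
                "term": term,
                "Df": dfree,
                "GVIF": g,
                "GVIF^(1/(2Df))": g ** (1.0 / (2 * dfree)),
                "flagged": g ** (1.0 / (2 * dfree)) > 2.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validation and prediction


def loo_cross_validate(
    records,
    tree: dendropy.Tree,
    formula: Sequence[str],
    *,
    seed: int = 0,
    epsilon: float | None = None,
    log10_response: bool = False,
):
    """Leave-one-out cross-validation of a PGLS model.

    Each record is held out in turn, the model refit on the remaining
    records (equivalent to pruning that tip: the BM covariance of the
    survivors is the corresponding submatrix), and the held-out speed
    predicted from the fixed effects.  Returns ``(pairs, r2)`` where
    ``pairs`` is a DataFrame of observed and predicted speeds and ``r2``
    the squared Pearson correlation between them.
    """
    df, labels, rtree, C = _prepare(records, tree, seed, epsilon)
    if len(df) < 10:
        raise DesignError("leave-one-out cross-validation needs n >= 10")
    y = df["speed"].to_numpy(dtype=float)
    preds = np.full(len(df), np.nan)
    for i in range(len(df)):
        keep = np.arange(len(df)) != i
        sub = df.loc[keep].reset_index(drop=True)
        Ci = C[np.ix_(keep, keep)]
        try:
            fit = _fit_on_prepared(sub, Ci, tuple(formula), log10_response)
            row = df.iloc[i]
            preds[i] = predict_speed(
                fit,
                {
                    "total_length": row["Length"],
                    "metrics": {m: row[m] for m in ("HeWiCF", "CircCF", "RoundCF", "SolCF", "AR") if m in row},
                    "mode": row.get("Mode"),
                    "condition": row.get("Cond"),
                    "loc_type": row.get("LocType"),
                    "group": row.get("Group"),
                },
            )
        except Exception as exc:
            logger.warning("LOO refit failed for record %d: %s", i, exc)
    ok = np.isfinite(preds)
    r = np.corrcoef(y[ok], preds[ok])[0, 1]
    pairs = pd.DataFrame({"species": df["species"], "observed": y, "predicted": preds})
    return pairs, float(r**2)


_METRIC_TO_COLUMN = {"he_wi": "HeWiCF", "circ": "CircCF", "round": "RoundCF", "sol": "SolCF", "ar": "AR"}


def _obs_to_frame(fit: PglsFit, new_obs: Mapping) -> pd.DataFrame:
    row: dict = {}
    metrics = new_obs.get("metrics")
    if isinstance(metrics, FinMetrics):
        metrics = metrics.as_dict()
    metrics = dict(metrics or {})
    for key, val in metrics.items():
        row[_METRIC_TO_COLUMN.get(key, key)] = float(val)
    if "total_length" in new_obs and new_obs["total_length"] is not None:
        row["Length"] = float(new_obs["total_length"])
    for key, col in (("mode", "Mode"), ("condition", "Cond"),
                     ("loc_type", "LocType"), ("group", "Group")):
        if new_obs.get(key) is not None:
            row[col] = str(new_obs[key])
    missing = [t for t in fit.formula if t not in row]
    if missing:
        raise PredictionError(f"new observation lacks required term(s): {missing}")
    return pd.DataFrame([row])


def predict_speed(fit: PglsFit, new_obs: Mapping) -> float:
    """Fixed-effects prediction for a new observation (no phylogenetic BLUP).

    ``new_obs`` maps ``total_length`` (cm), ``metrics`` (a FinMetrics or
    dict with keys like ``he_wi``), ``mode``, ``condition`` and optionally
    ``loc_type``/``group`` to values.  Unknown categorical levels raise
    :class:`PredictionError`.  Predictions are returned in BL/s even when
    the model was fitted on log10 speeds.
    """
    obs = _obs_to_frame(fit, new_obs)
    X, _, _, _ = build_design(obs, fit.formula, levels=fit.levels)
    pred = float((X @ fit.beta)[0])
    return 10**pred if fit.log10_response else pred


def prediction_se(fit: PglsFit, new_obs: Mapping) -> float:
    """Standard error of the fixed-effects linear predictor at ``new_obs``.

    ``sqrt(x' Cov(beta_hat) x)`` with ``Cov(beta_hat) = sigma2_hat (X' C^-1
    X)^-1``; quantifies how coefficient sampling error propagates into a
    prediction (it excludes the residual/BM variance of a new tip).
    """
    if fit.coef_cov is None:
        raise PredictionError("fit carries no coefficient covariance")
    obs = _obs_to_frame(fit, new_obs)
    X, _, _, _ = build_design(obs, fit.formula, levels=fit.levels)
    x = X[0]
    return float(np.sqrt(x @ fit.coef_cov @ x))
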