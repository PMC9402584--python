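"""End-to-end pipeline: speed model -> fossil predictions -> pool -> ASR -> trends.

The driver wires the library modules together in the order the analysis
requires: fit and select the PGLS speed model on the extant records,
measure the fossil fin outlines, predict fossil tip speeds (at recorded
maximum body lengths and size-normalized at a common reference length),
build the calibrated supertree pool, reconstruct ancestral speeds over
the pool (trait route), reconstruct ancestral fin shapes on a subsample
of trees and convert them to speeds (shape route), and fit BM vs drift
models of trait evolution on every tree.  Every stochastic stage draws a
named seed recorded in the output manifest, which suffices to reproduce
a run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .ancestral_inference import pool_asr, summarize_pool
from .errors import ConfigError, PipelineError
from .fin_geometry import compute_metrics, read_outline_csv
from .pgls_speed import (
    CATEGORICAL_TERMS,
    DEFAULT_CANDIDATE_FORMULAS,
    gvif,
    loo_cross_validate,
    model_table,
    predict_speed,
    select_models,
)
from .shape_evolution import asr_shapes, gpa, interpolate_semilandmarks, mean_shape, shape_to_speed
from .tree_assembly import NodeConstraint, StratRange, build_pool
from .trend_models import compare_models, summarize_comparison

logger = logging.getLogger(__name__)

#: terms that cannot be scored for fossil taxa
_FOSSIL_UNAVAILABLE = {"LocType", "Group"}


@dataclass
class PipelineConfig:
    """Paths and settings of a full pipeline run."""

    records: str
    extant_tree: str
    sources: str
    ranges: str
    lengths: str
    outlines_dir: str
    out_dir: str
    constraints: str | None = None
    clades: str | None = None
    candidate_formulas: tuple = DEFAULT_CANDIDATE_FORMULAS
    reference_length_m: float = 0.1
    n_topologies: int = 45
    n_calibrations: int = 100
    shape_subsample: int = 1000
    n_semilandmarks: int = 100
    min_branch: float = 1.0
    outgroup: str | None = None
    mrp_starts: int | None = None
    do_loo: bool = True
    seeds: dict = field(default_factory=lambda: {"fit": 1, "pool": 2, "shapes": 3})


@contextmanager
def _stage(name: str):
    logger.info("stage: %s", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_ranges(path) -> list[StratRange]:
    df = pd.read_csv(path)
    return [StratRange(r.taxon, float(r.oldest), float(r.youngest)) for r in df.itertuples()]


def _load_constraints(path) -> list[NodeConstraint]:
    if path is None:
        return []
    df = pd.read_csv(path)
    return [
        NodeConstraint(frozenset(r.clade.split(";")), float(r.min_age)) for r in df.itertuples()
    ]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory results.

    Outputs (CSV tables, Newick pool, manifest JSON) are written under
    ``cfg.out_dir``; partial outputs from completed stages are preserved
    if a later stage fails.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    with _stage("load"):
        for key in ("records", "extant_tree", "sources", "ranges", "lengths"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise ConfigError(f"input file for {key!r} not found: {p}")
        records = pio.read_records_csv(cfg.records)
        extant_tree = pio.read_newick(cfg.extant_tree)
        sources = pio.read_newick_list(cfg.sources)
        ranges = _load_ranges(cfg.ranges)
        constraints = _load_constraints(cfg.constraints)
        lengths = pd.read_csv(cfg.lengths).set_index("taxon")["max_length_cm"].to_dict()
        clade_defs = {}
        if cfg.clades:
            clade_defs = {k: set(v) for k, v in json.loads(Path(cfg.clades).read_text()).items()}

    with _stage("fit"):
        fits = select_models(
            records, extant_tree, cfg.candidate_formulas, seed=cfg.seeds.get("fit", 1)
        )
        table = model_table(fits)
        table.to_csv(out / "model_selection.csv", index=False)
        best = fits[0]
        fossil_fit = next(
            f for f in fits if not (set(f.formula) & _FOSSIL_UNAVAILABLE)
        )
        if fossil_fit is not best:
            logger.info(
                "best model %s uses terms unavailable for fossils; "
                "using best applicable model %s for predictions",
                best.formula_string, fossil_fit.formula_string,
            )
        if len(fossil_fit.formula) >= 2:
            gvif(records, fossil_fit.formula).to_csv(out / "gvif.csv", index=False)
        results["fits"] = fits
        results["best_fit"] = best
        results["fossil_fit"] = fossil_fit

    if cfg.do_loo:
        with _stage("cross-validate"):
            pairs, r2 = loo_cross_validate(
                records, extant_tree, fossil_fit.formula, seed=cfg.seeds.get("fit", 1)
            )
            pairs.to_csv(out / "loo_predictions.csv", index=False)
            results["loo_r2"] = r2

    with _stage("fossil-metrics"):
        odir = Path(cfg.outlines_dir)
        fossil_obs = {}
        for taxon in sorted(lengths):
            path = odir / f"{taxon}.csv"
            if not path.exists():
                raise ConfigError(f"no outline file for fossil taxon {taxon!r}: {path}")
            outline = read_outline_csv(path)
            fossil_obs[taxon] = {
                "outline": outline,
                "metrics": compute_metrics(outline),
                "max_length_cm": float(lengths[taxon]),
            }
        results["fossil_obs"] = fossil_obs

    with _stage("predict-fossils"):
        ref_cm = cfg.reference_length_m * 100.0
        tip_speeds_raw, tip_speeds_norm = {}, {}
        for taxon, obs in fossil_obs.items():
            base = {
                "metrics": obs["metrics"],
                "mode": "cruising",
                "condition": "free",
            }
            tip_speeds_raw[taxon] = predict_speed(
                fossil_fit, {**base, "total_length": obs["max_length_cm"]}
            )
            tip_speeds_norm[taxon] = predict_speed(fossil_fit, {**base, "total_length": ref_cm})
        pd.DataFrame(
            {
                "taxon": list(tip_speeds_raw),
                "speed_raw": list(tip_speeds_raw.values()),
                "speed_normalized": list(tip_speeds_norm.values()),
            }
        ).to_csv(out / "fossil_tip_speeds.csv", index=False)
        results["tip_speeds_raw"] = tip_speeds_raw
        results["tip_speeds_norm"] = tip_speeds_norm

    with _stage("pool"):
        pool, manifest = build_pool(
            sources,
            ranges,
            constraints,
            n_topologies=cfg.n_topologies,
            n_calibrations=cfg.n_calibrations,
            seed=cfg.seeds.get("pool", 2),
            outgroup=cfg.outgroup,
            min_branch=cfg.min_branch,
            n_starts=cfg.mrp_starts,
        )
        pio.write_newick_pool(pool, out / "pool.nwk")
        results["pool"] = pool
        results["pool_manifest"] = manifest

    with _stage("asr-traits"):
        asr_summaries = {}
        for name, speeds in (("raw", tip_speeds_raw), ("normalized", tip_speeds_norm)):
            dists = pool_asr(pool, speeds, clade_defs, strict_clades=False)
            summary = summarize_pool(dists)
            summary.to_csv(out / f"asr_{name}_summary.csv", index=False)
            asr_summaries[name] = {"distributions": dists, "summary": summary}
        results["asr"] = asr_summaries

    with _stage("asr-shapes"):
        rng = np.random.default_rng(cfg.seeds.get("shapes", 3))
        k = min(cfg.shape_subsample, len(pool))
        subsample_idx = sorted(rng.choice(len(pool), size=k, replace=False))
        subsample = [pool[i] for i in subsample_idx]
        configs = []
        for taxon, obs in fossil_obs.items():
            cfg_lm = interpolate_semilandmarks(obs["outline"], n=cfg.n_semilandmarks)
            cfg_lm.label = taxon
            configs.append(cfg_lm)
        proc = gpa(configs)
        aligned = {c.label: c for c in proc.aligned}
        per_tree = asr_shapes(subsample, aligned)
        clade_speeds: dict[str, list] = {name: [] for name in clade_defs}
        clade_speeds["root"] = []
        clade_shapes: dict[str, list] = {name: [] for name in list(clade_defs) + ["root"]}
        from ._phylo import is_monophyletic, mrca_node

        for tree, nodes in zip(subsample, per_tree):
            targets = {"root": tree.seed_node}
            for name, taxa in clade_defs.items():
                if is_monophyletic(tree, taxa):
                    targets[name] = mrca_node(tree, taxa)
            for name, node in targets.items():
                shape = nodes[node]
                clade_shapes[name].append(shape)
                clade_speeds[name].append(
                    shape_to_speed(shape, fossil_fit, cfg.reference_length_m)
                )
        rows = []
        mean_shapes = {}
        for name, vals in clade_speeds.items():
            arr = np.asarray(vals, dtype=float)
            rows.append(
                {
                    "clade": name,
                    "n_trees": len(arr),
                    "mean": float(arr.mean()) if len(arr) else np.nan,
                    "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                }
            )
            if clade_shapes[name]:
                mean_shapes[name] = mean_shape(clade_shapes[name])
        shape_summary = pd.DataFrame(rows)
        shape_summary.to_csv(out / "asr_shape_summary.csv", index=False)
        pio.write_tps({k: v.points for k, v in mean_shapes.items()}, out / "mean_ancestral_shapes.tps")
        results["shape_route"] = {
            "summary": shape_summary,
            "speeds": {k: np.asarray(v) for k, v in clade_speeds.items()},
            "mean_shapes": mean_shapes,
            "subsample_idx": [int(i) for i in subsample_idx],
        }

    with _stage("evofit"):
        evo = {}
        for name, speeds in (("raw", tip_speeds_raw), ("normalized", tip_speeds_norm)):
            tab = compare_models(pool, speeds)
            tab.to_csv(out / f"evomodels_{name}.csv", index=False)
            evo[name] = {"table": tab, "summary": summarize_comparison(tab)}
        (out / "evomodels_summary.json").write_text(
            json.dumps({k: v["summary"] for k, v in evo.items()}, indent=1)
        )
        results["trend"] = evo

    with _stage("manifest"):
        manifest = {
            "seeds": cfg.seeds,
            "n_topologies": cfg.n_topologies,
            "n_calibrations": cfg.n_calibrations,
            "shape_subsample": cfg.shape_subsample,
            "reference_length_m": cfg.reference_length_m,
            "best_model": results["best_fit"].formula_string,
            "fossil_model": results["fossil_fit"].formula_string,
            "hashes": {
                p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        results["manifest"] = manifest

    return results
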