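"""End-to-end pipeline: select -> allocate -> normalize -> fit -> integrate."""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .doe_select import (DescriptorTable, allocate_batches, build_design,
                         characterize, select_representative)
from .integrate import integrate_batches
from .io import RunConfig, read_descriptors, read_peak_areas, write_table
from .opls import fit_batch, run_order_effect
from .preprocess import PeakAreaMatrix, is_normalize
from .synthetic_data import SimulationConfig, simulate_descriptors, simulate_peak_areas

__all__ = ["run_pipeline", "select_samples", "fit_batches"]

log = logging.getLogger("metabatch")


def select_samples(table: DescriptorTable, cfg: RunConfig) -> pd.DataFrame:
    """Representative selection within every group; returns the manifest."""
    manifests = []
    for g in table.groups:
        model = characterize(table, g, n_components=2,
                             max_components=cfg.max_components)
        scores = model.scores.iloc[:, :2]
        design = build_design(scores, width_mode=cfg.width_mode,
                              width_parameter=cfg.width_parameter,
                              per_corner=cfg.per_corner,
                              per_center=cfg.per_center, allow_short=True)
        sel = select_representative(scores, design)
        sel.insert(0, "group", g)
        sel["t1"] = scores.iloc[:, 0].loc[sel.index]
        sel["t2"] = scores.iloc[:, 1].loc[sel.index]
        manifests.append(sel)
    return pd.concat(manifests)


def allocate_selected(manifest: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Add a batch column to a selection manifest by iterative peeling."""
    out = manifest.copy()
    out["batch"] = 0
    for g, sub in manifest.groupby("group", sort=True):
        scores = sub[["t1", "t2"]]
        design = build_design(scores, width_mode=cfg.width_mode,
                              width_parameter=1.0 if cfg.width_mode == "quantile"
                              else cfg.width_parameter,
                              per_corner=1, per_center=1)
        batch = allocate_batches(scores, pd.Series(g, index=scores.index),
                                 cfg.n_batches, design)
        out.loc[batch.index, "batch"] = batch
    return out


def fit_batches(pam: PeakAreaMatrix, cfg: RunConfig, case_label="case",
                control_label=None):
    """Normalize and fit one OPLS-DA per batch (case versus control).

    Every non-control group is pooled into the case class.  Returns
    ``(batch_results, run_order_effects, normalized_matrix)``.
    """
    control = control_label or cfg.control_group
    norm = is_normalize(pam, per_batch=cfg.is_normalize_per_batch)
    classes = pd.Series(np.where(norm.group == control, control, case_label),
                        index=norm.data.index, name="class")
    results, effects = [], {}
    for b in sorted(norm.batch.unique()):
        idx = norm.data.index[norm.batch == b]
        X = norm.metabolites.loc[idx]
        res = fit_batch(X, classes.loc[idx], batch_id=b, folds=cfg.folds,
                        n_orth=cfg.n_orth, scaling=cfg.scaling,
                        positive_class=case_label, alpha=cfg.alpha)
        results.append(res)
        pct, _ = run_order_effect(X, norm.run_order.loc[idx], scaling=cfg.scaling)
        effects[b] = pct
    return results, effects, norm


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the whole strategy and write all artifacts to ``cfg.out_dir``.

    Artifacts: ``selection_manifest.csv``, ``batch_manifest.csv``, one
    ``batch_<id>_results.csv`` per batch, ``combined_profile.csv``,
    ``summary.json`` and ``run.log``.  Returns the summary dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("metabatch %s on python %s", __version__, platform.python_version())
    log.info("seed=%s config_hash=%s", cfg.seed, cfg.config_hash())
    stage = "setup"
    try:
        sim = None
        if cfg.simulate:
            stage = "simulate"
            sim = SimulationConfig(seed=cfg.seed, n_batches=cfg.n_batches)
            table = simulate_descriptors(sim)
        else:
            stage = "read"
            table = read_descriptors(cfg.descriptors_path) \
                if cfg.descriptors_path else None

        manifest = None
        if table is not None:
            stage = "select"
            manifest = select_samples(table, cfg)
            write_table(manifest, out / "selection_manifest.csv")
            stage = "allocate"
            manifest = allocate_selected(manifest, cfg)
            write_table(manifest, out / "batch_manifest.csv")
            log.info("selected %d samples into %d batches",
                     len(manifest), cfg.n_batches)

        stage = "acquire"
        if cfg.simulate:
            from .synthetic_data import _default_batches
            batches = _default_batches(sim)
            if manifest is not None:
                batches.loc[manifest.index] = manifest["batch"]
            pam = simulate_peak_areas(sim, batch_assignment=batches)
            if manifest is not None:
                pam = pam.subset(manifest.index)
        else:
            pam = read_peak_areas(cfg.peak_areas_path, is_columns=cfg.is_columns)

        stage = "normalize+fit"
        results, ro_effects, norm = fit_batches(pam, cfg)
        for res in results:
            df = pd.DataFrame({
                "pcorr": res.pcorr,
                "jackknife_se": res.jackknife_se,
                "ci": res.ci,
                "significant": res.significant,
            })
            df["n_cv_groups"] = res.n_cv_groups
            write_table(df, out / f"batch_{res.batch_id}_results.csv",
                        index_label="metabolite_id")

        stage = "integrate"
        profile = integrate_batches(results, alpha=cfg.alpha)
        write_table(profile.to_frame(), out / "combined_profile.csv",
                    index_label="metabolite_id")

        summary = profile.summary()
        summary.update({
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "version": __version__,
            "n_samples": int(pam.data.shape[0]),
            "run_order_effect_percent": {str(k): round(float(v), 3)
                                         for k, v in ro_effects.items()},
            "batch_q2": {str(r.batch_id): round(float(r.model.q2), 4)
                         for r in results},
            "batch_r2x_pred_percent": {str(r.batch_id):
                                       round(float(r.model.r2x_pred_percent), 3)
                                       for r in results},
        })
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)
        log.info("done: %d sign-consistent, %s significant",
                 summary["n_sign_consistent"], summary["n_significant"])
        return summary
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
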