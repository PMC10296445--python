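"""End-to-end orchestration: preprocess -> cross-validate -> attribute -> score.

Driven by a YAML config naming the slides of one patient, the
hyperparameter grid, the SPG thresholds and a seed. Writes per-slide
importance matrices, the patient score table with SPG calls, and a JSON
run manifest (seeds, per-stage spot/gene counts, chosen hyperparameters,
CV-MDE per slide) sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import testfold_importance
from .io import SpatialSlide, read_slide, write_gene_scores
from .network import centroid_null_mde, cross_validate
from .preprocess import filter_genes, filter_spots, normalize, variance_filter
from .scoring import build_score_table, select_spgs

__all__ = ["validate_config", "preprocess_slide", "run_pipeline"]

_DEFAULTS = {
    "min_genes_per_spot": 200,
    "min_reads_per_gene": 10,
    "min_spots_per_gene": 2,
    "min_variance": 0.05,
    "normalize": {"method": "log1p_cpm", "scale_per_gene": True},
}


def validate_config(config: dict) -> dict:
    """Check required keys before any compute; fill preprocessing defaults."""
    if "slides" not in config or not config["slides"]:
        raise ValueError("config must name at least one slide under 'slides'")
    for i, s in enumerate(config["slides"]):
        for key in ("matrix", "coords"):
            if key not in s:
                raise ValueError(f"slide {i} is missing required key {key!r}")
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("k", 10)
    cfg.setdefault("patient_id", "patient")
    cfg.setdefault("grid", {"n_hidden_layers": [1, 3, 5], "learning_rate": [0.1, 0.01, 0.001]})
    cfg.setdefault("thresholds", {})
    cfg["thresholds"].setdefault("csmi", 0.15)
    cfg["thresholds"].setdefault("cspni", 20.0)
    pp = dict(_DEFAULTS)
    pp_norm = dict(_DEFAULTS["normalize"])
    user_pp = cfg.get("preprocess", {}) or {}
    pp_norm.update(user_pp.get("normalize", {}) or {})
    pp.update({k: v for k, v in user_pp.items() if k != "normalize"})
    pp["normalize"] = pp_norm
    cfg["preprocess"] = pp
    cfg.setdefault("training", {})
    cfg["training"].setdefault("batch_size", 32)
    cfg["training"].setdefault("max_epochs", 100)
    cfg["training"].setdefault("early_stopping_patience", 10)
    return cfg


def preprocess_slide(slide: SpatialSlide, pp: dict) -> tuple[SpatialSlide, dict]:
    """Spot filter -> gene filter -> normalize -> variance filter, with an audit log."""
    log = {"input": {"spots": slide.n_spots, "genes": slide.n_genes}}
    slide = filter_spots(slide, min_genes=pp["min_genes_per_spot"])
    log["after_spot_filter"] = {"spots": slide.n_spots, "genes": slide.n_genes}
    slide = filter_genes(
        slide, min_reads=pp["min_reads_per_gene"], min_spots=pp["min_spots_per_gene"]
    )
    log["after_gene_filter"] = {"spots": slide.n_spots, "genes": slide.n_genes}
    slide = normalize(
        slide,
        method=pp["normalize"]["method"],
        scale_per_gene=pp["normalize"]["scale_per_gene"],
    )
    slide, removed = variance_filter(slide, min_variance=pp["min_variance"])
    log["after_variance_filter"] = {"spots": slide.n_spots, "genes": slide.n_genes}
    log["variance_filtered_genes"] = removed
    return slide, log


def _load_slides(cfg: dict) -> list[SpatialSlide]:
    slides = []
    for i, s in enumerate(cfg["slides"]):
        slides.append(
            read_slide(
                matrix_path=s["matrix"],
                coords_path=s["coords"],
                genes_path=s.get("genes"),
                spots_path=s.get("spots"),
                patient_id=cfg["patient_id"],
                slide_id=s.get("slide_id", f"slide{i + 1}"),
                mtx_orientation=s.get("mtx_orientation", "genes_by_spots"),
            )
        )
    return slides


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    slides: list[SpatialSlide] | None = None,
) -> dict:
    """Run the whole workflow for one patient; returns the manifest.

    ``slides`` may be passed directly (already-loaded or simulated); the
    config's slide entries are then used only for ids.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if slides is None:
        slides = _load_slides(cfg)

    seed = int(cfg["seed"])
    grid = {
        "n_hidden_layers": tuple(cfg["grid"]["n_hidden_layers"]),
        "learning_rate": tuple(cfg["grid"]["learning_rate"]),
    }
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "slides"},
        "slides": {},
    }
    imps = {}
    for si, slide in enumerate(slides):
        pre, log = preprocess_slide(slide, cfg["preprocess"])
        cv = cross_validate(
            pre,
            grid=grid,
            k=int(cfg["k"]),
            seed=int(np.random.SeedSequence((seed, si)).generate_state(1)[0] % 2**31),
            batch_size=cfg["training"]["batch_size"],
            max_epochs=cfg["training"]["max_epochs"],
            early_stopping_patience=cfg["training"]["early_stopping_patience"],
        )
        imp = testfold_importance(cv, pre)
        imps[pre.slide_id] = imp
        pd.DataFrame(imp.values, index=imp.spot_ids, columns=imp.gene_ids).to_csv(
            out_dir / f"importance_{pre.slide_id}.tsv", sep="\t"
        )
        pd.DataFrame(
            cv.test_predictions, index=pre.spot_ids, columns=["x_pred", "y_pred"]
        ).to_csv(out_dir / f"predictions_{pre.slide_id}.tsv", sep="\t")
        manifest["slides"][pre.slide_id] = {
            "preprocess": log,
            "cv_mde": cv.cv_mde,
            "null_mde": centroid_null_mde(pre.coords),
            "best_hyperparams": {
                "n_hidden_layers": cv.best_hyperparams[0],
                "learning_rate": cv.best_hyperparams[1],
            },
            "grid_cv_mde": {f"{L}_{lr}": v for (L, lr), v in cv.grid_cv_mde.items()},
            "fold_assignment": cv.fold_assignment,
        }

    table = build_score_table(imps)
    table = select_spgs(
        table,
        csmi_threshold=float(cfg["thresholds"]["csmi"]),
        cspni_threshold=float(cfg["thresholds"]["cspni"]),
    )
    write_gene_scores(table, out_dir / "gene_scores.tsv")
    spgs = [g for g, f in zip(table.gene_ids, table.is_spg) if f]
    (out_dir / "spg_list.txt").write_text("".join(g + "\n" for g in spgs))
    manifest["n_spgs"] = len(spgs)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
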