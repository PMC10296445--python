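"""Gene-level aggregation of importance scores and SPG calling.

Per slide: MeanImp (mean importance over spots), MNI (mean over the spots
where a gene's importance is non-zero), and PNI (percentage of spots with
non-zero importance). Across the slides of a patient these average into
CSMI, CSMNI and CSPNI. SPGs are then called in two stages: a seed set with
CSMI above a threshold (default 0.15), plus a rescue set of genes whose
CSMNI reaches the seed set's minimum CSMNI and whose CSPNI exceeds 20 —
genes with strong importance concentrated in a reasonably sized subset of
spots, which slide-wide means underweight.
"""

from __future__ import annotations

import warnings

import numpy as np

from .attribution import ImportanceMatrix
from .io import GeneScoreTable

__all__ = [
    "mean_importance",
    "mni_pni",
    "cross_slide_scores",
    "build_score_table",
    "select_spgs",
    "importance_cluster_markers",
    "spg_svg_contingency",
]


def _agg(values: np.ndarray, agg: str, axis: int):
    if agg == "mean":
        return values.mean(axis=axis)
    if agg == "median":
        return np.median(values, axis=axis)
    if agg == "sum":
        return values.sum(axis=axis)
    raise ValueError(f"unknown aggregation {agg!r}")


def mean_importance(imp: ImportanceMatrix, agg: str = "mean") -> np.ndarray:
    """Per-gene slide-wide importance (MeanImp): aggregate over all spots."""
    if imp.values.size == 0:
        raise ValueError("empty importance matrix")
    return _agg(imp.values, agg, axis=0)


def mni_pni(
    imp: ImportanceMatrix, zero_tol: float = 0.0, agg: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene MNI and PNI.

    MNI aggregates importance over the n0 spots where it exceeds
    ``zero_tol`` (0 when n0 = 0); PNI = 100 * n0 / n_spots.
    """
    if imp.values.size == 0:
        raise ValueError("empty importance matrix")
    V = imp.values
    nonzero = V > zero_tol
    n0 = nonzero.sum(axis=0)
    n = V.shape[0]
    mni = np.zeros(V.shape[1])
    for j in np.flatnonzero(n0):
        mni[j] = _agg(V[nonzero[:, j], j], agg, axis=0)
    pni = 100.0 * n0 / n
    return mni, pni


def cross_slide_scores(
    per_slide_mean_imp: np.ndarray,
    per_slide_mni: np.ndarray,
    per_slide_pni: np.ndarray,
    agg: str = "mean",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unweighted per-gene aggregation of MeanImp/MNI/PNI across slides
    (genes x slides in, per-gene CSMI/CSMNI/CSPNI out)."""
    mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in
            (per_slide_mean_imp, per_slide_mni, per_slide_pni)]
    if mats[0].shape[1] < 1:
        raise ValueError("need at least one slide")
    return tuple(_agg(m, agg, axis=1) for m in mats)


def build_score_table(
    imps: dict[str, ImportanceMatrix], zero_tol: float = 0.0, agg: str = "mean"
) -> GeneScoreTable:
    """Assemble the full per-gene score table from per-slide importance matrices.

    Slides whose gene sets differ are intersected (with a warning), keeping
    the first slide's gene order.
    """
    if not imps:
        raise ValueError("need at least one slide")
    slide_ids = list(imps)
    gene_sets = [list(imps[s].gene_ids) for s in slide_ids]
    common = set(gene_sets[0])
    for gs in gene_sets[1:]:
        common &= set(gs)
    if not common:
        raise ValueError("slides share no genes")
    genes = [g for g in gene_sets[0] if g in common]
    if any(len(gs) != len(genes) for gs in gene_sets):
        warnings.warn(
            f"slides have differing gene sets; using the {len(genes)}-gene intersection"
        )

    n, h = len(genes), len(slide_ids)
    mi = np.zeros((n, h))
    mn = np.zeros((n, h))
    pn = np.zeros((n, h))
    for j, sid in enumerate(slide_ids):
        imp = imps[sid]
        col = {g: i for i, g in enumerate(imp.gene_ids)}
        sel = [col[g] for g in genes]
        sub = ImportanceMatrix(
            values=imp.values[:, sel], spot_ids=list(imp.spot_ids), gene_ids=genes
        )
        mi[:, j] = mean_importance(sub, agg=agg)
        mn[:, j], pn[:, j] = mni_pni(sub, zero_tol=zero_tol, agg=agg)
    csmi, csmni, cspni = cross_slide_scores(mi, mn, pn, agg=agg)
    return GeneScoreTable(
        gene_ids=genes,
        slide_ids=slide_ids,
        per_slide_mean_imp=mi,
        per_slide_mni=mn,
        per_slide_pni=pn,
        csmi=csmi,
        csmni=csmni,
        cspni=cspni,
        aggregate=agg,
    )


def select_spgs(
    table: GeneScoreTable,
    csmi_threshold: float = 0.15,
    cspni_threshold: float = 20.0,
) -> GeneScoreTable:
    """Two-stage SPG call.

    Seed: CSMI strictly above ``csmi_threshold``. Rescue: non-seed genes with
    CSMNI >= (minimum CSMNI over the seed set) and CSPNI strictly above
    ``cspni_threshold``. An empty seed set yields no SPGs and a warning.
    Returns a new table with is_spg / spg_reason filled.
    """
    seed = table.csmi > csmi_threshold
    reason = np.array(["none"] * table.n_genes, dtype=object)
    reason[seed] = "csmi_seed"
    if not seed.any():
        warnings.warn("no gene exceeds the CSMI threshold; no SPGs called")
    else:
        m = table.csmni[seed].min()
        rescue = (~seed) & (table.csmni >= m) & (table.cspni > cspni_threshold)
        reason[rescue] = "mni_rescue"
    return GeneScoreTable(
        gene_ids=list(table.gene_ids),
        slide_ids=list(table.slide_ids),
        per_slide_mean_imp=table.per_slide_mean_imp.copy(),
        per_slide_mni=table.per_slide_mni.copy(),
        per_slide_pni=table.per_slide_pni.copy(),
        csmi=table.csmi.copy(),
        csmni=table.csmni.copy(),
        cspni=table.cspni.copy(),
        is_spg=reason != "none",
        spg_reason=reason,
        aggregate=table.aggregate,
    )


def importance_cluster_markers(
    imp: ImportanceMatrix, cluster_labels: dict[str, object], top_n: int = 10
) -> dict:
    """Per-cluster gene rankings by mean importance within the cluster's spots.

    Every spot must be labeled. Returns {cluster: [(gene_id, score), ...]}
    with the top_n genes in descending score order (ties broken by gene
    order for determinism).
    """
    unlabeled = [s for s in imp.spot_ids if s not in cluster_labels]
    if unlabeled:
        raise ValueError(f"unlabeled spots: {unlabeled[:5]}")
    out = {}
    labels = np.array([cluster_labels[s] for s in imp.spot_ids], dtype=object)
    for cluster in sorted(set(labels), key=str):
        rows = labels == cluster
        scores = imp.values[rows].mean(axis=0)
        order = np.argsort(-scores, kind="stable")[:top_n]
        out[cluster] = [(imp.gene_ids[i], float(scores[i])) for i in order]
    return out


def spg_svg_contingency(spgs: set, svgs: set, universe: set) -> dict:
    """2x2 counts of SPG membership vs SVG membership over a gene universe."""
    spgs, svgs, universe = set(spgs), set(svgs), set(universe)
    if not spgs <= universe or not svgs <= universe:
        raise ValueError("SPG and SVG sets must be subsets of the universe")
    both = len(spgs & svgs)
    spg_only = len(spgs - svgs)
    svg_only = len(svgs - spgs)
    neither = len(universe) - both - spg_only - svg_only
    return {"neither": neither, "spg_only": spg_only, "svg_only": svg_only, "both": both}
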