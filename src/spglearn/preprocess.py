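"""Quality filters and the model-input transform for spatial count matrices.

Filter order follows the workflow: spot filter -> gene filter -> normalize ->
variance filter. The count filters are defined on raw counts and refuse
normalized input; the variance filter is defined on the normalized
representation actually fed to the network.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .io import SpatialSlide

__all__ = ["filter_spots", "filter_genes", "normalize", "variance_filter"]


def _require_counts(slide: SpatialSlide, op: str) -> None:
    if slide.normalized:
        raise ValueError(f"{op} is defined on raw counts; slide is already normalized")


def filter_spots(slide: SpatialSlide, min_genes: int = 200) -> SpatialSlide:
    """Keep spots with at least ``min_genes`` genes detected (count > 0).

    Raises if the result would contain no spots.
    """
    _require_counts(slide, "filter_spots")
    detected = (slide.expression > 0).sum(axis=1)
    keep = np.flatnonzero(detected >= min_genes)
    if keep.size == 0:
        raise ValueError(
            f"all {slide.n_spots} spots have fewer than {min_genes} detected genes"
        )
    return slide.subset_spots(keep)


def filter_genes(slide: SpatialSlide, min_reads: int = 10, min_spots: int = 2) -> SpatialSlide:
    """Keep genes with total reads >= ``min_reads`` and detection in >= ``min_spots`` spots."""
    _require_counts(slide, "filter_genes")
    total = slide.expression.sum(axis=0)
    n_detected = (slide.expression > 0).sum(axis=0)
    keep = np.flatnonzero((total >= min_reads) & (n_detected >= min_spots))
    return slide.subset_genes(keep)


def normalize(
    slide: SpatialSlide,
    method: str = "log1p_cpm",
    scale_per_gene: bool = True,
    target_sum: float = 1e4,
) -> SpatialSlide:
    """Build the model-input representation from counts.

    ``log1p_cpm`` scales each spot to a fixed library size (default 10,000),
    applies log(1 + x), and, when ``scale_per_gene``, centers/scales each gene
    to unit variance (zero-variance genes map to 0). ``none`` only sets the
    normalized flag, for inputs transformed elsewhere.
    """
    _require_counts(slide, "normalize")
    X = slide.expression.astype(float)
    if method == "log1p_cpm":
        lib = X.sum(axis=1)
        scale = np.divide(target_sum, lib, out=np.zeros_like(lib), where=lib > 0)
        X = np.log1p(X * scale[:, None])
        if scale_per_gene:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)  # population sd; ddof documented in variance_filter
            X = X - mu
            nz = sd > 0
            X[:, nz] /= sd[nz]
            X[:, ~nz] = 0.0
    elif method != "none":
        raise ValueError(f"unknown normalization method {method!r}")
    return replace(slide, expression=X, normalized=True)


def variance_filter(
    slide: SpatialSlide, min_variance: float = 0.05
) -> tuple[SpatialSlide, list[str]]:
    """Drop genes whose across-spot variance (population, ddof=0) is < ``min_variance``.

    Applied to the normalized model input, immediately before training.
    Returns the filtered slide and the removed gene ids for audit.
    """
    if not slide.normalized:
        raise ValueError("variance_filter applies to the normalized model input")
    if slide.n_spots < 2:
        raise ValueError("variance undefined with fewer than 2 spots")
    var = slide.expression.var(axis=0)
    keep = np.flatnonzero(var >= min_variance)
    removed = [slide.gene_ids[i] for i in np.flatnonzero(var < min_variance)]
    if keep.size == 0:
        raise ValueError("variance filter removed every gene")
    return slide.subset_genes(keep), removed
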