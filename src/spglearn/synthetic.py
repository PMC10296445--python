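"""Seeded synthetic Visium-like slides with planted gene classes.

Spots sit on a regular n x n grid with 2-unit spacing (the approximate
spacing of real capture arrays). Each gene belongs to one class:

* ``coordinate_encoding`` — mean expression is a smooth function of (x, y)
  (linear in x, linear in y, radial, or an x*y product term), spanning a
  stated dynamic range across the slide. These genes, jointly, determine
  where a spot is; they are the planted positives for coordinate
  prediction.
* ``patch_svg`` — mean elevated by a fold change inside a disc, flat
  outside: the classic localized spatially-variable pattern.
* ``noise`` — spatially constant mean; the planted negatives.

Counts are negative-binomial (gamma–Poisson) around the mean surface with
a quadratic mean–variance relation var = mu + dispersion * mu^2, and each
spot carries a lognormal library-size factor. Defaults: dispersion 0.5 and
a mean library of ~5,000 counts per spot, Visium-like overdispersion at
desk scale. Several slides of one synthetic "patient" share a single
ground truth (same surfaces, same patch geometry) and differ only in count
noise, mirroring serial sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneScoreTable, SpatialSlide

__all__ = [
    "SyntheticGroundTruth",
    "generate_slide",
    "generate_patient",
    "evaluate_recovery",
]

GENE_CLASSES = ("coordinate_encoding", "patch_svg", "noise")
_ENCODING_KINDS = ("linear_x", "linear_y", "radial", "product")


@dataclass
class SyntheticGroundTruth:
    """Planted per-gene classes and the parameters of their mean surfaces."""

    gene_class: dict[str, str]
    encoding_spec: dict[str, dict]
    patch_spec: dict[str, dict]
    base_mean: dict[str, float]
    nb_dispersion: float
    library_size_mean: float
    seed: int

    def __post_init__(self) -> None:
        for g, c in self.gene_class.items():
            if c not in GENE_CLASSES:
                raise ValueError(f"unknown gene class {c!r} for {g}")
            if (g in self.encoding_spec) != (c == "coordinate_encoding"):
                raise ValueError(f"encoding_spec must exist iff class is coordinate_encoding ({g})")
            if (g in self.patch_spec) != (c == "patch_svg"):
                raise ValueError(f"patch_spec must exist iff class is patch_svg ({g})")

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]


def _grid_coords(n_side: int, spacing: float) -> np.ndarray:
    ax = np.arange(n_side) * spacing
    xx, yy = np.meshgrid(ax, ax, indexing="xy")
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)


def _encoding_surface(kind: str, coords: np.ndarray, dynamic_range: float) -> np.ndarray:
    """Mean-one multiplicative surface spanning ``dynamic_range`` (max/min)."""
    x, y = coords[:, 0], coords[:, 1]

    def unit(v):  # rescale to [0, 1]
        lo, hi = v.min(), v.max()
        return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)

    if kind == "linear_x":
        t = unit(x)
    elif kind == "linear_y":
        t = unit(y)
    elif kind == "radial":
        c = coords.mean(axis=0)
        t = 1.0 - unit(np.sqrt(((coords - c) ** 2).sum(axis=1)))
    elif kind == "product":
        t = unit((x - x.mean()) * (y - y.mean()))
    else:
        raise ValueError(f"unknown encoding kind {kind!r}")
    s = dynamic_range ** t  # log-linear in t, range-spanning
    return s / s.mean()


def _build_truth(
    n_side: int,
    n_coord_genes: int,
    n_patch_genes: int,
    n_noise_genes: int,
    seed: int,
    nb_dispersion: float,
    library_size_mean: float,
    dynamic_range: float,
    patch_fold: float,
    patch_radius: float | None,
    spacing: float,
    rng: np.random.Generator,
    informative_abundance_boost: float = 4.0,
) -> tuple[SyntheticGroundTruth, np.ndarray]:
    coords = _grid_coords(n_side, spacing)
    extent = spacing * (n_side - 1)
    if patch_radius is None:
        patch_radius = 0.25 * extent
    if patch_radius > extent:
        raise ValueError(f"patch radius {patch_radius} exceeds slide extent {extent}")

    n_genes = n_coord_genes + n_patch_genes + n_noise_genes
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    gene_class, encoding_spec, patch_spec, base_mean = {}, {}, {}, {}

    # per-gene baseline abundance: lognormal around library_size_mean/n_genes
    base = rng.lognormal(
        mean=np.log(library_size_mean / max(n_genes, 1)) - 0.32, sigma=0.8, size=n_genes
    )
    # informative genes emulate abundant structural/housekeeping transcripts,
    # which in real tissue sit far above the median gene; keeps the low end of
    # a graded surface above the dropout floor
    n_informative = n_coord_genes + n_patch_genes
    base[:n_informative] *= informative_abundance_boost
    i = 0
    for j in range(n_coord_genes):
        g = gene_ids[i]
        kind = _ENCODING_KINDS[j % len(_ENCODING_KINDS)]
        gene_class[g] = "coordinate_encoding"
        encoding_spec[g] = {"kind": kind, "dynamic_range": float(dynamic_range)}
        base_mean[g] = float(base[i])
        i += 1
    for _ in range(n_patch_genes):
        g = gene_ids[i]
        gene_class[g] = "patch_svg"
        center = (
            float(rng.uniform(patch_radius, extent - patch_radius)),
            float(rng.uniform(patch_radius, extent - patch_radius)),
        )
        patch_spec[g] = {
            "center": center,
            "radius": float(patch_radius),
            "fold": float(patch_fold),
        }
        base_mean[g] = float(base[i])
        i += 1
    for _ in range(n_noise_genes):
        g = gene_ids[i]
        gene_class[g] = "noise"
        base_mean[g] = float(base[i])
        i += 1

    truth = SyntheticGroundTruth(
        gene_class=gene_class,
        encoding_spec=encoding_spec,
        patch_spec=patch_spec,
        base_mean=base_mean,
        nb_dispersion=float(nb_dispersion),
        library_size_mean=float(library_size_mean),
        seed=int(seed),
    )
    return truth, coords


def _mean_matrix(truth: SyntheticGroundTruth, coords: np.ndarray) -> tuple[list[str], np.ndarray]:
    gene_ids = list(truth.gene_class)
    n_spots = coords.shape[0]
    mu = np.zeros((n_spots, len(gene_ids)))
    for j, g in enumerate(gene_ids):
        b = truth.base_mean[g]
        cls = truth.gene_class[g]
        if cls == "coordinate_encoding":
            spec = truth.encoding_spec[g]
            s = _encoding_surface(spec["kind"], coords, spec["dynamic_range"])
        elif cls == "patch_svg":
            spec = truth.patch_spec[g]
            d = np.sqrt(((coords - np.asarray(spec["center"])) ** 2).sum(axis=1))
            s = np.where(d <= spec["radius"], spec["fold"], 1.0)
        else:
            s = np.ones(n_spots)
        mu[:, j] = b * s
    return gene_ids, mu


def _sample_counts(
    truth: SyntheticGroundTruth,
    coords: np.ndarray,
    rng: np.random.Generator,
    library_size_sigma: float,
) -> tuple[list[str], np.ndarray]:
    gene_ids, mu = _mean_matrix(truth, coords)
    # lognormal library factor with mean 1
    lib = rng.lognormal(-0.5 * library_size_sigma**2, library_size_sigma, size=mu.shape[0])
    mu = mu * lib[:, None]
    alpha = truth.nb_dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)
    return gene_ids, counts


def generate_slide(
    n_side: int,
    n_coord_genes: int = 6,
    n_patch_genes: int = 6,
    n_noise_genes: int = 48,
    seed: int = 0,
    nb_dispersion: float = 0.5,
    library_size_mean: float = 5000.0,
    library_size_sigma: float = 0.25,
    dynamic_range: float = 200.0,
    patch_fold: float = 8.0,
    patch_radius: float | None = None,
    spacing: float = 2.0,
    patient_id: str = "sim_patient",
    slide_id: str = "sim_slide",
) -> tuple[SpatialSlide, SyntheticGroundTruth]:
    """Generate one seeded synthetic slide and its ground truth."""
    if n_side < 4:
        raise ValueError("n_side must be >= 4")
    if min(n_coord_genes, n_patch_genes, n_noise_genes) < 0:
        raise ValueError("gene counts must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    truth, coords = _build_truth(
        n_side, n_coord_genes, n_patch_genes, n_noise_genes, seed,
        nb_dispersion, library_size_mean, dynamic_range, patch_fold,
        patch_radius, spacing, rng,
    )
    gene_ids, counts = _sample_counts(truth, coords, rng, library_size_sigma)
    slide = SpatialSlide(
        expression=counts,
        gene_ids=gene_ids,
        spot_ids=[f"s{i:04d}" for i in range(coords.shape[0])],
        coords=coords,
        patient_id=patient_id,
        slide_id=slide_id,
    )
    return slide, truth


def generate_patient(
    n_side: int,
    n_slides: int = 3,
    seed: int = 0,
    patient_id: str = "sim_patient",
    **kwargs,
) -> tuple[list[SpatialSlide], SyntheticGroundTruth]:
    """Generate several slides of one patient from a single ground truth.

    All slides share the grid and the per-gene mean surfaces; the
    negative-binomial count noise and library factors are drawn
    independently per slide.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    truth, coords = _build_truth(
        n_side,
        kwargs.pop("n_coord_genes", 6),
        kwargs.pop("n_patch_genes", 6),
        kwargs.pop("n_noise_genes", 48),
        seed,
        kwargs.pop("nb_dispersion", 0.5),
        kwargs.pop("library_size_mean", 5000.0),
        kwargs.pop("dynamic_range", 200.0),
        kwargs.pop("patch_fold", 8.0),
        kwargs.pop("patch_radius", None),
        kwargs.pop("spacing", 2.0),
        rng,
    )
    library_size_sigma = kwargs.pop("library_size_sigma", 0.25)
    if kwargs:
        raise TypeError(f"unknown generator options: {sorted(kwargs)}")
    slides = []
    for si in range(n_slides):
        slide_rng = np.random.default_rng(np.random.SeedSequence((seed, 1 + si)))
        gene_ids, counts = _sample_counts(truth, coords, slide_rng, library_size_sigma)
        slides.append(
            SpatialSlide(
                expression=counts,
                gene_ids=gene_ids,
                spot_ids=[f"s{i:04d}" for i in range(coords.shape[0])],
                coords=coords,
                patient_id=patient_id,
                slide_id=f"slide{si + 1}",
            )
        )
    return slides, truth


def evaluate_recovery(truth: SyntheticGroundTruth, scores: GeneScoreTable) -> dict:
    """Score SPG calls and CSMI ranking against the planted gene classes.

    Positives are the planted coordinate_encoding and patch_svg genes.
    Ranks are CSMI ranks (1 = largest CSMI, average rank for ties). When no
    SPGs are called, precision is reported as 0.0 with
    ``precision_defined = False``.
    """
    truth_genes = set(truth.gene_class)
    table_genes = set(scores.gene_ids)
    if truth_genes != table_genes:
        raise ValueError(
            f"gene sets differ: {len(truth_genes - table_genes)} missing from scores, "
            f"{len(table_genes - truth_genes)} unknown to truth"
        )
    from scipy.stats import rankdata

    ranks = rankdata(-scores.csmi, method="average")
    rank_of = dict(zip(scores.gene_ids, ranks))
    median_rank = {}
    for cls in GENE_CLASSES:
        genes = truth.genes_of_class(cls)
        median_rank[cls] = float(np.median([rank_of[g] for g in genes])) if genes else float("nan")

    called = {g for g, f in zip(scores.gene_ids, scores.is_spg) if f}
    positives = set(truth.genes_of_class("coordinate_encoding")) | set(
        truth.genes_of_class("patch_svg")
    )
    tp = len(called & positives)
    recall = tp / len(positives) if positives else float("nan")
    precision_defined = len(called) > 0
    precision = tp / len(called) if called else 0.0
    noise_fraction = (
        len(called & set(truth.genes_of_class("noise"))) / len(called) if called else 0.0
    )
    return {
        "n_genes": len(scores.gene_ids),
        "median_csmi_rank": median_rank,
        "n_spgs_called": len(called),
        "recall": recall,
        "precision": precision,
        "precision_defined": precision_defined,
        "noise_fraction_of_spgs": noise_fraction,
    }
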