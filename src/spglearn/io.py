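"""Containers and file round-trips for spatial-transcriptomic slides and gene scores.

A *slide* couples a spots x genes expression matrix with per-spot (x, y)
coordinates; spot identifiers, not row positions, are the join key between
the two. Matrices arrive either as MatrixMarket triplets (the Visium
convention, genes x spots) with sidecar gene/spot name files, or as one
dense TSV whose header row holds gene ids and whose first column holds
spot ids. Coordinates arrive as a TSV with columns ``spot_id``, ``x``, ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "SpatialSlide",
    "GeneScoreTable",
    "SPG_REASONS",
    "read_slide",
    "write_slide_dense",
    "write_slide_mtx",
    "write_gene_scores",
    "read_gene_scores",
]

SPG_REASONS = ("none", "csmi_seed", "mni_rescue")


@dataclass
class SpatialSlide:
    """One slide: expression (spots x genes), coordinates, and identifiers.

    ``normalized`` distinguishes raw counts (non-negative, required by the
    count-based filters) from a model-input representation, which may be
    signed after per-gene standardization.
    """

    expression: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray
    patient_id: str = ""
    slide_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.validate()

    def validate(self) -> None:
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2-D spots x genes matrix")
        n_spots, n_genes = self.expression.shape
        if n_spots != len(self.spot_ids):
            raise ValueError(
                f"expression has {n_spots} rows but {len(self.spot_ids)} spot ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"expression has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if self.coords.shape != (n_spots, 2):
            raise ValueError(
                f"coords must be ({n_spots}, 2), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("duplicate spot ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not self.normalized and np.any(self.expression < 0):
            raise ValueError("count (non-normalized) expression must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def subset_spots(self, index: np.ndarray) -> "SpatialSlide":
        index = np.asarray(index)
        return replace(
            self,
            expression=self.expression[index],
            spot_ids=[self.spot_ids[i] for i in index],
            coords=self.coords[index],
        )

    def subset_genes(self, index: np.ndarray) -> "SpatialSlide":
        index = np.asarray(index)
        return replace(
            self,
            expression=self.expression[:, index],
            gene_ids=[self.gene_ids[i] for i in index],
        )

    def copy(self) -> "SpatialSlide":
        return replace(
            self,
            expression=self.expression.copy(),
            coords=self.coords.copy(),
            gene_ids=list(self.gene_ids),
            spot_ids=list(self.spot_ids),
        )


@dataclass
class GeneScoreTable:
    """Per-gene importance statistics across the slides of one patient.

    Holds per-slide MeanImp / MNI / PNI (genes x slides) plus their
    cross-slide aggregates CSMI / CSMNI / CSPNI and the SPG call. With the
    default mean aggregation, CSMI is exactly the row-mean of MeanImp.
    """

    gene_ids: list[str]
    slide_ids: list[str]
    per_slide_mean_imp: np.ndarray
    per_slide_mni: np.ndarray
    per_slide_pni: np.ndarray
    csmi: np.ndarray
    csmni: np.ndarray
    cspni: np.ndarray
    is_spg: np.ndarray = field(default=None)
    spg_reason: np.ndarray = field(default=None)
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.is_spg is None:
            self.is_spg = np.zeros(n, dtype=bool)
        if self.spg_reason is None:
            self.spg_reason = np.array(["none"] * n, dtype=object)
        for name in ("per_slide_mean_imp", "per_slide_mni", "per_slide_pni"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), dtype=float)))
        for name in ("csmi", "csmni", "cspni"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.is_spg = np.asarray(self.is_spg, dtype=bool)
        self.spg_reason = np.asarray(self.spg_reason, dtype=object)
        self.validate()

    def validate(self) -> None:
        n, h = len(self.gene_ids), len(self.slide_ids)
        for name in ("per_slide_mean_imp", "per_slide_mni", "per_slide_pni"):
            if getattr(self, name).shape != (n, h):
                raise ValueError(f"{name} must have shape ({n}, {h})")
        for name in ("csmi", "csmni", "cspni", "is_spg", "spg_reason"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if np.any(self.cspni < -1e-9) or np.any(self.cspni > 100 + 1e-9):
            raise ValueError("cspni out of [0, 100]")
        if self.aggregate == "mean" and h > 0 and n > 0:
            if not np.allclose(self.csmi, self.per_slide_mean_imp.mean(axis=1), atol=1e-9):
                raise ValueError("csmi must equal the row-mean of per-slide MeanImp")
        bad = self.is_spg != (self.spg_reason != "none")
        if np.any(bad):
            raise ValueError("is_spg must be true exactly when spg_reason != 'none'")
        for r in self.spg_reason:
            if r not in SPG_REASONS:
                raise ValueError(f"unknown spg_reason {r!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "csmi": self.csmi,
                "csmni": self.csmni,
                "cspni": self.cspni,
                "is_spg": self.is_spg,
                "spg_reason": self.spg_reason,
            }
        )
        for j, sid in enumerate(self.slide_ids):
            df[f"mean_imp__{sid}"] = self.per_slide_mean_imp[:, j]
            df[f"mni__{sid}"] = self.per_slide_mni[:, j]
            df[f"pni__{sid}"] = self.per_slide_pni[:, j]
        return df


# ---------------------------------------------------------------------------
# readers / writers


def _read_id_list(path: Path) -> list[str]:
    # one id per line; tolerate 10x-style TSVs by taking the first column
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _read_coords(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str})
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinate file must have columns {sorted(required)}")
    for col in ("x", "y"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric coordinate in column {col!r}: {exc}") from exc
    if df["spot_id"].duplicated().any():
        dups = df["spot_id"][df["spot_id"].duplicated()].tolist()
        raise ValueError(f"duplicate spot ids in coordinate file: {dups}")
    return df


def read_slide(
    matrix_path: str | Path,
    coords_path: str | Path,
    genes_path: str | Path | None = None,
    spots_path: str | Path | None = None,
    patient_id: str = "",
    slide_id: str = "",
    mtx_orientation: str = "genes_by_spots",
) -> SpatialSlide:
    """Load one slide from disk.

    MatrixMarket input needs ``genes_path`` / ``spots_path`` name files and an
    orientation flag (default genes x spots, the Visium convention). Dense TSV
    input carries its own ids (header = genes, first column = spots). Spots are
    returned in coordinate-file order; every matrix spot must appear there.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or spots_path is None:
            raise ValueError("MTX input requires genes_path and spots_path")
        mat = mmread(matrix_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        if mtx_orientation == "genes_by_spots":
            mat = mat.T
        elif mtx_orientation != "spots_by_genes":
            raise ValueError(f"unknown mtx_orientation {mtx_orientation!r}")
        gene_ids = _read_id_list(Path(genes_path))
        spot_ids = _read_id_list(Path(spots_path))
        if mat.shape != (len(spot_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match {len(spot_ids)} spots x "
                f"{len(gene_ids)} genes (orientation={mtx_orientation!r})"
            )
        expr = pd.DataFrame(mat, index=spot_ids, columns=gene_ids)
    else:
        expr = pd.read_csv(matrix_path, sep="\t", index_col=0)
        expr.index = expr.index.astype(str)

    if expr.index.duplicated().any() or expr.columns.duplicated().any():
        raise ValueError("duplicate spot or gene ids in expression matrix")

    coords = _read_coords(Path(coords_path))
    known = set(coords["spot_id"])
    missing = [s for s in expr.index if s not in known]
    if missing:
        raise ValueError(f"spots missing from coordinate file: {missing}")
    # coordinate-file order drives spot order; extra coordinate rows are ignored
    coords = coords[coords["spot_id"].isin(set(expr.index))].reset_index(drop=True)
    expr = expr.loc[coords["spot_id"].tolist()]

    return SpatialSlide(
        expression=expr.to_numpy(dtype=float),
        gene_ids=[str(g) for g in expr.columns],
        spot_ids=coords["spot_id"].tolist(),
        coords=coords[["x", "y"]].to_numpy(dtype=float),
        patient_id=patient_id,
        slide_id=slide_id,
    )


def _write_coords(slide: SpatialSlide, coords_path: Path) -> None:
    pd.DataFrame(
        {"spot_id": slide.spot_ids, "x": slide.coords[:, 0], "y": slide.coords[:, 1]}
    ).to_csv(coords_path, sep="\t", index=False)


def write_slide_dense(slide: SpatialSlide, matrix_path: str | Path, coords_path: str | Path) -> None:
    """Write a slide as a dense TSV matrix plus a coordinate TSV (lossless round trip)."""
    df = pd.DataFrame(slide.expression, index=slide.spot_ids, columns=slide.gene_ids)
    df.index.name = "spot_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.17g")
    _write_coords(slide, Path(coords_path))


def write_slide_mtx(slide: SpatialSlide, out_dir: str | Path, prefix: str = "matrix") -> dict:
    """Write a slide as genes x spots MatrixMarket + name files + coordinate TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{prefix}.mtx",
        "genes": out_dir / f"{prefix}.genes.txt",
        "spots": out_dir / f"{prefix}.spots.txt",
        "coords": out_dir / f"{prefix}.coords.tsv",
    }
    mmwrite(str(paths["matrix"]), sparse.csr_matrix(slide.expression.T))
    paths["genes"].write_text("".join(g + "\n" for g in slide.gene_ids))
    paths["spots"].write_text("".join(s + "\n" for s in slide.spot_ids))
    _write_coords(slide, paths["coords"])
    return paths


def write_gene_scores(table: GeneScoreTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_scores(path: str | Path) -> GeneScoreTable:
    df = pd.read_csv(path, sep="\t")
    slide_ids = [c[len("mean_imp__"):] for c in df.columns if c.startswith("mean_imp__")]
    n = len(df)

    def block(prefix: str) -> np.ndarray:
        if not slide_ids:
            return np.zeros((n, 0))
        return df[[f"{prefix}__{s}" for s in slide_ids]].to_numpy(dtype=float)

    reason = df["spg_reason"].astype(str).to_numpy(dtype=object) if n else np.array([], dtype=object)
    return GeneScoreTable(
        gene_ids=df["gene_id"].astype(str).tolist(),
        slide_ids=slide_ids,
        per_slide_mean_imp=block("mean_imp").reshape(n, len(slide_ids)),
        per_slide_mni=block("mni").reshape(n, len(slide_ids)),
        per_slide_pni=block("pni").reshape(n, len(slide_ids)),
        csmi=df["csmi"].to_numpy(dtype=float),
        csmni=df["csmni"].to_numpy(dtype=float),
        cspni=df["cspni"].to_numpy(dtype=float),
        is_spg=df["is_spg"].to_numpy(dtype=bool),
        spg_reason=reason,
    )
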