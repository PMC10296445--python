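"""DeepLIFT (Rescale rule) input attributions for the coordinate model.

For a spot s and scalar target t (by default the sum of the predicted x and
y outputs), each input gene g receives a signed contribution C_gs relative
to a reference input (all zeros by default, i.e. the per-gene mean after
standardization), with the completeness constraint

    sum_g C_gs = t(x) - t(x0).

The network is a chain of affine maps (dense layers; batch-norm folded into
its inference-mode scale/shift) and ReLUs. Rescale propagates *multipliers*
backwards: affine layers pass multipliers through their weights (the linear
rule), and a ReLU with pre-activation difference du = u - u0 uses the
secant slope (relu(u) - relu(u0)) / du, falling back to the local derivative
where du is numerically zero. Contributions are m_input * (x - x0). Both
rules conserve sum(multiplier * delta) layer to layer, so completeness holds
to floating-point precision.

Gene importance is the contribution magnitude |C_gs|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpatialSlide
from .network import CVResult, MLPModel

__all__ = [
    "ContributionMatrix",
    "ImportanceMatrix",
    "TARGET_MODES",
    "deeplift_contributions",
    "importance_from_contributions",
    "testfold_importance",
]

TARGET_MODES = ("sum_xy", "per_axis_x", "per_axis_y")
_SECANT_EPS = 1e-9


@dataclass
class ContributionMatrix:
    """Signed spots x genes contributions for one declared scalar target."""

    values: np.ndarray
    target_mode: str
    reference: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    target: np.ndarray = None  # t per spot
    target_reference: float = 0.0  # t0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contributions contain non-finite values")
        if self.values.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise ValueError("contribution shape does not match ids")
        if self.target_mode not in TARGET_MODES:
            raise ValueError(f"unknown target_mode {self.target_mode!r}")

    def completeness_residual(self) -> np.ndarray:
        """Per-spot relative residual of the summation-to-delta constraint."""
        delta = self.target - self.target_reference
        return np.abs(self.values.sum(axis=1) - delta) / (np.abs(delta) + 1e-8)


@dataclass
class ImportanceMatrix:
    """Non-negative spots x genes importance scores |C_gs|."""

    values: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    fold_of_spot: np.ndarray = None  # provenance: which fold model scored each spot

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("importance scores must be non-negative")
        if self.values.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise ValueError("importance shape does not match ids")


def _target_weights(mode: str) -> np.ndarray:
    if mode == "sum_xy":
        return np.array([1.0, 1.0])
    if mode == "per_axis_x":
        return np.array([1.0, 0.0])
    if mode == "per_axis_y":
        return np.array([0.0, 1.0])
    raise ValueError(f"unknown target_mode {mode!r}")


def deeplift_contributions(
    model: MLPModel,
    expression: np.ndarray,
    target_mode: str = "sum_xy",
    reference: np.ndarray | None = None,
    spot_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> ContributionMatrix:
    """Rescale-rule contributions of every input gene, vectorized over spots."""
    X = np.asarray(expression, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_input:
        raise ValueError(f"expression shape {X.shape} does not match model input {model.n_input}")
    if reference is None:
        reference = np.zeros(model.n_input)
    reference = np.asarray(reference, dtype=float).reshape(-1)
    if reference.shape != (model.n_input,):
        raise ValueError(
            f"reference shape {reference.shape} does not match model input ({model.n_input},)"
        )

    hidden, (W_out, b_out) = model.inference_affine_layers()
    w_t = _target_weights(target_mode)

    # forward both the inputs and the reference, keeping post-BN pre-activations
    def _forward(h):
        us = []
        for W, b, a, c in hidden:
            u = (h @ W + b) * a + c
            us.append(u)
            h = np.maximum(u, 0.0)
        return us, h @ W_out + b_out

    us, out = _forward(X)
    us0, out0 = _forward(reference[None, :])

    t = out @ w_t
    t0 = float(out0[0] @ w_t)

    # multiplier backprop: output -> input
    m = np.broadcast_to(w_t, out.shape) @ W_out.T  # (n, last_width)
    for (W, _b, a, _c), u, u0 in zip(reversed(hidden), reversed(us), reversed(us0)):
        du = u - u0
        secant = np.where(
            np.abs(du) > _SECANT_EPS,
            (np.maximum(u, 0.0) - np.maximum(u0, 0.0)) / np.where(du == 0, 1.0, du),
            (u > 0).astype(float),
        )
        m = (m * secant * a) @ W.T

    values = m * (X - reference)
    n, g = X.shape
    return ContributionMatrix(
        values=values,
        target_mode=target_mode,
        reference=reference,
        spot_ids=list(spot_ids) if spot_ids is not None else [f"spot{i}" for i in range(n)],
        gene_ids=list(gene_ids) if gene_ids is not None else [f"gene{j}" for j in range(g)],
        target=t,
        target_reference=t0,
    )


def importance_from_contributions(contribs: ContributionMatrix) -> ImportanceMatrix:
    """Importance = |contribution|, elementwise."""
    return ImportanceMatrix(
        values=np.abs(contribs.values),
        spot_ids=list(contribs.spot_ids),
        gene_ids=list(contribs.gene_ids),
    )


def testfold_importance(
    cv: CVResult, slide: SpatialSlide, target_mode: str = "sum_xy"
) -> ImportanceMatrix:
    """Importance for every spot from the model that held it in the TEST fold.

    Assembles a full-slide importance matrix with a per-spot provenance
    record, guaranteeing no attribution model ever trained on the spot it
    scores.
    """
    if cv.spot_ids != slide.spot_ids or cv.gene_ids != slide.gene_ids:
        raise ValueError("CV result was not produced on this slide")
    if len(cv.per_fold_models) != cv.k:
        raise ValueError("missing fold models")
    values = np.zeros((slide.n_spots, slide.n_genes))
    fold_of_spot = np.full(slide.n_spots, -1, dtype=int)
    for fi, idx in enumerate(cv.folds):
        contribs = deeplift_contributions(
            cv.per_fold_models[fi],
            slide.expression[idx],
            target_mode=target_mode,
            spot_ids=[slide.spot_ids[i] for i in idx],
            gene_ids=slide.gene_ids,
        )
        values[idx] = np.abs(contribs.values)
        fold_of_spot[idx] = fi
    if np.any(fold_of_spot < 0):
        raise ValueError("some spots were not covered by any test fold")
    return ImportanceMatrix(
        values=values,
        spot_ids=list(slide.spot_ids),
        gene_ids=list(slide.gene_ids),
        fold_of_spot=fold_of_spot,
    )
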