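"""Dense feedforward coordinate-regression network, training, and cross-validation.

The model maps a spot's (preprocessed) expression vector to its (x, y) slide
coordinates: input(n_genes) -> [dense -> batch-norm -> ReLU] per hidden layer
-> dense(2, linear). Hidden widths follow a halving geometric series whose
total is approximately half the input size. Dense weights use He-normal
initialization; optimization is Adam on the mean distance error (MDE), the
mean Euclidean distance between predicted and actual coordinates, which is
both the loss and the reported metric.

Everything is implemented in numpy: the networks are small (at most a few
hundred units), so explicit forward/backward passes are fast, exact, and
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .io import SpatialSlide

__all__ = [
    "ArchitectureSpec",
    "CVResult",
    "MLPModel",
    "plan_architecture",
    "build_model",
    "mean_distance_error",
    "train_model",
    "cross_validate",
    "predict_coordinates",
    "centroid_null_mde",
    "DEFAULT_GRID",
]

DEFAULT_GRID = {
    "n_hidden_layers": (1, 3, 5),
    "learning_rate": (0.1, 0.01, 0.001),
}

_BN_EPS = 1e-3
# Running-statistic momentum; 0.9 lets inference-mode statistics track the
# batch statistics within a few epochs, which the early-stopping monitor needs.
_BN_MOMENTUM = 0.9
_ADAM_BETA1, _ADAM_BETA2, _ADAM_EPS = 0.9, 0.999, 1e-7


@dataclass
class ArchitectureSpec:
    """Resolved hyperparameters for one model."""

    n_input: int
    hidden_widths: list[int]
    learning_rate: float
    batch_size: int = 32
    max_epochs: int = 100
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_widths = [int(w) for w in self.hidden_widths]
        if any(w < 2 for w in self.hidden_widths):
            raise ValueError("hidden widths must all be >= 2")
        if any(a <= b for a, b in zip(self.hidden_widths, self.hidden_widths[1:])):
            raise ValueError("hidden widths must be strictly decreasing")


def plan_architecture(
    n_input: int, n_hidden_layers: int, first_layer_half: bool = False
) -> list[int]:
    """Hidden-layer widths: a halving series totalling about half the input size.

    Default reading: the total hidden-node budget is n_input / 2, split as a
    geometric halving series, so the first width is
    w1 = n_input / (2 * sum_j 2^-j) and width j is round(w1 / 2^j) (each width
    rounded from the unrounded w1, so the total stays closest to the budget).
    ``first_layer_half`` selects the alternative reading where the *first*
    hidden layer is n_input / 2 and subsequent layers halve.
    """
    if n_input < 4:
        raise ValueError("n_input must be >= 4")
    if n_hidden_layers < 1:
        raise ValueError("need at least one hidden layer")
    if first_layer_half:
        w1 = n_input / 2.0
    else:
        denom = 2.0 * sum(2.0 ** -j for j in range(n_hidden_layers))
        w1 = n_input / denom
    widths = [round(w1 / 2.0 ** j) for j in range(n_hidden_layers)]
    if any(w < 2 for w in widths) or any(
        a <= b for a, b in zip(widths, widths[1:])
    ):
        raise ValueError(
            f"n_input={n_input} too small for {n_hidden_layers} strictly decreasing "
            f"hidden layers of width >= 2 (got {widths})"
        )
    return widths


def mean_distance_error(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Mean Euclidean distance between predicted and actual (x, y) coordinates."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 2 or predicted.shape[1] != 2:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {actual.shape}")
    if predicted.shape[0] < 1:
        raise ValueError("need at least one spot")
    return float(np.sqrt(((predicted - actual) ** 2).sum(axis=1)).mean())


def centroid_null_mde(coords: np.ndarray) -> float:
    """MDE of the baseline that predicts every spot at the mean coordinate."""
    coords = np.asarray(coords, dtype=float)
    centroid = np.broadcast_to(coords.mean(axis=0), coords.shape)
    return mean_distance_error(centroid, coords)


class MLPModel:
    """Feedforward net with per-hidden-layer dense -> batch-norm -> ReLU blocks.

    Parameter layout per hidden layer i: W[i] (fan_in x width), b[i],
    batch-norm gamma/beta and running mean/var. The output layer is a plain
    linear dense(2). ``hidden_widths`` may be empty, giving a purely linear
    model (used for attribution sanity checks).
    """

    def __init__(self, n_input: int, hidden_widths: list[int], seed: int = 0):
        self.n_input = int(n_input)
        self.hidden_widths = [int(w) for w in hidden_widths]
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        self.gamma, self.beta = [], []
        self.run_mean, self.run_var = [], []
        fan_in = self.n_input
        for w in self.hidden_widths:
            self.W.append(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, w)))
            self.b.append(np.zeros(w))
            self.gamma.append(np.ones(w))
            self.beta.append(np.zeros(w))
            self.run_mean.append(np.zeros(w))
            self.run_var.append(np.ones(w))
            fan_in = w
        self.W_out = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, 2))
        self.b_out = np.zeros(2)

    # -- parameter bookkeeping -------------------------------------------------

    def trainable_parameters(self) -> list[np.ndarray]:
        params = []
        for i in range(len(self.hidden_widths)):
            params += [self.W[i], self.b[i], self.gamma[i], self.beta[i]]
        params += [self.W_out, self.b_out]
        return params

    def n_trainable_parameters(self) -> int:
        return sum(p.size for p in self.trainable_parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.trainable_parameters()] + [
            m.copy() for m in self.run_mean
        ] + [v.copy() for v in self.run_var]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        n_train = len(self.trainable_parameters())
        trainable, rest = weights[:n_train], weights[n_train:]
        for p, w in zip(self.trainable_parameters(), trainable):
            p[...] = w
        L = len(self.hidden_widths)
        for i in range(L):
            self.run_mean[i][...] = rest[i]
            self.run_var[i][...] = rest[L + i]

    # -- forward / backward ----------------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False):
        """Forward pass; returns (predictions, cache) where cache feeds backward()."""
        X = np.asarray(X, dtype=float)
        cache = {"X": X, "z": [], "u": [], "h": [], "bn": []}
        h = X
        for i in range(len(self.hidden_widths)):
            z = h @ self.W[i] + self.b[i]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.run_mean[i] = _BN_MOMENTUM * self.run_mean[i] + (1 - _BN_MOMENTUM) * mu
                self.run_var[i] = _BN_MOMENTUM * self.run_var[i] + (1 - _BN_MOMENTUM) * var
            else:
                mu, var = self.run_mean[i], self.run_var[i]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv_std
            u = self.gamma[i] * zhat + self.beta[i]
            h_next = np.maximum(u, 0.0)
            cache["z"].append(z)
            cache["u"].append(u)
            cache["h"].append(h)
            cache["bn"].append((zhat, inv_std))
            h = h_next
        out = h @ self.W_out + self.b_out
        cache["h_last"] = h
        return out, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference-mode forward pass (batch-norm uses running stats)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_input:
            raise ValueError(
                f"expected input with {self.n_input} genes, got shape {X.shape}"
            )
        out, _ = self.forward(X, training=False)
        return out

    def backward(self, cache, d_out: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. trainable parameters, in trainable_parameters() order."""
        grads_per_layer = []
        h = cache["h_last"]
        dW_out = h.T @ d_out
        db_out = d_out.sum(axis=0)
        dh = d_out @ self.W_out.T
        m = h.shape[0]
        for i in reversed(range(len(self.hidden_widths))):
            u = cache["u"][i]
            du = dh * (u > 0)
            zhat, inv_std = cache["bn"][i]
            dgamma = (du * zhat).sum(axis=0)
            dbeta = du.sum(axis=0)
            dzhat = du * self.gamma[i]
            # batch-norm backward over the batch axis
            dz = (inv_std / m) * (
                m * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
            )
            h_in = cache["h"][i]
            dW = h_in.T @ dz
            db = dz.sum(axis=0)
            dh = dz @ self.W[i].T
            grads_per_layer.append([dW, db, dgamma, dbeta])
        grads = []
        for layer in reversed(grads_per_layer):
            grads += layer
        grads += [dW_out, db_out]
        return grads

    def inference_affine_layers(self):
        """Per-hidden-layer (W, b, bn_scale, bn_shift) with batch-norm folded to
        its inference-mode affine form, plus the output (W_out, b_out).

        Used by the attribution module, which needs the network as a chain of
        affine maps and ReLUs.
        """
        layers = []
        for i in range(len(self.hidden_widths)):
            inv_std = 1.0 / np.sqrt(self.run_var[i] + _BN_EPS)
            a = self.gamma[i] * inv_std
            c = self.beta[i] - self.gamma[i] * self.run_mean[i] * inv_std
            layers.append((self.W[i], self.b[i], a, c))
        return layers, (self.W_out, self.b_out)


def build_model(spec: ArchitectureSpec) -> MLPModel:
    """Instantiate a seeded model from a resolved architecture spec."""
    return MLPModel(spec.n_input, spec.hidden_widths, seed=spec.seed)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - _ADAM_BETA1 ** self.t
        b2t = 1 - _ADAM_BETA2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= _ADAM_BETA1
            m += (1 - _ADAM_BETA1) * g
            v *= _ADAM_BETA2
            v += (1 - _ADAM_BETA2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + _ADAM_EPS)


def _mde_loss_grad(pred: np.ndarray, actual: np.ndarray):
    diff = pred - actual
    dist = np.sqrt((diff ** 2).sum(axis=1))
    loss = dist.mean()
    safe = np.where(dist > 0, dist, 1.0)
    d_pred = diff / (safe[:, None] * len(dist))
    d_pred[dist == 0] = 0.0
    return loss, d_pred


def train_model(
    train: SpatialSlide, val: SpatialSlide, spec: ArchitectureSpec
) -> tuple[MLPModel, list[dict]]:
    """Train with minibatch Adam on MDE; early-stop on validation MDE.

    Stops when the validation MDE has not improved for
    ``spec.early_stopping_patience`` consecutive epochs, or at
    ``spec.max_epochs``; the best-validation weights are restored. The
    returned history holds one record per completed epoch with train/val MDE
    (both measured in inference mode).
    """
    if train.gene_ids != val.gene_ids:
        raise ValueError("train and validation slides must share the gene set")
    X, Y = train.expression, train.coords
    Xv, Yv = val.expression, val.coords
    model = build_model(spec)
    params = model.trainable_parameters()
    opt = _Adam(params, spec.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    history: list[dict] = []
    best_val = np.inf
    best_weights = model.get_weights()
    wait = 0
    n = X.shape[0]
    for epoch in range(spec.max_epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            pred, cache = model.forward(X[idx], training=True)
            loss, d_pred = _mde_loss_grad(pred, Y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            grads = model.backward(cache, d_pred)
            opt.step(params, grads)
        train_mde = mean_distance_error(model.predict(X), Y)
        val_mde = mean_distance_error(model.predict(Xv), Yv)
        if not (np.isfinite(train_mde) and np.isfinite(val_mde)):
            raise RuntimeError(f"non-finite MDE at epoch {epoch}")
        history.append({"epoch": epoch, "train_mde": train_mde, "val_mde": val_mde})
        if val_mde < best_val:
            best_val = val_mde
            best_weights = model.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= spec.early_stopping_patience:
                break
    model.set_weights(best_weights)
    return model, history


def predict_coordinates(model: MLPModel, expression: np.ndarray) -> np.ndarray:
    """Inference-mode coordinate predictions for a spots x genes matrix."""
    return model.predict(expression)


@dataclass
class CVResult:
    """Outcome of k-fold cross-validation with train/val/test fold roles."""

    spot_ids: list[str]
    gene_ids: list[str]
    fold_assignment: dict
    folds: list[np.ndarray]
    val_fold_for_test: list[int]
    test_predictions: np.ndarray
    cv_mde: float
    per_fold_models: list[MLPModel]
    best_hyperparams: tuple
    grid_cv_mde: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.folds)


def _model_seed(seed: int, *context: int) -> int:
    # deterministic per-(grid point, fold) seed below 2**31
    ss = np.random.SeedSequence([int(seed)] + [int(c) for c in context])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def cross_validate(
    slide: SpatialSlide,
    grid: dict | None = None,
    k: int = 10,
    seed: int = 0,
    batch_size: int = 32,
    max_epochs: int = 100,
    early_stopping_patience: int = 10,
    first_layer_half: bool = False,
) -> CVResult:
    """Grid-search hidden-layer count and learning rate by k-fold CV.

    Spots are randomized to k folds once per seed. For test fold i the
    validation fold is (i + 1) mod k and the remaining k - 2 folds train.
    Each grid point's CV error is the MDE over the aggregated test-fold
    predictions; the best point's within-fold models and predictions are
    returned. Ties prefer fewer hidden layers, then smaller learning rates.
    """
    if k < 3:
        raise ValueError("k must be >= 3 (train/validation/test need distinct folds)")
    if slide.n_spots < k:
        raise ValueError(f"{slide.n_spots} spots cannot fill {k} folds")
    if grid is None:
        grid = DEFAULT_GRID
    layers_grid = sorted(grid["n_hidden_layers"])
    lr_grid = sorted(grid["learning_rate"])

    rng = np.random.default_rng(seed)
    perm = rng.permutation(slide.n_spots)
    folds = [np.sort(f) for f in np.array_split(perm, k)]
    fold_assignment = {}
    for fi, idx in enumerate(folds):
        for i in idx:
            fold_assignment[slide.spot_ids[i]] = fi
    val_for_test = [(i + 1) % k for i in range(k)]

    X, Y = slide.expression, slide.coords
    best = None
    grid_cv_mde: dict = {}
    for gi, (L, lr) in enumerate(itertools.product(layers_grid, lr_grid)):
        widths = plan_architecture(slide.n_genes, L, first_layer_half=first_layer_half)
        preds = np.zeros((slide.n_spots, 2))
        models = []
        for ti in range(k):
            vi = val_for_test[ti]
            train_idx = np.concatenate(
                [folds[j] for j in range(k) if j not in (ti, vi)]
            )
            spec = ArchitectureSpec(
                n_input=slide.n_genes,
                hidden_widths=widths,
                learning_rate=lr,
                batch_size=batch_size,
                max_epochs=max_epochs,
                early_stopping_patience=early_stopping_patience,
                seed=_model_seed(seed, gi, ti),
            )
            tr = slide.subset_spots(train_idx)
            va = slide.subset_spots(folds[vi])
            model, _ = train_model(tr, va, spec)
            preds[folds[ti]] = model.predict(X[folds[ti]])
            models.append(model)
        cv_mde = mean_distance_error(preds, Y)
        # grid iterated in (fewer layers, smaller lr) order; strict < keeps
        # the earlier point on ties
        if best is None or cv_mde < best["cv_mde"]:
            best = {
                "cv_mde": cv_mde,
                "hyperparams": (L, lr),
                "models": models,
                "preds": preds,
            }
        grid_cv_mde[(L, lr)] = cv_mde

    return CVResult(
        spot_ids=list(slide.spot_ids),
        gene_ids=list(slide.gene_ids),
        fold_assignment=fold_assignment,
        folds=folds,
        val_fold_for_test=val_for_test,
        test_predictions=best["preds"],
        cv_mde=best["cv_mde"],
        per_fold_models=best["models"],
        best_hyperparams=best["hyperparams"],
        grid_cv_mde=grid_cv_mde,
    )
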