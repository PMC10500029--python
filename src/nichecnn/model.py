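"""Permutation-invariant single-layer convolutional model over multi-cell
inputs, with random hyperparameter search.

Architecture (the CellCNN lineage): each convolutional filter is a per-cell
affine map followed by a ReLU, so for cell ``c`` and filter ``f`` the node
activity is ``a_fc = relu(w_f . x_c + b_f)``.  A pooling layer (mean by
default, max available) summarizes each filter's response across all cells of
a multi-cell input, making the output invariant to any permutation of the
input rows.  The pooled F-vector feeds a softmax head (classification,
cross-entropy) or a linear head (regression, squared error).

The whole model is small enough that it is implemented directly in NumPy:
explicit backpropagation through the two layers plus an Adam optimizer,
mini-batches, inverted dropout on the pooled vector, and early stopping on
validation loss.  Mean pooling sorts each filter's activations before
summing, so forward passes are *bitwise* identical under row permutations
(floating-point addition is not associative; fixing the summation order by
sorting removes even last-ulp order effects).

The per-cell *filter response* used downstream for cell selection is the bare
scalar product ``w_f . x`` — no bias, no activation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import SplitAssignment
from .neighborhoods import MultiCellInput

logger = logging.getLogger(__name__)

#: default random-search space (engineering defaults; the Adam + <=50-epoch
#: budget needs lr >= ~1e-3 to converge on these small nets)
DEFAULT_SEARCH_SPACE = {
    "n_filters": list(range(1, 9)),
    "learning_rate": (1e-3, 3e-2),  # log-uniform bounds
    "dropout": [0.0, 0.25, 0.5],
    "l1": [0.0, 1e-4, 1e-3],        # lasso on conv weights -> sparse, readable filters
}


@dataclass
class TrainedModel:
    """Weights and metadata of one trained conv/pool/head model."""

    filter_weights: np.ndarray          # (F, M')
    filter_biases: np.ndarray           # (F,)
    pooling: str                        # 'mean' | 'max'
    head_weights: np.ndarray            # (F, C) classification, (F,) regression
    head_bias: np.ndarray               # (C,) or scalar array
    task: str                           # 'classification' | 'regression'
    classes: list | None                # label order for class scores
    feature_names: list | None          # marker columns the model was fit on
    hyperparams: dict = field(default_factory=dict)
    val_score: float = float("nan")
    seed: int = 0

    @property
    def n_filters(self) -> int:
        return self.filter_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.filter_weights.shape[1]

    def forward_matrix(self, X: np.ndarray) -> np.ndarray:
        """Forward pass for one K x M' matrix (or a B x K x M' batch).

        Rows are first brought into a canonical (lexicographic) order — a
        no-op for a permutation-invariant model, but it pins down the exact
        floating-point evaluation so row-shuffled inputs give bitwise
        identical outputs (BLAS accumulation order depends on row position).
        """
        single = X.ndim == 2
        Xb = X[None] if single else X
        if Xb.shape[-1] != self.n_features:
            raise ValueError(
                f"input has {Xb.shape[-1]} features, model expects {self.n_features}"
            )
        Xb = np.stack([x[np.lexsort(x.T)] for x in Xb])
        P = _pool(_activations(Xb, self.filter_weights, self.filter_biases), self.pooling)
        if self.task == "classification":
            out = _softmax(P @ self.head_weights + self.head_bias)
        else:
            out = P @ self.head_weights + float(self.head_bias)
        return out[0] if single else out


def _activations(Xb: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.maximum(Xb @ W.T + b, 0.0)  # (B, K, F)

def _pool(A: np.ndarray, pooling: str) -> np.ndarray:
    if pooling == "max":
        return A.max(axis=1)
    # mean over a sorted copy: exact permutation invariance (see module docstring)
    return np.sort(A, axis=1).mean(axis=1)

def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=-1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=-1, keepdims=True)


def forward(model: TrainedModel, mci: MultiCellInput) -> np.ndarray | float:
    """Class probabilities (classification) or real prediction (regression)."""
    out = model.forward_matrix(mci.matrix)
    return float(out) if model.task == "regression" else out


def filter_response(model: TrainedModel, cell_markers: np.ndarray, filter_index: int) -> float:
    """The selection statistic: scalar product ``w_f . x`` (no bias, no relu)."""
    if not 0 <= filter_index < model.n_filters:
        raise IndexError(f"filter index {filter_index} out of range [0, {model.n_filters})")
    x = np.asarray(cell_markers, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(f"expected a length-{model.n_features} marker vector")
    return float(model.filter_weights[filter_index] @ x)


def regression_metrics(y: Sequence[float], yhat: Sequence[float]) -> dict:
    """R^2 (variance explained, about the mean of y) and RMSE.

    For constant ``y`` the R^2 denominator vanishes; the result carries
    ``r2=None`` (undefined) while RMSE is still returned.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("y and yhat must be equal-length nonempty 1-d arrays")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return {"r2": None, "rmse": rmse}
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return {"r2": r2, "rmse": rmse}


@dataclass
class TrainingReport:
    """Outcome of a random hyperparameter search."""

    n_trials: int
    trials: list            # per trial: {'hyperparams', 'val_score', 'failed'}
    best_trial: int
    test_score: float | dict | None


# -- training internals ---------------------------------------------------------

class _Net:
    """Mutable parameter bundle used during optimization."""

    def __init__(self, n_features: int, n_filters: int, n_out: int, task: str,
                 pooling: str, rng: np.random.Generator):
        s = 1.0 / math.sqrt(n_features)
        self.W = rng.normal(0.0, s, size=(n_filters, n_features))
        self.b = np.zeros(n_filters)
        so = 1.0 / math.sqrt(n_filters)
        self.Wh = rng.normal(0.0, so, size=(n_filters, n_out) if task == "classification" else (n_filters,))
        self.bh = np.zeros(n_out) if task == "classification" else np.zeros(())
        self.task = task
        self.pooling = pooling

    def params(self):
        return [self.W, self.b, self.Wh, self.bh]

    def loss_and_grads(self, Xb, y, dropout: float, rng: np.random.Generator | None,
                       l1: float = 0.0):
        B, K, _ = Xb.shape
        Z = Xb @ self.W.T + self.b                      # (B, K, F)
        A = np.maximum(Z, 0.0)
        if self.pooling == "max":
            P = A.max(axis=1)
        else:
            P = A.mean(axis=1)
        if dropout > 0 and rng is not None:
            mask = (rng.random(P.shape) >= dropout) / (1.0 - dropout)
            Pd = P * mask
        else:
            mask = None
            Pd = P
        if self.task == "classification":
            logits = Pd @ self.Wh + self.bh
            prob = _softmax(logits)
            loss = -np.mean(np.log(prob[np.arange(B), y] + 1e-12))
            dlogits = prob.copy()
            dlogits[np.arange(B), y] -= 1.0
            dlogits /= B
            dWh = Pd.T @ dlogits
            dbh = dlogits.sum(axis=0)
            dPd = dlogits @ self.Wh.T
        else:
            pred = Pd @ self.Wh + self.bh
            err = pred - y
            loss = float(np.mean(err ** 2))
            dpred = 2.0 * err / B
            dWh = Pd.T @ dpred
            dbh = np.asarray(dpred.sum())
            dPd = np.outer(dpred, self.Wh)
        dP = dPd * mask if mask is not None else dPd
        if self.pooling == "max":
            amax = A.argmax(axis=1)                     # (B, F)
            dA = np.zeros_like(A)
            bi = np.arange(B)[:, None]
            fi = np.arange(A.shape[2])[None, :]
            dA[bi, amax, fi] = dP
        else:
            dA = np.repeat(dP[:, None, :], K, axis=1) / K
        dZ = dA * (Z > 0)
        dW = np.einsum("bkf,bkm->fm", dZ, Xb)
        db = dZ.sum(axis=(0, 1))
        if l1 > 0:
            loss += l1 * float(np.abs(self.W).sum())
            dW += l1 * np.sign(self.W)
        return loss, [dW, db, dWh, dbh]

    def eval_loss(self, Xb, y):
        loss, _ = self.loss_and_grads(Xb, y, dropout=0.0, rng=None)
        return loss


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _fit_one(X_tr, y_tr, X_val, y_val, task, n_out, hp, pooling, rng,
             batch_size, max_epochs, patience):
    net = _Net(X_tr.shape[2], hp["n_filters"], n_out, task, pooling, rng)
    opt = _Adam(net.params(), hp["learning_rate"])
    best = None
    best_val = math.inf
    stale = 0
    n = len(X_tr)
    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            sel = order[start:start + batch_size]
            loss, grads = net.loss_and_grads(X_tr[sel], y_tr[sel], hp["dropout"], rng,
                                             l1=hp.get("l1", 0.0))
            if not math.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            opt.step(net.params(), grads)
        val_loss = net.eval_loss(X_val, y_val)
        if not math.isfinite(val_loss):
            raise FloatingPointError("non-finite validation loss")
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best = [p.copy() for p in net.params()]
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    if best is not None:
        net.W, net.b, net.Wh, net.bh = best
    return net


def _score(net, X, y, task):
    if task == "classification":
        P = _pool(_activations(X, net.W, net.b), net.pooling)
        pred = (P @ net.Wh + net.bh).argmax(axis=1)
        return float(np.mean(pred == y))
    P = _pool(_activations(X, net.W, net.b), net.pooling)
    yhat = P @ net.Wh + float(net.bh)
    m = regression_metrics(y, yhat)
    return m["r2"] if m["r2"] is not None else float("nan")


def train(
    inputs: Sequence[MultiCellInput],
    split: SplitAssignment,
    task: str = "classification",
    n_trials: int = 200,
    seed: int = 0,
    search_space: dict | None = None,
    pooling: str = "mean",
    batch_size: int = 64,
    max_epochs: int = 50,
    patience: int = 5,
    feature_names: Sequence[str] | None = None,
) -> tuple[TrainedModel, TrainingReport]:
    """Random hyperparameter search: train ``n_trials`` models on the training
    inputs and keep the one with the best validation score (accuracy for
    classification, R^2 for regression).

    The held-out test score (inputs from held-out samples) is computed once,
    for the selected model only.  Trials whose loss diverges are marked failed
    and excluded from selection.  Fully reproducible under ``seed``.

    In regression mode the filter count is fixed at 2 (a high-responding and a
    low-responding filter are analyzed separately downstream), so the search
    covers learning rate and dropout only.
    """
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    if not inputs:
        raise ValueError("no inputs")
    space = dict(DEFAULT_SEARCH_SPACE)
    if search_space:
        space.update(search_space)

    parts = split.partition_inputs(inputs)
    if len(parts["train"]) == 0 or len(parts["validation"]) == 0:
        raise ValueError("train and validation partitions must be non-empty")
    X_all = np.stack([inp.matrix for inp in inputs]).astype(float)

    if task == "classification":
        train_labels = {inputs[i].label for i in parts["train"]}
        if len(train_labels) < 2:
            raise ValueError("classification requires >=2 classes in the training set")
        classes = sorted({inp.label for inp in inputs}, key=str)
        lut = {c: i for i, c in enumerate(classes)}
        y_all = np.array([lut[inp.label] for inp in inputs])
        n_out = len(classes)
    else:
        classes = None
        y_all = np.array([float(inp.label) for inp in inputs])
        if np.var(y_all[parts["train"]]) == 0:
            raise ValueError("regression requires label variance > 0")
        n_out = 1

    X_tr, y_tr = X_all[parts["train"]], y_all[parts["train"]]
    X_val, y_val = X_all[parts["validation"]], y_all[parts["validation"]]

    rng = np.random.default_rng(seed)
    trials = []
    best_idx, best_score, best_net, best_hp = -1, -math.inf, None, None
    lo, hi = space["learning_rate"]
    for t in range(n_trials):
        hp = {
            "n_filters": 2 if task == "regression" else int(rng.choice(space["n_filters"])),
            "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            "dropout": float(rng.choice(space["dropout"])),
            "l1": float(rng.choice(space["l1"])),
        }
        trial_rng = np.random.default_rng(rng.integers(2 ** 31))
        try:
            net = _fit_one(X_tr, y_tr, X_val, y_val, task, n_out, hp, pooling,
                           trial_rng, batch_size, max_epochs, patience)
            score = _score(net, X_val, y_val, task)
            failed = not math.isfinite(score)
        except FloatingPointError:
            logger.warning("trial %d diverged (non-finite loss); skipped", t)
            net, score, failed = None, float("nan"), True
        trials.append({"hyperparams": hp, "val_score": score, "failed": failed})
        if not failed and score > best_score:
            best_idx, best_score, best_net, best_hp = t, score, net, hp

    if best_net is None:
        raise RuntimeError("all trials failed")

    model = TrainedModel(
        filter_weights=best_net.W.copy(),
        filter_biases=best_net.b.copy(),
        pooling=pooling,
        head_weights=best_net.Wh.copy(),
        head_bias=np.asarray(best_net.bh).copy(),
        task=task,
        classes=classes,
        feature_names=list(feature_names) if feature_names is not None else None,
        hyperparams=best_hp,
        val_score=best_score,
        seed=seed,
    )

    test_score: float | dict | None = None
    if len(parts["test"]):
        X_te, y_te = X_all[parts["test"]], y_all[parts["test"]]
        if task == "classification":
            test_score = _score(best_net, X_te, y_te, task)
        else:
            P = _pool(_activations(X_te, best_net.W, best_net.b), pooling)
            test_score = regression_metrics(y_te, P @ best_net.Wh + float(best_net.bh))

    report = TrainingReport(
        n_trials=n_trials, trials=trials, best_trial=best_idx, test_score=test_score
    )
    return model, report
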