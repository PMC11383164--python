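"""Funnel-shaped fully connected texture classifier, in NumPy.

Architecture: 12 -> 36 (x10) -> 24 -> 12 -> 3 (13 weight layers).  Every
layer is Linear -> BatchNorm; hidden layers add a leaky-ReLU activation and,
for the first 11 layers, inverted dropout with rates decreasing linearly
from 0.15 to 0.  Training minimises the class-balanced focal loss with
AdamW, 11 mini-batches per epoch, and an early-stopping rule that fires when
validation loss diverges from a still-decreasing training loss; the
best-validation weights are restored.

Forward, backward (including batch-norm backprop) and the optimiser are
implemented explicitly so that input gradients for integrated-gradients
attribution are exact.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

LEAKY_SLOPE = 0.01
BN_EPS = 1e-5
BN_MOMENTUM = 0.1

DEFAULT_WIDTHS: tuple[int, ...] = (12,) + (36,) * 10 + (24, 12, 3)


def funnel_dropout_rates(n_hidden: int = 12, n_dropout: int = 11, p_max: float = 0.15):
    """Dropout rates for the first ``n_dropout`` hidden layers: linear
    decrease from ``p_max`` to 0; remaining hidden layers get 0."""
    rates = np.zeros(n_hidden)
    rates[:n_dropout] = np.linspace(p_max, 0.0, n_dropout)
    return rates


def class_balance_weights(class_counts: np.ndarray, beta: float) -> np.ndarray:
    """Effective-number class weights (1-beta)/(1-beta^n_y)."""
    n = np.asarray(class_counts, dtype=float)
    if beta < 0 or beta >= 1:
        raise ValueError("beta must be in [0, 1)")
    if beta == 0:
        return np.ones_like(n)
    return (1.0 - beta) / (1.0 - np.power(beta, n))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def class_balanced_focal_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    class_counts: np.ndarray,
    beta: float = 0.999,
    gamma: float = 2.0,
) -> float:
    """Batch-mean class-balanced focal loss.

    loss_i = w_{y_i} * (1 - p_{y_i})^gamma * (-log p_{y_i}) with
    w_y = (1-beta)/(1-beta^{n_y}).  Reduces to plain cross-entropy at
    beta = 0, gamma = 0.
    """
    logits = np.asarray(logits, dtype=float)
    if not np.isfinite(logits).all():
        raise ValueError("non-finite logits")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    w = class_balance_weights(class_counts, beta)
    p = np.clip(_softmax(logits), 1e-12, 1.0)
    py = p[np.arange(len(labels)), labels]
    return float(np.mean(w[labels] * (1.0 - py) ** gamma * (-np.log(py))))


def _focal_loss_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    gamma: float,
) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. logits (batch mean)."""
    n = len(labels)
    p = np.clip(_softmax(logits), 1e-12, 1.0)
    py = p[np.arange(n), labels]
    wy = weights[labels]
    loss = float(np.mean(wy * (1.0 - py) ** gamma * (-np.log(py))))
    # d/du [-(1-u)^g log u] = g (1-u)^(g-1) log u - (1-u)^g / u
    fprime = gamma * (1.0 - py) ** np.maximum(gamma - 1.0, 0.0) * np.log(py) - (
        1.0 - py
    ) ** gamma / py
    onehot = np.zeros_like(p)
    onehot[np.arange(n), labels] = 1.0
    dz = (wy * fprime * py)[:, None] * (onehot - p) / n
    return loss, dz


@dataclass
class TrainingConfig:
    beta: float = 0.999
    gamma: float = 2.0
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    n_batches: int = 11
    max_epochs: int = 400
    patience: int = 20
    slope_window: int = 20
    seed: int = 0


class FunnelNet:
    """The 13-layer funnel network with batch norm and leaky-ReLU."""

    def __init__(
        self,
        widths: tuple[int, ...] = DEFAULT_WIDTHS,
        dropout_max: float = 0.15,
        n_dropout_layers: int = 11,
        seed: int | np.random.Generator = 0,
    ) -> None:
        rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
        self.widths = tuple(widths)
        self.n_layers = len(widths) - 1
        self.dropout = funnel_dropout_rates(
            self.n_layers - 1, min(n_dropout_layers, self.n_layers - 1), dropout_max
        )
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        for i in range(self.n_layers):
            din, dout = widths[i], widths[i + 1]
            # He initialisation suits the leaky-ReLU nonlinearity
            self.params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / din), (din, dout))
            self.params[f"b{i}"] = np.zeros(dout)
            self.params[f"g{i}"] = np.ones(dout)
            self.params[f"beta{i}"] = np.zeros(dout)
            self.running[f"mean{i}"] = np.zeros(dout)
            self.running[f"var{i}"] = np.ones(dout)
        self._rng = rng

    # ------------------------------------------------------------------
    def forward(
        self, X: np.ndarray, training: bool = False
    ) -> tuple[np.ndarray, list[dict]]:
        """Logits plus per-layer caches for backprop."""
        a = np.asarray(X, dtype=float)
        caches: list[dict] = []
        for i in range(self.n_layers):
            cache: dict = {"a_in": a}
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if training:
                mu = z.mean(axis=0)
                centered = z - mu
                var = np.einsum("ij,ij->j", centered, centered) / len(z)
                self.running[f"mean{i}"] = (
                    (1 - BN_MOMENTUM) * self.running[f"mean{i}"] + BN_MOMENTUM * mu
                )
                self.running[f"var{i}"] = (
                    (1 - BN_MOMENTUM) * self.running[f"var{i}"] + BN_MOMENTUM * var
                )
            else:
                centered = z - self.running[f"mean{i}"]
                var = self.running[f"var{i}"]
            inv_std = 1.0 / np.sqrt(var + BN_EPS)
            zhat = centered * inv_std
            h = self.params[f"g{i}"] * zhat + self.params[f"beta{i}"]
            cache.update(zhat=zhat, inv_std=inv_std, batch_norm_train=training)
            if i < self.n_layers - 1:
                act = np.where(h > 0, h, LEAKY_SLOPE * h)
                cache["h"] = h
                p = self.dropout[i] if i < len(self.dropout) else 0.0
                if training and p > 0:
                    mask = (self._rng.random(act.shape) >= p) / (1.0 - p)
                    act = act * mask
                    cache["mask"] = mask
                a = act
            else:
                a = h
            caches.append(cache)
        return a, caches

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(np.atleast_2d(X), training=False)
        return logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.predict_logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_logits(X).argmax(axis=1)

    # ------------------------------------------------------------------
    def backward(
        self, caches: list[dict], dlogits: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Parameter gradients and input gradient from dL/dlogits."""
        grads: dict[str, np.ndarray] = {}
        g = dlogits
        for i in reversed(range(self.n_layers)):
            cache = caches[i]
            if i < self.n_layers - 1:
                if "mask" in cache:
                    g = g * cache["mask"]
                g = g * np.where(cache["h"] > 0, 1.0, LEAKY_SLOPE)
            zhat, inv_std = cache["zhat"], cache["inv_std"]
            grads[f"g{i}"] = (g * zhat).sum(axis=0)
            grads[f"beta{i}"] = g.sum(axis=0)
            dzhat = g * self.params[f"g{i}"]
            if cache["batch_norm_train"]:
                n = len(zhat)
                dz = (
                    inv_std
                    / n
                    * (
                        n * dzhat
                        - dzhat.sum(axis=0)
                        - zhat * (dzhat * zhat).sum(axis=0)
                    )
                )
            else:
                dz = dzhat * inv_std
            a_in = cache["a_in"]
            grads[f"W{i}"] = a_in.T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            g = dz @ self.params[f"W{i}"].T
        return grads, g

    def input_gradient(self, X: np.ndarray, targets: np.ndarray) -> np.ndarray:
        """d logit_target / d input, evaluated in inference mode (row-wise).

        Inference-mode batch norm is a fixed affine map, so the backward
        pass here only chains activation masks and weight matrices — no
        parameter gradients are materialised.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        a = X
        masks: list[np.ndarray | None] = []
        for i in range(self.n_layers):
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            inv_std = 1.0 / np.sqrt(self.running[f"var{i}"] + BN_EPS)
            h = (
                self.params[f"g{i}"] * (z - self.running[f"mean{i}"]) * inv_std
                + self.params[f"beta{i}"]
            )
            if i < self.n_layers - 1:
                masks.append(np.where(h > 0, 1.0, LEAKY_SLOPE))
                a = np.where(h > 0, h, LEAKY_SLOPE * h)
            else:
                masks.append(None)
                a = h
        g = np.zeros_like(a)
        g[np.arange(len(X)), np.asarray(targets, dtype=int)] = 1.0
        for i in reversed(range(self.n_layers)):
            if masks[i] is not None:
                g = g * masks[i]
            scale = self.params[f"g{i}"] / np.sqrt(self.running[f"var{i}"] + BN_EPS)
            g = (g * scale) @ self.params[f"W{i}"].T
        return g

    def activation_signature(self, X: np.ndarray) -> np.ndarray:
        """Packed sign pattern of every hidden pre-activation (eval mode).

        Two inputs with identical signatures lie in the same linear region
        of the (piecewise-linear) network, where the input gradient is
        constant — the basis of exact path integration for attribution.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        a = X
        bits = []
        for i in range(self.n_layers):
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            inv_std = 1.0 / np.sqrt(self.running[f"var{i}"] + BN_EPS)
            h = (
                self.params[f"g{i}"] * (z - self.running[f"mean{i}"]) * inv_std
                + self.params[f"beta{i}"]
            )
            if i < self.n_layers - 1:
                bits.append(h > 0)
                a = np.where(h > 0, h, LEAKY_SLOPE * h)
            else:
                a = h
        return np.packbits(np.concatenate(bits, axis=1), axis=1)

    def state_dict(self) -> dict:
        return {
            "params": copy.deepcopy(self.params),
            "running": copy.deepcopy(self.running),
        }

    def load_state_dict(self, state: dict) -> None:
        self.params = copy.deepcopy(state["params"])
        self.running = copy.deepcopy(state["running"])


class _AdamW:
    """AdamW with decoupled weight decay (applied to weight matrices only)."""

    def __init__(self, params: dict, lr: float, weight_decay: float) -> None:
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        scale = self.lr / b1c
        for k, p in params.items():
            g = grads[k]
            m, v = self.m[k], self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= scale * (m / (np.sqrt(v / b2c) + self.eps))
            if k.startswith("W"):
                p -= (self.lr * self.wd) * p


@dataclass
class TrainingResult:
    model: "FunnelNet"
    epochs: int
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0


def train_sdm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    widths: tuple[int, ...] = DEFAULT_WIDTHS,
    config: TrainingConfig | None = None,
) -> TrainingResult:
    """Train the funnel network with early stopping on loss divergence.

    Stops when the validation loss has not improved for ``patience``
    consecutive epochs while the recent training-loss slope is negative
    (training still improving -> overfitting has begun), or at
    ``max_epochs``.  The best-validation weights are restored.
    """
    config = config or TrainingConfig()
    rng = np.random.default_rng(config.seed)
    model = FunnelNet(widths, seed=rng)
    n_classes = widths[-1]
    class_counts = np.bincount(y_train, minlength=n_classes).astype(float)
    class_counts[class_counts == 0] = 1.0
    weights = class_balance_weights(class_counts, config.beta)
    opt = _AdamW(model.params, config.learning_rate, config.weight_decay)

    best = {"val": np.inf, "state": model.state_dict(), "epoch": 0}
    train_losses: list[float] = []
    val_losses: list[float] = []
    since_best = 0
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(len(X_train))
        batch_losses = []
        for batch in np.array_split(perm, config.n_batches):
            if len(batch) == 0:
                continue
            logits, caches = model.forward(X_train[batch], training=True)
            loss, dlogits = _focal_loss_grad(
                logits, y_train[batch], weights, config.gamma
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            grads, _ = model.backward(caches, dlogits)
            opt.step(model.params, grads)
            batch_losses.append(loss)
        train_losses.append(float(np.mean(batch_losses)))

        val_logits = model.predict_logits(X_val)
        val_loss, _ = _focal_loss_grad(val_logits, y_val, weights, config.gamma)
        val_losses.append(val_loss)

        if val_loss < best["val"]:
            best = {"val": val_loss, "state": model.state_dict(), "epoch": epoch}
            since_best = 0
        else:
            since_best += 1

        if since_best >= config.patience:
            w = min(config.slope_window, len(train_losses))
            slope = np.polyfit(np.arange(w), train_losses[-w:], 1)[0]
            # divergence: validation worsening while training still improves;
            # a long plateau on both losses also ends the fit
            if slope < 0 or since_best >= 5 * config.patience:
                break

    model.load_state_dict(best["state"])
    return TrainingResult(
        model=model,
        epochs=epoch,
        train_losses=train_losses,
        val_losses=val_losses,
        best_epoch=best["epoch"],
    )


def evaluate_auc(model: FunnelNet, X: np.ndarray, y: np.ndarray) -> float:
    """Macro one-vs-rest ROC-AUC of the model's softmax scores."""
    y = np.asarray(y)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("AUC needs at least two classes present")
    proba = model.predict_proba(X)
    # macro average of one-vs-rest AUCs over the classes present
    aucs = [roc_auc_score(y == c, proba[:, c]) for c in present]
    return float(np.mean(aucs))
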