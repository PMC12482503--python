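"""The fingerprint-to-price MLP regressor.

The model maps a molecular feature vector through a small feed-forward
encoder to a low-dimensional latent vector ``z`` (default 10 dimensions)
and then through an affine *readout* ``f: R^N -> R`` to the predicted
natural-log price in USD/mmol.  The readout can be frozen, after which
further training updates encoder parameters only — the contract on which
the contrastive fine-tuning stage relies: a fixed latent-to-price map
means a shifted latent representation translates directly into a shifted
price label.

Implemented in plain numpy with hand-derived backpropagation and an Adam
optimizer; training is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import ConfigError, NumericalError

DEFAULT_LATENT_DIM = 10


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters for MSE pretraining and contrastive fine-tuning."""

    hidden: tuple[int, ...] = (256, 64)
    latent_dim: int = DEFAULT_LATENT_DIM
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 60
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ConfigError("latent_dim, batch_size and epochs must be positive")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PriceModel:
    """Encoder + affine readout, with a freezable readout head.

    Parameters are stored in ``self.params``: encoder weights ``W{i}``/
    ``b{i}`` (ReLU between hidden layers, linear into the latent layer)
    and readout ``w_out`` (shape ``(latent_dim,)``) and ``b_out``.
    """

    def __init__(
        self,
        input_dim: int,
        hidden: tuple[int, ...] = (256, 64),
        latent_dim: int = DEFAULT_LATENT_DIM,
        seed: int = 0,
    ):
        if input_dim <= 0:
            raise ConfigError(f"input_dim must be positive, got {input_dim}")
        self.input_dim = int(input_dim)
        self.hidden = tuple(int(h) for h in hidden)
        self.latent_dim = int(latent_dim)
        self.readout_frozen = False
        rng = np.random.default_rng(seed)
        dims = [self.input_dim, *self.hidden, self.latent_dim]
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(dims) - 1):
            fan_in = dims[i]
            # He initialization for the ReLU stack
            self.params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(dims[i], dims[i + 1]))
            self.params[f"b{i}"] = np.zeros(dims[i + 1])
        self.params["w_out"] = rng.normal(0.0, np.sqrt(1.0 / self.latent_dim), size=self.latent_dim)
        self.params["b_out"] = np.zeros(1)

    # ---- forward / backward -------------------------------------------------

    @property
    def n_encoder_layers(self) -> int:
        return len(self.hidden) + 1

    def _forward_cache(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ConfigError(
                f"expected input of shape (n, {self.input_dim}), got {X.shape}"
            )
        cache: dict = {"activations": [X], "preacts": []}
        a = X
        for i in range(self.n_encoder_layers):
            pre = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            cache["preacts"].append(pre)
            a = np.maximum(pre, 0.0) if i < self.n_encoder_layers - 1 else pre
            cache["activations"].append(a)
        Z = a
        yhat = Z @ self.params["w_out"] + self.params["b_out"][0]
        cache["Z"] = Z
        return Z, yhat, cache

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Latent vectors and predicted log-prices for a batch."""
        Z, yhat, _ = self._forward_cache(X)
        if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(yhat))):
            raise NumericalError("non-finite model output")
        return Z, yhat

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[1]

    def backward(
        self, cache: dict, dZ: np.ndarray | None, dy: np.ndarray | None
    ) -> dict[str, np.ndarray]:
        """Backpropagate upstream gradients to all parameters.

        ``dy`` is dLoss/dyhat per sample; ``dZ`` is any additional
        dLoss/dZ contribution that bypasses the readout (the latent-space
        loss terms).  Readout gradients are zeroed when the head is frozen.
        """
        Z = cache["Z"]
        n = Z.shape[0]
        grads: dict[str, np.ndarray] = {}
        dZ_total = np.zeros_like(Z) if dZ is None else np.asarray(dZ, dtype=np.float64).copy()
        if dy is not None:
            dy = np.asarray(dy, dtype=np.float64)
            dZ_total += dy[:, None] * self.params["w_out"][None, :]
            grads["w_out"] = Z.T @ dy
            grads["b_out"] = np.array([dy.sum()])
        else:
            grads["w_out"] = np.zeros_like(self.params["w_out"])
            grads["b_out"] = np.zeros(1)
        if self.readout_frozen:
            grads["w_out"] = np.zeros_like(grads["w_out"])
            grads["b_out"] = np.zeros(1)

        d = dZ_total
        for i in reversed(range(self.n_encoder_layers)):
            if i < self.n_encoder_layers - 1:
                d = d * (cache["preacts"][i] > 0)
            a_prev = cache["activations"][i]
            grads[f"W{i}"] = a_prev.T @ d
            grads[f"b{i}"] = d.sum(axis=0)
            if i > 0:
                d = d @ self.params[f"W{i}"].T
        del n
        return grads

    # ---- persistence / copying ---------------------------------------------

    def copy(self) -> "PriceModel":
        clone = PriceModel(self.input_dim, self.hidden, self.latent_dim, seed=0)
        clone.params = {k: v.copy() for k, v in self.params.items()}
        clone.readout_frozen = self.readout_frozen
        return clone

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.params)
        manifest = {
            "input_dim": self.input_dim,
            "hidden": list(self.hidden),
            "latent_dim": self.latent_dim,
            "readout_frozen": self.readout_frozen,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PriceModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        model = cls(
            manifest["input_dim"],
            tuple(manifest["hidden"]),
            manifest["latent_dim"],
            seed=0,
        )
        with np.load(path) as data:
            model.params = {k: data[k].copy() for k in data.files}
        model.readout_frozen = bool(manifest["readout_frozen"])
        return model


def build_model(input_dim: int, config: TrainConfig) -> PriceModel:
    """Construct an untrained model with deterministic seeded initialization."""
    return PriceModel(
        input_dim, hidden=config.hidden, latent_dim=config.latent_dim, seed=config.seed
    )


def freeze_readout(model: PriceModel) -> PriceModel:
    """Freeze the readout head; idempotent, returns the same model object."""
    model.readout_frozen = True
    return model


def mse_batch_grads(
    model: PriceModel, Xb: np.ndarray, yb: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and parameter gradients for one mean-squared-error minibatch."""
    _, yhat, cache = model._forward_cache(Xb)
    res = yhat - yb
    loss = float(np.mean(res**2))
    dy = 2.0 * res / len(yb)
    return loss, model.backward(cache, None, dy)


def train_mse(
    model: PriceModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> tuple[PriceModel, dict[str, list[float]]]:
    """MSE pretraining on priced (ES) data with best-checkpoint selection.

    Returns the model restored to the parameters with the lowest validation
    MSE seen during training, plus a per-epoch history.  Early-stops after
    ``config.patience`` epochs without validation improvement.
    """
    if model.readout_frozen:
        raise ConfigError("train_mse expects an unfrozen readout; use fine-tuning instead")
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    opt = Adam(lr=config.learning_rate)
    history: dict[str, list[float]] = {"train_mse": [], "val_mse": [], "val_mse_best": []}
    best_state = model.state_dict()
    best_val = float(np.mean((model.predict(X_val) - y_val) ** 2))
    stale = 0
    n = len(y_train)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = mse_batch_grads(model, X_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise NumericalError("training diverged: non-finite loss")
            opt.step(model.params, grads)
            epoch_losses.append(loss)
        val_mse = float(np.mean((model.predict(X_val) - y_val) ** 2))
        history["train_mse"].append(float(np.mean(epoch_losses)))
        history["val_mse"].append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
        history["val_mse_best"].append(best_val)
        if stale >= config.patience:
            break
    model.load_state_dict(best_state)
    return model, history
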