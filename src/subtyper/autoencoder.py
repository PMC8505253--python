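"""Deep symmetric AutoEncoder for compressing selected-voxel ALFF features.

The encoder follows a halving layer schedule (for 2175 input voxels:
2175-2048-1024-512-256-128-64-32-d) and the decoder mirrors it; training
minimizes mean squared reconstruction error with Adam.  Hidden layers use
ReLU; the bottleneck and the output layer are linear, which suits
standardized real-valued inputs.  The network is a plain numpy
implementation: forward/backward passes are a handful of matrix products,
which keeps training fully deterministic under a fixed seed and fast at
desk scale (hundreds of subjects, a few thousand voxels) on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AEConfig", "Embedding", "AutoEncoderModel", "build_layer_schedule",
           "train_autoencoder", "encode"]


def build_layer_schedule(input_dim: int, d: int) -> list[int]:
    """Encoder layer sizes from ``input_dim`` down to the bottleneck ``d``.

    Start at the largest power of two strictly below ``input_dim`` and halve
    down to 32, stopping early if the next halving would be <= ``d``; then
    append ``d``.  For 2175 inputs this yields the canonical
    [2175, 2048, 1024, 512, 256, 128, 64, 32, d].
    """
    if d < 1:
        raise ValueError("bottleneck dimension d must be >= 1")
    if d >= input_dim:
        raise ValueError(f"d ({d}) must be smaller than input_dim ({input_dim})")
    sizes = [input_dim]
    p = 1 << (int(input_dim - 1).bit_length() - 1)  # largest power of 2 < input_dim
    while p >= 32 and p > d:
        sizes.append(p)
        p //= 2
    sizes.append(d)
    return sizes


@dataclass
class AEConfig:
    """Training hyperparameters for one AutoEncoder."""

    d: int
    schedule: list[int] | None = None  # built from the input width if None
    activation: str = "relu"  # hidden layers; bottleneck/output stay linear
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    standardize: bool = True
    constant_columns: str = "error"  # or "drop"
    early_stop_tol: float = 0.0  # relative improvement; 0 disables
    early_stop_patience: int = 10

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.activation not in ("relu", "linear"):
            raise ValueError("activation must be 'relu' or 'linear'")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")
        if self.schedule is not None:
            diffs = np.diff(self.schedule)
            if np.any(diffs >= 0):
                raise ValueError("layer schedule must be strictly decreasing")
            if self.schedule[-1] != self.d:
                raise ValueError("schedule must end at d")


@dataclass
class Embedding:
    """Latent representation plus training provenance."""

    latent: np.ndarray  # subjects x d
    d: int
    seed: int
    initial_mse: float
    final_mse: float
    loss_trace: list[float] = field(default_factory=list)


class AutoEncoderModel:
    """Symmetric MLP autoencoder trained by minibatch Adam on MSE."""

    def __init__(self, schedule: list[int], config: AEConfig):
        self.schedule = list(schedule)
        self.config = config
        # full layer list: encoder ... bottleneck ... mirrored decoder
        self.sizes = self.schedule + self.schedule[-2::-1]
        self.n_encoder = len(self.schedule) - 1
        rng = np.random.default_rng(config.seed)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append((rng.standard_normal((fan_in, fan_out)) * scale).astype(np.float32))
            self.b.append(np.zeros(fan_out, dtype=np.float32))
        self._rng = rng
        self.mu: np.ndarray | None = None
        self.sd: np.ndarray | None = None
        self.kept_columns: np.ndarray | None = None
        self.n_input_features: int | None = None

    # -- layer activations: hidden ReLU (configurable), bottleneck & output linear
    def _is_linear(self, layer: int) -> bool:
        if self.config.activation == "linear":
            return True
        return layer == self.n_encoder - 1 or layer == len(self.W) - 1

    def _forward(self, X: np.ndarray, stop_at_bottleneck: bool = False):
        acts = [X]
        h = X
        n_layers = self.n_encoder if stop_at_bottleneck else len(self.W)
        for layer in range(n_layers):
            z = h @ self.W[layer] + self.b[layer]
            h = z if self._is_linear(layer) else np.maximum(z, 0.0)
            acts.append(h)
        return acts

    def _backward(self, acts: list[np.ndarray]) -> tuple[list, list]:
        X, out = acts[0], acts[-1]
        m = X.shape[0]
        delta = (2.0 / (m * X.shape[1])) * (out - X)  # d(MSE)/d(out)
        gW = [None] * len(self.W)
        gb = [None] * len(self.W)
        for layer in range(len(self.W) - 1, -1, -1):
            if not self._is_linear(layer):
                delta = delta * (acts[layer + 1] > 0)
            gW[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.W[layer].T
        return gW, gb

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if self.kept_columns is not None:
            X = X[:, self.kept_columns]
        if self.mu is not None:
            X = (X - self.mu) / self.sd
        return X

    def fit_standardizer(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        self.n_input_features = X.shape[1]
        if not self.config.standardize:
            return X
        sd = X.std(axis=0, ddof=0)
        const = sd == 0
        if const.any():
            if self.config.constant_columns == "drop":
                self.kept_columns = np.flatnonzero(~const)
                X = X[:, self.kept_columns]
                sd = sd[~const]
            else:
                raise ValueError(
                    f"{const.sum()} constant feature column(s); set "
                    "constant_columns='drop' to discard them"
                )
        self.mu = X.mean(axis=0)
        self.sd = sd.astype(np.float32)
        return (X - self.mu) / self.sd

    def reconstruction_mse(self, Xs: np.ndarray) -> float:
        out = self._forward(Xs)[-1]
        return float(np.mean((out - Xs) ** 2))

    def train(self, Xs: np.ndarray) -> tuple[float, float, list[float]]:
        cfg = self.config
        n = Xs.shape[0]
        lr, b1, b2, eps = cfg.learning_rate, 0.9, 0.999, 1e-8
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        step = 0
        initial = self.reconstruction_mse(Xs)
        best = initial
        best_params = ([w.copy() for w in self.W], [b.copy() for b in self.b])
        trace: list[float] = []
        stall = 0
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = Xs[order[start : start + cfg.batch_size]]
                acts = self._forward(batch)
                gW, gb = self._backward(acts)
                step += 1
                corr = np.float32(
                    np.sqrt(1.0 - b2**step) / (1.0 - b1**step)
                )
                for i in range(len(self.W)):
                    mW[i] = b1 * mW[i] + (1 - b1) * gW[i]
                    vW[i] = b2 * vW[i] + (1 - b2) * gW[i] ** 2
                    self.W[i] -= lr * corr * mW[i] / (np.sqrt(vW[i]) + eps)
                    mb[i] = b1 * mb[i] + (1 - b1) * gb[i]
                    vb[i] = b2 * vb[i] + (1 - b2) * gb[i] ** 2
                    self.b[i] -= lr * corr * mb[i] / (np.sqrt(vb[i]) + eps)
            mse = self.reconstruction_mse(Xs)
            if not np.isfinite(mse):
                raise FloatingPointError(
                    "non-finite reconstruction loss; try a lower learning rate"
                )
            trace.append(mse)
            if mse < best:
                improvement = (best - mse) / max(best, 1e-30)
                best = mse
                best_params = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                stall = 0 if improvement > cfg.early_stop_tol else stall + 1
            else:
                stall += 1
            if cfg.early_stop_tol > 0 and stall >= cfg.early_stop_patience:
                break
        self.W, self.b = best_params
        return initial, best, trace

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass to the bottleneck (float64 output)."""
        expected = self.n_input_features or self.sizes[0]
        if X.shape[1] != expected:
            raise ValueError(
                f"feature count {X.shape[1]} does not match the trained "
                f"model input width {expected}"
            )
        Xs = self._transform(X)
        return self._forward(Xs, stop_at_bottleneck=True)[-1].astype(np.float64)


def train_autoencoder(features, config: AEConfig):
    """Train one AutoEncoder on a feature matrix; return (Embedding, model).

    ``features`` is a :class:`~subtyper.glm.FeatureMatrix` or a plain
    subjects x voxels array.  All randomness (weight init, batch order) is
    driven by ``config.seed``; identical inputs and seed give bit-identical
    latent matrices.
    """
    X = np.asarray(getattr(features, "values", features), dtype=np.float64)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    width = X.shape[1]
    if config.standardize and config.constant_columns == "drop":
        width = int((np.asarray(X, dtype=np.float32).std(axis=0) > 0).sum())
    if config.schedule is not None:
        schedule = config.schedule
    elif config.d >= width:
        # degenerate request: a single (near-)identity mapping layer pair
        schedule = [width, config.d]
    else:
        schedule = build_layer_schedule(width, config.d)
    model = AutoEncoderModel(schedule, config)
    Xs = model.fit_standardizer(X)
    initial, final, trace = model.train(Xs)
    latent = model.encode(X)
    emb = Embedding(latent, config.d, config.seed, initial, final, trace)
    return emb, model


def encode(model: AutoEncoderModel, features) -> np.ndarray:
    """Encode a feature matrix with a trained model (d columns out)."""
    X = np.asarray(getattr(features, "values", features), dtype=np.float64)
    return model.encode(X)
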