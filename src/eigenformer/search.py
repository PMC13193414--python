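"""Training loop, validation-driven depth search, multi-seed protocol.

Training follows a fixed protocol: Adam (lr 1e-3, weight decay 1e-4),
cosine-annealed learning rate over 90 epochs, batch size 64, dropout
0.2, mean-squared-error loss, with epoch-level early stopping on
validation loss and the best-validation-epoch parameters returned.

Depth is not a hyperparameter here: models are trained at b = 1, 2, ...
blocks and deepening stops the first time the validation-loss
improvement ``delta(b) = L_val(b-1) - L_val(b)`` falls below a
threshold ``tau``; the returned depth ``b*`` is the best depth actually
trained, with ties within ``tau`` resolved toward the shallowest model
(which can precede the stopping depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transformer import ModelPlan, ParameterSet, eigen_initialize, forward, glorot_initialize

__all__ = [
    "TrainConfig",
    "TrainResult",
    "DepthSearchResult",
    "train",
    "evaluate_mse",
    "apply_depth_rule",
    "depth_search",
    "multi_seed_protocol",
    "PROTOCOL_SEEDS",
]

PROTOCOL_SEEDS = (42, 100, 500, 1000, 2000)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 90
    batch_size: int = 64
    patience: int = 15  # epoch-level early stop on validation loss
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.lr <= 0:
            raise ValueError("epochs must be >= 1 and lr > 0")


@dataclass
class TrainResult:
    params: ParameterSet  # best-validation-epoch parameters loaded
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss, lr
    best_epoch: int
    best_val_loss: float


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def evaluate_mse(params: ParameterSet, plan: ModelPlan, X: np.ndarray, y: np.ndarray,
                 batch_size: int = 512) -> float:
    """Deterministic (eval-mode) mean squared error on a dataset."""
    preds = predict(params, plan, X, batch_size=batch_size)
    return float(np.mean((preds - y) ** 2))


def predict(params: ParameterSet, plan: ModelPlan, X: np.ndarray,
            batch_size: int = 512) -> np.ndarray:
    out = []
    for start in range(0, len(X), batch_size):
        out.append(forward(X[start : start + batch_size], params, plan).data)
    return np.concatenate(out)


def train(
    plan: ModelPlan,
    params: ParameterSet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    dtype=np.float32,
) -> TrainResult:
    """Fit ``params`` in place and return the best-validation snapshot.

    All randomness (batch shuffling, dropout masks) is drawn from a
    generator seeded by ``config.seed``; identical inputs give
    bit-identical loss histories.  Optimisation runs in float32 for
    speed; the returned parameters are cast back to float64.
    """
    for name, arr in (("train", X_train), ("val", X_val)):
        if len(arr) == 0:
            raise ValueError(f"empty {name} split")
    for _, t in params.items():
        t.data = t.data.astype(dtype)
    rng = np.random.default_rng(config.seed)
    X_train = np.asarray(X_train, dtype=dtype)
    y_arr = np.asarray(y_train, dtype=dtype)
    m = {k: np.zeros_like(t.data) for k, t in params.items()}
    v = {k: np.zeros_like(t.data) for k, t in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    rows = []
    best_val, best_epoch, best_state = np.inf, -1, params.state()
    since_best = 0
    for epoch in range(config.epochs):
        lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))
        total, count = 0.0, 0
        for idx in _batches(len(X_train), config.batch_size, rng):
            params.zero_grad()
            yhat = forward(X_train[idx], params, plan, train_mode=True, rng=rng)
            diff = yhat - y_arr[idx]
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            step += 1
            for k, t in params.items():
                g = t.grad if t.grad is not None else np.zeros_like(t.data)
                if t.data.ndim >= 2:  # L2 weight decay on matrices only
                    g = g + config.weight_decay * t.data
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                t.data -= lr * mhat / (np.sqrt(vhat) + eps)
            total += float(loss.data) * len(idx)
            count += len(idx)
        val_loss = evaluate_mse(params, plan, X_val, y_val)
        rows.append({"epoch": epoch, "train_loss": total / count, "val_loss": val_loss, "lr": lr})
        if val_loss < best_val:
            best_val, best_epoch, best_state = val_loss, epoch, params.state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    for k, t in params.items():
        t.data = best_state[k].astype(np.float64)
    return TrainResult(params, pd.DataFrame(rows), best_epoch, best_val)


def _below_tau(delta: float, tau: float) -> bool:
    # strict '<' with a guard so a delta exactly equal to tau (up to
    # float representation of decimals like 0.078 - 0.0779) does not stop
    return delta < tau and not np.isclose(delta, tau, rtol=1e-9, atol=1e-15)


def apply_depth_rule(val_losses, tau: float) -> tuple[int, int]:
    """Pure stopping rule on a sequence of per-depth validation losses.

    ``val_losses[b-1]`` is L_val at depth ``b``.  Deepening stops after
    the first depth whose improvement over the previous depth falls
    strictly below ``tau`` (improvements may be negative; an improvement
    of exactly ``tau`` continues).  ``b*`` is the best trained depth
    with a parsimony tie-break: the shallowest depth whose loss is
    within ``tau`` of the minimum over all depths considered.  Returns
    ``(stop_depth, b_star)``.
    """
    losses = list(val_losses)
    if not losses:
        raise ValueError("need at least one validation loss")
    stop = len(losses)
    for b in range(2, len(losses) + 1):
        if _below_tau(losses[b - 2] - losses[b - 1], tau):
            stop = b
            break
    considered = np.asarray(losses[:stop])
    thresh = considered.min() + tau
    within = np.flatnonzero(
        (considered <= thresh) | np.isclose(considered, thresh, rtol=1e-9, atol=1e-15)
    )
    return stop, int(within[0]) + 1


@dataclass
class DepthSearchResult:
    depths: list[int]
    val_losses: list[float]
    deltas: list[float]  # delta(b) = L_val(b-1) - L_val(b); NaN at b=1
    stop_depth: int
    b_star: int
    tau: float
    results: dict = field(default_factory=dict)  # depth -> TrainResult
    training_calls: list[int] = field(default_factory=list)  # audit: depths trained, in order

    def best_params(self) -> ParameterSet:
        return self.results[self.b_star].params

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"blocks": self.depths, "val_loss": self.val_losses, "delta": self.deltas}
        )


def depth_search(
    base_plan: ModelPlan,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    tau: float = 1e-4,
    max_blocks: int = 6,
    spectrum=None,
) -> DepthSearchResult:
    """Incrementally deepen the model, stopping by the ``tau`` rule.

    Every candidate depth trains from scratch with the same
    ``TrainConfig`` (identical seed) and the same head count; when a
    ``spectrum`` is given each candidate is eigen-initialized.
    ``L_val(b)`` is the best validation MSE over that depth's epochs.
    """
    if max_blocks < 1:
        raise ValueError("max_blocks must be >= 1")
    from dataclasses import replace

    depths, losses, results, calls = [], [], {}, []
    for b in range(1, max_blocks + 1):
        plan = replace(base_plan, blocks=b)
        rng = np.random.default_rng(config.seed)
        params = (
            eigen_initialize(spectrum, plan, rng)
            if spectrum is not None
            else glorot_initialize(plan, rng)
        )
        calls.append(b)
        res = train(plan, params, X_train, y_train, X_val, y_val, config)
        depths.append(b)
        losses.append(res.best_val_loss)
        results[b] = res
        if b >= 2 and _below_tau(losses[-2] - losses[-1], tau):
            break
    stop_depth, b_star = apply_depth_rule(losses, tau)
    deltas = [float("nan")] + [losses[i - 1] - losses[i] for i in range(1, len(losses))]
    return DepthSearchResult(depths, losses, deltas, stop_depth, b_star, tau, results, calls)


def multi_seed_protocol(fit_fn, seeds=PROTOCOL_SEEDS) -> pd.DataFrame:
    """Run ``fit_fn(seed) -> dict of metrics`` across seeds and aggregate.

    Returns a DataFrame with one row per seed plus ``mean`` and ``std``
    rows; the spread uses the sample (n-1) standard deviation.  Fewer
    than two seeds is an error (no spread is defined).
    """
    seeds = tuple(seeds)
    if len(seeds) < 2:
        raise ValueError("multi-seed protocol needs at least 2 seeds")
    rows = []
    for seed in seeds:
        metrics = fit_fn(seed)
        rows.append({"seed": seed, **metrics})
    frame = pd.DataFrame(rows).set_index("seed")
    numeric = frame.select_dtypes("number")
    agg = pd.DataFrame(
        [numeric.mean(), numeric.std(ddof=1)], index=pd.Index(["mean", "std"], name="seed")
    )
    return pd.concat([frame, agg])
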