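"""The eigen-guided transformer: architecture, initialization, forward pass.

The network is a standard post-norm encoder regressor — input
projection, ``b`` blocks of multi-head self-attention plus a ReLU
feed-forward sublayer, and a linear head on the pooled representation.
What is non-standard is how it is configured and initialized: the head
count comes from the correlation eigenspectrum, and at initialization
head ``i``'s query/key/value projections are tied and aligned with
eigenvector ``v_i`` scaled by ``lambda_i**-gamma``, so each head starts
out attending along one principal component of the training features.

Concretely, with positional encoding off and zero biases, head ``i``'s
pre-softmax attention score between steps ``t`` and ``s`` is exactly

    sqrt(d_k) * lambda_i**(-2*gamma) * <x_t, v_i> * <x_s, v_i>

which unit tests assert numerically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import Tensor, affine, layer_norm, matmul, relu, softmax_last
from .eigen import EigenSpectrum

__all__ = [
    "ModelPlan",
    "ParameterSet",
    "resolve_dimensions",
    "glorot_initialize",
    "eigen_initialize",
    "forward",
    "estimate_flops",
    "sinusoidal_encoding",
]


def resolve_dimensions(d: int, h: int, hidden_target: int) -> tuple[int, int]:
    """Smallest head-divisible embedding width at least ``hidden_target``.

    Returns ``(d_k, d_model)`` with ``d_k = ceil(hidden_target / h)`` and
    ``d_model = h * d_k``; e.g. 11 heads with a hidden target of 40
    resolve to ``d_k = 4``, ``d_model = 44``.
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    if hidden_target < h:
        raise ValueError("hidden_target must be >= h")
    d_k = -(-hidden_target // h)
    return d_k, h * d_k


@dataclass(frozen=True)
class ModelPlan:
    """Resolved architecture dimensions and run-time knobs."""

    d: int
    h: int
    d_k: int
    d_ff: int
    blocks: int
    dropout: float = 0.2
    gamma: float = 0.5
    positional_encoding: str = "sinusoidal"  # 'sinusoidal' | 'none'
    pooling: str = "last"  # 'last' | 'mean'

    def __post_init__(self):
        if self.blocks < 1:
            raise ValueError("blocks must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.gamma not in (0.5, 1.0):
            raise ValueError("gamma must be 0.5 (whitening) or 1.0 (literal 1/lambda)")
        if self.positional_encoding not in ("sinusoidal", "none"):
            raise ValueError("positional_encoding must be 'sinusoidal' or 'none'")
        if self.pooling not in ("last", "mean"):
            raise ValueError("pooling must be 'last' or 'mean'")

    @property
    def d_model(self) -> int:
        return self.h * self.d_k

    @classmethod
    def from_selection(
        cls,
        d: int,
        h: int,
        hidden_target: int = 40,
        d_ff: int | None = None,
        blocks: int = 1,
        **kwargs,
    ) -> "ModelPlan":
        d_k, d_model = resolve_dimensions(d, h, hidden_target)
        return cls(d=d, h=h, d_k=d_k, d_ff=d_ff if d_ff is not None else 2 * d_model,
                   blocks=blocks, **kwargs)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelPlan":
        return cls(**json.loads(s))


class ParameterSet:
    """All learnable tensors of one model, addressable by name.

    Per block: tied-at-init ``Wq``/``Wk``/``Wv`` stacked as
    (h, d_model, d_k), shared ``Wo`` (d_model, d_model), LayerNorm
    gains/biases, and the ReLU feed-forward pair.  Plus the input
    projection (d_model, d) and the scalar regression head.
    """

    def __init__(self, plan: ModelPlan, tensors: dict[str, Tensor]):
        self.plan = plan
        self.tensors = tensors

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def items(self):
        return self.tensors.items()

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.tensors.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if self.tensors[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for '{k}'")
            self.tensors[k].data[...] = v

    def save(self, path) -> None:
        np.savez(path, __plan__=np.frombuffer(self.plan.to_json().encode(), dtype=np.uint8),
                 **self.state())

    @classmethod
    def load(cls, path) -> "ParameterSet":
        with np.load(path) as z:
            plan = ModelPlan.from_json(bytes(z["__plan__"]).decode())
            state = {k: z[k] for k in z.files if k != "__plan__"}
        params = glorot_initialize(plan, np.random.default_rng(0))
        params.load_state(state)
        return params


def _glorot(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _shared_tensors(plan: ModelPlan, rng) -> dict[str, Tensor]:
    dm, dff = plan.d_model, plan.d_ff
    t = {
        "W_in": Tensor(_glorot(rng, plan.d, dm, (dm, plan.d)), True),
        "b_in": Tensor(np.zeros(dm), True),
        "W_out": Tensor(_glorot(rng, dm, 1, (1, dm)), True),
        "b_out": Tensor(np.zeros(1), True),
    }
    for b in range(plan.blocks):
        t[f"blk{b}.Wo"] = Tensor(_glorot(rng, dm, dm, (dm, dm)), True)
        t[f"blk{b}.W1"] = Tensor(_glorot(rng, dm, dff, (dm, dff)), True)
        t[f"blk{b}.b1"] = Tensor(np.zeros(dff), True)
        t[f"blk{b}.W2"] = Tensor(_glorot(rng, dff, dm, (dff, dm)), True)
        t[f"blk{b}.b2"] = Tensor(np.zeros(dm), True)
        for ln in ("ln1", "ln2"):
            t[f"blk{b}.{ln}_g"] = Tensor(np.ones(dm), True)
            t[f"blk{b}.{ln}_b"] = Tensor(np.zeros(dm), True)
    return t


def glorot_initialize(plan: ModelPlan, rng: np.random.Generator) -> ParameterSet:
    """Baseline initialization: Glorot-uniform everywhere (no eigen prior)."""
    t = _shared_tensors(plan, rng)
    for b in range(plan.blocks):
        for name in ("Wq", "Wk", "Wv"):
            t[f"blk{b}.{name}"] = Tensor(
                _glorot(rng, plan.d_model, plan.d_k, (plan.h, plan.d_model, plan.d_k)), True
            )
    return ParameterSet(plan, t)


def eigen_initialize(
    spectrum: EigenSpectrum,
    plan: ModelPlan,
    rng: np.random.Generator,
    first_block_only: bool = False,
) -> ParameterSet:
    """Seed attention from the correlation eigenspectrum.

    * ``W_in`` row ``r`` is eigenvector ``v_{(r mod h) + 1}`` (the top-h
      eigenvectors cycled down the embedding rows), ``b_in = 0``, so
      embedding coordinate ``r`` of step ``t`` holds the principal-
      component score ``<x_t, v_{(r mod h)+1}>``.
    * For head ``i``, ``Wq = Wk = Wv`` with column ``c`` equal to
      ``lambda_i**-gamma * e_{(i-1) + c*h}``: a scaled selector of that
      head's own coordinates, so every per-head channel starts as the
      whitened PC score ``lambda_i**-gamma * <x_t, v_i>``.
    * ``Wo``, the feed-forward pair and the output head stay
      Glorot-uniform; all biases start at zero.

    When ``h > spectrum.d`` the eigenvectors cycle.  A selected
    eigenvalue at or below 1e-12 is a hard error (the scaling would not
    be invertible).
    """
    params = glorot_initialize(plan, rng)
    d, h, d_k, dm = spectrum.d, plan.h, plan.d_k, plan.d_model
    if plan.d != d:
        raise ValueError("plan.d does not match the spectrum's feature count")
    lam = np.array([spectrum.eigenvalues[(i % d)] for i in range(h)])
    if np.any(lam <= 1e-12):
        raise ValueError("selected eigenvalue <= 1e-12; lower alpha or drop degenerate features")
    W_in = np.empty((dm, d))
    for r in range(dm):
        W_in[r] = spectrum.eigenvectors[:, (r % h) % d]
    params["W_in"].data[...] = W_in
    params["b_in"].data[...] = 0.0
    scale = lam ** (-plan.gamma)
    Wqkv = np.zeros((h, dm, d_k))
    for i in range(h):
        for c in range(d_k):
            Wqkv[i, i + c * h, c] = scale[i]
    blocks = range(1) if first_block_only else range(plan.blocks)
    for b in blocks:
        for name in ("Wq", "Wk", "Wv"):
            params[f"blk{b}.{name}"].data[...] = Wqkv
    return params


def sinusoidal_encoding(L: int, d_model: int) -> np.ndarray:
    """Standard fixed sinusoidal positional encoding, (L, d_model)."""
    pos = np.arange(L)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


def _dropout(x: Tensor, rate: float, train_mode: bool, rng) -> Tensor:
    if not train_mode or rate <= 0.0:
        return x
    mask = ((rng.random(x.shape) >= rate) / (1.0 - rate)).astype(x.data.dtype)
    return x * Tensor(mask)


def forward(
    x: np.ndarray,
    params: ParameterSet,
    plan: ModelPlan,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    collect_attention: bool = False,
):
    """Run the model on a batch.

    Parameters
    ----------
    x : (B, L, d) or (L, d) normalized input sequences.
    train_mode : enables dropout (requires ``rng``).
    collect_attention : also return per-block attention diagnostics,
        a list of dicts with ``weights`` and pre-softmax ``scores``
        arrays of shape (B, h, L, L).

    Returns
    -------
    yhat : Tensor of shape (B,) — differentiate through this.
    attention : list (only if ``collect_attention``).
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    B, L, d = x.shape
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    if d != plan.d:
        raise ValueError(f"input has {d} features, plan expects {plan.d}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")
    if train_mode and plan.dropout > 0 and rng is None:
        raise ValueError("train_mode with dropout requires an rng")

    dm, h, d_k = plan.d_model, plan.h, plan.d_k
    dtype = params["W_in"].data.dtype
    xt = Tensor(x.astype(dtype, copy=False))
    # flatten batch and time into one GEMM axis: small per-step matrices
    # are far cheaper as a single (B*L, .) product
    z2 = affine(xt.reshape(B * L, d), params["W_in"].transpose(1, 0), params["b_in"])
    if plan.positional_encoding == "sinusoidal":
        pe = sinusoidal_encoding(L, dm).astype(dtype)
        z2 = z2 + Tensor(np.tile(pe, (B, 1)))

    inv_sqrt_dk = 1.0 / np.sqrt(d_k)
    attention = []
    for b in range(plan.blocks):
        # stacked per-head projections as one (d_model, d_model) GEMM each
        Wq = params[f"blk{b}.Wq"].transpose(1, 0, 2).reshape(dm, h * d_k)
        Wk = params[f"blk{b}.Wk"].transpose(1, 0, 2).reshape(dm, h * d_k)
        Wv = params[f"blk{b}.Wv"].transpose(1, 0, 2).reshape(dm, h * d_k)
        q = affine(z2, Wq).reshape(B, L, h, d_k).transpose(0, 2, 1, 3)  # (B,h,L,d_k)
        k = affine(z2, Wk).reshape(B, L, h, d_k).transpose(0, 2, 1, 3)
        v = affine(z2, Wv).reshape(B, L, h, d_k).transpose(0, 2, 1, 3)
        scores = matmul(q, k.transpose(0, 1, 3, 2)) * inv_sqrt_dk
        weights = softmax_last(scores)
        heads = matmul(weights, v)  # (B, h, L, d_k)
        concat = heads.transpose(0, 2, 1, 3).reshape(B * L, dm)
        mh = affine(concat, params[f"blk{b}.Wo"])
        mh = _dropout(mh, plan.dropout, train_mode, rng)
        z2 = layer_norm(z2 + mh, params[f"blk{b}.ln1_g"], params[f"blk{b}.ln1_b"])
        ff = affine(relu(affine(z2, params[f"blk{b}.W1"], params[f"blk{b}.b1"])),
                    params[f"blk{b}.W2"], params[f"blk{b}.b2"])
        ff = _dropout(ff, plan.dropout, train_mode, rng)
        z2 = layer_norm(z2 + ff, params[f"blk{b}.ln2_g"], params[f"blk{b}.ln2_b"])
        if not np.isfinite(z2.data).all():
            raise FloatingPointError(f"NaN/inf activations in block {b}")
        if collect_attention:
            attention.append({"weights": weights.data.copy(), "scores": scores.data.copy()})

    z = z2.reshape(B, L, dm)
    pooled = z.take_last_step() if plan.pooling == "last" else z.mean(axis=1)
    yhat = (affine(pooled, params["W_out"].transpose(1, 0), params["b_out"])).reshape(B)
    if collect_attention:
        return yhat, attention
    return yhat


def estimate_flops(plan: ModelPlan, L: int) -> int:
    """Analytic forward-pass FLOPs (multiply-add counted as 2 FLOPs).

    Term by term, with ``dm = d_model``:

    * input projection  ``2 L dm d``
    * per block:
        - Q/K/V projections   ``3 * 2 L dm dm``  (h heads of width d_k,
          h*d_k = dm, so the per-head work sums to one dm x dm map each)
        - attention scores + weighted values  ``2 * 2 L^2 dm``
        - output projection   ``2 L dm dm``
        - feed-forward        ``2 * 2 L dm d_ff``
    * regression head  ``2 L dm``

    LayerNorm, softmax and bias adds are excluded.  Pure integer
    arithmetic — exactly reproducible.
    """
    return flops_formula(L, plan.d, plan.d_model, plan.d_ff, plan.blocks)


def flops_formula(L: int, d: int, d_model: int, d_ff: int, blocks: int) -> int:
    """Closed-form FLOPs count; ``blocks = 0`` leaves projection + head only."""
    dm = d_model
    per_block = 6 * L * dm * dm + 4 * L * L * dm + 2 * L * dm * dm + 4 * L * dm * d_ff
    return 2 * L * dm * d + blocks * per_block + 2 * L * dm
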