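"""Evaluation, ablation arithmetic, fairness and interpretability audits.

Metrics are reported on the z-score scale and in clinical units (the
two are related exactly by the target feature's training sigma).  The
fairness audit stratifies test-set errors by age band, sex and
ethnicity and summarises disparity as the worst-to-best subgroup MSE
ratio, pooling the three stratifications.  Interpretability extraction
exposes head-averaged temporal attention and the principal-component
loadings that seeded the attention heads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .eigen import EigenSpectrum
from .search import TrainConfig, depth_search, evaluate_mse, train
from .transformer import (
    ModelPlan,
    ParameterSet,
    eigen_initialize,
    estimate_flops,
    forward,
    glorot_initialize,
)

__all__ = [
    "MetricReport",
    "SubgroupTable",
    "compute_metrics",
    "percent_reduction",
    "subgroup_fairness",
    "disparity_ratio",
    "extract_attention",
    "pc_loadings",
    "run_ablation",
    "AGE_BINS",
]

AGE_BINS = ((None, 50), (50, 65), (65, 80), (80, None))
SMALL_SUBGROUP_N = 30


@dataclass(frozen=True)
class MetricReport:
    """MSE/MAE/RMSE on both the normalized and clinical scales."""

    n: int
    mse_norm: float
    mae_norm: float
    mse_clinical: float
    mae_clinical: float
    rmse_clinical: float

    @property
    def rmse_norm(self) -> float:
        return float(np.sqrt(self.mse_norm))


def compute_metrics(y: np.ndarray, yhat: np.ndarray, target_sigma: float = 1.0) -> MetricReport:
    """Squared and absolute errors; clinical units via sigma (and sigma^2)."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.size == 0:
        raise ValueError("no samples")
    if y.shape != yhat.shape or not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("y and yhat must be aligned finite vectors")
    mse = float(np.mean((y - yhat) ** 2))
    mae = float(np.mean(np.abs(y - yhat)))
    return MetricReport(
        n=y.size,
        mse_norm=mse,
        mae_norm=mae,
        mse_clinical=mse * target_sigma**2,
        mae_clinical=mae * target_sigma,
        rmse_clinical=float(np.sqrt(mse)) * target_sigma,
    )


def percent_reduction(baseline_value: float, improved_value: float) -> float:
    """Relative decrease in percent, ``100 (baseline - improved) / baseline``."""
    if baseline_value <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (baseline_value - improved_value) / baseline_value


def disparity_ratio(subgroup_mses) -> float:
    """Worst-to-best subgroup MSE ratio (>= 1; 1 iff all equal)."""
    vals = np.asarray([v for v in subgroup_mses if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no subgroup errors")
    if np.any(vals <= 0):
        return float("inf") if vals.max() > 0 else 1.0
    return float(vals.max() / vals.min())


def _age_label(lo, hi) -> str:
    if lo is None:
        return f"Age < {hi}"
    if hi is None:
        return f"Age > {lo}"
    return f"Age {lo}–{hi}"


@dataclass
class SubgroupTable:
    """Per-subgroup errors plus the pooled worst-to-best MSE ratio."""

    table: pd.DataFrame
    disparity_ratio: float


def subgroup_fairness(
    y: np.ndarray,
    yhat: np.ndarray,
    demographics: pd.DataFrame,
    age_bins=AGE_BINS,
) -> SubgroupTable:
    """Stratify test errors by age band, sex and ethnicity.

    The disparity ratio is max subgroup MSE / min subgroup MSE across
    all listed subgroups (the three stratifications pooled).  Empty
    subgroups are reported with ``n = 0`` and excluded from the ratio;
    subgroups below 30 samples are flagged as small.
    """
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if len(demographics) != len(y):
        raise ValueError("demographics rows must align with samples")
    ages = demographics["age"].to_numpy(dtype=float)
    rows = []

    def add_row(strat, label, sel):
        n = int(sel.sum())
        if n == 0:
            rows.append({"stratification": strat, "subgroup": label, "n": 0,
                         "mse": np.nan, "mae": np.nan, "small_subgroup": False})
            return
        m = compute_metrics(y[sel], yhat[sel])
        rows.append({"stratification": strat, "subgroup": label, "n": n,
                     "mse": m.mse_norm, "mae": m.mae_norm,
                     "small_subgroup": n < SMALL_SUBGROUP_N})

    # half-open partition: <50, [50, 65), [65, 80), >=80 — covers all ages exactly once
    edges = [b[1] for b in age_bins[:-1]]
    binned = np.digitize(ages, edges)
    for i, bounds in enumerate(age_bins):
        add_row("age", _age_label(*bounds), binned == i)
    for col in ("sex", "ethnicity"):
        values = demographics[col].astype(str).to_numpy()
        for g in sorted(pd.unique(values)):
            add_row(col, f"{col.capitalize()}: {g}", values == g)
    table = pd.DataFrame(rows)
    valid = table["mse"].dropna()
    ratio = disparity_ratio(valid) if len(valid) else float("nan")
    return SubgroupTable(table=table, disparity_ratio=ratio)


@dataclass
class AttentionSummary:
    heatmap: np.ndarray  # (L, L) head- and sample-averaged, final block
    last_query: np.ndarray  # (h, L) per-head weights at the last query step
    per_block_heatmaps: list  # one (L, L) array per block


def extract_attention(params: ParameterSet, plan: ModelPlan, X: np.ndarray) -> AttentionSummary:
    """Head-averaged temporal attention maps from an eval-mode pass."""
    _, attention = forward(X, params, plan, collect_attention=True)
    per_block = [a["weights"].mean(axis=(0, 1)) for a in attention]  # avg samples & heads
    final = attention[-1]["weights"]
    last_query = final[:, :, -1, :].mean(axis=0)  # (h, L), avg over samples
    return AttentionSummary(heatmap=per_block[-1], last_query=last_query,
                            per_block_heatmaps=per_block)


def pc_loadings(spectrum: EigenSpectrum, top_k: int) -> pd.DataFrame:
    """Feature x component loading table (columns are eigenvectors)."""
    if top_k > spectrum.d:
        raise ValueError("top_k exceeds the number of components")
    return pd.DataFrame(
        spectrum.eigenvectors[:, :top_k],
        index=list(spectrum.feature_names),
        columns=[f"PC{i + 1}" for i in range(top_k)],
    )


def run_ablation(
    prepare_fn,
    seeds,
    config: TrainConfig,
    hidden_target: int = 40,
    alpha: float = 0.95,
    tau: float = 1e-4,
    max_blocks: int = 6,
    baseline_heads: int = 8,
    baseline_blocks: int = 4,
    standard_blocks: int = 6,
    dropout: float = 0.2,
) -> pd.DataFrame:
    """Cumulative component-wise ablation of the eigen-guided design.

    ``prepare_fn(seed)`` must return a dict with arrays ``X_train``,
    ``y_train``, ``X_val``, ``y_val``, ``X_test``, ``y_test`` and an
    ``EigenSpectrum`` under ``spectrum`` (splits reshuffled per seed,
    spectrum re-derived from that seed's training split).  Five arms are
    trained per seed with a shared ``TrainConfig``:

    1. arbitrary-config baseline (``baseline_heads`` heads,
       ``baseline_blocks`` blocks, Glorot init);
    2. + eigenvalue-selected head count;
    3. + eigenvector initialization;
    4. + validation-driven depth (the depth search runs once, on the
       first seed, and its ``b*`` is trained under every seed);
    5. the standard-config reference (``baseline_heads`` heads,
       ``standard_blocks`` blocks).

    Returns one row per arm with test-MSE mean +- sample std across
    seeds and the analytic FLOPs of that arm's architecture.
    """
    from .eigen import select_heads

    seeds = tuple(seeds)
    arm_results: dict[str, list[float]] = {}
    arm_meta: dict[str, dict] = {}
    b_star = None
    for seed in seeds:
        data = prepare_fn(seed)
        spectrum = data["spectrum"]
        d = data["X_train"].shape[-1]
        L = data["X_train"].shape[1]
        h_eigen = select_heads(spectrum.evr, alpha).h
        cfg = replace(config, seed=seed)
        arms = []
        plan_base = ModelPlan.from_selection(d, baseline_heads, hidden_target,
                                             blocks=baseline_blocks, dropout=dropout)
        arms.append(("baseline (arbitrary config)", plan_base, None))
        plan_heads = ModelPlan.from_selection(d, h_eigen, hidden_target,
                                              blocks=baseline_blocks, dropout=dropout)
        arms.append(("+ eigenvalue-guided heads", plan_heads, None))
        arms.append(("+ eigenvector initialization", plan_heads, spectrum))
        if b_star is None:  # depth search once, on the first seed's splits
            ds = depth_search(
                replace(plan_heads, blocks=1),
                data["X_train"], data["y_train"], data["X_val"], data["y_val"],
                cfg, tau=tau, max_blocks=max_blocks, spectrum=spectrum,
            )
            b_star = ds.b_star
        plan_depth = replace(plan_heads, blocks=b_star)
        arms.append(("+ depth optimization", plan_depth, spectrum))
        plan_std = replace(plan_base, blocks=standard_blocks)
        arms.append(("standard config reference", plan_std, None))

        for name, plan, spec_init in arms:
            rng = np.random.default_rng(seed)
            params = (
                eigen_initialize(spec_init, plan, rng)
                if spec_init is not None
                else glorot_initialize(plan, rng)
            )
            train(plan, params, data["X_train"], data["y_train"],
                  data["X_val"], data["y_val"], cfg)
            mse = evaluate_mse(params, plan, data["X_test"], data["y_test"])
            arm_results.setdefault(name, []).append(mse)
            arm_meta[name] = {"heads": plan.h, "blocks": plan.blocks,
                              "flops": estimate_flops(plan, L)}
    rows = []
    for name, mses in arm_results.items():
        rows.append(
            {
                "configuration": name,
                "heads": arm_meta[name]["heads"],
                "blocks": arm_meta[name]["blocks"],
                "mse_mean": float(np.mean(mses)),
                "mse_std": float(np.std(mses, ddof=1)) if len(mses) > 1 else float("nan"),
                "flops": arm_meta[name]["flops"],
                "mse": f"{np.mean(mses):.4f} ± {np.std(mses, ddof=1):.4f}"
                if len(mses) > 1
                else f"{np.mean(mses):.4f}",
            }
        )
    return pd.DataFrame(rows)
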