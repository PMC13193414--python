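"""Model/Results front-end tying the pipeline together.

``EigenGuidedTransformer`` is constructed from the raw long-format
event and demographics tables and owns the whole procedure: daily
aggregation and imputation, stratified patient splits, eigenspectrum
analysis of the training features, head selection, eigen
initialization, depth search and training.  ``fit`` returns an
``EigenGuidedResults`` carrying the fitted parameters together with
test metrics on both scales, MC-dropout uncertainty, calibration and
fairness audits, attention diagnostics and a ``summary()`` table.

    model = EigenGuidedTransformer.from_tables(events, demographics,
                                               target="creatinine")
    res = model.fit(seed=42, epochs=20)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import audit as audit_mod
from . import uq as uq_mod
from .cohort import CohortData, prepare_cohort
from .eigen import HeadSelection, correlation_matrix, eigendecompose, select_heads, sensitivity_sweep
from .search import (
    PROTOCOL_SEEDS,
    DepthSearchResult,
    TrainConfig,
    TrainResult,
    depth_search,
    multi_seed_protocol,
    predict,
    train,
)
from .transformer import ModelPlan, ParameterSet, eigen_initialize, estimate_flops, glorot_initialize

__all__ = ["EigenGuidedTransformer", "EigenGuidedResults"]


class EigenGuidedTransformer:
    """Eigen-guided transformer forecaster for daily clinical series.

    Parameters
    ----------
    events, demographics : long-format measurement table
        (patient_id, timestamp, variable, value) and per-patient
        (age, sex, ethnicity).
    target : feature whose future value is regressed.
    lookback, horizon : window length and forecast offset in days.
    alpha : cumulative explained-variance threshold for head selection.
    hidden_target : requested embedding width; rounded up to the next
        head-divisible value.
    gamma : eigen-scaling exponent (0.5 whitening, 1.0 literal
        ``1/lambda``).
    tau : depth-search stopping threshold on validation-loss gains.
    """

    def __init__(
        self,
        events: pd.DataFrame,
        demographics: pd.DataFrame | None = None,
        target: str = "creatinine",
        lookback: int = 7,
        horizon: int = 1,
        alpha: float = 0.95,
        hidden_target: int = 40,
        gamma: float = 0.5,
        dropout: float = 0.2,
        d_ff: int | None = None,
        tau: float = 1e-4,
        max_blocks: int = 6,
        positional_encoding: str = "sinusoidal",
        pooling: str = "last",
        policy: str = "mean",
        max_gap_days: int = 7,
        missing_threshold: float = 0.30,
        essential_features: list[str] | None = None,
        ratios: tuple[float, float, float] = (0.80, 0.10, 0.10),
    ):
        self.events = events
        self.demographics = demographics
        self.target = target
        self.lookback = lookback
        self.horizon = horizon
        self.alpha = alpha
        self.hidden_target = hidden_target
        self.gamma = gamma
        self.dropout = dropout
        self.d_ff = d_ff
        self.tau = tau
        self.max_blocks = max_blocks
        self.positional_encoding = positional_encoding
        self.pooling = pooling
        self._prep_kwargs = dict(
            target_feature=target,
            policy=policy,
            max_gap_days=max_gap_days,
            missing_threshold=missing_threshold,
            essential_features=essential_features,
            lookback=lookback,
            horizon=horizon,
            ratios=ratios,
        )
        self._cache: dict[int, dict] = {}

    @classmethod
    def from_tables(cls, events: pd.DataFrame, demographics: pd.DataFrame | None = None,
                    **kwargs) -> "EigenGuidedTransformer":
        """Build a model from long-format event and demographics tables."""
        return cls(events, demographics, **kwargs)

    # -- per-seed data and design --------------------------------------
    def prepare(self, seed: int) -> dict:
        """Cohort, arrays and eigen design for one split seed (cached).

        The patient split is reshuffled per seed and the eigenspectrum
        re-derived from that seed's training split.
        """
        if seed in self._cache:
            return self._cache[seed]
        cohort = prepare_cohort(self.events, self.demographics, seed=seed, **self._prep_kwargs)
        spectrum = eigendecompose(
            correlation_matrix(cohort.training_matrix, cohort.feature_names),
            cohort.feature_names,
        )
        selection = select_heads(spectrum.evr, self.alpha)
        plan = ModelPlan.from_selection(
            d=len(cohort.feature_names),
            h=selection.h,
            hidden_target=self.hidden_target,
            d_ff=self.d_ff,
            blocks=1,
            dropout=self.dropout,
            gamma=self.gamma,
            positional_encoding=self.positional_encoding,
            pooling=self.pooling,
        )
        out = {
            "cohort": cohort,
            "spectrum": spectrum,
            "selection": selection,
            "base_plan": plan,
        }
        for split in ("train", "val", "test"):
            X, y = cohort.arrays(split)
            out[f"X_{split}"], out[f"y_{split}"] = X, y
        self._cache[seed] = out
        return out

    def sensitivity(self, seed: int = 42, thresholds=(0.80, 0.85, 0.90, 0.95, 0.98)) -> pd.DataFrame:
        """Variance-threshold sweep of the head-selection rule."""
        data = self.prepare(seed)
        return sensitivity_sweep(data["cohort"].training_matrix, thresholds,
                                 data["cohort"].feature_names)

    # -- fitting -------------------------------------------------------
    def fit(
        self,
        seed: int = 42,
        depth: int | str = "search",
        epochs: int = 90,
        eigen_init: bool = True,
        config: TrainConfig | None = None,
    ) -> "EigenGuidedResults":
        """Train, optionally running the depth search first.

        ``depth='search'`` runs the incremental tau-rule search and
        keeps the argmin-depth model; an integer trains that depth
        directly.  ``eigen_init=False`` falls back to Glorot
        initialization everywhere (the ablation baseline).
        """
        data = self.prepare(seed)
        cfg = config if config is not None else TrainConfig(epochs=epochs, seed=seed)
        spectrum = data["spectrum"] if eigen_init else None
        depth_result: DepthSearchResult | None = None
        if depth == "search":
            depth_result = depth_search(
                data["base_plan"],
                data["X_train"], data["y_train"], data["X_val"], data["y_val"],
                cfg, tau=self.tau, max_blocks=self.max_blocks, spectrum=spectrum,
            )
            plan = replace(data["base_plan"], blocks=depth_result.b_star)
            train_result = depth_result.results[depth_result.b_star]
        else:
            plan = replace(data["base_plan"], blocks=int(depth))
            rng = np.random.default_rng(cfg.seed)
            params = (
                eigen_initialize(spectrum, plan, rng)
                if spectrum is not None
                else glorot_initialize(plan, rng)
            )
            train_result = train(plan, params, data["X_train"], data["y_train"],
                                 data["X_val"], data["y_val"], cfg)
        return EigenGuidedResults(
            model=self,
            seed=seed,
            config=cfg,
            plan=plan,
            params=train_result.params,
            train_result=train_result,
            depth_result=depth_result,
            cohort=data["cohort"],
            spectrum=data["spectrum"],
            selection=data["selection"],
        )

    def fit_protocol(
        self,
        seeds=PROTOCOL_SEEDS,
        depth: int | str = "search",
        epochs: int = 90,
        mc_passes: int = 0,
    ) -> pd.DataFrame:
        """Multi-seed statistical protocol: refit per seed, report mean +- std.

        Each seed reshuffles the patient-level split (keeping the
        80/10/10 ratio), re-derives the eigenspectrum, refits, and
        evaluates on that seed's test split; the aggregate rows use the
        sample standard deviation.
        """

        def fit_fn(seed):
            res = self.fit(seed=seed, depth=depth, epochs=epochs)
            out = {
                "heads": res.plan.h,
                "blocks": res.plan.blocks,
                "test_mse": res.mse,
                "test_mae": res.mae,
                "val_loss": res.train_result.best_val_loss,
            }
            if mc_passes >= 2:
                cal = res.calibration(T=mc_passes)
                cov90 = cal.loc[np.isclose(cal["expected_coverage"], 0.90), "observed_coverage"]
                out["coverage_90"] = float(cov90.iloc[0])
            return out

        return multi_seed_protocol(fit_fn, seeds)

    def ablation(self, seeds=PROTOCOL_SEEDS, epochs: int = 90, **kwargs) -> pd.DataFrame:
        """Component-wise ablation table (see :func:`eigenformer.audit.run_ablation`)."""

        def prep(seed):
            return self.prepare(seed)

        cfg = TrainConfig(epochs=epochs)
        return audit_mod.run_ablation(
            prep, seeds, cfg,
            hidden_target=self.hidden_target, alpha=self.alpha,
            tau=self.tau, max_blocks=self.max_blocks, dropout=self.dropout,
            **kwargs,
        )


@dataclass
class EigenGuidedResults:
    """Fitted model with its diagnostics and audits."""

    model: EigenGuidedTransformer
    seed: int
    config: TrainConfig
    plan: ModelPlan
    params: ParameterSet
    train_result: TrainResult
    depth_result: DepthSearchResult | None
    cohort: CohortData
    spectrum: object
    selection: HeadSelection
    _pred_cache: dict = field(default_factory=dict)

    # -- predictions and metrics --------------------------------------
    def predict(self, split: str = "test") -> np.ndarray:
        if split not in self._pred_cache:
            X, _ = self.cohort.arrays(split)
            self._pred_cache[split] = predict(self.params, self.plan, X)
        return self._pred_cache[split]

    def metrics(self, split: str = "test") -> audit_mod.MetricReport:
        _, y = self.cohort.arrays(split)
        sigma = self.cohort.stats.sigma_of(self.cohort.target_feature)
        return audit_mod.compute_metrics(y, self.predict(split), sigma)

    @property
    def mse(self) -> float:
        return self.metrics().mse_norm

    @property
    def mae(self) -> float:
        return self.metrics().mae_norm

    @property
    def flops(self) -> int:
        return estimate_flops(self.plan, self.cohort.lookback)

    @property
    def n_parameters(self) -> int:
        return int(sum(t.data.size for _, t in self.params.items()))

    @property
    def history(self) -> pd.DataFrame:
        return self.train_result.history

    # -- uncertainty ----------------------------------------------------
    def mc_dropout(self, split: str = "test", T: int = 50, seed: int | None = None):
        X, _ = self.cohort.arrays(split)
        return uq_mod.mc_dropout_predict(
            self.params, self.plan, X, T=T,
            seed=self.seed if seed is None else seed,
        )

    def calibration(self, split: str = "test", T: int = 50,
                    levels=uq_mod.DEFAULT_LEVELS, seed: int | None = None) -> pd.DataFrame:
        dist = self.mc_dropout(split, T=T, seed=seed)
        _, y = self.cohort.arrays(split)
        sigma = self.cohort.stats.sigma_of(self.cohort.target_feature)
        return uq_mod.calibration_table(dist, y, levels=levels, target_sigma=sigma)

    # -- audits ---------------------------------------------------------
    def fairness(self, split: str = "test") -> audit_mod.SubgroupTable:
        _, y = self.cohort.arrays(split)
        demo = self.cohort.demographics_frame(split)
        if "age" not in demo.columns:
            raise ValueError("no demographics attached to this cohort")
        return audit_mod.subgroup_fairness(y, self.predict(split), demo)

    def attention(self, split: str = "test", max_samples: int = 256):
        X, _ = self.cohort.arrays(split)
        return audit_mod.extract_attention(self.params, self.plan, X[:max_samples])

    def pc_loadings(self, top_k: int | None = None) -> pd.DataFrame:
        return audit_mod.pc_loadings(self.spectrum, top_k or self.plan.h)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        m = self.metrics()
        sigma = self.cohort.stats.sigma_of(self.cohort.target_feature)
        lines = [
            "Eigen-Guided Transformer Results",
            "=" * 54,
            f"{'Target feature:':<30}{self.cohort.target_feature}",
            f"{'Lookback / horizon (days):':<30}{self.cohort.lookback} / {self.cohort.horizon}",
            f"{'Features (d):':<30}{len(self.cohort.feature_names)}",
            f"{'Patients (train/val/test):':<30}"
            + "/".join(str(len(self.cohort.splits[s])) for s in ("train", "val", "test")),
            f"{'Sequences (train/val/test):':<30}"
            + "/".join(str(len(self.cohort.samples[s])) for s in ("train", "val", "test")),
            "-" * 54,
            f"{'Variance threshold alpha:':<30}{self.selection.alpha:.2f}",
            f"{'Attention heads h:':<30}{self.plan.h}  (EVR at h: {self.selection.evr_at_h:.3f})",
            f"{'Blocks b*:':<30}{self.plan.blocks}"
            + (f"  (stopped at {self.depth_result.stop_depth})" if self.depth_result else ""),
            f"{'d_model / d_k / d_ff:':<30}"
            f"{self.plan.d_model} / {self.plan.d_k} / {self.plan.d_ff}",
            f"{'Parameters:':<30}{self.n_parameters:,}",
            f"{'Forward FLOPs (M):':<30}{self.flops / 1e6:.2f}",
            "-" * 54,
            f"{'Test MSE (normalized):':<30}{m.mse_norm:.4f}",
            f"{'Test MAE (normalized):':<30}{m.mae_norm:.4f}",
            f"{'Test MSE (clinical units^2):':<30}{m.mse_clinical:.4f}",
            f"{'Test MAE (clinical units):':<30}{m.mae_clinical:.4f}",
            f"{'Target sigma (clinical):':<30}{sigma:.4f}",
            f"{'Best epoch / val loss:':<30}"
            f"{self.train_result.best_epoch} / {self.train_result.best_val_loss:.4f}",
            "=" * 54,
        ]
        return "\n".join(lines)
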