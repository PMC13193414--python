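"""Cohort construction: irregular clinical events -> model-ready sequences.

The pipeline mirrors how longitudinal EHR laboratory data are prepared
for forecasting: measurements are aggregated to a daily grid per
patient, missing days are filled by a three-stage causal scheme
(short internal gaps linearly interpolated, longer and trailing gaps
carried forward, heavily missing patients dropped), features are
z-scored with statistics frozen on the training split, and
(lookback, horizon) windows are cut with a strict no-look-ahead
guarantee.

Every imputed cell records the latest observation day it depends on
(``dep_day``); a window anchored at day ``t`` is only emitted when no
lookback cell depends on data after ``t``, so deleting all data after
the anchor can never change the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PROV_OBSERVED",
    "PROV_LOCF",
    "PROV_INTERP",
    "PROV_MISSING",
    "DailyPatientSeries",
    "NormStats",
    "RetentionReport",
    "SequenceSample",
    "aggregate_daily",
    "impute_three_stage",
    "impute_cohort",
    "zscore_normalize",
    "split_patients",
    "target_strata",
    "build_sequences",
    "prepare_cohort",
    "CohortData",
]

PROV_OBSERVED, PROV_LOCF, PROV_INTERP, PROV_MISSING = 0, 1, 2, 3
_PROV_LABELS = {0: "observed", 1: "locf", 2: "interp", 3: "missing"}


@dataclass
class DailyPatientSeries:
    """One patient's measurements on a contiguous daily grid.

    ``X`` is day x feature with NaN where no value is available;
    ``mask`` flags cells observed before imputation; ``provenance``
    holds the per-cell fill codes; ``dep_day`` is the largest day index
    whose observation the cell's value depends on (-1 for missing).
    """

    patient_id: object
    start: pd.Timestamp
    feature_names: tuple[str, ...]
    X: np.ndarray
    mask: np.ndarray
    provenance: np.ndarray
    dep_day: np.ndarray

    @property
    def n_days(self) -> int:
        return self.X.shape[0]

    def provenance_labels(self) -> np.ndarray:
        return np.vectorize(_PROV_LABELS.get)(self.provenance)


@dataclass(frozen=True)
class NormStats:
    """Per-feature z-score statistics, fit on the training split only."""

    mean: np.ndarray
    std: np.ndarray
    feature_names: tuple[str, ...]

    @classmethod
    def fit(cls, series_list: list[DailyPatientSeries]) -> "NormStats":
        names = series_list[0].feature_names
        stacked = np.vstack([s.X for s in series_list])
        mean = np.nanmean(stacked, axis=0)
        std = np.nanstd(stacked, axis=0, ddof=1)
        return cls(mean, std, tuple(names))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return zscore_normalize(X, self)

    def inverse(self, X_norm: np.ndarray) -> np.ndarray:
        return np.asarray(X_norm) * self.std + self.mean

    def sigma_of(self, feature: str) -> float:
        return float(self.std[self.feature_names.index(feature)])

    def mean_of(self, feature: str) -> float:
        return float(self.mean[self.feature_names.index(feature)])

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
        }


@dataclass
class RetentionReport:
    """Accounting of the imputation stages and patient retention."""

    n_input: int = 0
    n_retained: int = 0
    cells_observed: int = 0
    cells_locf: int = 0
    cells_interp: int = 0
    cells_missing: int = 0
    excluded: list = field(default_factory=list)  # (patient_id, feature, missing_frac)

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "retained_fraction": self.retained_fraction,
            "cells": {
                "observed": self.cells_observed,
                "locf": self.cells_locf,
                "interp": self.cells_interp,
                "missing": self.cells_missing,
            },
            "excluded": [
                {"patient_id": p, "feature": f, "missing_fraction": m} for p, f, m in self.excluded
            ],
        }


@dataclass
class SequenceSample:
    """One (lookback window, future target) regression example."""

    x: np.ndarray  # L x d, normalized
    y: float  # normalized future target value
    patient_id: object
    anchor_day: int
    horizon: int
    demographics: dict | None = None


def aggregate_daily(events: pd.DataFrame, policy: str = "mean") -> list[DailyPatientSeries]:
    """Collapse timestamped events to one value per (patient, day, feature).

    ``policy='mean'`` averages a day's measurements; ``policy='last'``
    keeps the latest by timestamp.  Non-finite values are dropped with a
    warning; unparseable timestamps raise.
    """
    if policy not in ("mean", "last"):
        raise ValueError("policy must be 'mean' or 'last'")
    required = {"patient_id", "timestamp", "variable", "value"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"], errors="raise")
    ev["value"] = pd.to_numeric(ev["value"], errors="coerce")
    bad = ~np.isfinite(ev["value"].to_numpy(dtype=float))
    if bad.any():
        logger.warning("dropping %d event rows with non-finite values", int(bad.sum()))
        ev = ev.loc[~bad]
    # ingest de-duplication: a repeated (patient, timestamp, variable) keeps the last row
    ev = ev.drop_duplicates(subset=["patient_id", "timestamp", "variable"], keep="last")
    feature_names = tuple(sorted(ev["variable"].unique()))
    fidx = {f: i for i, f in enumerate(feature_names)}
    ev["date"] = ev["timestamp"].dt.normalize()

    out: list[DailyPatientSeries] = []
    for pid, grp in ev.groupby("patient_id", sort=True):
        start = grp["date"].min()
        n_days = int((grp["date"].max() - start).days) + 1
        d = len(feature_names)
        X = np.full((n_days, d), np.nan)
        mask = np.zeros((n_days, d), dtype=bool)
        if policy == "mean":
            agg = grp.groupby(["date", "variable"])["value"].mean()
        else:
            agg = grp.sort_values("timestamp").groupby(["date", "variable"])["value"].last()
        for (date, var), val in agg.items():
            day = int((date - start).days)
            X[day, fidx[var]] = val
            mask[day, fidx[var]] = True
        provenance = np.where(mask, PROV_OBSERVED, PROV_MISSING).astype(np.int8)
        dep = np.where(mask, np.arange(n_days)[:, None], -1)
        out.append(DailyPatientSeries(pid, start, feature_names, X, mask, provenance, dep))
    return out


def _impute_column(x, observed_days, max_gap_days):
    """Fill one feature column in place; returns (provenance, dep_day) columns."""
    n = len(x)
    prov = np.full(n, PROV_MISSING, dtype=np.int8)
    dep = np.full(n, -1, dtype=np.int64)
    if observed_days.size == 0:
        return prov, dep
    prov[observed_days] = PROV_OBSERVED
    dep[observed_days] = observed_days
    for left, right in zip(observed_days[:-1], observed_days[1:]):
        gap = right - left - 1
        if gap == 0:
            continue
        days = np.arange(left + 1, right)
        if gap <= max_gap_days:
            frac = (days - left) / (right - left)
            x[days] = x[left] + frac * (x[right] - x[left])
            prov[days] = PROV_INTERP
            dep[days] = right  # interpolated values depend on the right endpoint
        else:
            x[days] = x[left]
            prov[days] = PROV_LOCF
            dep[days] = left
    last = observed_days[-1]
    if last < n - 1:
        x[last + 1 :] = x[last]
        prov[last + 1 :] = PROV_LOCF
        dep[last + 1 :] = last
    return prov, dep


def impute_three_stage(
    series: DailyPatientSeries,
    max_gap_days: int = 7,
    missing_threshold: float = 0.30,
    essential_features: list[str] | None = None,
) -> tuple[DailyPatientSeries | None, list]:
    """Three-stage causal imputation of one patient's daily grid.

    Internal gaps of at most ``max_gap_days`` missing days between two
    observations are linearly interpolated; longer internal gaps and
    trailing gaps are carried forward; days before a feature's first
    observation stay missing and count toward its missingness.  If any
    essential feature is still missing on more than ``missing_threshold``
    of the patient's window the patient is excluded (``None`` returned).
    Second return value lists ``(patient_id, feature, missing_frac)``
    for the violated rules.
    """
    X = series.X.copy()
    prov = np.empty_like(series.provenance)
    dep = np.empty_like(series.dep_day)
    for j in range(X.shape[1]):
        observed = np.flatnonzero(series.mask[:, j])
        prov[:, j], dep[:, j] = _impute_column(X[:, j], observed, max_gap_days)
    essential = (
        tuple(essential_features) if essential_features is not None else series.feature_names
    )
    violations = []
    for f in essential:
        j = series.feature_names.index(f)
        frac = float((prov[:, j] == PROV_MISSING).mean())
        if frac > missing_threshold:
            violations.append((series.patient_id, f, frac))
    if violations:
        return None, violations
    return replace(series, X=X, provenance=prov, dep_day=dep), []


def impute_cohort(
    series_list: list[DailyPatientSeries],
    max_gap_days: int = 7,
    missing_threshold: float = 0.30,
    essential_features: list[str] | None = None,
) -> tuple[list[DailyPatientSeries], RetentionReport]:
    """Apply :func:`impute_three_stage` across a cohort with accounting."""
    report = RetentionReport(n_input=len(series_list))
    retained = []
    for s in series_list:
        imputed, violations = impute_three_stage(
            s, max_gap_days, missing_threshold, essential_features
        )
        if imputed is None:
            report.excluded.extend(violations)
            continue
        retained.append(imputed)
        report.cells_observed += int((imputed.provenance == PROV_OBSERVED).sum())
        report.cells_locf += int((imputed.provenance == PROV_LOCF).sum())
        report.cells_interp += int((imputed.provenance == PROV_INTERP).sum())
        report.cells_missing += int((imputed.provenance == PROV_MISSING).sum())
    report.n_retained = len(retained)
    return retained, report


def zscore_normalize(X: np.ndarray, stats: NormStats) -> np.ndarray:
    """(X - mu) / sigma per feature, with training-split statistics."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[-1] != len(stats.feature_names):
        raise ValueError("feature count does not match NormStats")
    if np.any(stats.std <= 0) or not np.isfinite(stats.std).all():
        bad = [
            stats.feature_names[i]
            for i in np.flatnonzero(~(np.asarray(stats.std) > 0) | ~np.isfinite(stats.std))
        ]
        raise ValueError(f"non-positive/undefined sigma for feature(s) {bad}; exclude upstream")
    return (X - stats.mean) / stats.std


def target_strata(series_list: list[DailyPatientSeries], target_feature: str, n_bins: int = 4):
    """Quartile-bin labels of each patient's mean target value.

    Used to stratify the patient-level split so the target distribution
    is balanced across train/validation/test.
    """
    j = series_list[0].feature_names.index(target_feature)
    means = pd.Series(
        {s.patient_id: np.nanmean(s.X[:, j]) for s in series_list}, dtype=float
    )
    labels = pd.qcut(means, q=n_bins, labels=False, duplicates="drop")
    return {pid: int(lbl) for pid, lbl in labels.items()}


def split_patients(
    patient_ids,
    ratios: tuple[float, float, float] = (0.80, 0.10, 0.10),
    seed: int = 0,
    stratify_by: dict | None = None,
) -> tuple[list, list, list]:
    """Disjoint patient-level train/validation/test split.

    Within each stratum the split sizes follow ``ratios`` by largest-
    remainder rounding; strata with fewer than 3 patients fall back to a
    pooled unstratified assignment (logged).  Deterministic in ``seed``.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        groups = {0: ids}
    else:
        groups = {}
        for pid in ids:
            groups.setdefault(stratify_by[pid], []).append(pid)
        small = [k for k, v in groups.items() if len(v) < 3]
        if small:
            logger.info("strata %s have < 3 patients; pooled unstratified", small)
            pooled = [pid for k in small for pid in groups.pop(k)]
            groups["_pooled"] = pooled
    train, val, test = [], [], []
    for key in sorted(groups, key=str):
        members = sorted(groups[key], key=str)
        rng.shuffle(members)
        n = len(members)
        counts = [int(np.floor(r * n)) for r in ratios]
        remainder = n - sum(counts)
        # distribute leftovers by largest fractional part, ties to earlier sets
        fracs = sorted(
            range(3), key=lambda i: (-(ratios[i] * n - np.floor(ratios[i] * n)), i)
        )
        for i in range(remainder):
            counts[fracs[i % 3]] += 1
        train.extend(members[: counts[0]])
        val.extend(members[counts[0] : counts[0] + counts[1]])
        test.extend(members[counts[0] + counts[1] :])
    return sorted(train, key=str), sorted(val, key=str), sorted(test, key=str)


def build_sequences(
    series_list: list[DailyPatientSeries],
    lookback: int,
    horizon: int,
    target_feature: str,
    stats: NormStats,
    demographics: pd.DataFrame | None = None,
    enforce_causal: bool = True,
) -> list[SequenceSample]:
    """Cut normalized (lookback, horizon) windows from imputed series.

    A window anchored at day ``t`` covers days ``t-L+1 .. t`` and its
    target is the (normalized) target feature at ``t + horizon``.
    Windows are dropped when the target is missing at the horizon day,
    when any lookback cell is missing, or (``enforce_causal``) when an
    interpolated lookback cell depends on an observation after ``t``.
    """
    if lookback <= 0 or horizon < 1:
        raise ValueError("lookback must be positive and horizon >= 1")
    demo_map = {}
    if demographics is not None:
        demo_map = {
            row["patient_id"]: {
                "age": row["age"],
                "sex": row["sex"],
                "ethnicity": row["ethnicity"],
            }
            for _, row in demographics.iterrows()
        }
    samples: list[SequenceSample] = []
    for s in series_list:
        j = s.feature_names.index(target_feature)
        Xn = zscore_normalize(s.X, stats)
        T = s.n_days
        for t in range(lookback - 1, T - horizon):
            if s.provenance[t + horizon, j] == PROV_MISSING:
                continue
            window = slice(t - lookback + 1, t + 1)
            if (s.provenance[window] == PROV_MISSING).any():
                continue
            if enforce_causal and s.dep_day[window].max() > t:
                continue
            samples.append(
                SequenceSample(
                    x=Xn[window].copy(),
                    y=float(Xn[t + horizon, j]),
                    patient_id=s.patient_id,
                    anchor_day=t,
                    horizon=horizon,
                    demographics=demo_map.get(s.patient_id),
                )
            )
    return samples


@dataclass
class CohortData:
    """Everything downstream modules need, split and normalized."""

    feature_names: tuple[str, ...]
    target_feature: str
    lookback: int
    horizon: int
    stats: NormStats
    splits: dict  # split name -> list of patient ids
    samples: dict  # split name -> list of SequenceSample
    training_matrix: np.ndarray  # fully-imputed normalized daily rows, training patients
    retention: RetentionReport

    def arrays(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        ss = self.samples[split]
        if not ss:
            raise ValueError(f"split '{split}' has no samples")
        return np.stack([s.x for s in ss]), np.array([s.y for s in ss])

    def demographics_frame(self, split: str) -> pd.DataFrame:
        rows = []
        for s in self.samples[split]:
            rec = {"patient_id": s.patient_id, "anchor_day": s.anchor_day}
            rec.update(s.demographics or {})
            rows.append(rec)
        return pd.DataFrame(rows)


def prepare_cohort(
    events: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    target_feature: str = "creatinine",
    policy: str = "mean",
    max_gap_days: int = 7,
    missing_threshold: float = 0.30,
    essential_features: list[str] | None = None,
    lookback: int = 7,
    horizon: int = 1,
    ratios: tuple[float, float, float] = (0.80, 0.10, 0.10),
    seed: int = 0,
) -> CohortData:
    """Full preparation pipeline from an event table to model-ready data.

    Aggregate daily -> impute -> stratified patient split -> fit
    normalization on the training split -> window all three splits.
    Constant features (zero training-split variance) are dropped with a
    log message before normalization.
    """
    series = aggregate_daily(events, policy=policy)
    if target_feature not in series[0].feature_names:
        raise ValueError(f"target feature '{target_feature}' not present in events")
    imputed, retention = impute_cohort(
        series, max_gap_days, missing_threshold, essential_features
    )
    if not imputed:
        raise ValueError("no patients retained after imputation")
    strata = target_strata(imputed, target_feature)
    train_ids, val_ids, test_ids = split_patients(
        [s.patient_id for s in imputed], ratios=ratios, seed=seed, stratify_by=strata
    )
    by_id = {s.patient_id: s for s in imputed}

    def fit_stats(series):
        # statistics over fully-imputed training rows: the exact matrix
        # the correlation analysis consumes is then mean-0 / sd-1
        rows = np.vstack([s.X for s in series])
        rows = rows[~np.isnan(rows).any(axis=1)]
        return rows, NormStats(
            rows.mean(axis=0), rows.std(axis=0, ddof=1), series[0].feature_names
        )

    train_series = [by_id[p] for p in train_ids]
    rows, stats = fit_stats(train_series)
    keep = np.flatnonzero(np.asarray(stats.std) > 0)
    if len(keep) < len(stats.feature_names):
        dropped = [stats.feature_names[i] for i in range(len(stats.std)) if i not in keep]
        logger.warning("dropping constant feature(s) %s", dropped)
        if target_feature in dropped:
            raise ValueError("target feature is constant on the training split")
        imputed = [_drop_features(s, keep) for s in imputed]
        by_id = {s.patient_id: s for s in imputed}
        train_series = [by_id[p] for p in train_ids]
        rows, stats = fit_stats(train_series)
    training_matrix = zscore_normalize(rows, stats)

    samples = {}
    for name, pids in (("train", train_ids), ("val", val_ids), ("test", test_ids)):
        samples[name] = build_sequences(
            [by_id[p] for p in pids], lookback, horizon, target_feature, stats, demographics
        )
    return CohortData(
        feature_names=stats.feature_names,
        target_feature=target_feature,
        lookback=lookback,
        horizon=horizon,
        stats=stats,
        splits={"train": train_ids, "val": val_ids, "test": test_ids},
        samples=samples,
        training_matrix=training_matrix,
        retention=retention,
    )


def _drop_features(s: DailyPatientSeries, keep: np.ndarray) -> DailyPatientSeries:
    return replace(
        s,
        feature_names=tuple(s.feature_names[i] for i in keep),
        X=s.X[:, keep],
        mask=s.mask[:, keep],
        provenance=s.provenance[:, keep],
        dep_day=s.dep_day[:, keep],
    )
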