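"""Synthetic longitudinal lab cohorts with a controllable eigenspectrum.

A latent-factor model generates every cohort: each patient carries k
AR(1) latent processes (unit stationary variance), and the d observed
features are linear factor readouts plus white noise, scaled to
clinical-looking units.  Choosing factor loadings with equal row norms
makes the population feature correlation matrix exactly
``L L^T + psi I`` on the unit scale, so its eigenvalues — the quantity
the head-selection rule consumes — are known in closed form and can be
compared against the empirical spectrum.

Events are emitted at irregular within-day times and thinned by
per-feature Bernoulli missingness; demographics are independent of the
disease process except in the fairness regime, where one subgroup's
target noise is inflated so a disparity audit has a known ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

from .eigen import EigenSpectrum, eigendecompose

__all__ = ["CohortSpec", "GeneratedCohort", "generate_cohort", "make_fixture", "FIXTURES"]

_LAB_NAMES = (
    "creatinine",
    "egfr",
    "bun",
    "potassium",
    "sodium",
    "calcium",
    "phosphate",
    "albumin",
    "chloride",
    "bicarbonate",
)
# plausible clinical location/scale per lab, target first
_LAB_UNITS = {
    "creatinine": (1.6, 0.9),
    "egfr": (55.0, 20.0),
    "bun": (28.0, 12.0),
    "potassium": (4.4, 0.5),
    "sodium": (139.0, 3.5),
    "calcium": (9.2, 0.6),
    "phosphate": (3.9, 0.9),
    "albumin": (3.8, 0.5),
    "chloride": (103.0, 4.0),
    "bicarbonate": (24.0, 3.0),
}

_SEXES = ("M", "F")
_SEX_P = (0.43, 0.57)
_ETHNICITIES = ("White", "Black", "Hispanic", "Asian", "Other")
_ETH_P = (0.56, 0.18, 0.12, 0.03, 0.11)


@dataclass
class CohortSpec:
    """Generator configuration; defaults are the study conditions.

    ``factor_strengths`` shape the population correlation eigenspectrum:
    with equal-row-norm loadings the top-k population eigenvalues are
    ``s_j + psi`` and the remaining ``d - k`` equal ``psi``, where
    ``psi = noise_sd**2`` is the idiosyncratic feature noise variance.
    """

    n_patients: int = 1000
    days_range: tuple[int, int] = (14, 28)  # ICU-scale stays of 2-4 weeks
    n_features: int = 8
    factor_strengths: tuple[float, ...] = (4.0, 2.0, 1.2)
    ar_coef: float = 0.85
    noise_sd: float | None = None  # default: sqrt(1 - sum(strengths)/d), unit variance
    missing_rates: float | tuple[float, ...] = 0.08
    horizon: int = 1
    # 'linear': target feature is its factor readout.
    # 'interaction': adds a latent product term a1*a2.
    # 'relu-memory': adds a sign-alternating sum of relu(a1) over the
    #   trailing week.
    # 'lagged-linear': the target feature becomes a signed sum of
    #   distinct (factor, lag) terms.  Each attention head contributes
    #   roughly one separable lag-profile x direction term per block, so
    #   with few planted factors (small selected h) a single block
    #   cannot span all terms while two blocks can — the regime the
    #   depth search is meant to recover.
    target_mode: str = "linear"
    interaction_strength: float = 0.0
    memory_window: int = 7
    lag_terms: tuple = ((0, 0, 1.0), (1, 2, 1.0), (0, 4, -1.0), (1, 6, 1.0))
    demographic_mix: dict = field(
        default_factory=lambda: {
            "sex": dict(zip(_SEXES, _SEX_P)),
            "ethnicity": dict(zip(_ETHNICITIES, _ETH_P)),
            "age_range": (25, 92),
        }
    )
    target_noise_multiplier: dict | None = None  # e.g. {"sex": {"F": 2.0}}
    seed: int = 0

    def __post_init__(self):
        k, d = len(self.factor_strengths), self.n_features
        if k > d:
            raise ValueError("more factors than features")
        if any(s <= 0 for s in self.factor_strengths):
            raise ValueError("factor strengths must be positive")
        if self.noise_sd is None:
            resid = 1.0 - sum(self.factor_strengths) / d
            if resid <= 0:
                raise ValueError("factor strengths exceed total unit variance; lower them")
            self.noise_sd = float(np.sqrt(resid))
        rates = self.missing_rates
        rates = (rates,) * d if np.isscalar(rates) else tuple(rates)
        if len(rates) != d or any(not 0 <= r < 1 for r in rates):
            raise ValueError("missing rates must be d values in [0, 1)")
        self.missing_rates = rates
        if not 0 <= self.ar_coef < 1:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        modes = ("linear", "interaction", "relu-memory", "lagged-linear")
        if self.target_mode not in modes:
            raise ValueError(f"target_mode must be one of {modes}")
        if self.target_mode == "lagged-linear" and any(f >= self.k for f, _, _ in self.lag_terms):
            raise ValueError("lag_terms reference a factor beyond k")

    # -- closed-form population quantities -----------------------------
    @property
    def k(self) -> int:
        return len(self.factor_strengths)

    @property
    def feature_names(self) -> tuple[str, ...]:
        base = _LAB_NAMES[: self.n_features]
        extra = tuple(f"lab{i}" for i in range(len(base), self.n_features))
        return base + extra

    def loadings(self) -> np.ndarray:
        """d x k loading matrix with equal row norms (known spectrum)."""
        d, k = self.n_features, self.k
        if d & (d - 1) == 0 and d >= 2:  # power of two: exact Hadamard frame
            H = hadamard(d) / np.sqrt(d)
            U = H[:, 1 : k + 1]  # skip the constant column
        else:
            rng = np.random.default_rng(987_654_321)  # fixed frame, not per-cohort
            Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
            U = Q[:, :k]
        return U * np.sqrt(np.asarray(self.factor_strengths))

    def population_spectrum(self) -> EigenSpectrum:
        """Eigenspectrum of the population feature correlation matrix."""
        L = self.loadings()
        cov = L @ L.T + self.noise_sd**2 * np.eye(self.n_features)
        dinv = 1.0 / np.sqrt(np.diag(cov))
        corr = dinv[:, None] * cov * dinv[None, :]
        return eigendecompose(corr, self.feature_names)

    def matched_alpha(self) -> float:
        """Variance threshold that selects exactly k heads in population.

        Midpoint of the population cumulative EVR at k-1 and k, i.e. the
        most robust threshold for recovering the planted factor count.
        """
        evr = self.population_spectrum().evr
        lo = evr[self.k - 2] if self.k >= 2 else 0.0
        return float((lo + evr[self.k - 1]) / 2.0)

    def irreducible_variance(self) -> float:
        """Variance of the target unexplainable from the anchor-day latents.

        On the unit feature scale: AR(1) innovation over the horizon
        propagated through the target's latent readout, plus target
        noise.  For the lagged-linear target only terms whose lag is
        shorter than the horizon carry innovation variance.
        """
        rho, H = self.ar_coef, self.horizon
        if self.target_mode == "lagged-linear":
            innov = sum(
                c**2 * (1.0 - rho ** (2 * (H - lag)))
                for _, lag, c in self.lag_terms
                if lag < H
            )
            return innov + self.noise_sd**2
        L = self.loadings()
        signal = float(L[0] @ L[0])
        return (1.0 - rho ** (2 * H)) * signal + self.noise_sd**2


@dataclass
class GeneratedCohort:
    """Events + demographics plus the generator's ground truth."""

    spec: CohortSpec
    events: pd.DataFrame
    demographics: pd.DataFrame
    latents: dict  # patient_id -> (days x k) latent paths
    population_spectrum: EigenSpectrum

    def write(self, out_dir) -> None:
        import pathlib

        p = pathlib.Path(out_dir)
        p.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(p / "events.csv", index=False)
        self.demographics.to_csv(p / "demographics.csv", index=False)


def _sample_categorical(rng, mapping: dict, n: int) -> np.ndarray:
    cats = list(mapping)
    p = np.array([mapping[c] for c in cats], dtype=float)
    return rng.choice(cats, size=n, p=p / p.sum())


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Simulate one cohort; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    d, k, rho = spec.n_features, spec.k, spec.ar_coef
    L = spec.loadings()
    names = spec.feature_names
    bases = np.array([_LAB_UNITS.get(f, (10.0, 2.0))[0] for f in names])
    scales = np.array([_LAB_UNITS.get(f, (10.0, 2.0))[1] for f in names])

    n = spec.n_patients
    ages = rng.integers(*spec.demographic_mix["age_range"], size=n)
    sexes = _sample_categorical(rng, spec.demographic_mix["sex"], n)
    eths = _sample_categorical(rng, spec.demographic_mix["ethnicity"], n)
    demographics = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "ethnicity": eths,
        }
    )

    epoch = pd.Timestamp("2019-01-01")
    records = []
    latents = {}
    for i in range(n):
        pid = f"P{i:05d}"
        T = int(rng.integers(spec.days_range[0], spec.days_range[1] + 1))
        start = epoch + pd.Timedelta(days=int(rng.integers(0, 365)))
        a = np.empty((T, k))
        a[0] = rng.standard_normal(k)
        innov = rng.standard_normal((T - 1, k)) * np.sqrt(1 - rho**2)
        for t in range(1, T):
            a[t] = rho * a[t - 1] + innov[t - 1]
        latents[pid] = a

        noise_sd = np.full(d, spec.noise_sd)
        mult = _target_noise_multiplier(spec, sexes[i], eths[i], ages[i])
        target_noise = noise_sd[0] * mult
        u = a @ L.T + rng.standard_normal((T, d)) * noise_sd
        if mult != 1.0:
            u[:, 0] = a @ L[0] + rng.standard_normal(T) * target_noise
        if spec.target_mode == "lagged-linear":
            # target feature replaced by a signed sum of (factor, lag) terms
            u[:, 0] = rng.standard_normal(T) * target_noise
            for f, lag, c in spec.lag_terms:
                u[lag:, 0] += c * a[: T - lag, f]
        else:
            u[:, 0] += _target_extra(spec, a)
        x = bases + scales * u

        keep = rng.random((T, d)) >= np.asarray(spec.missing_rates)
        hours = rng.integers(6, 20, size=(T, d))
        minutes = rng.integers(0, 60, size=(T, d))
        days_idx, feat_idx = np.nonzero(keep)
        offsets_ns = (
            days_idx * 86_400 + hours[days_idx, feat_idx] * 3_600 + minutes[days_idx, feat_idx] * 60
        ).astype("timedelta64[s]")
        records.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "timestamp": np.datetime64(start, "s") + offsets_ns,
                    "variable": np.asarray(names)[feat_idx],
                    "value": x[days_idx, feat_idx],
                }
            )
        )
    events = pd.concat(records, ignore_index=True)
    return GeneratedCohort(spec, events, demographics, latents, spec.population_spectrum())


def _target_extra(spec: CohortSpec, a: np.ndarray) -> np.ndarray:
    """Planted nonlinear target component, scaled by ``interaction_strength``."""
    T = len(a)
    if spec.target_mode == "interaction" and spec.k >= 2:
        return spec.interaction_strength * a[:, 0] * a[:, 1]
    if spec.target_mode == "relu-memory":
        r = np.maximum(a[:, 0], 0.0)
        out = np.zeros(T)
        for j in range(spec.memory_window):
            out[j:] += (-1.0) ** j * r[: T - j]
        return spec.interaction_strength * out / np.sqrt(spec.memory_window)
    return np.zeros(T)


def _target_noise_multiplier(spec: CohortSpec, sex, ethnicity, age) -> float:
    if not spec.target_noise_multiplier:
        return 1.0
    values = {"sex": sex, "ethnicity": ethnicity}
    mult = 1.0
    for attr, table in spec.target_noise_multiplier.items():
        mult *= table.get(values.get(attr), 1.0)
    return mult


FIXTURES = ("tiny", "default", "fairness", "planted-depth")


def make_fixture(name: str, seed: int = 0, out_dir=None) -> GeneratedCohort:
    """Named cohort regimes used throughout the test-suite and reports.

    tiny
        30 patients x 5 features; seconds-scale smoke runs.
    default
        1000 patients x 8 features, 3 planted factors; protocol runs.
    fairness
        default regime with doubled target noise for one sex subgroup,
        so the disparity audit has a planted ground truth.
    planted-depth
        latent-interaction target in a low-noise regime where two
        transformer blocks suffice and one underfits.
    """
    if name == "tiny":
        spec = CohortSpec(
            n_patients=30,
            days_range=(20, 28),
            n_features=5,
            factor_strengths=(2.5, 1.2),
            missing_rates=0.05,
            seed=seed,
        )
    elif name == "default":
        spec = CohortSpec(seed=seed)
    elif name == "fairness":
        spec = CohortSpec(target_noise_multiplier={"sex": {"F": 2.0}}, seed=seed)
    elif name == "planted-depth":
        # one dominant factor makes the matched threshold select a single
        # head; the signed two-lag target (+a(t-2), -a(t-5)) then needs
        # two attention profiles with opposite signs, which one block's
        # single non-negative profile cannot represent while two blocks
        # can — and nothing is left for a third
        spec = CohortSpec(
            n_patients=400,
            days_range=(20, 30),
            factor_strengths=(6.0,),
            target_mode="lagged-linear",
            lag_terms=((0, 2, 1.0), (0, 5, -1.0)),
            ar_coef=0.9,
            missing_rates=0.0,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown fixture '{name}'; options: {FIXTURES}")
    cohort = generate_cohort(spec)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
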