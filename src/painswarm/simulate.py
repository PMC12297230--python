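"""Synthetic occupational-pain cohort generator.

Emulates the published summary statistics of a 350-person academic cohort:
continuous and ordinal margins (age, rank, experience, working hours, body
measures, exercise habits), categorical mixes (sex, college, extra work,
exercise), per-region current-pain prevalences, activity-impairment and
last-7-days frequencies, and a handful of headline pairwise correlations.

Dependence is modelled with a Gaussian copula: each row draws a latent
multivariate-normal vector whose correlation matrix carries the target rank
correlations (repaired to the nearest PSD matrix when infeasible); latent
coordinates are mapped through their normal CDF to uniforms and then to the
specified margins. Binary pain outcomes come from thresholding; impairment
and last-7-days outcomes are conditioned on current pain, so a row can never
report impairment without pain (structural zero). BMI is recomputed from the
generated weight and height rather than drawn, preserving the BMI identity.

Truncated-normal margins are *calibrated*: the parent mean/sd are solved by
least squares so that the truncated (and, for integer-valued variables,
rounded) variable reproduces the published mean and sd, which a naive
parameterisation would not (truncation shifts both moments).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import ndtr
from statsmodels.stats.correlation_tools import corr_nearest

from .cohort import REGIONS, CohortTable, pain_columns


# ---------------------------------------------------------------------------
# margins
# ---------------------------------------------------------------------------
@dataclass
class ContinuousMargin:
    """Truncated-normal margin with target moments on the observed scale."""

    mean: float
    sd: float
    min: float
    max: float
    integer: bool = False
    _mu: float = field(default=None, repr=False)  # calibrated parent mean
    _sigma: float = field(default=None, repr=False)  # calibrated parent sd

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.min >= self.max:
            raise ValueError("need min < max")

    # -- calibration -------------------------------------------------------
    def _moments(self, mu: float, sigma: float) -> tuple[float, float]:
        a = (self.min - mu) / sigma
        b = (self.max - mu) / sigma
        if not self.integer:
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
            return float(m), float(np.sqrt(v))
        ks = np.arange(math.floor(self.min), math.ceil(self.max) + 1)
        lo = np.maximum(ks - 0.5, self.min)
        hi = np.minimum(ks + 0.5, self.max)
        cdf = stats.truncnorm.cdf
        pk = cdf(hi, a, b, loc=mu, scale=sigma) - cdf(lo, a, b, loc=mu, scale=sigma)
        pk = np.clip(pk, 0.0, None)
        pk = pk / pk.sum()
        m = float(np.sum(ks * pk))
        v = float(np.sum((ks - m) ** 2 * pk))
        return m, math.sqrt(v)

    def calibrate(self) -> None:
        """Solve for parent (mu, sigma) matching the target mean and sd."""
        if self._mu is not None:
            return

        # Some printed (mean, sd) pairs are jointly infeasible for this
        # family: heavy left-truncation (age, experience) caps the reachable
        # sd, as does discretisation onto a narrow integer support (rank).
        # Feasible pairs still calibrate exactly; for infeasible ones the
        # mean residual is weighted up so the headline statistic is kept and
        # the sd takes the structural shortfall.
        def residual(theta):
            mu, log_sigma = theta
            m, s = self._moments(mu, math.exp(log_sigma))
            return [
                5.0 * (m - self.mean) / self.sd,
                (s - self.sd) / self.sd,
            ]

        sol = optimize.least_squares(
            residual,
            x0=[self.mean, math.log(self.sd)],
            xtol=1e-14,
            ftol=1e-14,
            max_nfev=2000,
        )
        self._mu = float(sol.x[0])
        self._sigma = float(math.exp(sol.x[1]))
        m, s = self._moments(self._mu, self._sigma)
        if abs(m - self.mean) > 0.02 * self.sd:
            warnings.warn(
                f"margin calibration imperfect: achieved mean {m:.3f} vs "
                f"target {self.mean:.3f}",
                stacklevel=2,
            )

    def transform(self, u: np.ndarray) -> np.ndarray:
        """Map copula uniforms to the margin (quantile transform)."""
        self.calibrate()
        a = (self.min - self._mu) / self._sigma
        b = (self.max - self._mu) / self._sigma
        x = stats.truncnorm.ppf(u, a, b, loc=self._mu, scale=self._sigma)
        if self.integer:
            x = np.clip(np.round(x), math.floor(self.min), math.ceil(self.max))
        return x


@dataclass
class CategoricalMargin:
    """Categories coded ``start, start+1, ...`` with given probabilities."""

    probs: tuple[float, ...]
    start: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("category probabilities must be >= 0 and sum to 1")

    def transform(self, u: np.ndarray) -> np.ndarray:
        cum = np.cumsum(self.probs)[:-1]
        return np.searchsorted(cum, u, side="right") + self.start


# ---------------------------------------------------------------------------
# published defaults
# ---------------------------------------------------------------------------
def _default_continuous() -> dict[str, ContinuousMargin]:
    return {
        "age": ContinuousMargin(32.45, 8.23, 24, 73),
        "scientific_rank": ContinuousMargin(2.45, 1.23, 1, 5, integer=True),
        "experience_years": ContinuousMargin(9.87, 8.56, 1, 50),
        "working_hours_day": ContinuousMargin(7.45, 1.23, 4, 10),
        "work_days_week": ContinuousMargin(4.78, 0.89, 3, 8, integer=True),
        "weight_kg": ContinuousMargin(75.23, 15.67, 45, 124),
        "height_cm": ContinuousMargin(166.45, 8.23, 150, 190),
        "exercising_days_week": ContinuousMargin(2.45, 1.23, 0, 7, integer=True),
        "exercising_hours_day": ContinuousMargin(1.23, 0.89, 0, 5),
    }


def _default_categorical() -> dict[str, CategoricalMargin]:
    return {
        "sex": CategoricalMargin((0.62, 0.38)),
        "college": CategoricalMargin((0.40, 0.15, 0.25, 0.12, 0.08), start=1),
        "extra_work": CategoricalMargin((0.20, 0.80)),
        "exercise": CategoricalMargin((0.45, 0.55)),
    }


#: Per-region current-pain prevalence (mean occurrence).
DEFAULT_PREVALENCE: dict[str, float] = {
    "neck": 0.65,
    "shoulder": 0.55,
    "elbow": 0.45,
    "wrist": 0.40,
    "thoracic": 0.50,
    "low_back": 0.70,
    "hip": 0.35,
    "knee": 0.60,
    "ankle": 0.30,
}

#: Marginal frequency of activity-preventing pain among all participants.
DEFAULT_IMPAIRMENT_FREQ: dict[str, float] = {
    "neck": 0.40,
    "shoulder": 0.35,
    "elbow": 0.30,
    "wrist": 0.25,
    "thoracic": 0.35,
    "low_back": 0.50,
    "hip": 0.20,
    "knee": 0.45,
    "ankle": 0.15,
}

#: Marginal frequency of pain within the last 7 days among all participants.
DEFAULT_LAST7_FREQ: dict[str, float] = {
    "neck": 0.45,
    "shoulder": 0.40,
    "elbow": 0.35,
    "wrist": 0.30,
    "thoracic": 0.40,
    "low_back": 0.55,
    "hip": 0.25,
    "knee": 0.50,
    "ankle": 0.20,
}

#: Headline pairwise rank-correlation targets from the published tables.
DEFAULT_CORRELATIONS: list[tuple[str, str, float]] = [
    ("age", "experience_years", 0.90),
    ("age", "scientific_rank", 0.897),
    ("exercise", "exercising_days_week", 0.886),
    ("exercising_days_week", "exercising_hours_day", 0.779),
    ("knee_pain_current", "exercising_days_week", -0.188),
    ("hip_pain_current", "exercising_days_week", -0.166),
    ("weight_kg", "knee_pain_last7", 0.142),  # BMI proxy: BMI is derived
    ("weight_kg", "height_cm", 0.50),  # joint body-size model behind BMI
]


@dataclass
class CohortSpec:
    """Full parameterisation of the generator (defaults = published tables)."""

    n: int = 350
    seed: int = 0
    continuous_margins: dict[str, ContinuousMargin] = field(
        default_factory=_default_continuous
    )
    categorical_margins: dict[str, CategoricalMargin] = field(
        default_factory=_default_categorical
    )
    pain_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    impairment_freq: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMPAIRMENT_FREQ)
    )
    last7_freq: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LAST7_FREQ))
    target_correlations: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_CORRELATIONS)
    )
    include_names: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for d in (self.pain_prevalence, self.impairment_freq, self.last7_freq):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"probability out of range for {k}: {v}")
        for a, b, rho in self.target_correlations:
            if abs(rho) >= 1.0:
                raise ValueError(f"|correlation| must be < 1 for ({a}, {b})")

    # -- latent layout -----------------------------------------------------
    @property
    def latent_names(self) -> list[str]:
        names = list(self.continuous_margins) + list(self.categorical_margins)
        names += [f"{r}_pain_current" for r in REGIONS]
        names += [f"{r}_pain_impairment" for r in REGIONS]
        names += [f"{r}_pain_last7" for r in REGIONS]
        return names

    def conditional_rate(self, region: str, outcome: str) -> float:
        """P(outcome = 1 | current pain = 1), back-solved from marginals."""
        prev = self.pain_prevalence[region]
        marg = (self.impairment_freq if outcome == "impairment" else self.last7_freq)[
            region
        ]
        if prev == 0:
            return 0.0
        rate = marg / prev
        if rate > 1.0:
            warnings.warn(
                f"{region} {outcome} marginal {marg} exceeds prevalence {prev}; "
                "conditional rate clipped to 1",
                stacklevel=2,
            )
        return min(rate, 1.0)

    def latent_correlation(self) -> np.ndarray:
        """Latent normal correlation matrix (nearest-PSD repaired if needed).

        Continuous-continuous rank targets are converted with the Gaussian
        copula identity r_latent = 2 sin(pi * rho_s / 6); pairs involving a
        thresholded (binary/ordinal) coordinate use the target directly and
        are attenuated by discretisation.
        """
        cached = getattr(self, "_latent_corr", None)
        if cached is not None:
            return cached
        names = self.latent_names
        idx = {n: i for i, n in enumerate(names)}
        C = np.eye(len(names))
        continuous = set(self.continuous_margins)
        for a, b, rho in self.target_correlations:
            if a not in idx or b not in idx:
                raise KeyError(f"unknown variable in correlation target: ({a}, {b})")
            if a in continuous and b in continuous:
                r = 2.0 * math.sin(math.pi * rho / 6.0)
            else:
                r = rho
            i, j = idx[a], idx[b]
            C[i, j] = C[j, i] = r
        if np.min(np.linalg.eigvalsh(C)) < 1e-10:
            warnings.warn(
                "target correlation matrix not positive definite; "
                "projected to the nearest PSD matrix",
                stacklevel=2,
            )
            with warnings.catch_warnings():
                # alternating projections stall below threshold; result is stable
                warnings.simplefilter("ignore")
                C = corr_nearest(C, threshold=1e-8, n_fact=50)
        self._latent_corr = C
        return C

    # -- YAML --------------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n": self.n,
            "seed": self.seed,
            "continuous_margins": {
                k: {
                    "mean": m.mean,
                    "sd": m.sd,
                    "min": m.min,
                    "max": m.max,
                    "integer": m.integer,
                }
                for k, m in self.continuous_margins.items()
            },
            "categorical_margins": {
                k: {"probs": list(m.probs), "start": m.start}
                for k, m in self.categorical_margins.items()
            },
            "pain_prevalence": dict(self.pain_prevalence),
            "impairment_freq": dict(self.impairment_freq),
            "last7_freq": dict(self.last7_freq),
            "target_correlations": [list(t) for t in self.target_correlations],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        doc = yaml.safe_load(Path(path).read_text())
        kwargs = {"n": doc.get("n", 350), "seed": doc.get("seed", 0)}
        if "continuous_margins" in doc:
            kwargs["continuous_margins"] = {
                k: ContinuousMargin(**v) for k, v in doc["continuous_margins"].items()
            }
        if "categorical_margins" in doc:
            kwargs["categorical_margins"] = {
                k: CategoricalMargin(tuple(v["probs"]), v.get("start", 0))
                for k, v in doc["categorical_margins"].items()
            }
        for key in ("pain_prevalence", "impairment_freq", "last7_freq"):
            if key in doc:
                kwargs[key] = dict(doc[key])
        if "target_correlations" in doc:
            kwargs["target_correlations"] = [
                (a, b, float(r)) for a, b, r in doc["target_correlations"]
            ]
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------
def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a schema-conformant cohort table from the copula model."""
    rng = np.random.default_rng(spec.seed)
    names = spec.latent_names
    C = spec.latent_correlation()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    Z = rng.standard_normal((spec.n, len(names))) @ L.T
    U = ndtr(Z)
    cols: dict[str, np.ndarray] = {}
    pos = {n: i for i, n in enumerate(names)}

    for name, margin in spec.continuous_margins.items():
        x = margin.transform(U[:, pos[name]])
        cols[name] = x if margin.integer else np.round(x, 2)
    for name, margin in spec.categorical_margins.items():
        cols[name] = margin.transform(U[:, pos[name]])

    # body-size identity: BMI derived, never drawn
    cols["weight_kg"] = np.round(cols["weight_kg"], 1)
    cols["height_cm"] = np.round(cols["height_cm"], 1)
    cols["bmi"] = np.round(cols["weight_kg"] / (cols["height_cm"] / 100.0) ** 2, 2)

    for region in REGIONS:
        prev = spec.pain_prevalence[region]
        current = (U[:, pos[f"{region}_pain_current"]] > 1.0 - prev).astype(int)
        cols[f"{region}_pain_current"] = current
        for outcome, col in (("impairment", "pain_impairment"), ("last7", "pain_last7")):
            rate = spec.conditional_rate(region, outcome)
            latent_u = U[:, pos[f"{region}_{col}"]]
            cols[f"{region}_{col}"] = current * (latent_u > 1.0 - rate).astype(int)

    frame = pd.DataFrame(cols)
    if spec.include_names:
        frame.insert(0, "name", [f"p{i + 1:04d}" for i in range(spec.n)])
    ordered = (["name"] if spec.include_names else []) + [
        c for c in _column_order() if c in frame.columns
    ]
    return CohortTable(frame[ordered])


def _column_order() -> list[str]:
    from .cohort import FEATURE_COLUMNS

    return list(FEATURE_COLUMNS) + pain_columns()


# ---------------------------------------------------------------------------
# linearly separable fixture cohort
# ---------------------------------------------------------------------------
#: Continuous columns carrying the class signal in the separable cohort.
SEPARABLE_SIGNAL_COLUMNS = (
    "age",
    "experience_years",
    "working_hours_day",
    "weight_kg",
    "height_cm",
    "exercising_hours_day",
)


def make_separable_cohort(n: int, gap: float, seed: int) -> CohortTable:
    """Two-class cohort with a linear decision rule and a margin of ``gap``.

    The label is the sign of a fixed linear score of standardised continuous
    features; rows are then pushed away from the boundary by gap/2 score-sd
    units on each side, so classes are linearly separable with margin ``gap``
    whenever gap > 0. With gap = 0 labels are independent coin flips (no
    signal). The label is written to every region's current-pain column, so
    any region can serve as the experiment target.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    base = generate_cohort(CohortSpec(n=n, seed=seed))
    df = base.frame.copy()
    rng = np.random.default_rng(seed + 1)

    sig = list(SEPARABLE_SIGNAL_COLUMNS)
    X = df[sig].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    beta = np.ones(len(sig)) / math.sqrt(len(sig))  # unit-norm direction
    score = Z @ beta  # ~ N(0, ~1) per construction

    if gap == 0:
        labels = rng.integers(0, 2, size=n)
    else:
        labels = (score > 0).astype(int)
        # move each row along beta so class scores clear +-gap/2
        shift = np.where(labels == 1, gap / 2.0, -gap / 2.0)
        Z = Z + shift[:, None] * beta[None, :]
        df[sig] = np.round(Z * sd + mu, 2)
        df["weight_kg"] = np.round(df["weight_kg"], 1)
        df["height_cm"] = np.round(df["height_cm"].clip(lower=100.0), 1)
        df["bmi"] = np.round(
            df["weight_kg"] / (df["height_cm"] / 100.0) ** 2, 2
        )

    for region in REGIONS:
        df[f"{region}_pain_current"] = labels
        df[f"{region}_pain_impairment"] = 0
        df[f"{region}_pain_last7"] = 0
    return CohortTable(df)
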