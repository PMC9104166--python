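"""Seeded synthetic office-survey generator.

Emulates the group-wise statistical structure of a cross-sectional office IAQ
survey: a satisfactory/unsatisfactory mixture, right-skewed correlated
surrogate levels (CO₂, RSP, TVOC), and non-surrogate pollutants that decide
whether an unsatisfactory office is a *hidden* failure (all three surrogates
pass, some other pollutant exceeds its limit) or a *visible* one.

Surrogate marginals are truncated log-normals coupled by a Gaussian copula.
Because truncation and the pass/fail conditioning both distort raw moments,
the generator does not use the textbook log-normal moment match directly:
it calibrates the underlying (μ, σ) per pollutant and group by iterative
simulation-based moment matching on the same conditional sampling path used
for the final draw, so that the *generated* group means and standard
deviations land on the configured targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import truncnorm

from .core import (
    POLLUTANTS,
    SCHEME_1,
    SCHEME_2,
    SURROGATES,
    Scheme,
    assess_frame,
    iaq_index_frame,
)
from .errors import CalibrationError

NON_SURROGATES: tuple[str, ...] = tuple(p for p in POLLUTANTS if p not in SURROGATES)

#: Fraction of the passing range used for non-surrogate levels of passing offices.
_PASS_LOW, _PASS_HIGH = 0.05, 0.85
#: Exceedance factor range for the single failing pollutant of a hidden failure.
_FAIL_LOW, _FAIL_HIGH = 1.05, 1.50


@dataclass(frozen=True)
class MarginalStats:
    """Target mean/sd and truncation range of one surrogate in one group."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("standard deviation must be > 0")
        if not self.lo < self.hi:
            raise ValueError("truncation bounds must satisfy lo < hi")
        if self.mean <= 0:
            raise ValueError("mean must be > 0 for a log-normal marginal")


# Group-wise surrogate statistics of the 525-office Hong Kong survey
# (mean, sd, min, max per pollutant), by labelling scheme.
SURVEY_GROUP_STATS: dict[str, dict[str, dict[str, MarginalStats]]] = {
    "scheme1": {
        "satisfactory": {
            "co2": MarginalStats(634.0, 126.0, 339.0, 998.0),
            "rsp": MarginalStats(28.0, 20.0, 4.0, 125.0),
            "tvoc": MarginalStats(242.0, 152.0, 0.0, 597.0),
        },
        "unsatisfactory": {
            "co2": MarginalStats(709.0, 184.0, 396.0, 1497.0),
            "rsp": MarginalStats(34.0, 19.0, 7.0, 91.0),
            "tvoc": MarginalStats(607.0, 446.0, 45.0, 3144.0),
        },
    },
    "scheme2": {
        "satisfactory": {
            "co2": MarginalStats(634.0, 126.0, 339.0, 998.0),
            "rsp": MarginalStats(27.0, 18.0, 4.0, 99.0),
            "tvoc": MarginalStats(240.0, 152.0, 0.0, 597.0),
        },
        "unsatisfactory": {
            "co2": MarginalStats(707.0, 183.0, 396.0, 1497.0),
            "rsp": MarginalStats(36.0, 22.0, 7.0, 125.0),
            "tvoc": MarginalStats(598.0, 442.0, 45.0, 3144.0),
        },
    },
}

#: Survey satisfactory proportions: 358/525 (Scheme 1) and 352/525 (Scheme 2).
SURVEY_P_SATISFACTORY: dict[str, float] = {
    "scheme1": 358.0 / 525.0,
    "scheme2": 352.0 / 525.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic survey generator.

    hidden_failure_fraction is the probability that an unsatisfactory office
    fails *only* on a non-surrogate pollutant while all three surrogates pass;
    it is the irreducible error floor any surrogate-only screening model faces.
    """

    n_offices: int = 525
    p_satisfactory: float = SURVEY_P_SATISFACTORY["scheme1"]
    surrogate_group_stats: Mapping[str, Mapping[str, MarginalStats]] = field(
        default_factory=lambda: SURVEY_GROUP_STATS["scheme1"]
    )
    surrogate_correlation: float = 0.3
    hidden_failure_fraction: float = 0.2
    seed: int = 0
    max_rejection_rounds: int = 1000
    calibration_iterations: int = 45
    calibration_sample: int = 6000

    def __post_init__(self) -> None:
        if self.n_offices < 1:
            raise ValueError("n_offices must be >= 1")
        if not 0.0 <= self.p_satisfactory <= 1.0:
            raise ValueError("p_satisfactory must lie in [0, 1]")
        if not 0.0 <= self.hidden_failure_fraction <= 1.0:
            raise ValueError("hidden_failure_fraction must lie in [0, 1]")
        if not -0.99 < self.surrogate_correlation < 0.99:
            raise ValueError("surrogate_correlation must lie in (-0.99, 0.99)")
        for group, stats in self.surrogate_group_stats.items():
            missing = [s for s in SURROGATES if s not in stats]
            if missing:
                raise ValueError(f"group {group!r} lacks stats for {missing}")

    @classmethod
    def for_scheme(cls, scheme: Scheme, **overrides) -> "GeneratorConfig":
        """Default survey-matched configuration for a built-in scheme."""
        key = scheme.name if scheme.name in SURVEY_GROUP_STATS else "scheme1"
        base = cls(
            p_satisfactory=SURVEY_P_SATISFACTORY[key],
            surrogate_group_stats=SURVEY_GROUP_STATS[key],
        )
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated records, their intended labels, and full provenance."""

    frame: pd.DataFrame
    intended_satisfactory: pd.Series
    scheme_name: str
    config: GeneratorConfig

    def labels(self, scheme: Scheme) -> pd.Series:
        """Boolean satisfaction labels under an arbitrary scheme."""
        return assess_frame(self.frame, scheme)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6g")


def _lognormal_init(stats: MarginalStats) -> tuple[float, float]:
    """Untruncated log-normal (μ, σ) matching the target mean/sd; the starting
    point for calibration, not the final parameters."""
    sigma2 = np.log1p((stats.sd / stats.mean) ** 2)
    mu = np.log(stats.mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def _copula_cholesky(rho: float) -> np.ndarray:
    corr = np.full((3, 3), rho)
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


class _GroupSampler:
    """Draws correlated truncated log-normal surrogate triples for one group."""

    def __init__(self, stats: Mapping[str, MarginalStats], rho: float):
        self.stats = {s: stats[s] for s in SURROGATES}
        self.chol = _copula_cholesky(rho)
        self.mu = np.array([_lognormal_init(self.stats[s])[0] for s in SURROGATES])
        self.sigma = np.array([_lognormal_init(self.stats[s])[1] for s in SURROGATES])
        self.log_lo = np.array(
            [np.log(self.stats[s].lo) if self.stats[s].lo > 0 else -np.inf for s in SURROGATES]
        )
        self.log_hi = np.array([np.log(self.stats[s].hi) for s in SURROGATES])

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        z = rng.standard_normal((n, 3)) @ self.chol.T
        u = ndtr(z)
        # Truncated log-normal ≡ exp of a truncated normal on the log scale.
        out = np.empty((n, 3))
        for j in range(3):
            a = (self.log_lo[j] - self.mu[j]) / self.sigma[j]
            b = (self.log_hi[j] - self.mu[j]) / self.sigma[j]
            # Clip u away from {0, 1} so ppf stays finite at float edges.
            uj = np.clip(u[:, j], 1e-12, 1.0 - 1e-12)
            out[:, j] = np.exp(truncnorm.ppf(uj, a, b, loc=self.mu[j], scale=self.sigma[j]))
        return out

    def draw_conditional(
        self,
        rng: np.random.Generator,
        n: int,
        predicate,
        max_rounds: int,
        what: str,
    ) -> np.ndarray:
        """Rejection-sample triples until ``predicate`` holds for every row."""
        out = np.empty((n, 3))
        remaining = n
        filled = 0
        for _ in range(max_rounds):
            if remaining == 0:
                return out
            batch = self.draw(rng, max(remaining * 2, 16))
            keep = batch[predicate(batch)]
            take = min(len(keep), remaining)
            out[filled : filled + take] = keep[:take]
            filled += take
            remaining -= take
        raise CalibrationError(
            f"could not draw {n} {what} triples within {max_rounds} rejection rounds; "
            "the configured group statistics are infeasible for this scheme"
        )


def _surrogate_limits(scheme: Scheme) -> np.ndarray:
    return np.array([scheme.limit(s) for s in SURROGATES])


@lru_cache(maxsize=64)
def _calibrated_params(
    stats_key: tuple,
    rho: float,
    mixture_key: tuple,
    limits_key: tuple,
    cal_seed: int,
    n_iter: int,
    n_cal: int,
    max_rounds: int,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Cached calibration: identical configs share one calibration run.

    The cache is safe for reproducibility because every argument that can
    influence the result (targets, copula, mixture, limits, seed, sizes) is
    part of the key.
    """
    stats = {name: MarginalStats(*vals) for name, vals in stats_key}
    limits = np.array(limits_key)
    sampler = _GroupSampler(stats, rho)
    pass_all = lambda x: (x <= limits).all(axis=1)  # noqa: E731
    fail_any = lambda x: (x > limits).any(axis=1)  # noqa: E731
    predicates = [
        (w, pass_all if kind == "pass" else fail_any) for w, kind in mixture_key
    ]
    cfg = GeneratorConfig(
        calibration_iterations=n_iter,
        calibration_sample=n_cal,
        max_rejection_rounds=max_rounds,
    )
    _calibrate(sampler, np.random.default_rng(cal_seed), predicates, cfg, "cached")
    return tuple(sampler.mu), tuple(sampler.sigma)


def _make_sampler(
    stats: Mapping[str, MarginalStats],
    config: GeneratorConfig,
    mixture: list[tuple[float, str]],
    limits: np.ndarray,
    cal_seed: int,
) -> _GroupSampler:
    stats_key = tuple(
        (name, (stats[name].mean, stats[name].sd, stats[name].lo, stats[name].hi))
        for name in SURROGATES
    )
    mu, sigma = _calibrated_params(
        stats_key,
        float(config.surrogate_correlation),
        tuple((float(w), kind) for w, kind in mixture if w > 0),
        tuple(float(v) for v in limits),
        cal_seed,
        config.calibration_iterations,
        config.calibration_sample,
        config.max_rejection_rounds,
    )
    sampler = _GroupSampler(stats, config.surrogate_correlation)
    sampler.mu = np.array(mu)
    sampler.sigma = np.array(sigma)
    return sampler


def _calibrate(
    sampler: _GroupSampler,
    rng: np.random.Generator,
    predicates: list[tuple[float, object]],
    config: GeneratorConfig,
    group: str,
) -> None:
    """Iterative moment matching of (μ, σ) on the conditional sampling path.

    ``predicates`` is a list of (weight, predicate) pairs describing the
    mixture the group is generated from (e.g. hidden vs. visible failures).
    Damped fixed-point updates: an additive shift on μ from the mean ratio,
    a log-scale shift on σ from the sd ratio. The σ updates run only for the
    first two thirds of the iterations; the remaining μ-only iterations
    polish the means, which are the moments the conditioning distorts most
    and the ones downstream checks rely on.
    """
    targets_m = np.array([sampler.stats[s].mean for s in SURROGATES])
    targets_s = np.array([sampler.stats[s].sd for s in SURROGATES])
    n_cal = config.calibration_sample
    n_iter = config.calibration_iterations
    sigma_phase = (2 * n_iter) // 3
    for it in range(n_iter):
        parts = []
        for weight, predicate in predicates:
            k = int(round(weight * n_cal))
            if k == 0:
                continue
            parts.append(
                sampler.draw_conditional(
                    rng, k, predicate, config.max_rejection_rounds, f"{group} calibration"
                )
            )
        sample = np.vstack(parts)
        m = sample.mean(axis=0)
        s = sample.std(axis=0, ddof=1)
        sampler.mu += 0.5 * np.clip(np.log(targets_m / m), -0.5, 0.5)
        if it < sigma_phase:
            sampler.sigma *= np.exp(
                0.3 * np.clip(np.log(targets_s / np.maximum(s, 1e-9)), -0.3, 0.3)
            )
            sampler.sigma = np.clip(sampler.sigma, 1e-3, 2.0)


def generate_offices(
    config: GeneratorConfig, scheme: Scheme = SCHEME_1
) -> SyntheticDataset:
    """Generate a synthetic office survey labelled under ``scheme``.

    Satisfactory offices pass all nine limits; unsatisfactory offices fail at
    least one, a configured fraction of them *only* on a non-surrogate
    pollutant. The returned dataset's intended labels agree with
    :func:`iaqscreen.core.assess_frame` on the generating scheme by
    construction (and this is re-verified before returning).
    """
    seed = int(config.seed) % (2**31)
    # Calibration is a deterministic function of the target statistics, not
    # of the draw: a fixed internal seed lets every generation seed share the
    # same calibrated parameters.
    cal_seed = 20170425
    rng = np.random.default_rng(seed)
    limits = _surrogate_limits(scheme)

    n = config.n_offices
    satisfied = rng.random(n) < config.p_satisfactory
    n_sat = int(satisfied.sum())
    n_uns = n - n_sat
    hidden = np.zeros(n, dtype=bool)
    hidden[~satisfied] = rng.random(n_uns) < config.hidden_failure_fraction

    pass_all = lambda x: (x <= limits).all(axis=1)  # noqa: E731
    fail_any = lambda x: (x > limits).any(axis=1)  # noqa: E731

    surrogate_values = np.empty((n, 3))

    if n_sat:
        sat_sampler = _make_sampler(
            config.surrogate_group_stats["satisfactory"],
            config,
            [(1.0, "pass")],
            limits,
            cal_seed,
        )
        surrogate_values[satisfied] = sat_sampler.draw_conditional(
            rng, n_sat, pass_all, config.max_rejection_rounds, "satisfactory"
        )
    if n_uns:
        h = config.hidden_failure_fraction
        uns_sampler = _make_sampler(
            config.surrogate_group_stats["unsatisfactory"],
            config,
            [(h, "pass"), (1.0 - h, "fail")],
            limits,
            cal_seed,
        )
        n_hidden = int(hidden.sum())
        if n_hidden:
            surrogate_values[hidden] = uns_sampler.draw_conditional(
                rng, n_hidden, pass_all, config.max_rejection_rounds, "hidden-failure"
            )
        n_visible = n_uns - n_hidden
        if n_visible:
            visible = ~satisfied & ~hidden
            surrogate_values[visible] = uns_sampler.draw_conditional(
                rng, n_visible, fail_any, config.max_rejection_rounds, "visible-failure"
            )

    frame = pd.DataFrame(index=pd.RangeIndex(n), columns=list(POLLUTANTS), dtype=float)
    for j, name in enumerate(SURROGATES):
        frame[name] = surrogate_values[:, j]

    # Non-surrogates: only their pass/fail status matters downstream. Passing
    # offices sit at a uniform fraction of the limit; a hidden failure exceeds
    # exactly one randomly chosen non-surrogate limit.
    for name in NON_SURROGATES:
        frame[name] = scheme.limit(name) * rng.uniform(_PASS_LOW, _PASS_HIGH, size=n)
    if hidden.any():
        idx = np.flatnonzero(hidden)
        which = rng.integers(0, len(NON_SURROGATES), size=len(idx))
        factors = rng.uniform(_FAIL_LOW, _FAIL_HIGH, size=len(idx))
        for i, j, f in zip(idx, which, factors):
            name = NON_SURROGATES[j]
            frame.loc[i, name] = scheme.limit(name) * f

    intended = pd.Series(satisfied, index=frame.index, name=f"satisfactory_{scheme.name}")
    actual = assess_frame(frame, scheme)
    if not actual.equals(intended):
        raise CalibrationError(
            "generated records disagree with their intended labels; "
            "check the configured group statistics against the scheme limits"
        )
    return SyntheticDataset(
        frame=frame, intended_satisfactory=intended, scheme_name=scheme.name, config=config
    )


_SUMMARY_ROWS = ("count", "mean", "std dev", "min", "25%", "50%", "75%", "max")


def _describe(frame: pd.DataFrame, theta: pd.Series) -> pd.DataFrame:
    data = frame[list(SURROGATES)].copy()
    data["theta"] = theta
    desc = data.describe(percentiles=[0.25, 0.5, 0.75])
    desc = desc.rename(index={"std": "std dev"})
    return desc.loc[list(_SUMMARY_ROWS)]


def summarize(
    dataset: SyntheticDataset | pd.DataFrame,
    scheme: Scheme = SCHEME_1,
    reference: Scheme = SCHEME_1,
) -> dict[str, pd.DataFrame]:
    """Survey-style summary: count/mean/sd/min/quartiles/max of the surrogates
    and θ, overall and per satisfaction group under ``scheme``.

    θ is always computed against ``reference`` limits (Scheme 1 by default).
    """
    frame = dataset.frame if isinstance(dataset, SyntheticDataset) else dataset
    if len(frame) == 0:
        raise ValueError("cannot summarize an empty dataset")
    theta = iaq_index_frame(frame, reference)
    labels = assess_frame(frame, scheme)
    out = {"overall": _describe(frame, theta)}
    for group, mask in (("satisfactory", labels), ("unsatisfactory", ~labels)):
        if mask.any():
            out[group] = _describe(frame[mask], theta[mask])
        else:
            warnings.warn(f"group {group!r} is empty; omitted from summary", stacklevel=2)
    return out
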