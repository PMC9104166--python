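"""Screening-table update via Monte-Carlo sampling and likelihood ratios.

A five-level screening test assigns an office to a bin of the IAQ index θ;
each bin carries a likelihood ratio LR = P(bin | unsatisfactory) /
P(bin | satisfactory), evaluated from normal distributions fitted to the
per-group θ values. When the assessment scheme is tightened, each bin's LR
changes by a relative impact ratio r₂,₁ = LR₂ / LR₁, so an existing
screening table can be updated without resurveying: LR₂ = r₂,₁ · LR₁.

The per-scheme satisfaction surface is provided by an ensemble of fitted
screening classifiers: surrogate triples are sampled uniformly over the
observable office ranges, every model votes, and the majority label (ties
resolved to *unsatisfactory*, the conservative screening outcome) labels
each sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import SCHEME_1, SURROGATES, Scheme, iaq_index_frame
from .harness import ModelResult

logger = logging.getLogger(__name__)

#: Denominator probability mass below which an LR is reported as +inf.
_MASS_FLOOR = 1e-12


@dataclass(frozen=True)
class SamplingRanges:
    """Uniform sampling intervals over the observable office ranges."""

    co2: tuple[float, float] = (400.0, 1400.0)
    rsp: tuple[float, float] = (1.0, 120.0)
    tvoc: tuple[float, float] = (0.0, 1500.0)
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in SURROGATES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: interval must satisfy lower < upper")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class IndexBin:
    """One screening level: a half-open θ interval [lower, upper).

    Printed bin labels follow the 2-decimal rounding convention (0.32–0.42,
    0.43–0.53, …); the raw-θ edges are placed at the rounding boundaries so
    the bins partition the axis without gaps.
    """

    label: str
    lower: float
    upper: float

    def contains(self, theta) -> np.ndarray:
        t = np.asarray(theta, dtype=float)
        return (t >= self.lower) & (t < self.upper)


#: The five screening levels. The first bin is open below so that the bins
#: partition the whole real axis (θ itself is non-negative).
DEFAULT_BINS: tuple[IndexBin, ...] = (
    IndexBin("<0.32", -np.inf, 0.315),
    IndexBin("0.32-0.42", 0.315, 0.425),
    IndexBin("0.43-0.53", 0.425, 0.535),
    IndexBin("0.54-0.64", 0.535, 0.645),
    IndexBin(">=0.65", 0.645, np.inf),
)

#: Published Scheme-1 likelihood ratios for air-conditioned offices.
DEFAULT_LR1: dict[str, float] = {
    "<0.32": 0.1,
    "0.32-0.42": 0.4,
    "0.43-0.53": 0.8,
    "0.54-0.64": 1.7,
    ">=0.65": 25.0,
}


@dataclass(frozen=True)
class GroupDistributions:
    """Normal θ distributions of the satisfactory/unsatisfactory groups.

    ``u_satisfactory``/``u_unsatisfactory`` carry the studentized-range
    normality statistic u = (max − min)/s of each group; normality is an
    assumption of the LR computation, and an extreme u is logged as a
    warning rather than raised.
    """

    mean_satisfactory: float
    sd_satisfactory: float
    mean_unsatisfactory: float
    sd_unsatisfactory: float
    u_satisfactory: float = float("nan")
    u_unsatisfactory: float = float("nan")

    def __post_init__(self) -> None:
        if self.sd_satisfactory <= 0 or self.sd_unsatisfactory <= 0:
            raise ValueError("group standard deviations must be > 0")


def monte_carlo_sample(ranges: SamplingRanges) -> pd.DataFrame:
    """Independent uniform surrogate triples over the configured intervals."""
    rng = np.random.default_rng(int(ranges.seed) % (2**31))
    data = {
        name: rng.uniform(*getattr(ranges, name), size=ranges.n_samples)
        for name in SURROGATES
    }
    return pd.DataFrame(data)


def _model_pairs(models: Sequence) -> list[tuple[object, object]]:
    pairs = []
    for m in models:
        if isinstance(m, ModelResult):
            if m.model is None or m.scaler is None:
                raise ValueError(
                    "ModelResult lacks a kept model/scaler; run the evaluation "
                    "with keep_models=True"
                )
            pairs.append((m.model, m.scaler))
        else:
            pairs.append((m[0], m[1]))
    return pairs


def model_average_predict(models: Sequence, triples: pd.DataFrame):
    """Ensemble vote over surrogate triples.

    Each model sees the triples through its *own* fitted min-max scaler.
    Returns ``(fractions, labels)``: the per-sample fraction of models
    predicting satisfactory, and the majority label with ties resolved to
    unsatisfactory (the conservative screening outcome).
    """
    pairs = _model_pairs(models)
    if not pairs:
        raise ValueError("need at least one fitted model")
    X = triples[list(SURROGATES)].to_numpy(dtype=float)
    votes = np.zeros(len(X))
    for model, scaler in pairs:
        if scaler.n_features_in_ != X.shape[1]:
            raise ValueError("model scaler does not match the surrogate features")
        votes += np.asarray(model.predict(scaler.transform(X)), dtype=float)
    fractions = votes / len(pairs)
    labels = fractions > 0.5
    return fractions, labels


def assign_bins(theta, bins: Sequence[IndexBin] = DEFAULT_BINS) -> np.ndarray:
    """Index of the bin containing each θ; every θ must fall in exactly one."""
    t = np.asarray(theta, dtype=float)
    out = np.full(len(t), -1)
    for i, b in enumerate(bins):
        mask = b.contains(t)
        if np.any(out[mask] >= 0):
            raise ValueError("bins overlap")
        out[mask] = i
    if np.any(out < 0):
        raise ValueError("some θ values fall outside every bin")
    return out


def bin_percentages(
    theta, labels, bins: Sequence[IndexBin] = DEFAULT_BINS
) -> pd.DataFrame:
    """Percent satisfactory/unsatisfactory per bin (summing to 100 per bin)."""
    idx = assign_bins(theta, bins)
    y = np.asarray(labels, dtype=bool)
    rows = []
    for i, b in enumerate(bins):
        mask = idx == i
        count = int(mask.sum())
        if count == 0:
            rows.append(
                {"bin": b.label, "count": 0,
                 "pct_satisfactory": np.nan, "pct_unsatisfactory": np.nan}
            )
            continue
        pct_sat = 100.0 * y[mask].mean()
        rows.append(
            {"bin": b.label, "count": count,
             "pct_satisfactory": pct_sat, "pct_unsatisfactory": 100.0 - pct_sat}
        )
    return pd.DataFrame(rows)


def _studentized_range(values: np.ndarray) -> float:
    s = values.std(ddof=1)
    return float((values.max() - values.min()) / s)


def fit_index_distributions(theta, labels) -> GroupDistributions:
    """Fit per-group normal distributions to θ.

    The studentized range u = (max − min)/s of each group is computed and
    logged as a rough normality diagnostic.
    """
    t = np.asarray(theta, dtype=float)
    y = np.asarray(labels, dtype=bool)
    groups = {}
    for name, mask in (("satisfactory", y), ("unsatisfactory", ~y)):
        vals = t[mask]
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs at least 2 samples")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {name!r} is degenerate (zero variance)")
        u = _studentized_range(vals)
        logger.info("group %s: n=%d mean=%.4f sd=%.4f u=%.3f", name, len(vals),
                    vals.mean(), sd, u)
        groups[name] = (float(vals.mean()), float(sd), u)
    return GroupDistributions(
        mean_satisfactory=groups["satisfactory"][0],
        sd_satisfactory=groups["satisfactory"][1],
        mean_unsatisfactory=groups["unsatisfactory"][0],
        sd_unsatisfactory=groups["unsatisfactory"][1],
        u_satisfactory=groups["satisfactory"][2],
        u_unsatisfactory=groups["unsatisfactory"][2],
    )


def likelihood_ratio(bin_: IndexBin, dists: GroupDistributions) -> float:
    """LR of one bin: unsatisfactory-group mass over satisfactory-group mass."""
    mass_u = norm.cdf(bin_.upper, dists.mean_unsatisfactory, dists.sd_unsatisfactory) - \
        norm.cdf(bin_.lower, dists.mean_unsatisfactory, dists.sd_unsatisfactory)
    mass_s = norm.cdf(bin_.upper, dists.mean_satisfactory, dists.sd_satisfactory) - \
        norm.cdf(bin_.lower, dists.mean_satisfactory, dists.sd_satisfactory)
    if mass_s < _MASS_FLOOR:
        return float("inf")
    return float(mass_u / mass_s)


def likelihood_ratio_table(
    dists: GroupDistributions, bins: Sequence[IndexBin] = DEFAULT_BINS
) -> dict[str, float]:
    return {b.label: likelihood_ratio(b, dists) for b in bins}


def empirical_likelihood_ratio_table(
    theta, labels, bins: Sequence[IndexBin] = DEFAULT_BINS
) -> dict[str, float]:
    """Counting estimator of the per-bin LR (the distribution-free oracle)."""
    idx = assign_bins(theta, bins)
    y = np.asarray(labels, dtype=bool)
    n_s, n_u = int(y.sum()), int((~y).sum())
    if n_s == 0 or n_u == 0:
        raise ValueError("both groups must be non-empty")
    out = {}
    for i, b in enumerate(bins):
        mask = idx == i
        p_u = (mask & ~y).sum() / n_u
        p_s = (mask & y).sum() / n_s
        out[b.label] = float("inf") if p_s == 0 else float(p_u / p_s)
    return out


def relative_impact(
    lr_scheme2: Mapping[str, float], lr_scheme1: Mapping[str, float]
) -> dict[str, float]:
    """Per-bin r₂,₁ = LR₂ / LR₁; undefined (NaN) where either LR is 0 or ∞."""
    if set(lr_scheme2) != set(lr_scheme1):
        raise ValueError("bin labels of the two LR tables do not match")
    out = {}
    for label in lr_scheme1:
        lr1, lr2 = lr_scheme1[label], lr_scheme2[label]
        if not (np.isfinite(lr1) and np.isfinite(lr2)) or lr1 <= 0 or lr2 <= 0:
            logger.warning("bin %s: relative impact undefined (LR1=%s, LR2=%s)",
                           label, lr1, lr2)
            out[label] = float("nan")
        else:
            out[label] = float(lr2 / lr1)
    return out


def display_round(value: float) -> float:
    """Screening-table display convention: one decimal below 10, integer at
    10 and above, round-half-up."""
    d = Decimal(repr(float(value)))
    if value < 10:
        return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return float(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def update_screening_table(
    lr1_table: Mapping[str, float],
    impacts: Mapping[str, float],
    bins: Sequence[IndexBin] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Updated screening table: LR₂ = r₂,₁ · LR₁ per bin, stored unrounded
    alongside its display rounding."""
    if set(lr1_table) != set(impacts):
        raise ValueError("bin labels of LR₁ table and impact table do not match")
    rows = []
    for b in bins:
        lr1 = float(lr1_table[b.label])
        r = float(impacts[b.label])
        lr2 = r * lr1
        rows.append(
            {"bin": b.label, "lr1": lr1, "impact": r,
             "lr2": lr2, "lr2_display": display_round(lr2)}
        )
    return pd.DataFrame(rows)


def post_test_probability(pre_p: float, lr: float) -> float:
    """Diagnostic odds update: post-odds = LR × pre-odds."""
    if lr < 0:
        raise ValueError("likelihood ratio must be >= 0")
    if pre_p in (0.0, 1.0):
        import warnings

        warnings.warn("degenerate pre-test probability returned unchanged", stacklevel=2)
        return pre_p
    if not 0.0 < pre_p < 1.0:
        raise ValueError("pre-test probability must lie in (0, 1)")
    post_odds = lr * pre_p / (1.0 - pre_p)
    return post_odds / (1.0 + post_odds)


def select_best_models(
    results: Sequence[ModelResult], scheme_name: str, count: int = 4
) -> list[ModelResult]:
    """Top ``count`` distinct-classifier models for one scheme.

    Ranks every kept model of the scheme's conditions by test accuracy across
    both stages, keeps the best entry per algorithm, and returns the top
    ``count`` algorithms — mirroring an ensemble of a handful of distinct
    best-performing classifiers. Ties rank deterministically (algorithm
    declaration order, trained before retrained).
    """
    candidates = [
        r for r in results
        if r.condition.scheme_name == scheme_name and r.model is not None
    ]
    if not candidates:
        raise ValueError(f"no kept models for scheme {scheme_name!r}")
    best_per_algorithm: dict[str, ModelResult] = {}
    for r in candidates:
        cur = best_per_algorithm.get(r.algorithm)
        if cur is None or r.test_accuracy > cur.test_accuracy:
            best_per_algorithm[r.algorithm] = r
    ranked = sorted(
        best_per_algorithm.values(), key=lambda r: -r.test_accuracy
    )
    return ranked[:count]


@dataclass(frozen=True)
class ScreeningUpdate:
    """Everything the update pipeline produces, per scheme and combined."""

    table: pd.DataFrame
    lr_scheme1: dict[str, float]
    lr_scheme2: dict[str, float]
    impacts: dict[str, float]
    percentages_scheme1: pd.DataFrame
    percentages_scheme2: pd.DataFrame
    dists_scheme1: GroupDistributions
    dists_scheme2: GroupDistributions


def run_screening_update(
    models_scheme1: Sequence,
    models_scheme2: Sequence,
    ranges: SamplingRanges = SamplingRanges(),
    bins: Sequence[IndexBin] = DEFAULT_BINS,
    lr1_table: Mapping[str, float] | None = None,
    reference: Scheme = SCHEME_1,
) -> ScreeningUpdate:
    """Full §-style update: one shared Monte-Carlo sample, per-scheme ensemble
    predictions, fitted group normals, per-bin LRs, impact ratios, and the
    updated table LR₂ = r₂,₁ · LR₁.

    Both schemes see the *same* uniformly sampled triples (shared seed), so
    running the update with identical model ensembles yields r₂,₁ = 1 exactly.
    """
    if lr1_table is None:
        lr1_table = dict(DEFAULT_LR1)
    triples = monte_carlo_sample(ranges)
    theta = iaq_index_frame(triples, reference).to_numpy()

    per_scheme = {}
    for key, models in (("scheme1", models_scheme1), ("scheme2", models_scheme2)):
        fractions, labels = model_average_predict(models, triples)
        spread = _ensemble_spread(models, triples, bins, theta)
        logger.info("%s: max per-bin ensemble spread %.3f", key, spread)
        dists = fit_index_distributions(theta, labels)
        per_scheme[key] = {
            "lr": likelihood_ratio_table(dists, bins),
            "pct": bin_percentages(theta, labels, bins),
            "dists": dists,
        }
    impacts = relative_impact(per_scheme["scheme2"]["lr"], per_scheme["scheme1"]["lr"])
    table = update_screening_table(lr1_table, impacts, bins)
    return ScreeningUpdate(
        table=table,
        lr_scheme1=per_scheme["scheme1"]["lr"],
        lr_scheme2=per_scheme["scheme2"]["lr"],
        impacts=impacts,
        percentages_scheme1=per_scheme["scheme1"]["pct"],
        percentages_scheme2=per_scheme["scheme2"]["pct"],
        dists_scheme1=per_scheme["scheme1"]["dists"],
        dists_scheme2=per_scheme["scheme2"]["dists"],
    )


def _ensemble_spread(models, triples, bins, theta) -> float:
    """Largest across bins of the spread (max − mean) of per-model
    satisfactory fractions; a soft agreement diagnostic, logged not asserted."""
    pairs = _model_pairs(models)
    idx = assign_bins(theta, bins)
    X = triples[list(SURROGATES)].to_numpy(dtype=float)
    per_model = []
    for model, scaler in pairs:
        pred = np.asarray(model.predict(scaler.transform(X)), dtype=float)
        per_model.append(
            [pred[idx == i].mean() if np.any(idx == i) else np.nan
             for i in range(len(bins))]
        )
    arr = np.asarray(per_model)
    with np.errstate(invalid="ignore"):
        spread = np.nanmax(np.abs(arr - np.nanmean(arr, axis=0)), axis=0)
    return float(np.nanmax(spread))
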