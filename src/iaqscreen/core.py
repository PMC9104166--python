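"""IAQ index, assessment schemes and satisfaction labelling.

The screening statistic is the IAQ index θ: the arithmetic mean of the
fractional doses Φ* = Φ/Φ_e of the three surrogate indicators CO₂, RSP and
TVOC, where Φ is the measured 8-h level and Φ_e the reference exposure limit.
An office is *satisfactory* under an assessment scheme iff every one of the
nine pollutant levels is at or below the scheme's exposure limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import IncompleteRecordError, InvalidSchemeError

#: Canonical pollutant identifiers, in the scheme-table order.
POLLUTANTS: tuple[str, ...] = (
    "co2",       # carbon dioxide, ppm
    "co",        # carbon monoxide, ppm
    "rsp",       # respirable suspended particulates, µg/m³
    "no2",       # nitrogen dioxide, µg/m³
    "o3",        # ozone, µg/m³
    "hcho",      # formaldehyde, µg/m³
    "tvoc",      # total volatile organic compounds, µg/m³
    "radon",     # radon, Bq/m³
    "abc",       # airborne bacteria count, CFU/m³
)

#: The three surrogate indicators entering the IAQ index.
SURROGATES: tuple[str, str, str] = ("co2", "rsp", "tvoc")

SATISFACTORY = "satisfactory"
UNSATISFACTORY = "unsatisfactory"


@dataclass(frozen=True)
class PollutantRecord:
    """One office's 8-h average levels of the nine scheme pollutants."""

    co2: float
    co: float
    rsp: float
    no2: float
    o3: float
    hcho: float
    tvoc: float
    radon: float
    abc: float

    def __post_init__(self) -> None:
        for name in POLLUTANTS:
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise IncompleteRecordError(f"missing value for {name!r}")
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in POLLUTANTS}

    @property
    def surrogates(self) -> "SurrogateTriple":
        return SurrogateTriple(co2=self.co2, rsp=self.rsp, tvoc=self.tvoc)


@dataclass(frozen=True)
class SurrogateTriple:
    """Levels of the three surrogate indicators (CO₂ ppm, RSP µg/m³, TVOC µg/m³)."""

    co2: float
    rsp: float
    tvoc: float

    def __post_init__(self) -> None:
        for name in SURROGATES:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class IndexValue:
    """An IAQ index value together with its three fractional doses."""

    theta: float
    doses: Mapping[str, float]


@dataclass(frozen=True)
class Scheme:
    """A named, complete set of nine 8-h exposure limits."""

    name: str
    limits: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [p for p in POLLUTANTS if p not in self.limits]
        extra = [p for p in self.limits if p not in POLLUTANTS]
        if missing or extra:
            raise InvalidSchemeError(
                f"scheme {self.name!r}: missing limits {missing}, unknown {extra}"
            )
        for pollutant, limit in self.limits.items():
            if not math.isfinite(limit) or limit <= 0:
                raise InvalidSchemeError(
                    f"scheme {self.name!r}: limit for {pollutant} must be > 0, got {limit!r}"
                )

    def limit(self, pollutant: str) -> float:
        try:
            return float(self.limits[pollutant])
        except KeyError:
            raise InvalidSchemeError(
                f"scheme {self.name!r} has no limit for {pollutant!r}"
            ) from None


#: Old Hong Kong IAQ objective (pre-2019 office certification scheme).
SCHEME_1 = Scheme(
    name="scheme1",
    limits={
        "co2": 1000.0,
        "co": 8.7,
        "rsp": 180.0,
        "no2": 150.0,
        "o3": 120.0,
        "hcho": 100.0,
        "tvoc": 600.0,
        "radon": 200.0,
        "abc": 1000.0,
    },
)

#: Updated Hong Kong IAQ objective: CO, RSP and radon limits tightened.
SCHEME_2 = Scheme(
    name="scheme2",
    limits={
        "co2": 1000.0,
        "co": 6.1,
        "rsp": 100.0,
        "no2": 150.0,
        "o3": 120.0,
        "hcho": 100.0,
        "tvoc": 600.0,
        "radon": 167.0,
        "abc": 1000.0,
    },
)

SCHEMES: dict[str, Scheme] = {"scheme1": SCHEME_1, "scheme2": SCHEME_2}


def fractional_dose(level: float, limit: float) -> float:
    """Fractional dose Φ* = level / limit of one pollutant.

    Parameters
    ----------
    level : measured 8-h exposure level (same unit as the limit), >= 0.
    limit : reference exposure limit, > 0.
    """
    if not math.isfinite(limit) or limit <= 0:
        raise InvalidSchemeError(f"exposure limit must be > 0, got {limit!r}")
    if not math.isfinite(level) or level < 0:
        raise ValueError(f"exposure level must be finite and >= 0, got {level!r}")
    return level / limit


def iaq_index(triple: SurrogateTriple, reference: Scheme = SCHEME_1) -> IndexValue:
    """IAQ index θ: the mean fractional dose of the three surrogates.

    The reference limits default to Scheme 1 regardless of which scheme is
    used for satisfaction labelling, so that index values remain comparable
    across scheme updates.
    """
    doses = {
        name: fractional_dose(getattr(triple, name), reference.limit(name))
        for name in SURROGATES
    }
    theta = sum(doses.values()) / 3.0
    return IndexValue(theta=theta, doses=doses)


def assess(record: PollutantRecord, scheme: Scheme) -> str:
    """Label a record satisfactory iff all nine levels are at or below the limits.

    A level exactly at the limit passes.
    """
    for pollutant in POLLUTANTS:
        if getattr(record, pollutant) > scheme.limit(pollutant):
            return UNSATISFACTORY
    return SATISFACTORY


def _require_columns(frame: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise IncompleteRecordError(f"missing pollutant column(s): {missing}")
    bad = frame[list(columns)].isna()
    if bad.to_numpy().any():
        col = bad.columns[int(bad.any().to_numpy().argmax())]
        row = bad.index[int(bad[col].to_numpy().argmax())]
        raise IncompleteRecordError(f"missing value for {col!r} at row {row}")


def iaq_index_frame(frame: pd.DataFrame, reference: Scheme = SCHEME_1) -> pd.Series:
    """Vectorised θ for a dataset with the three surrogate columns."""
    _require_columns(frame, SURROGATES)
    theta = sum(
        frame[name].to_numpy(dtype=float) / reference.limit(name) for name in SURROGATES
    ) / 3.0
    return pd.Series(theta, index=frame.index, name="theta")


def assess_frame(frame: pd.DataFrame, scheme: Scheme) -> pd.Series:
    """Vectorised assessment: True where all nine levels pass the scheme."""
    _require_columns(frame, POLLUTANTS)
    ok = np.ones(len(frame), dtype=bool)
    for pollutant in POLLUTANTS:
        ok &= frame[pollutant].to_numpy(dtype=float) <= scheme.limit(pollutant)
    return pd.Series(ok, index=frame.index, name=f"satisfactory_{scheme.name}")


class IAQIndexTransformer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer mapping surrogate levels to the IAQ index θ.

    Accepts a DataFrame with co2/rsp/tvoc columns or an array with the three
    surrogate columns in that order; returns an (n, 1) array of θ values.
    """

    def __init__(self, reference: Scheme = SCHEME_1):
        self.reference = reference

    def fit(self, X, y=None):  # noqa: N803 - sklearn signature
        self.limits_ = np.array([self.reference.limit(s) for s in SURROGATES])
        return self

    def transform(self, X):  # noqa: N803
        if not hasattr(self, "limits_"):
            self.fit(X)
        if isinstance(X, pd.DataFrame):
            values = X[list(SURROGATES)].to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
        if values.ndim != 2 or values.shape[1] != 3:
            raise ValueError("expected three surrogate columns (co2, rsp, tvoc)")
        theta = (values / self.limits_).mean(axis=1)
        return theta.reshape(-1, 1)
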