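"""Dataset, scheme and run-config readers/writers, plus the full pipeline.

CSV dialect: comma-separated, UTF-8, ``.`` decimal, mandatory header row with
the nine pollutant ids. Extra columns (e.g. precomputed labels) are ignored
on read. Schemes and run configs are flat YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import harness, screening, synthetic
from .core import POLLUTANTS, SCHEMES, Scheme, assess_frame, iaq_index_frame
from .errors import IncompleteRecordError

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.6g"


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a pollutant dataset CSV.

    Every pollutant column must be present, numeric, non-negative and
    complete; violations raise with the row number and column name.
    """
    frame = pd.read_csv(path)
    missing = [p for p in POLLUTANTS if p not in frame.columns]
    if missing:
        raise IncompleteRecordError(f"dataset {path}: missing column(s) {missing}")
    frame = frame[list(POLLUTANTS)].copy()
    for col in POLLUTANTS:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() | ~np.isfinite(values) | (values < 0)
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"dataset {path}: invalid value in column {col!r} at row {row} "
                f"({frame[col].iloc[row]!r}); values must be numeric and >= 0"
            )
        frame[col] = values.astype(float)
    return frame


def write_dataset(frame: pd.DataFrame, path) -> None:
    frame[list(POLLUTANTS)].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_scheme(path) -> Scheme:
    raw = yaml.safe_load(Path(path).read_text())
    return Scheme(name=str(raw["name"]), limits={k: float(v) for k, v in raw["limits"].items()})


def write_scheme(scheme: Scheme, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {"name": scheme.name, "limits": {k: float(v) for k, v in scheme.limits.items()}},
            sort_keys=False,
        )
    )


def bundled_scheme(name: str) -> Scheme:
    """Load one of the two bundled scheme files (``scheme1`` / ``scheme2``)."""
    text = resources.files("iaqscreen").joinpath(f"data/{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    return Scheme(name=str(raw["name"]), limits={k: float(v) for k, v in raw["limits"].items()})


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    seed: int = 0
    n_offices: int = 2000
    generation_scheme: str = "scheme1"
    hidden_failure_fraction: float = 0.2
    surrogate_correlation: float = 0.3
    r_d_levels: tuple[float, ...] = harness.R_D_LEVELS
    k_levels: tuple[int, ...] = harness.K_LEVELS
    schemes: tuple[str, ...] = ("scheme1", "scheme2")
    algorithms: tuple[str, ...] = dataclasses.field(default_factory=lambda: tuple())
    reduced_grids: bool = True
    ensemble_size: int = 4
    mc_samples: int = 100_000
    lr1_table: dict = field(default_factory=lambda: dict(screening.DEFAULT_LR1))

    def resolved_algorithms(self) -> tuple[str, ...]:
        from .backends import ALGORITHMS

        return self.algorithms or ALGORITHMS

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                value = raw[f.name]
                kwargs[f.name] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """simulate → evaluate → update-screening, persisting every artifact.

    Returns the output directory. Two runs with the same config produce
    byte-identical artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    scheme = SCHEMES[config.generation_scheme]
    gen_config = synthetic.GeneratorConfig.for_scheme(
        scheme,
        n_offices=config.n_offices,
        seed=config.seed,
        hidden_failure_fraction=config.hidden_failure_fraction,
        surrogate_correlation=config.surrogate_correlation,
    )
    logger.info("pipeline stage 1/3: simulate (n=%d, scheme=%s, seed=%d)",
                config.n_offices, scheme.name, config.seed)
    dataset = synthetic.generate_offices(gen_config, scheme)
    write_dataset(dataset.frame, out / "dataset.csv")
    for name in config.schemes:
        labels = assess_frame(dataset.frame, SCHEMES[name])
        report = harness.baseline_accuracy(labels)
        logger.info("dataset baseline accuracy under %s: %.3f (n=%d)",
                    name, report.baseline, report.n)

    logger.info("pipeline stage 2/3: evaluate")
    conditions = harness.full_design(
        schemes=config.schemes, r_d_levels=config.r_d_levels, k_levels=config.k_levels
    )
    from .backends import grids

    results = harness.run_evaluation(
        dataset.frame,
        conditions=conditions,
        algorithms=config.resolved_algorithms(),
        grid_set=grids(reduced=config.reduced_grids),
        master_seed=config.seed,
        keep_models=True,
    )
    harness.results_frame(results).to_csv(
        out / "results.csv", index=False, float_format=_FLOAT_FORMAT
    )
    harness.tally_best(results).to_csv(
        out / "tally.csv", index=False, float_format=_FLOAT_FORMAT
    )

    logger.info("pipeline stage 3/3: update-screening")
    update = screening.run_screening_update(
        screening.select_best_models(results, "scheme1", config.ensemble_size),
        screening.select_best_models(results, "scheme2", config.ensemble_size),
        ranges=screening.SamplingRanges(n_samples=config.mc_samples, seed=config.seed),
        lr1_table=config.lr1_table,
    )
    update.table.to_csv(out / "screening_table.csv", index=False, float_format=_FLOAT_FORMAT)
    update.percentages_scheme1.to_csv(
        out / "bin_percentages_scheme1.csv", index=False, float_format=_FLOAT_FORMAT
    )
    update.percentages_scheme2.to_csv(
        out / "bin_percentages_scheme2.csv", index=False, float_format=_FLOAT_FORMAT
    )
    return out


def index_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Convenience: dataset plus θ and per-scheme labels."""
    out = frame.copy()
    out["theta"] = iaq_index_frame(frame)
    for name, scheme in SCHEMES.items():
        out[f"satisfactory_{name}"] = assess_frame(frame, scheme)
    return out
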