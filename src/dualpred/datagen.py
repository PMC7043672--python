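"""Synthetic predation-kinetics datasets.

The wet-lab design being emulated: four culture conditions (prey only,
prey + *Bdellovibrio*, prey + phage, prey + both predators), sampled every
2 h for 48 h, three replicate counts per sample, with a plating detection
limit of 10 CFU/ml.  Replicate scatter is modelled as multiplicative
lognormal noise on the counts (plated dilution series are dominated by
dilution/pipetting error at these densities); counts below the detection
limit are censored flags, not zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import (
    CONDITIONS,
    Condition,
    ModelVariant,
    ParameterSet,
    observables,
    simulate_conditions,
)

__all__ = [
    "POPULATIONS",
    "ExperimentDesign",
    "NoiseModel",
    "ObservedDataset",
    "generate_dataset",
]

POPULATIONS = ("prey", "bdellovibrio", "phage")


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of a 48-h predation-kinetics experiment."""

    duration: float = 48.0            # h
    sampling_interval: float = 2.0    # h
    replicates: int = 3
    conditions: tuple = CONDITIONS
    detection_limit: float = 10.0     # CFU/ml

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        n = self.duration / self.sampling_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_interval must divide duration")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        object.__setattr__(
            self, "conditions", tuple(Condition(c).value for c in self.conditions)
        )

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.sampling_interval))
        return np.linspace(0.0, self.duration, n + 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        d["conditions"] = tuple(d.get("conditions", CONDITIONS))
        return cls(**d)


@dataclass(frozen=True)
class NoiseModel:
    """Replicate count noise: ``measured = truth * 10**eps`` with
    ``eps ~ Normal(0, log10_sd)`` independently per count.  An optional
    Poisson stage resamples counts below 100/ml (off by default)."""

    log10_sd: float = 0.15
    seed: int = 0
    poisson_low_counts: bool = False

    def __post_init__(self) -> None:
        if self.log10_sd < 0:
            raise ValueError("log10_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


class ObservedDataset:
    """Noisy, censored, replicated time series per condition/population.

    Backed by a tidy frame with columns ``condition, population, time_h,
    replicate, density_per_ml, censored``; censored rows carry NaN
    density.  ``detection_limit`` travels with the dataset because the
    fitting distance floors values there.
    """

    def __init__(self, frame: pd.DataFrame, detection_limit: float, meta: dict | None = None):
        required = {"condition", "population", "time_h", "replicate",
                    "density_per_ml", "censored"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"dataset frame missing columns {sorted(missing)}")
        grids = frame.groupby("condition")["time_h"].unique()
        ref = np.sort(grids.iloc[0])
        for g in grids:
            if not np.array_equal(np.sort(g), ref):
                raise ValueError("time grid must be identical across conditions")
        uncens = frame.loc[~frame["censored"], "density_per_ml"]
        if (uncens < detection_limit - 1e-9).any():
            raise ValueError("uncensored densities below the detection limit")
        self.frame = frame.reset_index(drop=True)
        self.detection_limit = float(detection_limit)
        self.meta = meta or {}

    @property
    def conditions(self) -> list:
        seen = dict.fromkeys(self.frame["condition"])
        return list(seen)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_h"].unique())

    @property
    def n_replicates(self) -> int:
        return int(self.frame["replicate"].nunique())

    def n_censored(self) -> int:
        return int(self.frame["censored"].sum())

    def subset(self, conditions) -> "ObservedDataset":
        conditions = [Condition(c).value for c in conditions]
        sub = self.frame[self.frame["condition"].isin(conditions)]
        if sub.empty:
            raise ValueError(f"no data for conditions {conditions}")
        return ObservedDataset(sub.copy(), self.detection_limit, dict(self.meta))

    def log10_means(self) -> np.ndarray:
        """Replicates averaged on the log10 scale, censored entries at the
        detection limit: array (n_conditions, 3 populations, n_times)."""
        times = self.times
        out = np.full((len(self.conditions), len(POPULATIONS), times.size), np.nan)
        floor = max(self.detection_limit, 1e-300)
        df = self.frame
        vals = df["density_per_ml"].to_numpy(dtype=float).copy()
        vals[df["censored"].to_numpy(dtype=bool)] = floor
        vals = np.log10(np.maximum(vals, floor))
        ci = pd.Categorical(df["condition"], categories=self.conditions).codes
        pi = pd.Categorical(df["population"], categories=list(POPULATIONS)).codes
        ti = np.searchsorted(times, df["time_h"].to_numpy(dtype=float))
        sums = np.zeros_like(out)
        counts = np.zeros_like(out)
        np.add.at(sums, (ci, pi, ti), vals)
        np.add.at(counts, (ci, pi, ti), 1.0)
        with np.errstate(invalid="ignore"):
            out = sums / counts
        return out


def _simulate_observables(
    variant: ModelVariant,
    params: ParameterSet,
    design: ExperimentDesign,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> np.ndarray:
    """Noiseless truth: array (n_conditions, 3, n_times)."""
    states = simulate_conditions(
        variant, params, design.conditions, design.times, rtol=rtol, atol=atol
    )
    return np.stack(
        [observables(states[c]).T for c in design.conditions], axis=0
    )


def generate_dataset(
    variant: ModelVariant,
    params: ParameterSet,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
) -> ObservedDataset:
    """Simulate the design, add replicate noise, censor below detection."""
    design = design or ExperimentDesign()
    noise = noise or NoiseModel()
    truth = _simulate_observables(variant, params, design)
    rng = np.random.default_rng(noise.seed)
    times = design.times
    rows = []
    for icond, cond in enumerate(design.conditions):
        for ipop, pop in enumerate(POPULATIONS):
            base = truth[icond, ipop]
            for rep in range(design.replicates):
                eps = rng.normal(0.0, noise.log10_sd, size=times.size)
                vals = base * 10.0 ** eps
                if noise.poisson_low_counts:
                    low = vals < 100.0
                    vals[low] = rng.poisson(vals[low]).astype(float)
                cens = vals < design.detection_limit
                rows.append(
                    pd.DataFrame(
                        {
                            "condition": cond,
                            "population": pop,
                            "time_h": times,
                            "replicate": rep,
                            "density_per_ml": np.where(cens, np.nan, vals),
                            "censored": cens,
                        }
                    )
                )
    frame = pd.concat(rows, ignore_index=True)
    meta = {
        "design": design.to_dict(),
        "noise": noise.to_dict(),
        "variant": variant.to_dict(),
        "params": params.to_dict(),
    }
    return ObservedDataset(frame, design.detection_limit, meta)
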