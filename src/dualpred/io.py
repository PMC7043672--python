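"""Readers, writers and the flat key=value run configuration.

Artifacts are tidy CSVs with JSON sidecars so that every product of one
pipeline step can be consumed by the next (and by anything else that
reads CSV).  The config format is deliberately plain::

    # comment
    variant.prey_types = N3
    variant.conversion = SG
    params.mu_max = 0.4
    design.replicates = 3
    smc.n_particles = 200

Sections: ``variant.*``, ``params.*``, ``prior.<name> = loguniform lo hi``
(or ``uniform lo hi`` / ``fixed value``), ``design.*``, ``noise.*``,
``smc.*`` and top-level ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abc import PriorSpec, SMCConfig
from .datagen import ExperimentDesign, NoiseModel, ObservedDataset
from .model import COMPARTMENTS, ModelVariant, ParameterSet, Trajectory

__all__ = [
    "RunConfig",
    "read_config",
    "write_trajectory",
    "read_trajectory",
    "write_dataset",
    "read_dataset",
]


# ---------------------------------------------------------------------------
# Trajectory round trip
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, stem: Path, solver_opts: dict | None = None,
                     seed: int | None = None) -> None:
    """Tidy CSV (time_h, compartment, density_per_ml) + JSON sidecar."""
    stem = Path(stem)
    records = []
    for j, comp in enumerate(COMPARTMENTS):
        records.append(
            pd.DataFrame(
                {
                    "time_h": traj.times,
                    "compartment": comp,
                    "density_per_ml": traj.states[:, j],
                }
            )
        )
    pd.concat(records, ignore_index=True).to_csv(
        stem.with_suffix(".csv"), index=False, float_format="%.17g"
    )
    sidecar = {
        "variant": traj.variant.to_dict(),
        "params": traj.params.to_dict(),
        "solver_opts": solver_opts or {},
        "seed": seed,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trajectory(stem: Path) -> Trajectory:
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"), float_precision="round_trip")
    df["time_h"] = df["time_h"].astype(float)
    df["density_per_ml"] = df["density_per_ml"].astype(float)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    times = np.sort(df["time_h"].unique())
    states = np.empty((times.size, len(COMPARTMENTS)))
    for j, comp in enumerate(COMPARTMENTS):
        sub = df[df["compartment"] == comp].sort_values("time_h")
        states[:, j] = sub["density_per_ml"].to_numpy()
    return Trajectory(
        times,
        states,
        ModelVariant.from_dict(sidecar["variant"]),
        ParameterSet.from_dict(sidecar["params"]),
    )


# ---------------------------------------------------------------------------
# Dataset round trip
# ---------------------------------------------------------------------------


def write_dataset(ds: ObservedDataset, stem: Path) -> None:
    stem = Path(stem)
    ds.frame.to_csv(stem.with_suffix(".csv"), index=False, float_format="%.17g")
    sidecar = {"detection_limit": ds.detection_limit, "meta": ds.meta}
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_dataset(stem: Path) -> ObservedDataset:
    stem = Path(stem)
    frame = pd.read_csv(stem.with_suffix(".csv"), float_precision="round_trip")
    frame["time_h"] = frame["time_h"].astype(float)
    frame["density_per_ml"] = frame["density_per_ml"].astype(float)
    frame["censored"] = frame["censored"].astype(bool)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    return ObservedDataset(frame, sidecar["detection_limit"], sidecar.get("meta"))


# ---------------------------------------------------------------------------
# Flat key=value configuration
# ---------------------------------------------------------------------------


def _coerce(text: str):
    text = text.strip()
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", "null", ""):
        return None
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def _parse_flat(path: Path) -> dict:
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out


@dataclass
class RunConfig:
    """Fully resolved configuration for one CLI invocation."""

    seed: int = 0
    variant: ModelVariant = field(default_factory=ModelVariant)
    params: ParameterSet = field(default_factory=ParameterSet)
    prior: PriorSpec | None = None
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    noise: NoiseModel = field(default_factory=NoiseModel)
    smc: SMCConfig = field(default_factory=SMCConfig)
    extra: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "variant": self.variant.to_dict(),
            "params": self.params.to_dict(),
            "prior": self.prior.to_dict() if self.prior else None,
            "design": self.design.to_dict(),
            "noise": self.noise.to_dict(),
            "smc": dict(self.smc.__dict__),
            "extra": self.extra,
        }


def read_config(path: Path) -> RunConfig:
    """Parse and validate a flat key=value config file."""
    flat = _parse_flat(path)
    groups: dict = {"variant": {}, "params": {}, "prior": {}, "design": {},
                    "noise": {}, "smc": {}}
    seed = 0
    extra = {}
    for key, raw in flat.items():
        if key == "seed":
            seed = int(raw)
            continue
        if "." not in key:
            extra[key] = _coerce(raw)
            continue
        group, name = key.split(".", 1)
        if group not in groups:
            raise ValueError(f"unknown config section in key {key!r}")
        groups[group][name] = raw
    try:
        variant_kw = {k: _coerce(v) for k, v in groups["variant"].items()}
        variant = (
            ModelVariant(**variant_kw) if variant_kw else ModelVariant()
        )
        params_kw = {k: float(v) for k, v in groups["params"].items()}
        params = ParameterSet(**{**ParameterSet().to_dict(), **params_kw})
        design_kw = {k: _coerce(v) for k, v in groups["design"].items()}
        if "conditions" in design_kw:
            design_kw["conditions"] = tuple(
                s.strip() for s in groups["design"]["conditions"].split(",")
            )
        design = ExperimentDesign(**design_kw) if design_kw else ExperimentDesign()
        noise_kw = {k: _coerce(v) for k, v in groups["noise"].items()}
        noise = NoiseModel(**noise_kw) if noise_kw else NoiseModel()
        smc_kw = {k: _coerce(v) for k, v in groups["smc"].items()}
        smc = SMCConfig(**{**smc_kw, "seed": smc_kw.get("seed", seed)})
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc
    prior = None
    if groups["prior"]:
        free, fixed = {}, {}
        for name, raw in groups["prior"].items():
            parts = raw.split()
            if parts[0] == "fixed":
                fixed[name] = float(parts[1])
            elif parts[0] in ("loguniform", "uniform") and len(parts) == 3:
                free[name] = (parts[0], float(parts[1]), float(parts[2]))
            else:
                raise ValueError(
                    f"invalid prior spec for {name!r}: {raw!r} "
                    "(want 'loguniform LO HI', 'uniform LO HI' or 'fixed VALUE')"
                )
        prior = PriorSpec(free=free, fixed=fixed)
    return RunConfig(
        seed=seed, variant=variant, params=params, prior=prior,
        design=design, noise=noise, smc=smc, extra=extra,
    )
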