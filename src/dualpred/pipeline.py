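"""Hierarchical model selection, final fitting and what-if sweeps.

Orchestrates the staged competitions that whittle the model family down
to a single variant (prey phenotypes -> conversion mechanism -> signal
source -> resistance origin -> attack saturation -> mortality mode),
then final fits, typical-parameter extraction via PCA, the
fit-without-dual-predation prediction exercise, and 10-fold
initial-density sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .abc import PriorSpec, SMCConfig, SMCResult, default_prior, run_abc_smc
from .datagen import ExperimentDesign, ObservedDataset
from .model import (
    Condition,
    ModelVariant,
    ParameterSet,
    observables,
    simulate,
    initial_state,
)

__all__ = [
    "Stage",
    "StagePlan",
    "SweepResult",
    "default_stage_plan",
    "run_stage",
    "run_plan",
    "fit_final",
    "typical_parameter_set",
    "density_sweep",
]


@dataclass(frozen=True)
class Stage:
    name: str
    candidates: tuple            # tuple of ModelVariant
    conditions: tuple | None = None  # None = all conditions in the dataset


@dataclass(frozen=True)
class StagePlan:
    """Ordered competition ladder; each stage's winner seeds the next."""

    stages: tuple

    def __iter__(self):
        return iter(self.stages)


def _with(v: ModelVariant, **kw) -> ModelVariant:
    d = v.to_dict()
    d.update(kw)
    return ModelVariant.from_dict(d)


def default_stage_plan() -> StagePlan:
    """The default seven-stage ladder (A–G).

    A: number of prey phenotypes (N1–N4), everything else at the
    richest shared setting (signal from both predators, both resistance
    origins, saturating *Bdellovibrio* attack, non-saturating phage).
    B: plastic-resistance conversion mechanism (I vs IG vs S).
    C: combined SG against its parent variants.
    D: signal source (B only / both / V only).
    E: phage-resistance origin (preexisting / de novo / both).
    F: attack-rate saturation (Pi/Pii x Vi/Vii).
    G: Bdellovibrio mortality fixed from the literature vs fitted.
    """
    base3 = ModelVariant(
        prey_types="N3", conversion="SG", signal_source="both",
        resistance_origin="both", p_saturation="Pii", v_saturation="Vi",
        mortality_mode="fitted",
    )
    stage_a = Stage(
        "A_prey_types",
        (
            ModelVariant("N1", None, None, None, "Pii", "Vi", "fitted"),
            ModelVariant("N2", None, None, "both", "Pii", "Vi", "fitted"),
            base3,
            _with(base3, prey_types="N4"),
        ),
    )
    stage_b = Stage(
        "B_conversion",
        (
            _with(base3, conversion="I", signal_source=None),
            _with(base3, conversion="IG", signal_source=None),
            _with(base3, conversion="S"),
        ),
    )
    stage_c = Stage(
        "C_combined_conversion",
        (
            _with(base3, conversion="IG", signal_source=None),
            _with(base3, conversion="SG"),
            _with(base3, conversion="S"),
        ),
    )
    stage_d = Stage(
        "D_signal_source",
        (
            _with(base3, signal_source="B_only"),
            _with(base3, signal_source="both"),
            _with(base3, signal_source="V_only"),
        ),
    )
    best = _with(base3, signal_source="B_only")
    stage_e = Stage(
        "E_resistance_origin",
        (
            _with(best, resistance_origin="preexisting"),
            _with(best, resistance_origin="de_novo"),
            _with(best, resistance_origin="both"),
        ),
    )
    stage_f = Stage(
        "F_saturation",
        (
            _with(best, p_saturation="Pi", v_saturation="Vi"),
            _with(best, p_saturation="Pi", v_saturation="Vii"),
            _with(best, p_saturation="Pii", v_saturation="Vi"),
            _with(best, p_saturation="Pii", v_saturation="Vii"),
        ),
    )
    stage_g = Stage(
        "G_mortality",
        (
            _with(best, mortality_mode="literature_fixed"),
            _with(best, mortality_mode="fitted"),
        ),
    )
    return StagePlan(
        (stage_a, stage_b, stage_c, stage_d, stage_e, stage_f, stage_g)
    )


def run_stage(
    candidates,
    obs: ObservedDataset,
    config: SMCConfig,
    n_runs: int = 1,
    prior: PriorSpec | None = None,
) -> pd.DataFrame:
    """Repeat a model competition ``n_runs`` times with derived seeds.

    Each run is an independent joint ABC-SMC whose winner is the
    plurality model of the final generation.  Returns one row per
    candidate with win counts and frequencies.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate")
    if prior is None:
        prior = default_prior(candidates)
    wins = np.zeros(len(candidates), dtype=int)
    results = []
    for r in range(n_runs):
        cfg = SMCConfig(
            **{**config.__dict__, "seed": (config.seed + 7919 * r) % (2**31)}
        )
        res = run_abc_smc(candidates, prior, obs, cfg)
        wins[res.winner()] += 1
        results.append(res)
    df = pd.DataFrame(
        {
            "candidate": [c.label for c in candidates],
            "wins": wins,
            "runs": n_runs,
            "win_frequency": wins / n_runs,
        }
    )
    df.attrs["results"] = results
    return df


def run_plan(
    plan: StagePlan,
    obs: ObservedDataset,
    config: SMCConfig,
    n_runs: int = 1,
) -> pd.DataFrame:
    """Run every stage of the ladder; returns the concatenated stage
    tables with the per-stage winner flagged."""
    frames = []
    for stage in plan:
        data = obs if stage.conditions is None else obs.subset(stage.conditions)
        df = run_stage(stage.candidates, data, config, n_runs=n_runs)
        df.insert(0, "stage", stage.name)
        df["winner"] = df["wins"] == df["wins"].max()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def fit_final(
    variant: ModelVariant,
    obs: ObservedDataset,
    config: SMCConfig,
    data_subset: str = "all",
    prior: PriorSpec | None = None,
) -> SMCResult:
    """Fit one variant to all data or to all data except dual predation."""
    if data_subset not in ("all", "exclude_dual"):
        raise ValueError(f"unknown data_subset {data_subset!r}")
    if data_subset == "exclude_dual":
        keep = [c for c in obs.conditions if c != Condition.DUAL.value]
        obs = obs.subset(keep)
    if prior is None:
        prior = default_prior(variant)
    return run_abc_smc([variant], prior, obs, config)


def typical_parameter_set(result: SMCResult, generation: int = -1) -> ParameterSet:
    """PCA medoid of the accepted cloud: a real accepted particle.

    Log-parameters are standardised, projected with PCA, and the
    particle closest (Euclidean, in PC space) to the weighted centroid
    is returned — an objectively "typical" fit that is guaranteed to be
    simulable, unlike a synthetic average.
    """
    gen = result.generations[generation]
    if gen.thetas.shape[0] == 0:
        raise ValueError("empty result: no accepted particles")
    prior = result.prior
    x = gen.thetas.copy()
    lg = prior.is_log()
    x[:, lg] = np.log10(x[:, lg])
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    n_comp = min(z.shape[0], z.shape[1])
    scores = PCA(n_components=n_comp).fit_transform(z) if n_comp > 0 else z
    w = gen.weights / gen.weights.sum()
    centroid = np.average(scores, axis=0, weights=w)
    d2 = np.sum((scores - centroid) ** 2, axis=1)
    best = int(np.argmin(d2))
    return prior.param_set(gen.thetas[best])


@dataclass
class SweepResult:
    """End-state densities and prey-survival flags for 10-fold initial
    density perturbations, one row per population x factor x condition."""

    table: pd.DataFrame
    detection_limit: float

    def survival(self, population: str, factor: float, condition: str) -> bool:
        t = self.table
        row = t[
            (t["population"] == population)
            & (t["factor"] == factor)
            & (t["condition"] == condition)
        ]
        if row.empty:
            raise KeyError((population, factor, condition))
        return bool(row["prey_survives"].iloc[0])


_SWEEP_FIELDS = {"prey": "N0", "bdellovibrio": "P0", "phage": "V0"}


def density_sweep(
    variant: ModelVariant,
    params: ParameterSet,
    design: ExperimentDesign | None = None,
    factors=(0.1, 1.0, 10.0),
) -> SweepResult:
    """Scale each inoculum 10-fold up and down and classify prey survival
    (any prey phenotype at or above the detection limit at the horizon)."""
    design = design or ExperimentDesign()
    times = design.times
    rows = []
    for pop, field_name in _SWEEP_FIELDS.items():
        for factor in factors:
            p = params.replace(**{field_name: getattr(params, field_name) * factor})
            for cond in design.conditions:
                init = initial_state(p, cond, variant)
                traj = simulate(variant, p, init, times)
                end = observables(traj)[-1]
                prey_end = float(end[0])
                rows.append(
                    {
                        "population": pop,
                        "factor": factor,
                        "condition": cond,
                        "prey_end": prey_end,
                        "bdellovibrio_end": float(end[1]),
                        "phage_end": float(end[2]),
                        "prey_survives": prey_end >= design.detection_limit,
                    }
                )
    return SweepResult(pd.DataFrame(rows), design.detection_limit)
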