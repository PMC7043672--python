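"""Likelihood-free inference: ABC with sequential Monte Carlo.

Joint model selection and parameter inference in the style of Toni &
Stumpf: particles are (model index, parameter vector, importance weight)
triples propagated through a decreasing tolerance schedule.  Generation 0
is rejection sampling from the prior at a tolerance set to a quantile of
a pilot sample's distances; later generations resample within a model,
perturb with an adaptive multivariate Gaussian kernel (twice the weighted
empirical covariance of the previous generation, in log space for
log-uniform parameters), and reweight with the usual importance ratio.
A competition "win" is a plurality of final-generation particles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import ObservedDataset, POPULATIONS
from .model import (
    IntegrationError,
    ModelVariant,
    ParameterSet,
    observables,
    simulate_conditions,
)

__all__ = [
    "PriorSpec",
    "Particle",
    "SMCConfig",
    "Generation",
    "SMCResult",
    "distance",
    "sample_prior",
    "perturb",
    "run_abc_smc",
    "default_prior",
]

_FAMILIES = ("loguniform", "uniform")


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter priors plus pinned (fixed) parameters.

    ``free`` maps parameter name -> (family, lower, upper) with family in
    {"loguniform", "uniform"}; ``fixed`` maps name -> value.  Together
    they must cover every field of :class:`ParameterSet` that the model
    variant uses.
    """

    free: dict
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (fam, lo, hi) in self.free.items():
            if fam not in _FAMILIES:
                raise ValueError(f"{name}: unknown family {fam!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name}: bounds must be finite with lower < upper")
            if fam == "loguniform" and lo <= 0:
                raise ValueError(f"{name}: log-uniform needs positive bounds")

    @property
    def names(self) -> tuple:
        return tuple(self.free)

    def is_log(self) -> np.ndarray:
        return np.array([self.free[n][0] == "loguniform" for n in self.names])

    def bounds(self) -> np.ndarray:
        return np.array([[self.free[n][1], self.free[n][2]] for n in self.names])

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(len(self.free))
        for i, n in enumerate(self.names):
            fam, lo, hi = self.free[n]
            if fam == "loguniform":
                out[i] = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            else:
                out[i] = rng.uniform(lo, hi)
        return out

    def in_support(self, theta: np.ndarray) -> bool:
        b = self.bounds()
        return bool(np.all(theta >= b[:, 0]) and np.all(theta <= b[:, 1]))

    def param_set(self, theta: np.ndarray) -> ParameterSet:
        d = dict(self.fixed)
        d.update({n: float(v) for n, v in zip(self.names, theta)})
        return ParameterSet(**d)

    def to_dict(self) -> dict:
        return {"free": {k: list(v) for k, v in self.free.items()},
                "fixed": dict(self.fixed)}


def default_prior(variants=None) -> PriorSpec:
    """Broad log-uniform priors (4 decades for rate constants) centred on
    physically plausible scales; initial densities are pinned to the
    measured inocula and ``sigma_C`` is pinned because only the product
    ``sigma_C * k_sig`` is identifiable (the signal unit is arbitrary).

    When ``variants`` (one or a list of :class:`ModelVariant`) is given,
    parameters that no candidate uses are pinned at their defaults
    instead of fitted, which keeps the particle dimension — and the
    inference problem — as small as the competition allows.
    """
    d = ParameterSet()
    if variants is None:
        variants = [ModelVariant()]
        need = lambda pred: True  # noqa: E731 - fit everything
    else:
        if isinstance(variants, ModelVariant):
            variants = [variants]
        need = lambda pred: any(pred(v) for v in variants)  # noqa: E731
    free = {
        "mu_max": ("loguniform", 0.004, 4.0),
        "K_M": ("loguniform", 5e5, 5e9),
        "a_P": ("loguniform", 0.005, 50.0),
        "a_V": ("loguniform", 2e-12, 2e-8),
        "k_B": ("loguniform", 0.01, 10.0),
        "beta_P": ("loguniform", 1.0, 100.0),
        "k_I": ("loguniform", 0.05, 50.0),
        "beta_V": ("loguniform", 5.0, 2000.0),
        "eps_B": ("uniform", 0.0, 0.95),
        "eps_I": ("uniform", 0.0, 0.95),
        "M0": ("loguniform", 4e6, 4e10),
    }
    fixed = {"sigma_C": d.sigma_C, "N0": d.N0, "P0": d.P0, "V0": d.V0}

    def add(name, spec, used):
        if used:
            free[name] = spec
        else:
            fixed[name] = getattr(d, name)

    add("K_P", ("loguniform", 5e4, 5e8), need(lambda v: v.p_saturation == "Pii"))
    add("K_V", ("loguniform", 1e6, 1e10), need(lambda v: v.v_saturation == "Vii"))
    add("k_sig", ("loguniform", 3e-8, 3e-4), need(lambda v: v.uses_signal))
    add("r_I", ("loguniform", 1e-5, 10.0),
        need(lambda v: v.has_P_type and v.conversion in ("I", "IG")))
    add("r_back", ("loguniform", 1e-5, 10.0),
        need(lambda v: v.has_P_type and v.conversion in ("I", "S")))
    add("m", ("loguniform", 1e-10, 1e-5),
        need(lambda v: v.has_R and v.resistance_origin in ("de_novo", "both")))
    add("f_R", ("loguniform", 1e-8, 1e-4),
        need(lambda v: v.has_R and v.resistance_origin in ("preexisting", "both")))
    add("d_P", ("loguniform", 0.001, 1.0),
        need(lambda v: v.mortality_mode == "fitted"))
    # parameters a variant does not use are pinned at defaults; the RHS
    # ignores them under that variant anyway (e.g. r_I under SG)
    if not need(lambda v: v.has_R and v.resistance_origin in ("de_novo", "both")):
        fixed["m"] = 0.0
    if not need(lambda v: v.has_R and v.resistance_origin in ("preexisting", "both")):
        fixed["f_R"] = 0.0
    return PriorSpec(free=free, fixed=fixed)


@dataclass
class Particle:
    """One candidate in an SMC population."""

    model: int
    theta: np.ndarray
    weight: float = 1.0


@dataclass(frozen=True)
class SMCConfig:
    n_particles: int = 1000
    alpha: float = 0.3              # tolerance = alpha-quantile of last accepted
    max_generations: int = 8
    min_acceptance_rate: float = 0.002
    kernel_factor: float = 1.0      # kernel cov = factor * 2 * weighted cov
    max_proposals_factor: int = 50  # proposal budget per generation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class Generation:
    tolerance: float
    models: np.ndarray        # (n_particles,) model indices
    thetas: np.ndarray        # (n_particles, n_free)
    weights: np.ndarray       # (n_particles,) summing to 1
    distances: np.ndarray
    acceptance_rate: float

    def model_counts(self, n_models: int) -> np.ndarray:
        return np.bincount(self.models, minlength=n_models)


@dataclass
class SMCResult:
    """Weighted posterior particles per generation plus bookkeeping."""

    models: list                    # list of ModelVariant
    prior: PriorSpec
    config: SMCConfig
    generations: list = field(default_factory=list)

    @property
    def final(self) -> Generation:
        return self.generations[-1]

    def model_frequencies(self) -> np.ndarray:
        return self.final.model_counts(len(self.models))

    def winner(self) -> int:
        return int(np.argmax(self.model_frequencies()))

    def tolerances(self) -> list:
        return [g.tolerance for g in self.generations]

    def posterior_df(self, generation: int = -1) -> pd.DataFrame:
        g = self.generations[generation]
        df = pd.DataFrame(g.thetas, columns=list(self.prior.names))
        df.insert(0, "model", g.models)
        df["weight"] = g.weights
        df["distance"] = g.distances
        return df

    def weighted_median(self, name: str, generation: int = -1) -> float:
        g = self.generations[generation]
        i = list(self.prior.names).index(name)
        order = np.argsort(g.thetas[:, i])
        cw = np.cumsum(g.weights[order])
        cw /= cw[-1]
        k = int(np.searchsorted(cw, 0.5))
        return float(g.thetas[order[np.minimum(k, order.size - 1)], i])

    # -- persistence -----------------------------------------------------
    def write(self, stem: Path) -> None:
        stem = Path(stem)
        summary = {
            "config": asdict(self.config),
            "prior": self.prior.to_dict(),
            "models": [m.to_dict() for m in self.models],
            "generations": [
                {
                    "tolerance": g.tolerance,
                    "acceptance_rate": g.acceptance_rate,
                    "model_counts": g.model_counts(len(self.models)).tolist(),
                }
                for g in self.generations
            ],
        }
        stem.with_suffix(".json").write_text(json.dumps(summary, indent=2))
        frames = []
        for t, g in enumerate(self.generations):
            df = pd.DataFrame(g.thetas, columns=list(self.prior.names))
            df.insert(0, "generation", t)
            df.insert(1, "model", g.models)
            df.insert(2, "weight", g.weights)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            stem.with_suffix(".particles.csv"), index=False, float_format="%.17g"
        )


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------


def distance(sim: np.ndarray, obs_log10: np.ndarray, detection_limit: float) -> float:
    """Sum of squared log10 differences over condition x population x time.

    ``sim`` holds simulated (uncensored) densities, ``obs_log10`` the
    observed replicate log10 means with censored replicates entered at
    the detection limit; both are floored at the detection limit so that
    sub-detection disagreement does not count.
    """
    if sim.shape != obs_log10.shape:
        raise ValueError(f"grid mismatch: sim {sim.shape} vs obs {obs_log10.shape}")
    floor = max(detection_limit, 1e-300)
    s = np.log10(np.maximum(sim, floor))
    o = np.maximum(obs_log10, np.log10(floor))
    return float(np.sum((s - o) ** 2))


def dataset_distance(a: ObservedDataset, b: ObservedDataset) -> float:
    """Distance between two datasets (both sides replicate-averaged)."""
    if a.conditions != b.conditions or not np.array_equal(a.times, b.times):
        raise ValueError("datasets must share conditions and time grid")
    lim = max(a.detection_limit, b.detection_limit, 1e-300)
    am = np.maximum(a.log10_means(), np.log10(lim))
    bm = np.maximum(b.log10_means(), np.log10(lim))
    return float(np.sum((am - bm) ** 2))


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


def sample_prior(prior: PriorSpec, models: list, rng: np.random.Generator) -> Particle:
    """Draw a particle from the joint prior (uniform over models)."""
    model = int(rng.integers(len(models)))
    return Particle(model=model, theta=prior.sample(rng), weight=1.0)


def _kernel_chol(prior: PriorSpec, thetas: np.ndarray, weights: np.ndarray,
                 factor: float) -> np.ndarray:
    """Cholesky factor of the kernel covariance: ``factor`` times twice
    the weighted empirical covariance of the source cloud (log10 space
    for log-uniform parameters) — the standard adaptive multivariate
    Gaussian transition for SMC samplers."""
    x = thetas.copy()
    lg = prior.is_log()
    x[:, lg] = np.log10(x[:, lg])
    w = weights / weights.sum()
    mu = np.average(x, axis=0, weights=w)
    xc = x - mu
    cov = (xc * w[:, None]).T @ xc
    cov = factor * 2.0 * cov
    d = cov.shape[0]
    cov[np.diag_indices(d)] += 1e-12 + 1e-12 * np.trace(cov) / max(d, 1)
    return np.linalg.cholesky(cov)


def perturb(
    particle: Particle,
    generation: Generation,
    prior: PriorSpec,
    rng: np.random.Generator,
    kernel_factor: float = 1.0,
    max_tries: int = 1000,
) -> Particle:
    """Multivariate Gaussian-kernel move of one particle; out-of-support
    proposals are redrawn.  The kernel covariance comes from the source
    generation's spread among particles of the same model."""
    sel = generation.models == particle.model
    if not np.any(sel):
        raise ValueError(f"empty source generation for model {particle.model}")
    if kernel_factor == 0.0:
        return Particle(particle.model, particle.theta.copy(), particle.weight)
    L = _kernel_chol(
        prior, generation.thetas[sel], generation.weights[sel], kernel_factor
    )
    return _perturb_fast(particle, L, prior, rng, max_tries)


def _perturb_fast(particle, L, prior, rng, max_tries=1000) -> Particle:
    lg = prior.is_log()
    b = prior.bounds()
    x0 = particle.theta.copy()
    x0[lg] = np.log10(x0[lg])
    lo = b[:, 0].copy()
    hi = b[:, 1].copy()
    lo[lg] = np.log10(lo[lg])
    hi[lg] = np.log10(hi[lg])
    for _ in range(max_tries):
        x = x0 + L @ rng.normal(0.0, 1.0, size=x0.size)
        if np.all(x >= lo) and np.all(x <= hi):
            theta = x.copy()
            theta[lg] = 10 ** theta[lg]
            return Particle(model=particle.model, theta=theta, weight=particle.weight)
    raise RuntimeError("could not draw an in-support perturbation")


# ---------------------------------------------------------------------------
# The SMC loop
# ---------------------------------------------------------------------------


def _make_simulator(models, prior, obs: ObservedDataset):
    """Build sim(model_idx, theta) -> (n_cond, 3, n_times) densities."""
    conditions = obs.conditions
    times = obs.times

    def sim(model_idx: int, theta: np.ndarray) -> np.ndarray:
        params = prior.param_set(theta)
        states = simulate_conditions(models[model_idx], params, conditions, times)
        return np.stack([observables(states[c]).T for c in conditions], axis=0)

    return sim


def _gaussian_weight(theta, prev_thetas, prev_w, L, lg):
    """Importance weight denominator Σ_j w_j K(theta | theta_j) for the
    multivariate Gaussian kernel with Cholesky factor ``L``."""
    from scipy.linalg import solve_triangular

    x = theta.copy()
    x[lg] = np.log10(x[lg])
    xs = prev_thetas.copy()
    xs[:, lg] = np.log10(xs[:, lg])
    z = solve_triangular(L, (x[None, :] - xs).T, lower=True).T
    logk = -0.5 * np.sum(z * z, axis=1)
    logk -= np.sum(np.log(np.diag(L))) + 0.5 * x.size * np.log(2 * np.pi)
    mx = logk.max()
    return float(np.exp(mx) * np.sum(prev_w * np.exp(logk - mx)))


def run_abc_smc(
    models,
    prior: PriorSpec,
    obs: ObservedDataset,
    config: SMCConfig,
    simulator=None,
    dist=None,
    verbose: bool = False,
) -> SMCResult:
    """Joint ABC-SMC over a list of :class:`ModelVariant` candidates.

    ``simulator``/``dist`` may be overridden (used by the engine sanity
    tests with toy problems); by default the ODE model family is
    simulated on the dataset's grid and compared with the log10
    sum-of-squares distance.
    """
    models = list(models)
    rng = np.random.default_rng(config.seed)
    if simulator is None:
        simulator = _make_simulator(models, prior, obs)
    if dist is None:
        obs_log10 = obs.log10_means()
        lim = obs.detection_limit

        def dist(simdata):
            return distance(simdata, obs_log10, lim)

    result = SMCResult(models=models, prior=prior, config=config)
    n = config.n_particles
    budget = config.max_proposals_factor * n
    lg = prior.is_log()

    # --- generation 0: pilot + rejection at the pilot quantile ----------
    pilot_d = np.empty(n)
    pilot_m = np.empty(n, dtype=np.int64)
    pilot_t = np.empty((n, len(prior.names)))
    for i in range(n):
        p = sample_prior(prior, models, rng)
        pilot_m[i] = p.model
        pilot_t[i] = p.theta
        pilot_d[i] = _safe_dist(simulator, dist, p)
    eps = float(np.quantile(pilot_d[np.isfinite(pilot_d)], config.alpha))
    keep = pilot_d <= eps
    acc_m = list(pilot_m[keep])
    acc_t = list(pilot_t[keep])
    acc_d = list(pilot_d[keep])
    tries = n
    while len(acc_m) < n:
        if tries >= budget:
            raise RuntimeError(
                f"generation 0: proposal budget exhausted at tolerance {eps}"
            )
        p = sample_prior(prior, models, rng)
        d = _safe_dist(simulator, dist, p)
        tries += 1
        if d <= eps:
            acc_m.append(p.model)
            acc_t.append(p.theta)
            acc_d.append(d)
    gen = Generation(
        tolerance=eps,
        models=np.array(acc_m[:n]),
        thetas=np.array(acc_t[:n]),
        weights=np.full(n, 1.0 / n),
        distances=np.array(acc_d[:n]),
        acceptance_rate=len(acc_m) / tries,
    )
    result.generations.append(gen)
    if verbose:
        print(f"generation 0: eps={eps:.4g} acc={gen.acceptance_rate:.3f}",
              flush=True)

    # --- generations 1.. ------------------------------------------------
    for _ in range(1, config.max_generations):
        prev = result.generations[-1]
        eps_new = float(np.quantile(prev.distances, config.alpha))
        if eps_new >= prev.tolerance:
            eps_new = prev.tolerance * (1 - 1e-12)
        live = sorted(set(prev.models.tolist()))
        per_model = {}
        for mi in live:
            sel = prev.models == mi
            w = prev.weights[sel]
            wsum = w.sum()
            w = w / wsum if wsum > 0 else np.full(sel.sum(), 1.0 / sel.sum())
            per_model[mi] = (
                prev.thetas[sel],
                w,
                _kernel_chol(prior, prev.thetas[sel], w, config.kernel_factor),
            )
        # model proposal follows the previous generation's weighted
        # marginal (the resampled particle keeps its model), so effort
        # concentrates on models that still hold posterior mass
        model_w = np.array(
            [prev.weights[prev.models == mi].sum() for mi in live]
        )
        model_w = model_w / model_w.sum()
        acc_m, acc_t, acc_d, acc_w = [], [], [], []
        accepted = 0
        tries = 0
        while accepted < n and tries < budget:
            mi = live[int(rng.choice(len(live), p=model_w))]
            thetas_j, w_j, L = per_model[mi]
            src = int(rng.choice(thetas_j.shape[0], p=w_j))
            base = Particle(model=mi, theta=thetas_j[src])
            try:
                prop = _perturb_fast(base, L, prior, rng)
            except RuntimeError:
                tries += 1
                continue
            d = _safe_dist(simulator, dist, prop)
            tries += 1
            if d <= eps_new:
                denom = _gaussian_weight(prop.theta, thetas_j, w_j, L, lg)
                acc_m.append(mi)
                acc_t.append(prop.theta)
                acc_d.append(d)
                acc_w.append(1.0 / denom if denom > 0 else 0.0)
                accepted += 1
        if accepted == 0:
            raise RuntimeError(
                f"zero acceptances at tolerance {eps_new} "
                f"(generation {len(result.generations)})"
            )
        w = np.array(acc_w)
        if w.sum() <= 0:
            w = np.ones(accepted)
        w = w / w.sum()
        gen = Generation(
            tolerance=eps_new,
            models=np.array(acc_m),
            thetas=np.array(acc_t),
            weights=w,
            distances=np.array(acc_d),
            acceptance_rate=accepted / tries,
        )
        result.generations.append(gen)
        if verbose:
            print(
                f"generation {len(result.generations) - 1}: eps={eps_new:.4g} "
                f"acc={gen.acceptance_rate:.3f}", flush=True,
            )
        if accepted < n or gen.acceptance_rate < config.min_acceptance_rate:
            break
    return result


def _safe_dist(simulator, dist, particle: Particle) -> float:
    try:
        return float(dist(simulator(particle.model, particle.theta)))
    except IntegrationError:
        return np.inf
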