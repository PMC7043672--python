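"""Deterministic ODE model family for dual predation of *E. coli*.

A single bacterial prey population is attacked simultaneously by the
periplasmic predator *Bdellovibrio bacteriovorus* and a lytic
bacteriophage.  The model family tracks up to four prey phenotypes

* ``N_S`` — sensitive to both predators,
* ``N_P`` — transiently ("plastically") resistant to *Bdellovibrio*,
* ``N_R`` — genetically resistant to the phage,
* ``N_D`` — doubly resistant,

together with free attack-phase *Bdellovibrio* ``P``, bdelloplasts ``B``
(the intracellular predator stage), free phage virions ``V``, infected
prey ``I``, a recyclable resource pool ``M`` (denominated in prey-cell
equivalents), and a resistance-inducing signal ``C``.

Processes: Monod growth on ``M`` with unit yield; predator attack
(optionally saturating, Holling type II in total susceptible prey);
first-order bdelloplast/infected-cell resolution releasing ``beta``
progeny and ``eps < 1`` cell-equivalents of nutrients; first-order
*Bdellovibrio* mortality; phenotype conversions (signal-driven or
intrinsic forward, growth-coupled or intrinsic back); and Luria–Delbrück
style heritable phage resistance (a preexisting fraction ``f_R`` and/or a
per-division mutation probability ``m``).

Units are hours and per-ml densities throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from numba import njit

__all__ = [
    "COMPARTMENTS",
    "Condition",
    "IntegrationError",
    "ModelVariant",
    "ParameterSet",
    "Trajectory",
    "derivatives",
    "initial_state",
    "observables",
    "simulate",
    "simulate_conditions",
]

# Compartment order used everywhere (state vectors are plain float arrays).
COMPARTMENTS = ("N_S", "N_P", "N_R", "N_D", "P", "B", "V", "I", "M", "C")
_IDX = {name: i for i, name in enumerate(COMPARTMENTS)}
N_COMP = len(COMPARTMENTS)


class Condition(str, enum.Enum):
    """Experimental culture conditions of the predation-kinetics assay."""

    PREY_ONLY = "prey_only"
    BDELLOVIBRIO_ONLY = "bdellovibrio_only"
    PHAGE_ONLY = "phage_only"
    DUAL = "dual"


CONDITIONS = tuple(c.value for c in Condition)


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails (step-size underflow etc.)."""


_PREY_LEVEL = {"N1": 1, "N2": 2, "N3": 3, "N4": 4}
_CONVERSIONS = ("I", "IG", "S", "SG")
_SIGNAL_SOURCES = ("B_only", "V_only", "both")
_ORIGINS = ("preexisting", "de_novo", "both")


@dataclass(frozen=True)
class ModelVariant:
    """Discrete configuration selecting one member of the model family.

    ``conversion`` codes: intrinsic both ways (``I``), intrinsic forward +
    growth-coupled back (``IG``), signal forward + intrinsic back (``S``),
    signal forward + growth-coupled back (``SG``).  ``p_saturation`` /
    ``v_saturation``: ``Pi``/``Vi`` = mass action, ``Pii``/``Vii`` =
    Holling type II.  Fields that only make sense with more prey types
    must be ``None`` otherwise (rejected at construction).
    """

    prey_types: str = "N3"
    conversion: str | None = "SG"
    signal_source: str | None = "B_only"
    resistance_origin: str | None = "both"
    p_saturation: str = "Pii"
    v_saturation: str = "Vi"
    mortality_mode: str = "fitted"

    def __post_init__(self) -> None:
        if self.prey_types not in _PREY_LEVEL:
            raise ValueError(f"unknown prey_types {self.prey_types!r}")
        if self.p_saturation not in ("Pi", "Pii"):
            raise ValueError(f"unknown p_saturation {self.p_saturation!r}")
        if self.v_saturation not in ("Vi", "Vii"):
            raise ValueError(f"unknown v_saturation {self.v_saturation!r}")
        if self.mortality_mode not in ("literature_fixed", "fitted"):
            raise ValueError(f"unknown mortality_mode {self.mortality_mode!r}")
        lvl = _PREY_LEVEL[self.prey_types]
        if lvl >= 3:
            if self.conversion not in _CONVERSIONS:
                raise ValueError(
                    f"prey_types {self.prey_types} needs a conversion mode, "
                    f"got {self.conversion!r}"
                )
            if self.conversion in ("S", "SG"):
                if self.signal_source not in _SIGNAL_SOURCES:
                    raise ValueError(
                        f"signal conversion needs signal_source, got "
                        f"{self.signal_source!r}"
                    )
            # signal_source is ignored (but tolerated) for intrinsic modes
        else:
            if self.conversion is not None or self.signal_source is not None:
                raise ValueError(
                    f"conversion/signal fields are meaningless under "
                    f"{self.prey_types}; pass None"
                )
        if lvl >= 2:
            if self.resistance_origin not in _ORIGINS:
                raise ValueError(
                    f"prey_types {self.prey_types} needs resistance_origin, "
                    f"got {self.resistance_origin!r}"
                )
        elif self.resistance_origin is not None:
            raise ValueError("resistance_origin is meaningless under N1; pass None")

    # -- helpers ---------------------------------------------------------
    @property
    def prey_level(self) -> int:
        return _PREY_LEVEL[self.prey_types]

    @property
    def has_R(self) -> bool:
        return self.prey_level >= 2

    @property
    def has_P_type(self) -> bool:
        return self.prey_level >= 3

    @property
    def has_D(self) -> bool:
        return self.prey_level == 4

    @property
    def uses_signal(self) -> bool:
        return self.has_P_type and self.conversion in ("S", "SG")

    def active_compartments(self) -> tuple[str, ...]:
        out = ["N_S", "P", "B", "V", "I", "M"]
        if self.has_R:
            out.append("N_R")
        if self.has_P_type:
            out.append("N_P")
        if self.has_D:
            out.append("N_D")
        if self.uses_signal:
            out.append("C")
        return tuple(out)

    def flags(self) -> np.ndarray:
        """Encode the variant as the int8 vector the jitted RHS consumes."""
        f = np.zeros(9, dtype=np.int8)
        f[0] = self.prey_level
        if self.has_P_type:
            f[1] = 1 if self.conversion in ("S", "SG") else 0
            f[2] = 1 if self.conversion in ("IG", "SG") else 0
            if self.uses_signal:
                f[3] = 1 if self.signal_source in ("B_only", "both") else 0
                f[4] = 1 if self.signal_source in ("V_only", "both") else 0
        if self.has_R:
            f[5] = 1 if self.resistance_origin in ("preexisting", "both") else 0
            f[6] = 1 if self.resistance_origin in ("de_novo", "both") else 0
        f[7] = 1 if self.p_saturation == "Pii" else 0
        f[8] = 1 if self.v_saturation == "Vii" else 0
        return f

    @property
    def label(self) -> str:
        bits = [self.prey_types]
        if self.has_P_type:
            conv = self.conversion
            if self.uses_signal:
                src = {"B_only": "B", "V_only": "V", "both": ""}[self.signal_source]
                conv = conv[0] + src + conv[1:]  # S -> SB, SG -> SBG etc.
            bits.append(conv)
        bits.append(self.p_saturation)
        bits.append(self.v_saturation)
        label = "-".join(bits)
        if self.has_R and self.resistance_origin != "both":
            label += {"preexisting": "+pre", "de_novo": "+dn"}[self.resistance_origin]
        if self.mortality_mode == "literature_fixed":
            label += "+litdP"
        return label

    def to_dict(self) -> dict:
        return {
            "prey_types": self.prey_types,
            "conversion": self.conversion,
            "signal_source": self.signal_source,
            "resistance_origin": self.resistance_origin,
            "p_saturation": self.p_saturation,
            "v_saturation": self.v_saturation,
            "mortality_mode": self.mortality_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelVariant":
        return cls(**{k: d.get(k) for k in cls.__dataclass_fields__})


# Order of the kinetic parameters in the vector handed to the jitted RHS.
_RHS_PARAMS = (
    "mu_max", "K_M", "a_P", "K_P", "a_V", "K_V", "k_B", "beta_P",
    "k_I", "beta_V", "eps_B", "eps_I", "d_P", "sigma_C", "k_sig",
    "r_I", "r_back", "m",
)


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants, yields and initial-condition parameters.

    Units: rates 1/h; ``a_P``/``a_V`` are ml/h under mass action and the
    maximal per-predator attack rate (1/h) under the saturating forms;
    half-saturations and densities per ml; burst sizes dimensionless;
    ``eps_*`` in prey-cell equivalents per lysis event (< 1).
    """

    mu_max: float = 0.4      # prey max specific growth rate (1/h)
    K_M: float = 5e7         # Monod half-saturation for growth (cell-eq/ml)
    a_P: float = 0.5         # Bdellovibrio attack rate (Pii: 1/h, Pi: ml/h)
    K_P: float = 8e6         # half-saturation of Bdellovibrio attack (cells/ml)
    a_V: float = 2e-10       # phage adsorption rate (Vi: ml/h, Vii: 1/h)
    K_V: float = 1e8         # half-saturation of phage attack (cells/ml, Vii)
    k_B: float = 0.42        # bdelloplast progression-and-lysis rate (1/h)
    beta_P: float = 4.0      # Bdellovibrio burst size (per bdelloplast)
    k_I: float = 1.0         # infected-cell lysis rate (1/h)
    beta_V: float = 100.0    # phage burst size (virions per infected cell)
    eps_B: float = 0.2       # medium released per bdelloplast lysis (cell-eq)
    eps_I: float = 0.4       # medium released per infected-cell lysis (cell-eq)
    d_P: float = 0.06        # free Bdellovibrio mortality (1/h)
    sigma_C: float = 1e-8    # signal produced per predation event (units)
    k_sig: float = 3e-6      # signal-driven conversion constant (ml/(units*h))
    r_I: float = 0.0         # intrinsic forward conversion N_S -> N_P (1/h)
    r_back: float = 0.0      # intrinsic back conversion N_P -> N_S (1/h)
    m: float = 5e-8          # de novo phage-resistance mutation prob./division
    f_R: float = 2.6e-6      # preexisting phage-resistant fraction
    N0: float = 2.9e8        # initial total prey (cells/ml)
    P0: float = 2.8e6        # initial Bdellovibrio (cells/ml)
    V0: float = 3.7e6        # initial phage (virions/ml)
    M0: float = 4e8          # initial medium (cell-equivalents/ml)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        if self.beta_P < 1 or self.beta_V < 1:
            raise ValueError("burst sizes must be >= 1")
        if not 0 <= self.m <= 1:
            raise ValueError("m must lie in [0, 1]")
        if not 0 <= self.f_R <= 1:
            raise ValueError("f_R must lie in [0, 1]")
        if self.eps_B >= 1 or self.eps_I >= 1:
            # lysis debris cannot rebuild a whole prey cell
            raise ValueError("eps_B and eps_I must be < 1 cell equivalent")

    def rhs_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _RHS_PARAMS], dtype=np.float64)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """A simulated time course: ``states[i, j]`` is compartment ``j`` at
    ``times[i]`` in the global :data:`COMPARTMENTS` order."""

    times: np.ndarray
    states: np.ndarray
    variant: ModelVariant
    params: ParameterSet

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, N_COMP):
            raise ValueError("states must be (n_times, n_compartments)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __getitem__(self, compartment: str) -> np.ndarray:
        return self.states[:, _IDX[compartment]]


# ---------------------------------------------------------------------------
# Right-hand side (numba) — one function handles every variant via flags.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rhs(flags, th, y, dy):  # pragma: no cover - exercised via wrappers
    nsys = y.shape[0] // 10
    (mu_max, K_M, a_P, K_P, a_V, K_V, k_B, beta_P, k_I, beta_V,
     eps_B, eps_I, d_P, sigma_C, k_sig, r_I, r_back, m) = (
        th[0], th[1], th[2], th[3], th[4], th[5], th[6], th[7], th[8],
        th[9], th[10], th[11], th[12], th[13], th[14], th[15], th[16], th[17])
    lvl = flags[0]
    has_R = lvl >= 2
    has_P = lvl >= 3
    has_D = lvl >= 4
    for s in range(nsys):
        o = 10 * s
        NS = y[o + 0]
        NP = y[o + 1]
        NR = y[o + 2]
        ND = y[o + 3]
        P = y[o + 4]
        B = y[o + 5]
        V = y[o + 6]
        In = y[o + 7]
        M = y[o + 8]
        C = y[o + 9]

        g = mu_max * M / (K_M + M) if (K_M + M) > 0.0 else 0.0
        G_S = g * NS
        G_R = g * NR if has_R else 0.0
        G_P = g * NP if has_P else 0.0
        G_D = g * ND if has_D else 0.0

        m_S = m if (flags[6] == 1 and has_R) else 0.0
        m_P = m if (flags[6] == 1 and has_D) else 0.0

        conv_f = 0.0
        conv_b = 0.0
        if has_P:
            conv_f = k_sig * C * NS if flags[1] == 1 else r_I * NS
            conv_b = 0.0 if flags[2] == 1 else r_back * NP

        S_sum = NS + (NR if has_R else 0.0)
        if flags[7] == 1:
            fac = a_P * P / (K_P + S_sum) if (K_P + S_sum) > 0.0 else 0.0
        else:
            fac = a_P * P
        attP_S = fac * NS
        attP_R = fac * NR if has_R else 0.0
        attP = attP_S + attP_R

        V_sum = NS + (NP if has_P else 0.0)
        if flags[8] == 1:
            fv = a_V * V / (K_V + V_sum) if (K_V + V_sum) > 0.0 else 0.0
        else:
            fv = a_V * V
        attV_S = fv * NS
        attV_P = fv * NP if has_P else 0.0
        attV = attV_S + attV_P

        lysB = k_B * B
        lysI = k_I * In

        dNS = (1.0 - m_S) * G_S - attP_S - attV_S - conv_f + conv_b
        dNP = 0.0
        if has_P:
            if flags[2] == 1:  # growth-coupled back conversion
                dNS += (1.0 - m_P) * G_P
            else:
                dNP += (1.0 - m_P) * G_P
            dNP += conv_f - conv_b - attV_P
        dNR = (G_R + m_S * G_S - attP_R) if has_R else 0.0
        dND = (G_D + m_P * G_P) if has_D else 0.0
        dP = beta_P * lysB - attP - d_P * P
        dB = attP - lysB
        dV = beta_V * lysI - attV
        dI = attV - lysI
        dM = -(G_S + G_R + G_P + G_D) + eps_B * lysB + eps_I * lysI
        dC = 0.0
        if has_P and flags[1] == 1:
            src = 0.0
            if flags[3] == 1:
                src += attP
            if flags[4] == 1:
                src += attV
            dC = sigma_C * src

        dy[o + 0] = dNS
        dy[o + 1] = dNP
        dy[o + 2] = dNR
        dy[o + 3] = dND
        dy[o + 4] = dP
        dy[o + 5] = dB
        dy[o + 6] = dV
        dy[o + 7] = dI
        dy[o + 8] = dM
        dy[o + 9] = dC


# Dormand-Prince 5(4) coefficients.
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
    [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
])
_DP_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_DP_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                   -92097 / 339200, 187 / 2100, 1 / 40])


@njit(cache=True)
def _integrate(flags, th, y0, t_grid, rtol, atol, max_steps):
    """Adaptive Dormand-Prince 5(4); steps land exactly on grid points.

    Returns (status, states): status 0 = ok, 1 = step underflow,
    2 = step budget exhausted.  States are clamped at zero after each
    accepted step.
    """
    n = y0.size
    nt = t_grid.size
    out = np.zeros((nt, n))
    y = y0.copy()
    for i in range(n):
        if y[i] < 0.0:
            y[i] = 0.0
    out[0] = y
    t = t_grid[0]
    h = 1e-3
    k = np.zeros((7, n))
    ytmp = np.zeros(n)
    gi = 1
    steps = 0
    while gi < nt:
        t_target = t_grid[gi]
        if t + h > t_target:
            h = t_target - t
        # stage evaluations
        _rhs(flags, th, y, k[0])
        for st in range(1, 6):
            for i in range(n):
                acc = 0.0
                for j in range(st):
                    acc += _DP_A[st, j] * k[j, i]
                ytmp[i] = y[i] + h * acc
            _rhs(flags, th, ytmp, k[st])
        # 5th order solution
        for i in range(n):
            acc = 0.0
            for j in range(6):
                acc += _DP_B5[j] * k[j, i]
            ytmp[i] = y[i] + h * acc
        _rhs(flags, th, ytmp, k[6])
        # error estimate
        errnorm = 0.0
        for i in range(n):
            e4 = 0.0
            for j in range(7):
                e4 += (_DP_B5[j] - _DP_B4[j]) * k[j, i]
            e4 *= h
            sc = atol + rtol * max(abs(y[i]), abs(ytmp[i]))
            r = e4 / sc
            errnorm += r * r
        errnorm = math.sqrt(errnorm / n)
        if errnorm <= 1.0:
            t = t + h
            for i in range(n):
                y[i] = ytmp[i] if ytmp[i] > 0.0 else 0.0
            if t >= t_target - 1e-12:
                out[gi] = y
                gi += 1
        if errnorm == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * errnorm ** -0.2
            if fac < 0.2:
                fac = 0.2
            elif fac > 5.0:
                fac = 5.0
        h = h * fac
        if h < 1e-12:
            return 1, out
        steps += 1
        if steps > max_steps:
            return 2, out
    return 0, out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def _check_state(variant: ModelVariant, state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (N_COMP,):
        raise ValueError(f"state must have {N_COMP} compartments")
    if np.any(state < 0):
        bad = COMPARTMENTS[int(np.argmin(state))]
        raise ValueError(f"negative state compartment {bad}")
    active = set(variant.active_compartments())
    for name in COMPARTMENTS:
        if name not in active and state[_IDX[name]] != 0.0:
            raise ValueError(
                f"compartment {name} must be 0 under variant {variant.label}"
            )
    return state


def derivatives(
    variant: ModelVariant, params: ParameterSet, state: np.ndarray
) -> np.ndarray:
    """Instantaneous d/dt of every compartment at ``state``."""
    state = _check_state(variant, state)
    dy = np.zeros(N_COMP)
    _rhs(variant.flags(), params.rhs_vector(), state, dy)
    return dy


def initial_state(
    params: ParameterSet,
    condition: str | Condition,
    variant: ModelVariant | None = None,
) -> np.ndarray:
    """Initial compartment densities for one culture condition.

    A preexisting phage-resistant fraction ``f_R`` of the prey starts in
    ``N_R`` when the variant carries that compartment and its resistance
    origin includes preexisting mutants; otherwise all prey start in
    ``N_S``.
    """
    condition = Condition(condition).value
    if variant is None:
        variant = ModelVariant()
    y0 = np.zeros(N_COMP)
    use_fR = variant.has_R and variant.resistance_origin in ("preexisting", "both")
    fR = params.f_R if use_fR else 0.0
    y0[_IDX["N_S"]] = (1.0 - fR) * params.N0
    y0[_IDX["N_R"]] = fR * params.N0
    y0[_IDX["M"]] = params.M0
    if condition in ("bdellovibrio_only", "dual"):
        y0[_IDX["P"]] = params.P0
    if condition in ("phage_only", "dual"):
        y0[_IDX["V"]] = params.V0
    return y0


def simulate(
    variant: ModelVariant,
    params: ParameterSet,
    init: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    max_steps: int = 2_000_000,
) -> Trajectory:
    """Integrate the model over ``times`` (hours, strictly increasing)."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-d grid")
    init = _check_state(variant, init)
    status, states = _integrate(
        variant.flags(), params.rhs_vector(), init, times, rtol, atol, max_steps
    )
    if status != 0:
        reason = "step-size underflow" if status == 1 else "step budget exhausted"
        raise IntegrationError(
            f"integration failed ({reason}) for variant {variant.label} "
            f"with params {params.to_dict()}"
        )
    states[states < 1e-12] = 0.0
    return Trajectory(times, states, variant, params)


def simulate_conditions(
    variant: ModelVariant,
    params: ParameterSet,
    conditions,
    times: np.ndarray,
    rtol: float = 1e-5,
    atol: float = 1e-2,
    max_steps: int = 8_000,
) -> dict:
    """Integrate several culture conditions in one stacked solver call.

    The conditions share parameters and differ only in initial state, so
    stacking them into one system amortises stepping overhead — the ABC
    machinery calls this hundreds of thousands of times.  Returns
    ``{condition: states}``; accuracy defaults are looser than
    :func:`simulate` because fit distances live on a log10 scale.
    """
    conditions = [Condition(c).value for c in conditions]
    times = np.asarray(times, dtype=float)
    y0 = np.concatenate(
        [initial_state(params, c, variant) for c in conditions]
    )
    status, states = _integrate(
        variant.flags(), params.rhs_vector(), y0, times, rtol, atol, max_steps
    )
    if status != 0:
        reason = "step-size underflow" if status == 1 else "step budget exhausted"
        raise IntegrationError(
            f"integration failed ({reason}) for variant {variant.label} "
            f"conditions {conditions} with params {params.to_dict()}"
        )
    states[states < 1e-12] = 0.0
    return {
        c: states[:, 10 * i: 10 * (i + 1)] for i, c in enumerate(conditions)
    }


def observables(traj_or_states) -> np.ndarray:
    """Experiment-comparable counts: columns (prey CFU, Bd PFU, phage PFU).

    Prey colonies come from every live prey phenotype; a bdelloplast and a
    phage-infected cell each form one plaque just as the free predator
    does, so the plaque counts are ``P + B`` and ``V + I``.
    """
    states = (
        traj_or_states.states
        if isinstance(traj_or_states, Trajectory)
        else np.asarray(traj_or_states, dtype=float)
    )
    prey = states[..., 0] + states[..., 1] + states[..., 2] + states[..., 3]
    bd = states[..., 4] + states[..., 5]
    phage = states[..., 6] + states[..., 7]
    return np.stack([prey, bd, phage], axis=-1)
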