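"""EZ drift-diffusion estimation and Wiener first-passage simulation.

The EZ scheme maps a participant's three go-trial summary statistics —
proportion correct ``Pc``, mean correct RT ``MRT`` (s) and variance of
correct RT ``VRT`` (s^2) — onto the three core diffusion parameters in
closed form:

    L   = logit(Pc)
    v   = sign(Pc - 1/2) * s * [ L * (L*Pc^2 - L*Pc + Pc - 1/2) / VRT ]^(1/4)
    a   = s^2 * L / v
    MDT = (a / 2v) * (1 - y) / (1 + y),   y = exp(-v*a / s^2)
    Ter = MRT - MDT

where ``s`` is the arbitrary within-trial noise scaling (0.1 by
convention).  The model assumes an unbiased starting point (a/2) and no
cross-trial parameter variability, which is what makes the inversion
exact.  :func:`ez_forward` is the analytic inverse and is used throughout
the test-suite as the oracle for the trial-level simulator.

The simulator draws first-passage times of a Wiener process with two
absorbing boundaries by Euler–Maruyama stepping plus a Brownian-bridge
interstep crossing correction (see :func:`simulate_diffusion_trials`).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SCALING",
    "DDMError",
    "InvalidInput",
    "ParametersUndefined",
    "DegenerateParameters",
    "SummaryStats",
    "DDMParameters",
    "SimulatedTrial",
    "DiffusionSample",
    "ez_fit",
    "ez_forward",
    "simulate_diffusion_trials",
    "goodness_of_fit",
    "GOF_QUANTILES",
]

#: Conventional within-trial noise scaling of the diffusion process.
DEFAULT_SCALING = 0.1

#: RT quantiles reported by the goodness-of-fit procedure (fractions).
GOF_QUANTILES = (0.10, 0.30, 0.50, 0.70, 0.90)


class DDMError(ValueError):
    """Base class for diffusion-model estimation errors."""


class InvalidInput(DDMError):
    """Summary statistics or simulator settings outside the valid domain."""


class ParametersUndefined(DDMError):
    """Pc of exactly 0 or 1: the logit diverges and no parameters exist.

    Children at ceiling (100% hit rate) must be excluded upstream rather
    than repaired; edge corrections recover parameters unreliably at the
    40-trial scale this task provides.
    """


class DegenerateParameters(DDMError):
    """Pc of exactly 0.5 (or v = 0): boundary separation is indeterminate."""


@dataclass(frozen=True)
class SummaryStats:
    """Go-trial moments consumed by :func:`ez_fit`.

    Attributes
    ----------
    pc : float
        Proportion correct (hits / go trials), in [0, 1].
    mrt : float
        Mean RT of correct (hit) responses, in seconds.
    vrt : float
        Sample variance of correct-response RT, in seconds^2.
    """

    pc: float
    mrt: float
    vrt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pc <= 1.0:
            raise InvalidInput(f"Pc must lie in [0, 1], got {self.pc}")
        if not self.mrt > 0.0:
            raise InvalidInput(f"MRT must be positive, got {self.mrt}")


@dataclass(frozen=True)
class DDMParameters:
    """Diffusion parameters: drift rate, boundary separation, nondecision time.

    Units follow the s = 0.1 scaling convention with time in seconds:
    ``v`` in evidence units/s, ``a`` in evidence units, ``ter`` in s.
    ``ter`` may be negative when estimated from data (flagged with a
    warning by :func:`ez_fit`, never silently clamped).
    """

    v: float
    a: float
    ter: float
    s: float = DEFAULT_SCALING

    def __post_init__(self) -> None:
        if not self.a > 0.0:
            raise InvalidInput(f"boundary separation must be positive, got {self.a}")
        if not self.s > 0.0:
            raise InvalidInput(f"scaling constant must be positive, got {self.s}")

    def with_scaling(self, s: float) -> "DDMParameters":
        """Re-express the same model under a different noise scaling.

        Multiplying ``s`` by c rescales v and a by c and leaves every
        observable prediction unchanged.
        """
        c = s / self.s
        return replace(self, v=self.v * c, a=self.a * c, s=s)


@dataclass(frozen=True)
class SimulatedTrial:
    """One simulated diffusion trial."""

    absorbed_boundary: str  # "upper" or "lower"
    decision_time: float
    total_rt: float


class DiffusionSample:
    """Array-backed collection of simulated diffusion trials.

    Iterating yields :class:`SimulatedTrial` records; the ``upper``,
    ``decision_time`` and ``total_rt`` arrays give vectorised access.
    """

    def __init__(self, upper: np.ndarray, decision_time: np.ndarray, ter: float):
        self.upper = np.asarray(upper, dtype=bool)
        self.decision_time = np.asarray(decision_time, dtype=float)
        self.total_rt = self.decision_time + ter
        self.ter = float(ter)

    def __len__(self) -> int:
        return self.upper.size

    def __iter__(self):
        for up, dt_, rt in zip(self.upper, self.decision_time, self.total_rt):
            yield SimulatedTrial("upper" if up else "lower", float(dt_), float(rt))

    @property
    def p_upper(self) -> float:
        """Fraction of trials absorbed at the upper (correct) boundary."""
        return float(self.upper.mean())

    def correct_rts(self) -> np.ndarray:
        """Total RTs (s) of upper-boundary trials."""
        return self.total_rt[self.upper]


# ---------------------------------------------------------------------------
# Closed-form estimation
# ---------------------------------------------------------------------------

def ez_fit(stats: SummaryStats, s: float = DEFAULT_SCALING) -> DDMParameters:
    """Estimate (v, a, Ter) from go-trial accuracy and RT moments.

    Parameters
    ----------
    stats
        Summary statistics with ``0 < pc < 1``, ``pc != 0.5`` and
        ``vrt > 0``.
    s
        Within-trial noise scaling constant; 0.1 by convention.

    Returns
    -------
    DDMParameters
        Closed-form estimates.  Below-chance accuracy (pc < 0.5) yields a
        negative drift rate; a negative nondecision time is possible with
        noisy inputs — both are reported with a warning, not repaired.

    Raises
    ------
    ParametersUndefined
        If pc is exactly 0 or 1 (the logit diverges).
    DegenerateParameters
        If pc is exactly 0.5 (zero drift makes ``a`` indeterminate).
    InvalidInput
        If vrt <= 0 or s <= 0.
    """
    if not s > 0.0:
        raise InvalidInput(f"scaling constant must be positive, got {s}")
    pc, mrt, vrt = stats.pc, stats.mrt, stats.vrt
    if pc in (0.0, 1.0):
        raise ParametersUndefined(
            f"Pc = {pc:g} prevents calculation of diffusion parameters; "
            "exclude this participant"
        )
    if pc == 0.5:
        raise DegenerateParameters(
            "Pc = 0.5 implies zero drift; boundary separation is indeterminate"
        )
    if not vrt > 0.0:
        raise InvalidInput(f"VRT must be positive, got {vrt}")

    if pc < 0.5:
        warnings.warn(
            f"below-chance accuracy (Pc = {pc:g}): fitted drift rate is negative",
            stacklevel=2,
        )

    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    v = math.copysign(s * x ** 0.25, pc - 0.5)
    a = s * s * L / v
    y = math.exp(-v * a / (s * s))
    mdt = (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
    ter = mrt - mdt
    if ter < 0.0:
        warnings.warn(
            f"fitted nondecision time is negative (Ter = {ter:.4f} s); "
            "reported as-is",
            stacklevel=2,
        )
    return DDMParameters(v=v, a=a, ter=ter, s=s)


def ez_forward(params: DDMParameters) -> SummaryStats:
    """Predict (Pc, MRT, VRT) from diffusion parameters.

    The unique analytic inverse of :func:`ez_fit`:

        L   = v*a / s^2
        Pc  = 1 / (1 + exp(-L))
        MDT = (a / 2v) * (1 - y) / (1 + y),  y = exp(-L)
        MRT = Ter + MDT
        VRT = s^4 * L * (L*Pc^2 - L*Pc + Pc - 1/2) / v^4

    Raises
    ------
    DegenerateParameters
        If v = 0.
    """
    v, a, ter, s = params.v, params.a, params.ter, params.s
    if v == 0.0:
        raise DegenerateParameters("zero drift has no defined EZ moments")
    L = v * a / (s * s)
    pc = 1.0 / (1.0 + math.exp(-L))
    y = math.exp(-L)
    mdt = (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
    vrt = s ** 4 * L * (L * pc * pc - L * pc + pc - 0.5) / v ** 4
    return SummaryStats(pc=pc, mrt=ter + mdt, vrt=vrt)


def mean_decision_time(params: DDMParameters) -> float:
    """Closed-form mean decision time (s) at the given parameters."""
    v, a, s = params.v, params.a, params.s
    if v == 0.0:
        # Limit of the unbiased process: a^2 / (4 s^2).
        return a * a / (4.0 * s * s)
    y = math.exp(-v * a / (s * s))
    return (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)


# ---------------------------------------------------------------------------
# Trial-level simulation
# ---------------------------------------------------------------------------

def simulate_diffusion_trials(
    params: DDMParameters,
    n_trials: int,
    dt: float = 0.001,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_time: float = 120.0,
) -> DiffusionSample:
    """Simulate first-passage trials of the Wiener process.

    Evidence starts unbiased at a/2 and evolves by Euler–Maruyama steps

        dx = v*dt + s*sqrt(dt)*eps,   eps ~ N(0, 1)

    until absorption at 0 (lower boundary, error/withhold) or a (upper
    boundary, correct response).  Between steps a Brownian-bridge
    correction is applied: even when both endpoints lie inside the
    boundaries, the continuous path crossed the nearer boundary with
    probability exp(-2*d0*d1 / (s^2*dt)) (d0, d1 the endpoint distances
    to that boundary), and such crossings are resolved by an extra
    uniform draw.  This removes the O(sqrt(dt)) absorption bias of naive
    discrete stepping, leaving a residual bias of order dt.

    Parameters
    ----------
    params
        Diffusion parameters; ``ter`` is added to decision times.
    n_trials
        Number of trials (>= 1).
    dt
        Step size in seconds, 0 < dt <= 0.005.
    seed, rng
        Either a seed for a fresh :class:`numpy.random.Generator` or an
        existing generator (exactly one source of randomness is used;
        ``rng`` wins when both are given).
    max_time
        Safety horizon (s); trials still unabsorbed are forced to the
        nearer boundary (astronomically rare at task-scale parameters).

    Returns
    -------
    DiffusionSample
    """
    if not isinstance(n_trials, (int, np.integer)) or n_trials < 1:
        raise InvalidInput(f"n_trials must be a positive integer, got {n_trials}")
    if not 0.0 < dt <= 0.005:
        raise InvalidInput(f"dt must lie in (0, 0.005], got {dt}")
    if rng is None:
        rng = np.random.default_rng(seed)

    v, a, s = params.v, params.a, params.s
    drift = v * dt
    diff_sd = s * math.sqrt(dt)
    two_over_s2dt = 2.0 / (s * s * dt)
    max_steps = int(math.ceil(max_time / dt))

    x = np.full(n_trials, a / 2.0)
    decision_time = np.zeros(n_trials)
    upper = np.zeros(n_trials, dtype=bool)
    active = np.arange(n_trials)

    step = 0
    while active.size:
        step += 1
        xo = x[active]
        xn = xo + drift + diff_sd * rng.standard_normal(active.size)

        hit_up = xn >= a
        hit_lo = xn <= 0.0

        interior = ~(hit_up | hit_lo)
        if interior.any():
            xi_o = xo[interior]
            xi_n = xn[interior]
            # Bridge crossing probabilities for each boundary.
            with np.errstate(under="ignore"):
                p_up = np.exp(-two_over_s2dt * (a - xi_o) * (a - xi_n))
                p_lo = np.exp(-two_over_s2dt * xi_o * xi_n)
            u = rng.random(xi_o.size)
            bridged_up = u < p_up
            bridged_lo = (~bridged_up) & (u < p_up + p_lo)
            hit_up[interior] |= bridged_up
            hit_lo[interior] |= bridged_lo

        done = hit_up | hit_lo
        if done.any():
            idx = active[done]
            decision_time[idx] = step * dt
            upper[active[hit_up]] = True
            active = active[~done]
            xn = xn[~done]
        x[active] = xn

        if step >= max_steps and active.size:
            decision_time[active] = step * dt
            upper[active] = x[active] >= a / 2.0
            break

    return DiffusionSample(upper, decision_time, params.ter)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def goodness_of_fit(
    cohort: pd.DataFrame,
    n_trials: int = 1000,
    seed: int | None = None,
    dt: float = 0.001,
    s: float = DEFAULT_SCALING,
) -> pd.DataFrame:
    """Group-averaged supersubject goodness-of-fit summary.

    For each group the fitted parameters are arithmetically averaged
    across children, a single supersubject of ``n_trials`` diffusion
    trials is simulated at the averaged parameters, and its accuracy,
    mean correct RT and correct-RT quantiles are tabulated beside the
    observed group means.

    Parameters
    ----------
    cohort
        One row per child with columns ``group``, ``v``, ``a``, ``ter``
        and (optionally) observed ``hit_rate_pct`` and ``mrt_ms``.
    n_trials
        Supersubject trials per group (1,000 by default).
    seed
        Master seed; each group gets an independent child stream.
    dt
        Simulator step size (s).
    s
        Noise scaling the parameters were fitted under.

    Returns
    -------
    pandas.DataFrame
        One row per group: n_children, mean parameters, simulated
        accuracy (%) and mean correct RT (ms), observed analogues, and
        simulated correct-RT quantiles (ms) at 10/30/50/70/90%.
    """
    required = {"group", "v", "a", "ter"}
    missing = required - set(cohort.columns)
    if missing:
        raise InvalidInput(f"cohort table lacks columns: {sorted(missing)}")

    rows = []
    groups = sorted(cohort["group"].unique())
    streams = np.random.SeedSequence(seed).spawn(len(groups))
    for grp, ss in zip(groups, streams):
        sub = cohort[cohort["group"] == grp]
        if sub.empty:
            raise InvalidInput(f"group {grp!r} has no children")
        mean_params = DDMParameters(
            v=float(sub["v"].mean()),
            a=float(sub["a"].mean()),
            ter=float(sub["ter"].mean()),
            s=s,
        )
        sample = simulate_diffusion_trials(
            mean_params, n_trials, dt=dt, rng=np.random.default_rng(ss)
        )
        correct_ms = sample.correct_rts() * 1000.0
        row = {
            "group": grp,
            "n_children": int(len(sub)),
            "mean_v": mean_params.v,
            "mean_a": mean_params.a,
            "mean_ter": mean_params.ter,
            "sim_accuracy_pct": 100.0 * sample.p_upper,
            "sim_mrt_ms": float(correct_ms.mean()) if correct_ms.size else math.nan,
        }
        row["obs_accuracy_pct"] = (
            float(sub["hit_rate_pct"].mean()) if "hit_rate_pct" in sub else math.nan
        )
        row["obs_mrt_ms"] = float(sub["mrt_ms"].mean()) if "mrt_ms" in sub else math.nan
        for q in GOF_QUANTILES:
            row[f"q{int(q * 100)}"] = (
                float(np.quantile(correct_ms, q)) if correct_ms.size else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
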