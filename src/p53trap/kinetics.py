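"""Kinetic model of bifunctional-compound trapping by an abundant target protein.

A membrane-permeable bifunctional molecule equilibrates between an extracellular
reservoir (held at constant concentration ``M_A``) and the cytosol (``M_B``) by
first-order diffusion, and is sequestered intracellularly by reversible binding
to a target protein ``P`` that is continuously produced and degraded with
first-order kinetics (half-life ``t_half``).  Because the bound complex ``MP``
is degraded together with the protein, slowly degraded (e.g. missense-mutant
p53) targets trap far more compound at steady state than rapidly turned-over
wild-type protein — the quantitative basis for abundance-selective cytotoxicity.

State variables (molar):

====  ======================================================
M_A   free compound outside the cell (constant by assumption)
M_B   free compound inside the cell
P     free target protein
MP    compound-target complex
====  ======================================================

Rate equations::

    dM_A/dt = 0
    dM_B/dt = -k_diff*M_B + k_diff*M_A - k_bind*M_B*P + k_unbind*MP
    dMP/dt  =  k_bind*M_B*P - k_unbind*MP - MP*ln2/t_half
    dP/dt   = -k_bind*M_B*P + k_unbind*MP - P*ln2/t_half + r_prod

The production rate ``r_prod`` is calibrated once from a reference steady
state (``P_ss_ref`` at ``t_half_ref``) and held fixed across all simulated
half-lives, so that varying ``t_half`` varies the steady-state protein pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

LN2 = math.log(2.0)

#: seconds per hour / minute, for callers working in human units
HOUR = 3600.0
MINUTE = 60.0

#: default integration endpoint (600 h), long enough that even a 48 h
#: half-life protein pool has relaxed to well under 0.1% of steady state
T_END_DEFAULT = 600.0 * HOUR

#: solver tolerances: concentrations span pM-uM and the system is stiff
#: (k_diff = 1e3 /s against hour-scale turnover), so an implicit method
#: with a tight absolute floor is required
RTOL = 1e-8
ATOL = 1e-15


class KineticsError(ValueError):
    """Invalid kinetic parameters or an inadmissible steady state."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the solver's diagnostic message."""


def calibrate_production_rate(P_ss_ref: float, t_half_ref: float) -> float:
    """Production rate (M/s) balancing first-order decay at a reference steady state.

    Setting dP/dt = 0 for an unliganded protein gives
    ``r_prod = P_ss_ref * ln2 / t_half_ref``.  The rate is calibrated at the
    reference half-life and then reused unchanged for every simulated
    half-life, so the steady-state protein pool scales with t_half.
    """
    if t_half_ref <= 0:
        raise KineticsError(f"t_half_ref must be positive, got {t_half_ref}")
    if P_ss_ref < 0:
        raise KineticsError(f"P_ss_ref must be non-negative, got {P_ss_ref}")
    return P_ss_ref * LN2 / t_half_ref


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and initial conditions, in seconds and molar.

    Defaults are the published constants for a pharmaceutically optimized
    p53 binder: k_diff = 1e3 /s, k_bind = 8.7e5 /M/s, k_unbind = 1e-6 /s,
    initial protein 1 uM, production calibrated at a 24 h reference
    half-life so that the 24 h steady-state pool is 1 uM.
    """

    k_diff: float = 1.0e3
    k_bind: float = 8.7e5
    k_unbind: float = 1.0e-6
    t_half: float = 24.0 * HOUR
    M_A0: float = 1.0e-10
    P0: float = 1.0e-6
    t_half_ref: float = 24.0 * HOUR
    P_ss_ref: float = 1.0e-6
    r_prod: float | None = None  # None -> calibrated from the reference pair

    def __post_init__(self) -> None:
        for name in ("k_diff", "k_bind", "k_unbind", "M_A0", "P0", "P_ss_ref"):
            if getattr(self, name) < 0:
                raise KineticsError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not self.t_half > 0:
            raise KineticsError(f"t_half must be positive, got {self.t_half}")
        if not self.t_half_ref > 0:
            raise KineticsError(f"t_half_ref must be positive, got {self.t_half_ref}")
        if self.r_prod is None:
            object.__setattr__(
                self, "r_prod", calibrate_production_rate(self.P_ss_ref, self.t_half_ref)
            )
        elif self.r_prod < 0:
            raise KineticsError(f"r_prod must be non-negative, got {self.r_prod}")

    def with_(self, **kwargs) -> "KineticParameters":
        """Copy with fields replaced (r_prod recalibrated unless given)."""
        if "r_prod" not in kwargs and not {"P_ss_ref", "t_half_ref"}.isdisjoint(kwargs):
            kwargs.setdefault("r_prod", None)
        return replace(self, **kwargs)

    @property
    def lam(self) -> float:
        """First-order degradation rate ln2/t_half (1/s)."""
        return LN2 / self.t_half

    def initial_state(self) -> np.ndarray:
        """(M_A0, 0, P0, 0): compound outside only, protein unliganded."""
        return np.array([self.M_A0, 0.0, self.P0, 0.0])


# state vector component indices
I_MA, I_MB, I_P, I_MP = 0, 1, 2, 3
STATE_NAMES = ("M_A", "M_B", "P", "MP")


def derivatives(state: Sequence[float], params: KineticParameters) -> np.ndarray:
    """Evaluate the four rate equations at ``state`` (M/s per component)."""
    M_A, M_B, P, MP = state
    lam = params.lam
    bind = params.k_bind * M_B * P
    unbind = params.k_unbind * MP
    dM_A = 0.0
    dM_B = -params.k_diff * M_B + params.k_diff * M_A - bind + unbind
    dMP = bind - unbind - MP * lam
    dP = -bind + unbind - P * lam + params.r_prod
    return np.array([dM_A, dM_B, dP, dMP])


def _jacobian(state: np.ndarray, params: KineticParameters) -> np.ndarray:
    """Analytic Jacobian in state order (M_A, M_B, P, MP)."""
    _, M_B, P, MP = state
    kb, ku, kd, lam = params.k_bind, params.k_unbind, params.k_diff, params.lam
    return np.array(
        [
            [0.0, 0.0, 0.0, 0.0],
            [kd, -kd - kb * P, -kb * M_B, ku],
            [0.0, -kb * P, -kb * M_B - lam, ku],
            [0.0, kb * P, kb * M_B, -ku - lam],
        ]
    )


@dataclass(frozen=True)
class Trajectory:
    """Solver output: state time course plus the parameters that produced it."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 4), columns M_A, M_B, P, MP
    params: KineticParameters

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    @property
    def intracellular_total(self) -> np.ndarray:
        """M_B + MP over time — the quantity trapping acts on."""
        return self.states[:, I_MB] + self.states[:, I_MP]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.states, columns=list(STATE_NAMES)).assign(
            time_s=self.times
        )[["time_s", *STATE_NAMES]]


def simulate(
    params: KineticParameters,
    t_end: float = T_END_DEFAULT,
    n_out: int = 200,
) -> Trajectory:
    """Integrate the model from the initial state to ``t_end`` seconds.

    Uses the implicit BDF method with an analytic Jacobian (the system is
    stiff). Output times are log-spaced between 1 s and t_end, prepended with
    t = 0; the final state is the integrator endpoint, not an interpolation.

    Raises :class:`IntegrationError` if the solver does not converge.
    """
    if t_end <= 0:
        raise KineticsError(f"t_end must be positive, got {t_end}")
    if n_out < 2:
        raise KineticsError(f"n_out must be >= 2, got {n_out}")
    t_eval = np.concatenate([[0.0], np.geomspace(min(1.0, t_end / 2), t_end, n_out - 1)])
    sol = solve_ivp(
        lambda t, y: derivatives(y, params),
        (0.0, t_end),
        params.initial_state(),
        method="BDF",
        jac=lambda t, y: _jacobian(y, params),
        rtol=RTOL,
        atol=ATOL,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed for params={params!r}: {sol.message}"
        )
    states = np.clip(sol.y.T, 0.0, None)  # clamp solver noise below atol
    return Trajectory(times=sol.t, states=states, params=params)


def steady_state_closed_form(params: KineticParameters) -> np.ndarray:
    """Analytic steady state (M_A, M_B, P, MP), the unique admissible root.

    Setting the derivatives to zero gives, with lam = ln2/t_half:

    * total protein: ``P + MP = r_prod/lam``  (production balances decay)
    * complex balance: ``k_bind*M_B*P = MP*(k_unbind + lam)``
    * diffusion balance: ``M_B = M_A0 - MP*lam/k_diff``

    which reduce to a quadratic in MP; the root with
    ``0 <= MP <= r_prod/lam`` and ``M_B >= 0`` is returned and checked by
    evaluating the derivatives.

    Raises :class:`KineticsError` if no admissible root exists (e.g. a
    nonzero protein pool with zero degradation has no steady state).
    """
    M_A = params.M_A0
    lam = params.lam
    P_tot = params.r_prod / lam
    if params.k_bind == 0.0 or M_A == 0.0 or P_tot == 0.0:
        # no binding flux: compound equilibrates by diffusion alone
        return np.array([M_A, M_A, P_tot, 0.0])
    a = lam / params.k_diff
    # k_bind*a*MP^2 - (k_bind*(M_A + a*P_tot) + k_unbind + lam)*MP + k_bind*M_A*P_tot = 0
    qa = params.k_bind * a
    qb = -(params.k_bind * (M_A + a * P_tot) + params.k_unbind + lam)
    qc = params.k_bind * M_A * P_tot
    # numerically stable quadratic roots (qb < 0 always)
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0:
        raise KineticsError("no real steady-state root for these parameters")
    q = -0.5 * (qb - math.sqrt(disc))
    roots = sorted({q / qa, qc / q})
    for MP in roots:
        M_B = M_A - a * MP
        P = P_tot - MP
        if -1e-12 * P_tot <= MP <= P_tot * (1 + 1e-12) and M_B >= -1e-12 * M_A:
            state = np.array([M_A, max(M_B, 0.0), max(P, 0.0), max(MP, 0.0)])
            resid = derivatives(state, params)[1:]
            scale = max(abs(params.r_prod), params.k_diff * max(M_A, 1e-300))
            if np.all(np.abs(resid) <= 1e-6 * scale + 1e-18):
                return state
    raise KineticsError(
        f"no admissible steady-state root (candidates {roots}) for params={params!r}"
    )


def accumulation_fold(trajectory: Trajectory) -> float:
    """Final (M_B + MP)/M_A — intracellular enrichment over the reservoir."""
    final = trajectory.final_state
    if final[I_MA] <= 0:
        raise KineticsError("accumulation fold undefined: extracellular compound is zero")
    return float((final[I_MB] + final[I_MP]) / final[I_MA])


@dataclass(frozen=True)
class SweepResult:
    """Grid evaluation of final intracellular compound over (t_half, dose).

    ``intracellular_final[i, j]`` is final M_B + MP for ``half_lives[i]`` at
    dose ``doses[j]``; ``accumulation_fold`` is the same divided by the dose.
    """

    half_lives: np.ndarray
    doses: np.ndarray
    intracellular_final: np.ndarray
    accumulation_fold: np.ndarray
    params: KineticParameters = field(repr=False, default=None)

    def to_frame(self):
        import pandas as pd

        hh, dd = np.meshgrid(self.half_lives, self.doses, indexing="ij")
        return pd.DataFrame(
            {
                "t_half_s": hh.ravel(),
                "dose_M": dd.ravel(),
                "intracellular_M": self.intracellular_final.ravel(),
                "fold": self.accumulation_fold.ravel(),
            }
        )


def sweep_halflife_dose(
    params: KineticParameters,
    half_lives: Sequence[float],
    doses: Sequence[float],
    t_end: float = T_END_DEFAULT,
) -> SweepResult:
    """Simulate every (t_half, dose) pair with r_prod fixed at the reference calibration.

    The production rate is NOT recalibrated per half-life: a longer-lived
    protein therefore accumulates to a proportionally larger steady-state
    pool, which is what drives differential compound trapping.
    """
    half_lives = np.asarray(half_lives, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if half_lives.size == 0 or doses.size == 0:
        raise KineticsError("sweep grids must be non-empty")
    if np.any(half_lives <= 0) or np.any(doses <= 0):
        raise KineticsError("sweep grids must be positive")
    r_prod = calibrate_production_rate(params.P_ss_ref, params.t_half_ref)
    intra = np.empty((half_lives.size, doses.size))
    fold = np.empty_like(intra)
    for i, th in enumerate(half_lives):
        for j, dose in enumerate(doses):
            p = params.with_(t_half=float(th), M_A0=float(dose), r_prod=r_prod)
            try:
                traj = simulate(p, t_end=t_end)
            except IntegrationError as exc:
                raise IntegrationError(
                    f"sweep cell (t_half={th} s, dose={dose} M) failed: {exc}"
                ) from exc
            final = traj.final_state
            intra[i, j] = final[I_MB] + final[I_MP]
            fold[i, j] = intra[i, j] / dose
    return SweepResult(
        half_lives=half_lives,
        doses=doses,
        intracellular_final=intra,
        accumulation_fold=fold,
        params=params,
    )
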