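"""The equation of change: least-time free-energy consumption.

Every transformation r carries an event rate linear in its affinity,

    v_r = sigma_r * A_r / kT,        A_r = -dmu_r + deltaQ_r,

and populations evolve as dN/dt = S v with S the net stoichiometric matrix.
The dissipated power is

    T dS/dt = sum_r v_r A_r = sum_r sigma_r A_r^2 / kT >= 0,

so entropy accumulated along a trajectory is non-decreasing by construction;
it vanishes exactly at thermodynamic balance, where every affinity is zero.

Integration is carried out in reaction-extent space, N(t) = N0 + S xi(t).
Because the columns of S are elementally balanced integers, the closed-system
matter total sum_j c_j N_j is conserved to float rounding regardless of
integrator error.  Near extinction, populations entering logarithms are
clipped at a hard floor (default 1e-12); the logarithmic divergence of the
chemical potential then drives the flux back toward positive populations, so
the floor is an inert guard in well-posed systems.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .diagram import SystemSpec, SystemState
from .statmech import system_entropy

__all__ = [
    "Trajectory",
    "SteadyStateReport",
    "DriveSchedule",
    "IntegrationError",
    "UnsupportedCaseError",
    "population_rates",
    "power",
    "evolve",
    "euler_evolve",
    "detect_steady_state",
    "stationary_ratio",
    "conserved_matter",
]

POPULATION_FLOOR = 1e-12


class IntegrationError(RuntimeError):
    """Integrator failure; carries whatever partial trajectory exists."""

    def __init__(self, message: str, partial: "Trajectory | None" = None):
        super().__init__(message)
        self.partial = partial


class UnsupportedCaseError(ValueError):
    """Closed-form result requested for a case it does not cover."""


@dataclass(frozen=True)
class DriveSchedule:
    """Time-periodic quantum coupling on one transformation.

    The effective coupling is deltaQ(t) = base + amplitude*sin(2 pi t/period
    + phase), with ``base`` the spec's static deltaQ.  Amplitude is in the
    same energy units as kT; zero amplitude reproduces the undriven system
    bit-for-bit.
    """

    transformation: int = 0
    amplitude: float = 0.0
    period: float = 1.0
    phase: float = 0.0

    def deltaQ_offset(self, t: float) -> float:
        return self.amplitude * math.sin(2.0 * math.pi * t / self.period + self.phase)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "transformation": self.transformation,
                    "amplitude": self.amplitude,
                    "period": self.period,
                    "phase": self.phase,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "DriveSchedule":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)


@dataclass
class Trajectory:
    """Time series of states with derived thermodynamic series.

    ``states`` is (time x species); ``affinity_series`` (time x
    transformation).  ``entropy_series`` is the free-energy-consumption
    entropy: the affinity-mode state value at t0 plus the cumulative
    integral of power/T, hence exactly non-decreasing.
    """

    times: np.ndarray
    states: np.ndarray
    entropy_series: np.ndarray
    power_series: np.ndarray
    affinity_series: np.ndarray
    species_ids: list[str]
    extents: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> SystemState:
        return SystemState(self.states[i].copy(), float(self.times[i]))

    def final_state(self) -> SystemState:
        return self.state_at(self.n_samples - 1)

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times}
        for j, sid in enumerate(self.species_ids):
            data[f"N_{sid}"] = self.states[:, j]
        data["S"] = self.entropy_series
        data["TdS_dt"] = self.power_series
        for r in range(self.affinity_series.shape[1]):
            data[f"A_{r}"] = self.affinity_series[:, r]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        # default float formatting is repr-based, so re-import is bit exact
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        if "time" not in df.columns:
            raise ValueError(f"trajectory file {path} has no 'time' column")
        species_ids = [c[2:] for c in df.columns if c.startswith("N_")]
        if not species_ids:
            raise ValueError(f"trajectory file {path} has no population columns (N_<id>)")
        a_cols = sorted(
            (c for c in df.columns if c.startswith("A_")), key=lambda c: int(c[2:])
        )
        n = len(df)
        return cls(
            times=df["time"].to_numpy(),
            states=df[[f"N_{sid}" for sid in species_ids]].to_numpy(),
            entropy_series=df["S"].to_numpy() if "S" in df else np.full(n, np.nan),
            power_series=df["TdS_dt"].to_numpy() if "TdS_dt" in df else np.full(n, np.nan),
            affinity_series=(
                df[a_cols].to_numpy() if a_cols else np.zeros((n, 0))
            ),
            species_ids=species_ids,
        )


@dataclass
class SteadyStateReport:
    """Verdict on whether a trajectory reached thermodynamic balance."""

    converged: bool
    time_reached: float | None
    final_affinities: np.ndarray
    final_power: float
    tolerance: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "converged": bool(self.converged),
                    "time_reached": None if self.time_reached is None else float(self.time_reached),
                    "final_affinities": [float(a) for a in self.final_affinities],
                    "final_power": float(self.final_power),
                    "tolerance": float(self.tolerance),
                },
                fh,
                indent=2,
            )


def _sigma(spec: SystemSpec) -> np.ndarray:
    return np.array([tr.sigma for tr in spec.transformations])


def _static_deltaQ(spec: SystemSpec) -> np.ndarray:
    return np.array([tr.deltaQ for tr in spec.transformations])


def _affinity_vector(
    N: np.ndarray,
    G: np.ndarray,
    S_mat: np.ndarray,
    deltaQ: np.ndarray,
    kT: float,
    floor: float,
) -> np.ndarray:
    mu = G + kT * np.log(np.maximum(N, floor))
    return deltaQ - S_mat.T @ mu


def population_rates(
    state: SystemState,
    spec: SystemSpec,
    floor: float = POPULATION_FLOOR,
    drive: DriveSchedule | None = None,
) -> np.ndarray:
    """dN_j/dt = sum_r S_jr sigma_r A_r / kT at the given state.

    Populations at or below the floor are clipped before the logarithm; the
    resulting finite potential keeps extinct substrates from being driven
    negative (their consumption channel has strongly negative affinity, i.e.
    runs in reverse, replenishing them).
    """
    S_mat = spec.stoichiometry()
    deltaQ = _static_deltaQ(spec)
    if drive is not None:
        deltaQ = deltaQ.copy()
        deltaQ[drive.transformation] += drive.deltaQ_offset(state.time)
    A = _affinity_vector(
        np.asarray(state.populations, float), spec.energies(), S_mat, deltaQ, spec.kT, floor
    )
    v = _sigma(spec) * A / spec.kT
    return S_mat @ v


def power(
    state: SystemState,
    spec: SystemSpec,
    floor: float = POPULATION_FLOOR,
    drive: DriveSchedule | None = None,
) -> float:
    """Dissipated power T dS/dt = sum_r sigma_r A_r^2 / kT (never negative)."""
    S_mat = spec.stoichiometry()
    deltaQ = _static_deltaQ(spec)
    if drive is not None:
        deltaQ = deltaQ.copy()
        deltaQ[drive.transformation] += drive.deltaQ_offset(state.time)
    A = _affinity_vector(
        np.asarray(state.populations, float), spec.energies(), S_mat, deltaQ, spec.kT, floor
    )
    return float(np.sum(_sigma(spec) * A * A) / spec.kT)


def evolve(
    spec: SystemSpec,
    t_end: float,
    *,
    n_samples: int = 500,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    floor: float = POPULATION_FLOOR,
    drive: DriveSchedule | None = None,
    sigma_rule: Callable[[float, np.ndarray], np.ndarray] | None = None,
) -> Trajectory:
    """Integrate the rate law from the spec's initial state to ``t_end``.

    Integration is in reaction-extent space (conserves elemental matter to
    rounding).  ``sigma_rule(t, N) -> sigma vector`` optionally replaces the
    constant conductances with an evolving mechanism.  Returns a Trajectory
    sampled at ``t_eval`` (default: ``n_samples`` uniform points including
    t = 0).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    S_mat = spec.stoichiometry()
    G = spec.energies()
    kT = spec.kT
    N0 = spec.initial_state().populations
    sigma0 = _sigma(spec)
    deltaQ0 = _static_deltaQ(spec)
    nR = spec.n_transformations

    def dQ_at(t: float) -> np.ndarray:
        if drive is None:
            return deltaQ0
        dq = deltaQ0.copy()
        dq[drive.transformation] += drive.deltaQ_offset(t)
        return dq

    def rhs(t, xi):
        N = N0 + S_mat @ xi
        A = _affinity_vector(N, G, S_mat, dQ_at(t), kT, floor)
        sigma = sigma_rule(t, N) if sigma_rule is not None else sigma0
        return sigma * A / kT

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_samples)
    else:
        t_eval = np.asarray(t_eval, dtype=float)

    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        np.zeros(nR),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    times = sol.t
    extents = sol.y.T
    states = np.maximum(N0[None, :] + extents @ S_mat.T, 0.0)

    n = len(times)
    aff = np.empty((n, nR))
    pw = np.empty(n)
    for i in range(n):
        A = _affinity_vector(states[i], G, S_mat, dQ_at(times[i]), kT, floor)
        sigma = sigma_rule(times[i], states[i]) if sigma_rule is not None else sigma0
        aff[i] = A
        pw[i] = float(np.sum(sigma * A * A) / kT)

    S0 = system_entropy(SystemState(states[0], float(times[0])), spec, mode="affinity")
    # equation-of-change entropy: accumulate T dS/dt = power; exactly monotone
    dS = np.zeros(n)
    if n > 1:
        dt = np.diff(times)
        dS[1:] = np.cumsum(0.5 * (pw[1:] + pw[:-1]) * dt) / kT
    entropy = S0 + dS

    traj = Trajectory(
        times=times,
        states=states,
        entropy_series=entropy,
        power_series=pw,
        affinity_series=aff,
        species_ids=spec.species_ids,
        extents=extents,
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}", partial=traj)
    return traj


def euler_evolve(
    spec: SystemSpec,
    t_end: float,
    dt: float,
    *,
    sample_every: int = 1000,
    floor: float = POPULATION_FLOOR,
) -> Trajectory:
    """Fixed-step explicit Euler reference integrator.

    Deliberately naive and structurally independent of :func:`evolve`: it
    steps populations directly (not extents) with a constant step.  Used as
    a brute-force oracle for the adaptive integrator on small systems.
    """
    S_mat = spec.stoichiometry()
    G = spec.energies()
    kT = spec.kT
    sigma = _sigma(spec)
    deltaQ = _static_deltaQ(spec)
    N = spec.initial_state().populations.copy()
    n_steps = int(round(t_end / dt))
    times = [0.0]
    samples = [N.copy()]
    ST = S_mat.T
    for step in range(1, n_steps + 1):
        mu = G + kT * np.log(np.maximum(N, floor))
        A = deltaQ - ST @ mu
        N = N + dt * (S_mat @ (sigma * A / kT))
        np.maximum(N, 0.0, out=N)
        if step % sample_every == 0 or step == n_steps:
            times.append(step * dt)
            samples.append(N.copy())
    times = np.array(times)
    states = np.array(samples)
    n = len(times)
    aff = np.empty((n, spec.n_transformations))
    pw = np.empty(n)
    for i in range(n):
        A = _affinity_vector(states[i], G, S_mat, deltaQ, kT, floor)
        aff[i] = A
        pw[i] = float(np.sum(sigma * A * A) / kT)
    S0 = system_entropy(SystemState(states[0], 0.0), spec, mode="affinity")
    dS = np.zeros(n)
    if n > 1:
        dtv = np.diff(times)
        dS[1:] = np.cumsum(0.5 * (pw[1:] + pw[:-1]) * dtv) / kT
    return Trajectory(
        times=times,
        states=states,
        entropy_series=S0 + dS,
        power_series=pw,
        affinity_series=aff,
        species_ids=spec.species_ids,
    )


def detect_steady_state(
    trajectory: Trajectory,
    spec: SystemSpec,
    tolerance: float = 1e-6,
) -> SteadyStateReport:
    """Find the first stored time from which balance holds to the end.

    Balance requires BOTH the power and every |affinity| at or below the
    tolerance (power alone can vanish while a zero-conductance channel still
    holds free energy).
    """
    if trajectory.n_samples == 0:
        raise ValueError("empty trajectory")
    ok = (trajectory.power_series <= tolerance) & (
        np.max(np.abs(trajectory.affinity_series), axis=1) <= tolerance
        if trajectory.affinity_series.size
        else np.ones(trajectory.n_samples, bool)
    )
    final_aff = trajectory.affinity_series[-1] if trajectory.affinity_series.size else np.zeros(0)
    final_power = float(trajectory.power_series[-1])
    converged = bool(ok[-1])
    time_reached = None
    if converged:
        # first index from which the condition persists to the end
        idx = len(ok) - 1
        while idx > 0 and ok[idx - 1]:
            idx -= 1
        time_reached = float(trajectory.times[idx])
    return SteadyStateReport(
        converged=converged,
        time_reached=time_reached,
        final_affinities=np.asarray(final_aff, float),
        final_power=final_power,
        tolerance=tolerance,
    )


def stationary_ratio(spec: SystemSpec, r: int) -> float:
    """Balance population ratio product/substrate of a 1:1 transformation.

    Solves A_r = 0 for the isomerization substrate -> product:
    N_product / N_substrate = exp((G_substrate - G_product + deltaQ) / kT).
    General fixed points are found numerically via :func:`evolve`.
    """
    tr = spec.transformations[r]
    if len(tr.substrates) != 1 or len(tr.products) != 1:
        raise UnsupportedCaseError(
            "stationary_ratio covers 1:1 transformations only; "
            "find general fixed points numerically with evolve()"
        )
    (sub_id, sub_c), = tr.substrates.items()
    (prod_id, prod_c), = tr.products.items()
    if sub_c != 1 or prod_c != 1:
        raise UnsupportedCaseError("stationary_ratio requires unit stoichiometric coefficients")
    G = {s.id: s.G for s in spec.species}
    return float(np.exp((G[sub_id] - G[prod_id] + tr.deltaQ) / spec.kT))


def conserved_matter(trajectory: Trajectory, spec: SystemSpec) -> np.ndarray:
    """Series of total elemental matter sum_j c_j N_j along a trajectory."""
    return trajectory.states @ spec.compositions()
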