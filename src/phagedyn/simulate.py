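"""Outbreak scenario execution and approximation-quality metrics.

A Scenario bundles a (dimensionless) parameter set, the phage-free fixed
point the colony sits in before the attack, the phage inoculum applied at
t = 0, and the integration settings.  Integration uses the forward-Euler
scheme, which keeps the discrete state-space and amplitude-space dynamics
exactly conjugate step by step.

Two packaged scenarios cover the canonical outbreak study: PASSIVE, where
the only brake on exponential growth is the depletion of susceptibles
(alpha' = gamma' = 0), and ACTIVE, where resistant mutants additionally
suppress the contact rate (alpha' = 1, gamma' = 5).  The remaining
dimensionless parameters are shared: k1 = 0.2/day, k2 = 1/day,
beta0' = 5/day, mu = 0, s0 = 1, r0 = 0.01, inoculum p(0) = 0.001, one-week
horizon at dt = 0.001 day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import amplitude as amp
from .errors import IntegrationError, ValidationError
from .model import FixedPoint, ModelParams, SystemState, phage_free_fixed_point, rhs
from .spectral import SpectralDecomposition, decompose

__all__ = [
    "Scenario",
    "Trajectory",
    "ScenarioResult",
    "euler_integrate",
    "run_scenario",
    "approximation_error",
    "passive_scenario",
    "active_scenario",
    "FIXTURES",
]

#: relative-error level defining "departure" from an approximation track
DEVIATION_LEVEL = 0.10


@dataclass(frozen=True)
class Scenario:
    """A reproducible outbreak experiment specification."""

    params: ModelParams
    fixed_point: FixedPoint
    perturbation: SystemState
    dt: float = 0.001
    horizon: float = 7.0
    label: str = "scenario"

    def __post_init__(self) -> None:
        problems = []
        if not self.dt > 0:
            problems.append(f"dt must be > 0, got {self.dt}")
        elif not self.horizon >= self.dt:
            problems.append(f"horizon must be >= dt, got horizon={self.horizon}")
        if not self.perturbation.P > 0:
            problems.append(
                f"perturbation must carry phages (P > 0), got P={self.perturbation.P}"
            )
        if problems:
            raise ValidationError(f"invalid scenario {self.label!r}", items=problems)

    @property
    def initial_state(self) -> np.ndarray:
        return self.fixed_point.state.as_array() + self.perturbation.as_array()


@dataclass(frozen=True)
class Trajectory:
    """Uniform-grid trajectory with amplitude and approximation tracks."""

    times: np.ndarray          # (n,)
    states: np.ndarray         # (n, 4) in (S, I, P, R) order
    amplitudes: np.ndarray     # (n, 4) coordinates (A1..A4)
    op_track: np.ndarray       # (n, 4) order-parameter approximation states
    dexp_track: np.ndarray     # (n, 2) double-exponential (I, P) approximation

    def __post_init__(self) -> None:
        n = len(self.times)
        if n == 0:
            raise ValidationError("empty trajectory")
        dts = np.diff(self.times)
        if dts.size and not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
            raise ValidationError("trajectory grid must be uniform")
        for name in ("states", "amplitudes", "op_track", "dexp_track"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"track {name!r} length inconsistent with time grid")


def euler_integrate(rhs_func, state0, dt: float, horizon: float):
    """Forward-Euler integration x_{n+1} = x_n + dt f(x_n).

    Returns ``(times, states)`` with ``round(horizon/dt)`` steps.  A
    non-finite state aborts with an :class:`IntegrationError` carrying the
    offending step index (typically a too-large dt).
    """
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    x = np.asarray(state0, dtype=float).copy()
    n_steps = int(round(horizon / dt))
    out = np.empty((n_steps + 1, x.size))
    out[0] = x
    for n in range(n_steps):
        x = x + dt * np.asarray(rhs_func(x))
        if not np.all(np.isfinite(x)):
            raise IntegrationError(
                f"non-finite state at step {n + 1} (t = {(n + 1) * dt:g}); "
                "reduce dt",
                step=n + 1,
            )
        out[n + 1] = x
    return dt * np.arange(n_steps + 1), out


@dataclass(frozen=True)
class ScenarioResult:
    """Everything a scenario run produces."""

    scenario: Scenario
    spectral: SpectralDecomposition
    trajectory: Trajectory
    metrics: dict = field(default_factory=dict)


def run_scenario(sc: Scenario) -> ScenarioResult:
    """Full pipeline: fixed point -> spectrum -> integrate -> amplitudes
    -> approximation tracks -> quality metrics."""
    fp = sc.fixed_point
    params = sc.params
    spec = decompose(fp, params)

    times, states = euler_integrate(lambda x: rhs(x, params), sc.initial_state, sc.dt, sc.horizon)

    u = states - fp.state.as_array()
    amplitudes = u @ spec.W.T
    a0 = amplitudes[0]

    offset = amp.order_parameter_offset(a0, spec, fp)
    op_track = offset + np.multiply.outer(np.exp(spec.lambda2 * times), spec.v2 * a0[1])
    dexp_track = amp.double_exponential(times, a0[1], a0[2], spec)

    traj = Trajectory(
        times=times,
        states=states,
        amplitudes=amplitudes,
        op_track=op_track,
        dexp_track=dexp_track,
    )
    metrics = approximation_error(traj, spec, fp)
    return ScenarioResult(scenario=sc, spectral=spec, trajectory=traj, metrics=metrics)


def approximation_error(
    traj: Trajectory, spec: SpectralDecomposition, fp: FixedPoint
) -> dict:
    """Quantify how well the reduced descriptions track the simulation.

    Reported per time point:

    - ``angle_deg``: angular distance (degrees) between the displacement
      X(t) - Xst0 and the order-parameter line span(v2);
    - ``dexp_rel_err``: relative Euclidean error of the double-exponential
      (I, P) prediction.

    Summary scalars: time of first sustained-exceedance of the 10% level by
    the double-exponential error (horizon if never exceeded), the longest
    contiguous stretch of time with angle < 5 degrees, and the mean/max of
    both per-time series.
    """
    u = traj.states - fp.state.as_array()
    norms = np.linalg.norm(u, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(u @ spec.v2) / np.where(norms > 0, norms, np.nan)
    angle_deg = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    ip = traj.states[:, 1:3]
    ip_norm = np.linalg.norm(ip, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_err = np.linalg.norm(ip - traj.dexp_track, axis=1) / np.where(
            ip_norm > 0, ip_norm, np.nan
        )
    rel_err = np.nan_to_num(rel_err, nan=0.0)

    exceeded = rel_err > DEVIATION_LEVEL
    first_dev = float(traj.times[np.argmax(exceeded)]) if exceeded.any() else float(
        traj.times[-1]
    )

    below = angle_deg < 5.0
    dt = float(traj.times[1] - traj.times[0]) if len(traj.times) > 1 else 0.0
    longest = _longest_run(below) * dt

    return {
        "angle_deg": angle_deg,
        "dexp_rel_err": rel_err,
        "first_deviation_time": first_dev,
        "longest_aligned_window": longest,
        "mean_dexp_rel_err": float(np.mean(rel_err)),
        "max_angle_deg": float(np.nanmax(angle_deg)),
        "final_angle_deg": float(angle_deg[-1]),
    }


def _longest_run(mask: np.ndarray) -> int:
    """Length (in samples) of the longest contiguous True run."""
    best = run = 0
    for flag in mask:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best


def _canonical_scenario(label: str, alpha: float, gamma: float) -> Scenario:
    params = ModelParams(
        beta0=5.0, gamma=gamma, alpha=alpha, Rm=1.0, q=0.2, k1=0.2, k2=1.0, mu=0.0, K=1.0
    )
    fp = phage_free_fixed_point(1.0, 0.01, params)
    return Scenario(
        params=params,
        fixed_point=fp,
        perturbation=SystemState(0.0, 0.0, 0.001, 0.0),
        dt=0.001,
        horizon=7.0,
        label=label,
    )


def passive_scenario() -> Scenario:
    """Outbreak with susceptible depletion as the only stopping mechanism."""
    return _canonical_scenario("passive", alpha=0.0, gamma=0.0)


def active_scenario() -> Scenario:
    """Outbreak with the resistant-mutant defense switched on."""
    return _canonical_scenario("active", alpha=1.0, gamma=5.0)


FIXTURES = {"passive": passive_scenario, "active": active_scenario}
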