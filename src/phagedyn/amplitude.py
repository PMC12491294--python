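"""Amplitude-equation view of the outbreak dynamics.

Writing the state as X = Xst0 + sum_j A_j v_j turns the model into an exact
closed system for the amplitudes,

    dA_j/dt = lambda_j A_j + N_j(A),    N_j(A) = w_j . G(u(A)),

where u = X - Xst0 = (delta, I, P, omega) is the displacement from the
phage-free fixed point and G collects every nonlinear term of the vector
field.  This is a plain (nonlinear) change of coordinates: integrating the
amplitude system and mapping back reproduces the state-space trajectory
exactly.  On top of the exact system this module provides the three reduced
descriptions used to interpret an outbreak: the rank-1 order-parameter
approximation along v2, the quadratic expansion of N_2 separating the
passive (susceptible-depletion) and active (resistant-accumulation)
stopping mechanisms, the induced linear predictor slopes between species,
and the two-mode double-exponential approximation of (I, P).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .model import FixedPoint, ModelParams, SystemState, rhs
from .spectral import SpectralDecomposition

__all__ = [
    "AmplitudeVector",
    "DifferenceVector",
    "amplitudes_from_state",
    "state_from_amplitudes",
    "nonlinear_G",
    "amplitude_rhs",
    "order_parameter_offset",
    "order_parameter_approx",
    "StoppingTerms",
    "stopping_terms",
    "predictor_slopes",
    "predictor_intercepts",
    "double_exponential",
]


@dataclass(frozen=True)
class AmplitudeVector:
    """Coordinates (A1, A2, A3, A4) of the state along the eigenvectors."""

    A1: float
    A2: float
    A3: float
    A4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.A3, self.A4])

    @classmethod
    def from_array(cls, a) -> "AmplitudeVector":
        return cls(*np.asarray(a, dtype=float).tolist())


@dataclass(frozen=True)
class DifferenceVector:
    """Displacement u = X - Xst0 with components (delta, I, P, omega)."""

    delta: float
    I: float
    P: float
    omega: float

    def as_array(self) -> np.ndarray:
        return np.array([self.delta, self.I, self.P, self.omega])


def _as_u(state_or_u, fp: FixedPoint | None = None) -> np.ndarray:
    if isinstance(state_or_u, DifferenceVector):
        return state_or_u.as_array()
    x = (
        state_or_u.as_array()
        if isinstance(state_or_u, SystemState)
        else np.asarray(state_or_u, dtype=float)
    )
    if fp is not None:
        x = x - fp.state.as_array()
    return x


def amplitudes_from_state(state, fp: FixedPoint, W: np.ndarray) -> np.ndarray:
    """Project a state onto the eigenbasis: A_j = w_j . (X - Xst0)."""
    return W @ _as_u(state, fp)


def state_from_amplitudes(A, fp: FixedPoint, V: np.ndarray) -> SystemState:
    """Reconstruct X = Xst0 + sum_j A_j v_j (inverse of amplitudes_from_state)."""
    a = A.as_array() if isinstance(A, AmplitudeVector) else np.asarray(A, dtype=float)
    return SystemState.from_array(fp.state.as_array() + V @ a)


def nonlinear_G(u, fp: FixedPoint, params: ModelParams) -> np.ndarray:
    """Nonlinear remainder G(u) with rhs(Xst0 + u) = J u + G(u) exactly.

    Componentwise G = (-G_I - (mu/K) delta^2, G_I, 0, G_R) with

        G_I = beta0 P [ (Sst0+delta)/(1+gamma(Rst0+omega)) - Sst0/(1+gamma Rst0) ]
        G_R = -alpha I omega / Rm

    The defining identity above is exact (no expansion) and serves as the
    master consistency check between the model, the Jacobian and this
    function.
    """
    delta, I_val, P_val, omega = _as_u(u)
    Sst0, Rst0 = fp.state.S, fp.state.R
    denom = 1.0 + params.gamma * (Rst0 + omega)
    if denom <= 0:
        raise DomainError(f"1 + gamma (Rst0 + omega) must be > 0, got {denom}")
    g_i = params.beta0 * P_val * (
        (Sst0 + delta) / denom - Sst0 / (1.0 + params.gamma * Rst0)
    )
    g_r = -params.alpha * I_val * omega / params.Rm
    quad_s = (params.mu / params.K) * delta**2 if params.mu > 0 else 0.0
    return np.array([-g_i - quad_s, g_i, 0.0, g_r])


def amplitude_rhs(
    A, spec: SpectralDecomposition, fp: FixedPoint, params: ModelParams
) -> np.ndarray:
    """Exact amplitude vector field dA_j/dt = lambda_j A_j + w_j . G(u(A))."""
    a = A.as_array() if isinstance(A, AmplitudeVector) else np.asarray(A, dtype=float)
    u = spec.V @ a
    return spec.lambdas * a + spec.W @ nonlinear_G(u, fp, params)


def order_parameter_offset(A0, spec: SpectralDecomposition, fp: FixedPoint) -> np.ndarray:
    """Constant offset of the early-time rank-1 description.

    The outward dynamics is X(t) ~ C + v2 A2(0) exp(lambda2 t) with C the
    fixed point shifted by the initial amplitudes along the neutral
    directions (A1 only enters for mu = 0, where v1 is not decaying).
    """
    a0 = A0.as_array() if isinstance(A0, AmplitudeVector) else np.asarray(A0, dtype=float)
    C = fp.state.as_array() + a0[3] * spec.V[:, 3]
    if spec.lambdas[0] == 0.0:
        C = C + a0[0] * spec.V[:, 0]
    return C


def order_parameter_approx(
    t, A2_0: float, spec: SpectralDecomposition, fp: FixedPoint
) -> np.ndarray:
    """Rank-1 state change Delta X(t) = v2 A2(0) (exp(lambda2 t) - 1).

    Valid for the early outbreak only; once the quadratic stopping terms
    bite, the true trajectory bends away from the v2 line.  For a stable
    configuration (case I) there is no outbreak to organize and the call
    only makes descriptive sense, so a warning is issued.
    """
    if spec.lambda2 <= 0:
        warnings.warn(
            "order-parameter approximation requested with lambda_2 <= 0 "
            "(case I: no outbreak to organize)",
            stacklevel=2,
        )
    t = np.asarray(t, dtype=float)
    growth = np.expm1(spec.lambda2 * t)  # exp(lambda2 t) - 1
    return np.multiply.outer(growth, spec.v2 * A2_0)


@dataclass(frozen=True)
class StoppingTerms:
    """Quadratic decomposition of dA2/dt = linear - passive - active + O(eps^3).

    ``passive`` (prefactor * (-P delta)) measures braking by depletion of
    susceptibles, ``active`` (prefactor * gamma Sst0 fst0 * P omega) braking
    by accumulation of resistant mutants; both are >= 0 during an outbreak
    (delta <= 0, omega >= 0, P >= 0).
    """

    linear: float
    passive: float
    active: float
    prefactor: float

    @property
    def quadratic_rate(self) -> float:
        return self.linear - self.passive - self.active


def stopping_terms(
    u, spec: SpectralDecomposition, params: ModelParams, fp: FixedPoint
) -> StoppingTerms:
    """Split the order-parameter growth rate into its stopping mechanisms.

    Expanding N_2 = w2 . G to second order in the displacement gives

        dA2/dt = lambda2 A2 - c (-P delta) - c gamma Sst0 fst0 P omega + O(eps^3)

    with the common prefactor c = w2_I beta0 fst0 (w2 has no S or R
    component, so only G_I contributes).  With the package's eigenvector
    sign convention c > 0 in the outbreak regime, making both braking terms
    non-negative whenever delta <= 0, omega >= 0, P >= 0.
    """
    uv = _as_u(u)
    delta, _, P_val, omega = uv
    A2 = float(spec.W[1] @ uv)
    c = spec.W[1, 1] * params.beta0 * spec.fst0
    return StoppingTerms(
        linear=spec.lambda2 * A2,
        passive=c * (-P_val * delta),
        active=c * params.gamma * fp.state.S * spec.fst0 * P_val * omega,
        prefactor=c,
    )


def predictor_slopes(spec: SpectralDecomposition) -> np.ndarray:
    """Linear predictor slopes r_ij = v2_i / v2_j between all species pairs.

    Along the order parameter every species is a linear function of every
    other, X_i ~ a_ij + r_ij X_j.  Pairs whose predictor component v2_j is
    zero have no defined slope and are reported as NaN.
    """
    v2 = spec.v2
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(v2[np.newaxis, :] != 0, np.outer(v2, 1.0 / v2), np.nan)
    # the diagonal is exactly 1 wherever it is defined at all
    np.fill_diagonal(r, np.where(v2 != 0, 1.0, np.nan))
    return r


def predictor_intercepts(spec: SpectralDecomposition, fp: FixedPoint) -> np.ndarray:
    """Intercepts a_ij = Xst0_i - r_ij Xst0_j of the predictor equations.

    In particular a_I,P = 0 because Ist0 = Pst0 = 0 at a phage-free point.
    """
    x0 = fp.state.as_array()
    r = predictor_slopes(spec)
    return x0[:, np.newaxis] - r * x0[np.newaxis, :]


def double_exponential(t, A2_0: float, A3_0: float, spec: SpectralDecomposition) -> np.ndarray:
    """Two-mode early-time approximation of the infected/phage pair.

    (I, P)(t) ~ v2' A2(0) exp(lambda2 t) + v3' A3(0) exp(lambda3 t), where
    v2', v3' are the (I, P)-projections of v2, v3.  The reduction to two
    modes is structurally exact (v1 and v4 have no I or P components), so
    at t = 0 the initial (I, P) perturbation is recovered exactly; the
    approximation consists of dropping the nonlinear amplitude coupling.

    Returns an array of shape ``t.shape + (2,)`` with components (I, P).
    """
    t = np.asarray(t, dtype=float)
    v2p = spec.V[1:3, 1]
    v3p = spec.V[1:3, 2]
    return (
        np.multiply.outer(np.exp(spec.lambda2 * t), v2p * A2_0)
        + np.multiply.outer(np.exp(spec.lambda3 * t), v3p * A3_0)
    )
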