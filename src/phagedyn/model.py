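"""Four-species bacteriophage infection model with bacterial defense.

The state is X = (S, I, P, R): susceptible bacteria, infected bacteria,
phage load, and phage-resistant bacteria (all concentrations).  The dynamics
is a TIV-style compartment model extended by a CRISPR-like adaptive defense:

    dS/dt = -k0(P, R) S + mu S (1 - S/K)
    dI/dt =  k0(P, R) S - k1 I
    dP/dt =  q I - k2 P
    dR/dt =  alpha I (1 - R/Rm)

where the effective contact rate k0(P, R) = beta0 P / (1 + gamma R) is
lowered by the presence of resistant mutants.  The dimensionless (scaled)
variant used in the outbreak scenarios is the *same* family of equations
with transformed parameters, so one right-hand side serves both; see
:func:`to_scaled`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "ModelParams",
    "SystemState",
    "FixedPoint",
    "ScaledTransform",
    "contact_rate",
    "rhs",
    "phage_free_fixed_point",
    "endemic_exists",
    "to_scaled",
]

log = logging.getLogger(__name__)

#: index convention for state vectors, shared package-wide
S, I, P, R = 0, 1, 2, 3
STATE_NAMES = ("S", "I", "P", "R")


@dataclass(frozen=True)
class ModelParams:
    """Rate and capacity constants of the infection/defense model.

    Parameters
    ----------
    beta0 : float
        Baseline effective contact rate [1/(conc day)].
    gamma : float
        Effectivity of the active defense mechanism [1/conc]; ``gamma = 0``
        switches the contact-rate reduction off.
    alpha : float
        Growth rate of resistant mutants per infected bacterium [1/day];
        ``alpha = 0`` freezes the resistant population.
    Rm : float
        Maximal (saturating) concentration of resistant bacteria [conc].
    q : float
        Phage production rate per infected bacterium [1/day].
    k1, k2 : float
        Decay rates of infected bacteria and of phages [1/day].
    mu : float
        Logistic growth rate of susceptibles [1/day]; ``mu = 0`` drops the
        growth term, which does not change the initial outbreak dynamics.
    K : float
        Carrying capacity [conc]; only meaningful (and then required
        positive) when ``mu > 0``.
    """

    beta0: float
    gamma: float = 0.0
    alpha: float = 0.0
    Rm: float = 1.0
    q: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    mu: float = 0.0
    K: float = 1.0

    def __post_init__(self) -> None:
        problems = []
        if not self.k1 > 0:
            problems.append(f"k1 must be > 0, got {self.k1}")
        if not self.k2 > 0:
            problems.append(f"k2 must be > 0, got {self.k2}")
        if not self.q > 0:
            problems.append(f"q must be > 0, got {self.q}")
        if not self.beta0 > 0:
            problems.append(f"beta0 must be > 0, got {self.beta0}")
        if self.gamma < 0:
            problems.append(f"gamma must be >= 0, got {self.gamma}")
        if self.alpha < 0:
            problems.append(f"alpha must be >= 0, got {self.alpha}")
        if not self.Rm > 0:
            problems.append(f"Rm must be > 0, got {self.Rm}")
        if self.mu < 0:
            problems.append(f"mu must be >= 0, got {self.mu}")
        if self.mu > 0 and not self.K > 0:
            problems.append(f"K must be > 0 when mu > 0, got K={self.K}")
        if problems:
            raise ValidationError("invalid model parameters", items=problems)


@dataclass(frozen=True)
class SystemState:
    """A point X = (S, I, P, R) of the model's state space."""

    S: float
    I: float
    P: float
    R: float

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.I, self.P, self.R], dtype=float)

    @classmethod
    def from_array(cls, x) -> "SystemState":
        x = np.asarray(x, dtype=float)
        if x.shape != (4,):
            raise ValidationError(f"state vector must have shape (4,), got {x.shape}")
        return cls(*x.tolist())

    def validate(self, params: ModelParams | None = None) -> "SystemState":
        """Check non-negativity and (if params given) R <= Rm; return self."""
        problems = [
            f"{name} must be >= 0, got {val}"
            for name, val in zip(STATE_NAMES, self.as_array())
            if val < 0
        ]
        if params is not None and self.R > params.Rm:
            problems.append(f"R must be <= Rm={params.Rm}, got {self.R}")
        if problems:
            raise ValidationError("invalid system state", items=problems)
        return self


@dataclass(frozen=True)
class FixedPoint:
    """A stationary state, tagged phage-free (I = P = 0) or endemic."""

    kind: str
    state: SystemState

    def __post_init__(self) -> None:
        if self.kind not in ("phage_free", "endemic"):
            raise ValidationError(f"unknown fixed-point kind {self.kind!r}")
        if self.kind == "phage_free" and (self.state.I != 0 or self.state.P != 0):
            raise ValidationError("phage_free fixed point requires I = 0 and P = 0")


def contact_rate(P_val: float, R_val: float, params: ModelParams) -> float:
    """Effective S -> I transition rate k0(P, R) = beta0 P / (1 + gamma R).

    Monotone increasing in the phage load P and non-increasing in the
    resistant concentration R: resistant mutants shield susceptibles.
    """
    if P_val < 0 or R_val < 0:
        raise DomainError(f"contact_rate requires P, R >= 0, got P={P_val}, R={R_val}")
    return params.beta0 * P_val / (1.0 + params.gamma * R_val)


def rhs(state, params: ModelParams) -> np.ndarray:
    """Time derivatives (dS, dI, dP, dR) of the model at ``state``.

    ``state`` may be a :class:`SystemState` or any length-4 array-like in
    (S, I, P, R) order; an ndarray is returned either way (the integrator's
    hot path stays allocation-light).
    """
    x = state.as_array() if isinstance(state, SystemState) else np.asarray(state, dtype=float)
    if params.mu > 0 and params.K <= 0:
        raise ValidationError(f"mu > 0 requires K > 0, got K={params.K}")
    s, i, p, r = x
    k0 = params.beta0 * p / (1.0 + params.gamma * r)
    infection = k0 * s
    growth = params.mu * s * (1.0 - s / params.K) if params.mu > 0 else 0.0
    return np.array(
        [
            -infection + growth,
            infection - params.k1 * i,
            params.q * i - params.k2 * p,
            params.alpha * i * (1.0 - r / params.Rm),
        ]
    )


def phage_free_fixed_point(Sst0: float, Rst0: float, params: ModelParams) -> FixedPoint:
    """The phage-free stationary state (Sst0, 0, 0, Rst0).

    Any S >= 0 and R in [0, Rm] is stationary when mu = 0; with logistic
    growth switched on (mu > 0) the susceptibles must sit at the carrying
    capacity, S = K, for dS/dt to vanish.
    """
    if Sst0 < 0:
        raise DomainError(f"Sst0 must be >= 0, got {Sst0}")
    if not 0 <= Rst0 <= params.Rm:
        raise DomainError(f"Rst0 must lie in [0, Rm={params.Rm}], got {Rst0}")
    if params.mu > 0 and not math.isclose(Sst0, params.K, rel_tol=1e-12, abs_tol=0.0):
        raise ValidationError(
            f"with mu > 0 the phage-free fixed point requires Sst0 = K "
            f"(got Sst0={Sst0}, K={params.K})"
        )
    return FixedPoint(kind="phage_free", state=SystemState(Sst0, 0.0, 0.0, Rst0))


def endemic_exists(params: ModelParams) -> bool:
    """Whether an endemic fixed point (Ist > 0, Pst > 0) exists.

    For mu > 0 an endemic state exists iff even a fully saturated resistant
    population cannot stabilize the phage-free state at S = K:

        k1 k2 < q beta0 K / (1 + gamma Rm)

    For mu = 0 the model has only phage-free fixed points; False is
    returned (with a log note) rather than raising.
    """
    if params.mu == 0:
        log.info("endemic_exists: mu = 0, the model has only phage-free fixed points")
        return False
    f_rmax = 1.0 / (1.0 + params.gamma * params.Rm)
    return params.k1 * params.k2 < params.q * params.beta0 * f_rmax * params.K


@dataclass(frozen=True)
class ScaledTransform:
    """Bijective map between original and dimensionless state variables.

    s = S/Sst0,  i = I/Sst0,  p = k1 P / (q Sst0),  r = R/Rm.

    The p-scaling measures phage load in bacteria-equivalent units, making
    the I -> p conversion 1:1 (production term k1*i in the scaled p-equation
    balances the -k1*i loss of infected bacteria).
    """

    Sst0: float
    Rm: float
    q: float
    k1: float

    @property
    def _diag(self) -> np.ndarray:
        return np.array(
            [1.0 / self.Sst0, 1.0 / self.Sst0, self.k1 / (self.q * self.Sst0), 1.0 / self.Rm]
        )

    def forward(self, state) -> np.ndarray:
        """(S, I, P, R) -> (s, i, p, r)."""
        x = state.as_array() if isinstance(state, SystemState) else np.asarray(state, dtype=float)
        return x * self._diag

    def inverse(self, scaled) -> np.ndarray:
        """(s, i, p, r) -> (S, I, P, R)."""
        return np.asarray(scaled, dtype=float) / self._diag


def to_scaled(params: ModelParams, Sst0: float) -> tuple[ModelParams, ScaledTransform]:
    """Dimensionless parameter set and the matching state transform.

    The scaled equations are the same model family, so the returned
    ``ModelParams`` feeds straight back into :func:`rhs`:

        beta0' = beta0 Sst0 q / k1,  gamma' = gamma Rm,
        alpha' = alpha Sst0 / Rm,    Rm' = 1,  q' = k1,  K' = K / Sst0.
    """
    if Sst0 <= 0:
        raise DomainError(f"Sst0 must be > 0, got {Sst0}")
    scaled = ModelParams(
        beta0=params.beta0 * Sst0 * (params.q / params.k1),
        gamma=params.gamma * params.Rm,
        alpha=params.alpha * Sst0 / params.Rm,
        Rm=1.0,
        q=params.k1,
        k1=params.k1,
        k2=params.k2,
        mu=params.mu,
        K=params.K / Sst0,
    )
    return scaled, ScaledTransform(Sst0=Sst0, Rm=params.Rm, q=params.q, k1=params.k1)
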