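"""Linear stability analysis at the phage-free fixed point.

The Jacobian there is block-structured: the (I, P) pair forms a closed
linear subsystem [[-k1, F0], [q, -k2]] with F0 = beta0 * fst0 * Sst0 and
fst0 = 1/(1 + gamma * Rst0), while S and R couple to it one-way.  This
yields closed-form eigenvalues

    lambda_1 = -mu,   lambda_4 = 0,
    lambda_{2,3} = -(k1+k2)/2 +- sqrt((k1+k2)^2/4 - k1 k2 + q F0),

indexed by the convention used throughout the package: j=2 is the upper
sign (the only eigenvalue that can turn positive; its eigenvector v2 is the
order parameter of an outbreak) and lambda_3 < 0 always.  The basic
reproduction number from the next-generation method is
R0 = q F0 / (k1 k2), and sign(lambda_2) = sign(R0 - 1).

Eigenvectors are built from the closed forms and the dual (bi-orthogonal)
vectors w_j by inverting the eigenvector matrix; the analytic v1 = e_S and
v4 = e_R are used directly, which keeps the mu = 0 double-zero eigenvalue
well defined where a numeric eigensolver would return an arbitrary basis
for the null space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegeneracyError, ThresholdError, ValidationError
from .model import FixedPoint, ModelParams

__all__ = [
    "SpectralDecomposition",
    "jacobian",
    "eigenvalues",
    "eigenvectors",
    "biorthogonal",
    "basic_reproduction_number",
    "classify_case",
    "decompose",
]

#: condition-number ceiling above which the eigenbasis is treated as singular
_COND_MAX = 1e10


def _check_phage_free(fp: FixedPoint) -> None:
    if fp.kind != "phage_free":
        raise ValidationError(
            "spectral analysis supports phage-free fixed points only; "
            "the endemic state is out of scope"
        )


def _f0_fst0(fp: FixedPoint, params: ModelParams) -> tuple[float, float]:
    fst0 = 1.0 / (1.0 + params.gamma * fp.state.R)
    return params.beta0 * fst0 * fp.state.S, fst0


def _alpha_star(fp: FixedPoint, params: ModelParams) -> float:
    return params.alpha * (1.0 - fp.state.R / params.Rm)


def jacobian(fp: FixedPoint, params: ModelParams) -> np.ndarray:
    """4x4 Jacobian of the model at a phage-free fixed point, (S,I,P,R) order."""
    _check_phage_free(fp)
    F0, _ = _f0_fst0(fp, params)
    a_star = _alpha_star(fp, params)
    # logistic term linearized at S = K gives -mu; the infection terms vanish
    # at P = 0 except through the P-column
    j_ss = params.mu * (1.0 - 2.0 * fp.state.S / params.K) if params.mu > 0 else 0.0
    return np.array(
        [
            [j_ss, 0.0, -F0, 0.0],
            [0.0, -params.k1, F0, 0.0],
            [0.0, params.q, -params.k2, 0.0],
            [0.0, a_star, 0.0, 0.0],
        ]
    )


def eigenvalues(fp: FixedPoint, params: ModelParams) -> np.ndarray:
    """Closed-form eigenvalues in index order (lambda_1, ..., lambda_4)."""
    _check_phage_free(fp)
    F0, _ = _f0_fst0(fp, params)
    half = 0.5 * (params.k1 + params.k2)
    disc = half * half - params.k1 * params.k2 + params.q * F0
    # disc = (k1-k2)^2/4 + qF0 > 0, so the root pair is always real and split
    if disc <= 0:
        raise DegeneracyError(f"degenerate lambda_2 = lambda_3 (discriminant {disc})")
    root = np.sqrt(disc)
    return np.array([-params.mu, -half + root, -half - root, 0.0])


def eigenvectors(fp: FixedPoint, params: ModelParams, lambdas: np.ndarray) -> np.ndarray:
    """Unit eigenvectors as columns, index order (v1, v2, v3, v4).

    v1 = (1,0,0,0) and v4 = (0,0,0,1) are exact.  For j = 2, 3 the
    unnormalized solution of J v = lambda v is

        ( -F0 lam (lam+k1) / (lam+mu),  F0 lam,  lam (lam+k1),  F0 alpha* )

    normalized to unit length with sign fixed so that the P-component is
    >= 0 (tie-break: I-component >= 0), making downstream amplitude signs
    reproducible.
    """
    _check_phage_free(fp)
    F0, _ = _f0_fst0(fp, params)
    a_star = _alpha_star(fp, params)
    V = np.zeros((4, 4))
    V[0, 0] = 1.0
    V[3, 3] = 1.0
    scale = abs(lambdas[1] - lambdas[2])
    for j in (1, 2):
        lam = lambdas[j]
        for guard, name in ((lam, "0"), (lam + params.mu, "-mu"), (lam + params.k1, "-k1")):
            if abs(guard) < 1e-12 * max(1.0, scale):
                raise DegeneracyError(
                    f"eigenvalue lambda_{j + 1} = {lam} too close to {name}; "
                    "eigenvector construction unsafe"
                )
        v = np.array(
            [
                -F0 * lam * (lam + params.k1) / (lam + params.mu),
                F0 * lam,
                lam * (lam + params.k1),
                F0 * a_star,
            ]
        )
        v /= np.linalg.norm(v)
        if v[2] < 0 or (v[2] == 0 and v[1] < 0):
            v = -v
        V[:, j] = v
    return V


def biorthogonal(V: np.ndarray) -> np.ndarray:
    """Dual vectors w_j (rows) with w_i . v_k = delta_ik, via basis inversion."""
    if np.linalg.cond(V) > _COND_MAX:
        raise DegeneracyError("eigenvector matrix is near-singular; no bi-orthogonal basis")
    return np.linalg.inv(V)


def basic_reproduction_number(fp: FixedPoint, params: ModelParams) -> float:
    """R0 = q beta0 fst0 Sst0 / (k1 k2) from the next-generation method."""
    _check_phage_free(fp)
    F0, _ = _f0_fst0(fp, params)
    return params.q * F0 / (params.k1 * params.k2)


@dataclass(frozen=True)
class SpectralDecomposition:
    """Full spectral picture of the linearization at a phage-free fixed point.

    Attributes
    ----------
    lambdas : (4,) ndarray
        Eigenvalues (lambda_1, lambda_2, lambda_3, lambda_4) = (-mu, ., ., 0).
    V : (4, 4) ndarray
        Unit eigenvectors as columns; ``V[:, 1]`` is the order parameter v2.
    W : (4, 4) ndarray
        Bi-orthogonal vectors as rows, W = V^{-1}.
    F0, fst0, R0 : float
        Linearized infection pressure beta0*fst0*Sst0, defense attenuation
        1/(1+gamma*Rst0), and the basic reproduction number.
    alpha_star : float
        Effective defense growth rate alpha*(1 - Rst0/Rm).
    B : float
        The (I,P)-block determinant v2_I v3_P - v2_P v3_I entering the
        closed-form w2, w3.
    """

    lambdas: np.ndarray
    V: np.ndarray
    W: np.ndarray
    F0: float
    fst0: float
    R0: float
    alpha_star: float
    B: float
    case_label: str = field(default="")

    @property
    def v2(self) -> np.ndarray:
        return self.V[:, 1]

    @property
    def v3(self) -> np.ndarray:
        return self.V[:, 2]

    @property
    def w2(self) -> np.ndarray:
        return self.W[1]

    @property
    def lambda2(self) -> float:
        return float(self.lambdas[1])

    @property
    def lambda3(self) -> float:
        return float(self.lambdas[2])

    def residuals(self, J: np.ndarray) -> dict[str, float]:
        """Max |J v - lambda v| and |W V - I| norms (diagnostics)."""
        eig_res = max(
            float(np.max(np.abs(J @ self.V[:, j] - self.lambdas[j] * self.V[:, j])))
            for j in range(4)
        )
        return {
            "eigen_residual": eig_res,
            "biorthogonality_residual": float(np.max(np.abs(self.W @ self.V - np.eye(4)))),
        }


def classify_case(spec: SpectralDecomposition) -> str:
    """Outbreak classification: 'I' (lambda_2 < 0, subcritical, no outbreak)
    or 'II' (lambda_2 > 0, supercritical outbreak)."""
    lam2 = spec.lambda2
    if lam2 == 0.0:
        raise ThresholdError("lambda_2 = 0: the system sits exactly on the epidemic threshold")
    return "II" if lam2 > 0 else "I"


def decompose(fp: FixedPoint, params: ModelParams) -> SpectralDecomposition:
    """Run the full spectral pipeline and attach the case label."""
    lambdas = eigenvalues(fp, params)
    V = eigenvectors(fp, params, lambdas)
    W = biorthogonal(V)
    F0, fst0 = _f0_fst0(fp, params)
    spec = SpectralDecomposition(
        lambdas=lambdas,
        V=V,
        W=W,
        F0=F0,
        fst0=fst0,
        R0=basic_reproduction_number(fp, params),
        alpha_star=_alpha_star(fp, params),
        B=float(V[1, 1] * V[2, 2] - V[2, 1] * V[1, 2]),
    )
    return SpectralDecomposition(
        **{**spec.__dict__, "case_label": classify_case(spec)}
    )
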