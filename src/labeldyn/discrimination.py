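"""Model acceptance statistics: Hessian, effective parameters, Q test.

A fitted model is judged by the probability Q that a correct model's χ²
would exceed the fitted minimum by chance: Q = Q(F/2, χ²/2), the regularized
upper incomplete gamma function, with F = N − P degrees of freedom.  The
model is acceptable if Q > 0.05, marginal down to 0.001 (tolerable if errors
are non-normal or moderately underestimated), and rejected below 0.001.

Because an underdetermined model has parameters the data cannot distinguish,
P is not the raw parameter count but the size of the maximal subset whose
Gauss–Newton Hessian submatrix is numerically non-singular.  The Hessian is
the standard first-derivative ("Gauss–Newton") approximation

    α_kl = 2 Σ_i (1/σ_i²) (∂y_i/∂a_k)(∂y_i/∂a_l),

positive-semidefinite by construction (the curvature matrix at a χ² minimum
must be PSD, so the positive sign is used).  Singular value decomposition
provides the condition number, the effective-parameter search and the
parameter covariance C = V·diag(1/w)·Uᵀ when the matrix is invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaincc

__all__ = [
    "HessianAnalysis",
    "DiscriminationReport",
    "gauss_newton_hessian",
    "residual_jacobian",
    "hessian_analysis",
    "effective_parameter_count",
    "degrees_of_freedom",
    "q_value",
    "verdict",
    "discrimination_report",
]


@dataclass
class HessianAnalysis:
    matrix: np.ndarray
    singular_values: np.ndarray
    condition_number: float
    effective_params: int
    selected: list[str]
    covariance: np.ndarray | None

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("Hessian approximation must be symmetric")


@dataclass
class DiscriminationReport:
    n_points: int
    p_effective: int
    dof: int
    chi2: float
    q: float
    verdict: str

    def to_dict(self) -> dict:
        return {
            "N": self.n_points,
            "P_eff": self.p_effective,
            "F": self.dof,
            "chi2": self.chi2,
            "Q": self.q,
            "verdict": self.verdict,
        }


def residual_jacobian(
    simulate: Callable[[np.ndarray], np.ndarray],
    params: np.ndarray,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Central finite-difference Jacobian ∂y_i/∂a_k of the model predictions.

    ``simulate(a)`` returns the vector of predicted observables.  The step is
    relative per parameter (absolute floor 1e-12 for zero-valued parameters).
    """
    params = np.asarray(params, dtype=float)
    y0 = np.asarray(simulate(params), dtype=float)
    J = np.zeros((len(y0), len(params)))
    for k, a in enumerate(params):
        h = max(abs(a) * rel_step, 1e-12)
        up, dn = params.copy(), params.copy()
        up[k] += h
        dn[k] -= h
        yk = (np.asarray(simulate(up)) - np.asarray(simulate(dn))) / (2 * h)
        if not np.all(np.isfinite(yk)):
            raise FloatingPointError(
                f"non-finite derivative for parameter index {k}"
            )
        J[:, k] = yk
    return J


def gauss_newton_hessian(
    jacobian: np.ndarray, sigmas: np.ndarray
) -> np.ndarray:
    """α = 2·Jᵀ diag(1/σ²) J — the PSD Gauss–Newton curvature of χ²."""
    J = np.asarray(jacobian, dtype=float)
    w = 1.0 / np.asarray(sigmas, dtype=float) ** 2
    return 2.0 * (J.T * w) @ J


def effective_parameter_count(
    hessian: np.ndarray,
    cond_threshold: float = 1e-10,
    names: Sequence[str] | None = None,
) -> tuple[int, list[str]]:
    """Maximal parameter subset with a numerically non-singular Hessian.

    Greedy forward selection: parameters are ranked by diagonal sensitivity
    (ties broken lexicographically by name, so the count is deterministic),
    and added while the reciprocal condition number of the selected submatrix
    stays above ``cond_threshold``.
    """
    H = np.asarray(hessian, dtype=float)
    P = H.shape[0]
    if names is None:
        names = [f"a{k}" for k in range(P)]
    order = sorted(range(P), key=lambda k: (-H[k, k], names[k]))
    selected: list[int] = []
    for k in order:
        if H[k, k] <= 0:
            continue
        trial = selected + [k]
        sub = H[np.ix_(trial, trial)]
        w = np.linalg.svd(sub, compute_uv=False)
        if w[0] <= 0 or w[-1] / w[0] <= cond_threshold:
            continue
        selected = trial
    return len(selected), [names[k] for k in sorted(selected)]


def hessian_analysis(
    hessian: np.ndarray,
    cond_threshold: float = 1e-10,
    names: Sequence[str] | None = None,
) -> HessianAnalysis:
    H = np.asarray(hessian, dtype=float)
    U, w, Vt = np.linalg.svd(H)
    cond = float(w[0] / w[-1]) if w[-1] > 0 else float("inf")
    p_eff, selected = effective_parameter_count(H, cond_threshold, names)
    covariance = None
    if w[-1] > 0 and w[-1] / w[0] > cond_threshold:
        covariance = (Vt.T * (1.0 / w)) @ U.T
    return HessianAnalysis(
        matrix=H,
        singular_values=w,
        condition_number=cond,
        effective_params=p_eff,
        selected=selected,
        covariance=covariance,
    )


def degrees_of_freedom(n_points: int, p_effective: int) -> int:
    """F = N − P; raises when the problem is underdetermined (N < P)."""
    if n_points < p_effective:
        raise ValueError(
            f"underdetermined problem: N={n_points} < P={p_effective}; "
            "no valid number of degrees of freedom"
        )
    return n_points - p_effective


def q_value(dof: int, chi2: float) -> float:
    """Q(F/2, χ²/2): probability that χ² exceeds the observed value by chance.

    Computed with the regularized upper incomplete gamma function (series /
    continued-fraction split), strictly decreasing in χ² and equal to 1 at 0.
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    return float(gammaincc(dof / 2.0, chi2 / 2.0))


def verdict(q: float) -> str:
    """accept (Q > 0.05) / marginal (0.001 < Q ≤ 0.05) / reject (Q ≤ 0.001)."""
    if not (0.0 <= q <= 1.0):
        raise ValueError("Q must lie in [0, 1]")
    if q > 0.05:
        return "accept"
    if q > 0.001:
        return "marginal"
    return "reject"


def discrimination_report(
    n_points: int, p_effective: int, chi2: float
) -> DiscriminationReport:
    dof = degrees_of_freedom(n_points, p_effective)
    q = q_value(dof, chi2)
    return DiscriminationReport(
        n_points=n_points,
        p_effective=p_effective,
        dof=dof,
        chi2=chi2,
        q=q,
        verdict=verdict(q),
    )
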