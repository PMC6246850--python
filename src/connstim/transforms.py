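"""Analytic network deconvolution / transitive closure and spectral scaling.

The two transforms form an exact inverse pair on symmetric matrices:
deconvolution maps eigenvalues through x -> x/(1+x), closure through
x -> x/(1-x).  Closure equals the matrix power series D + D^2 + D^3 + ...
whenever the spectral radius of D is below one, so a connectivity matrix
is interpreted as the accumulation of all direct and indirect paths of a
direct-interaction matrix.

A shared linear rescaling (``compute_scaling_factor`` / ``apply_scaling``)
bounds the deconvolved spectra by ``beta`` so that arbitrary multiplicative
perturbations of the direct network stay inside the convergent regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FunctionalConnectome",
    "DirectNetwork",
    "ScalingParams",
    "SingularTransformError",
    "DivergenceError",
    "network_deconvolution",
    "transitive_closure",
    "compute_scaling_factor",
    "apply_scaling",
]

#: default tolerance for the eigenvalue guards (lambda != -1, eta < 1)
DEFAULT_GUARD_TOL = 1e-9

#: asymmetry above this is an input error; below it the matrix is symmetrized
SYMMETRY_TOL = 1e-12


class SingularTransformError(ValueError):
    """Deconvolution is singular: an eigenvalue of F is (numerically) -1."""


class DivergenceError(ValueError):
    """Closure diverges: an eigenvalue of D is (numerically) >= 1."""


def _as_symmetric(matrix: np.ndarray, *, what: str = "matrix") -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{what} must be square, got shape {m.shape}")
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(
            f"{what} is asymmetric beyond {SYMMETRY_TOL:g} (max |M - M^T| = {asym:g})"
        )
    return (m + m.T) / 2.0


def _default_regions(n: int) -> tuple[str, ...]:
    return tuple(f"r{i + 1}" for i in range(n))


@dataclass(frozen=True)
class FunctionalConnectome:
    """Symmetric region-by-region connectivity matrix in Fisher-z units.

    Measured connectomes carry an exactly-zero diagonal (self-correlation is
    undefined under the z-transform); matrices produced analytically by
    :func:`transitive_closure` may have nonzero diagonals and are accepted
    as-is so the transform pair stays exactly invertible.
    """

    matrix: np.ndarray
    regions: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = _as_symmetric(self.matrix, what="connectivity matrix")
        regions = tuple(self.regions) or _default_regions(m.shape[0])
        if len(regions) != m.shape[0]:
            raise ValueError(
                f"{len(regions)} region IDs for a {m.shape[0]}x{m.shape[0]} matrix"
            )
        if len(set(regions)) != len(regions):
            raise ValueError("region IDs must be unique")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "regions", regions)

    @classmethod
    def from_measurement(
        cls, matrix: np.ndarray, regions: Sequence[str] | None = ()
    ) -> "FunctionalConnectome":
        """Construct from a measured matrix, enforcing the zero diagonal."""
        m = _as_symmetric(matrix, what="connectivity matrix")
        if np.any(np.diag(m) != 0.0):
            raise ValueError("measured connectome must have an exactly-zero diagonal")
        return cls(m, tuple(regions or ()))

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def with_matrix(self, matrix: np.ndarray) -> "FunctionalConnectome":
        return FunctionalConnectome(matrix, self.regions)


@dataclass(frozen=True)
class DirectNetwork:
    """Symmetric direct-interaction matrix (output of deconvolution)."""

    matrix: np.ndarray
    regions: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = _as_symmetric(self.matrix, what="direct network")
        regions = tuple(self.regions) or _default_regions(m.shape[0])
        if len(regions) != m.shape[0]:
            raise ValueError(
                f"{len(regions)} region IDs for a {m.shape[0]}x{m.shape[0]} matrix"
            )
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "regions", regions)

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvalsh(self.matrix)))) if self.matrix.size else 0.0


@dataclass(frozen=True)
class ScalingParams:
    """Pooled scaling factor alpha for a family of matrices at parameter beta.

    ``alpha`` is the minimum of the per-matrix upper bounds; multiplying every
    matrix by it caps the deconvolved spectral radius at ``beta``.
    """

    beta: float
    alpha: float
    per_matrix_bounds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must lie in (0, 1), got {self.beta}")
        if not self.per_matrix_bounds:
            raise ValueError("per_matrix_bounds must be nonempty")
        if not np.isclose(self.alpha, min(self.per_matrix_bounds)):
            raise ValueError("alpha must equal the minimum per-matrix bound")
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and positive, got {self.alpha}")


def _eig_sym(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.linalg.eigh(matrix)


def network_deconvolution(
    connectome: FunctionalConnectome, *, tol: float = DEFAULT_GUARD_TOL
) -> DirectNetwork:
    """Recover the direct network whose path expansion yields ``connectome``.

    Eigenvalues are mapped through ``x -> x/(1+x)`` in the eigenbasis of the
    input; eigenvectors are untouched.

    Raises
    ------
    SingularTransformError
        If an eigenvalue is within ``tol`` of -1 (the map has a pole there).
    """
    lam, u = _eig_sym(connectome.matrix)
    bad = np.abs(lam + 1.0) <= tol
    if np.any(bad):
        offending = lam[bad][0]
        raise SingularTransformError(
            f"eigenvalue {offending:.12g} of the connectivity matrix is within "
            f"{tol:g} of -1; deconvolution is singular"
        )
    d = (u * (lam / (1.0 + lam))) @ u.T
    return DirectNetwork((d + d.T) / 2.0, connectome.regions)


def transitive_closure(
    direct: DirectNetwork, *, tol: float = DEFAULT_GUARD_TOL
) -> FunctionalConnectome:
    """Accumulate all direct and indirect paths of ``direct``.

    Analytic form of the series ``D + D^2 + D^3 + ...``: eigenvalues are
    mapped through ``x -> x/(1-x)``.

    Raises
    ------
    DivergenceError
        If any eigenvalue is >= ``1 - tol``: the series diverges, i.e. the
        (post-stimulation) network is infeasible.  Callers simulating
        stimulation may catch this and mark the strength infeasible.
    """
    eta, v = _eig_sym(direct.matrix)
    if np.any(eta >= 1.0 - tol):
        offending = float(eta[eta >= 1.0 - tol][0])
        raise DivergenceError(
            f"eigenvalue {offending:.12g} of the direct network is >= 1 - {tol:g}; "
            "the path series diverges"
        )
    f = (v * (eta / (1.0 - eta))) @ v.T
    return FunctionalConnectome((f + f.T) / 2.0, direct.regions)


def _per_matrix_bound(matrix: np.ndarray, beta: float) -> float:
    """Upper bound on alpha for one matrix from its extreme eigenvalues.

    min( beta / ((1-beta) * lambda_max_pos), -beta / ((1+beta) * lambda_min_neg) );
    a missing positive (or negative) eigenvalue drops its term.  An all-zero
    spectrum contributes +inf (the matrix imposes no constraint).
    """
    lam = np.linalg.eigvalsh(matrix)
    bounds = []
    lam_pos = lam[lam > 0]
    if lam_pos.size:
        bounds.append(beta / ((1.0 - beta) * float(lam_pos.max())))
    lam_neg = lam[lam < 0]
    if lam_neg.size:
        bounds.append(-beta / ((1.0 + beta) * float(lam_neg.min())))
    return min(bounds) if bounds else float("inf")


def compute_scaling_factor(
    matrices: Sequence[FunctionalConnectome | np.ndarray], beta: float = 0.5
) -> ScalingParams:
    """Pooled scaling factor: the minimum per-matrix bound over ``matrices``.

    After multiplying every pooled matrix by the returned alpha, each
    deconvolved matrix has spectral radius at most ``beta``.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must lie in (0, 1), got {beta}")
    if len(matrices) == 0:
        raise ValueError("need at least one matrix to compute a scaling factor")
    bounds = []
    for m in matrices:
        arr = m.matrix if isinstance(m, FunctionalConnectome) else _as_symmetric(m)
        bounds.append(_per_matrix_bound(arr, beta))
    alpha = min(bounds)
    if not np.isfinite(alpha):
        raise ValueError("all matrices have zero spectrum; nothing to scale")
    return ScalingParams(beta=beta, alpha=alpha, per_matrix_bounds=tuple(bounds))


def apply_scaling(
    connectome: FunctionalConnectome, params: ScalingParams
) -> FunctionalConnectome:
    """Multiply every entry by ``params.alpha``."""
    return connectome.with_matrix(connectome.matrix * params.alpha)
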