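"""Perturbation operators and simulated focal stimulation.

A stimulation event is modelled as an element-wise multiplicative operator
on the direct network: entries in the target rows/columns carry the
strength ``s`` (s > 1 up-regulates, s < 1 down-regulates), all other
entries are 1.  The post-stimulation connectome is the transitive closure
of the perturbed direct network; if the perturbed spectrum reaches 1 the
combination is reported as infeasible rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectome import Parcellation
from .evaluation import OutcomeRecord, connectomic_similarity, relative_change
from .transforms import (
    DEFAULT_GUARD_TOL,
    DirectNetwork,
    FunctionalConnectome,
    network_deconvolution,
)

__all__ = [
    "PerturbationOperator",
    "StimulationProtocol",
    "build_perturbation",
    "apply_stimulation",
    "sweep",
    "default_strength_grid",
]


@dataclass(frozen=True)
class PerturbationOperator:
    """Multiplicative operator: ``s`` on the target rows/columns, 1 elsewhere."""

    matrix: np.ndarray
    target_regions: frozenset[int]  # 0-based row/column indices
    strength: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if self.strength <= 0:
            raise ValueError(f"strength must be positive, got {self.strength}")
        if np.max(np.abs(m - m.T)) > 0:
            raise ValueError("perturbation operator must be symmetric")
        mask = np.zeros(m.shape, dtype=bool)
        targets = sorted(self.target_regions)
        mask[targets, :] = True
        mask[:, targets] = True
        expected = np.where(mask, self.strength, 1.0)
        if not np.array_equal(m, expected):
            raise ValueError("entries must be s on target rows/columns and 1 elsewhere")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "target_regions", frozenset(self.target_regions))

    @classmethod
    def from_targets(
        cls, n_regions: int, target_regions: Sequence[int], strength: float
    ) -> "PerturbationOperator":
        matrix = np.ones((n_regions, n_regions))
        targets = sorted(set(target_regions))
        if targets and (targets[0] < 0 or targets[-1] >= n_regions):
            raise ValueError("target region index out of range")
        matrix[targets, :] = strength
        matrix[:, targets] = strength
        return cls(matrix, frozenset(targets), strength)

    def compose(self, other: "PerturbationOperator") -> np.ndarray:
        """Element-wise product (not necessarily a two-valued operator)."""
        return self.matrix * other.matrix


def default_strength_grid(
    low: float = 0.02, high: float = 2.0, step: float = 0.02
) -> tuple[float, ...]:
    """Evenly spaced multiplicative strengths; must bracket and include 1.0."""
    n = int(round((high - low) / step)) + 1
    grid = tuple(round(low + i * step, 10) for i in range(n))
    return grid


@dataclass(frozen=True)
class StimulationProtocol:
    """Which homologous pairs to stimulate and at which strengths."""

    strength_grid: tuple[float, ...]
    target_pair_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        grid = tuple(float(s) for s in self.strength_grid)
        if not grid:
            raise ValueError("strength grid is empty")
        if any(s <= 0 for s in grid):
            raise ValueError("strengths must be strictly positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("strength grid must be strictly increasing")
        if not any(np.isclose(s, 1.0) for s in grid):
            raise ValueError("strength grid must contain 1.0 (the identity strength)")
        if not self.target_pair_ids:
            raise ValueError("protocol needs at least one target pair")
        object.__setattr__(self, "strength_grid", grid)
        object.__setattr__(self, "target_pair_ids", tuple(int(p) for p in self.target_pair_ids))

    @classmethod
    def default(cls, parcellation: Parcellation) -> "StimulationProtocol":
        """All bilateral pairs, strengths 0.02 ... 2.00 in steps of 0.02."""
        return cls(default_strength_grid(), parcellation.pair_ids)


def build_perturbation(
    parcellation: Parcellation, target_pair_id: int, strength: float
) -> PerturbationOperator:
    """Bilateral operator for one homologous pair (both rows and columns)."""
    left, right = parcellation.pair_members(target_pair_id)
    return PerturbationOperator.from_targets(
        parcellation.n_regions, (left.index - 1, right.index - 1), strength
    )


def apply_stimulation(
    connectome: FunctionalConnectome,
    perturbation: PerturbationOperator,
    *,
    tol: float = DEFAULT_GUARD_TOL,
    direct: DirectNetwork | None = None,
) -> FunctionalConnectome | None:
    """Post-stimulation connectome TC(ND(F) * P), or None if infeasible.

    ``direct`` may pass a cached deconvolution of ``connectome`` (it is
    strength-independent, so sweeps compute it once).
    """
    if perturbation.matrix.shape[0] != connectome.n_regions:
        raise ValueError("perturbation and connectome dimensions do not match")
    if direct is None:
        direct = network_deconvolution(connectome, tol=tol)
    d_prime = direct.matrix * perturbation.matrix
    eta, v = np.linalg.eigh(d_prime)
    if eta[-1] >= 1.0 - tol:
        return None
    f = (v * (eta / (1.0 - eta))) @ v.T
    return FunctionalConnectome((f + f.T) / 2.0, connectome.regions)


def sweep(
    connectome: FunctionalConnectome,
    protocol: StimulationProtocol,
    healthy_ref: FunctionalConnectome,
    parcellation: Parcellation,
    *,
    subject_id: str = "subject",
    tol: float = DEFAULT_GUARD_TOL,
) -> list[OutcomeRecord]:
    """Evaluate every (target pair, strength) combination for one connectome.

    Returns one record per combination; infeasible combinations carry
    ``feasible=False`` and NaN outcome values.
    """
    if connectome.regions != healthy_ref.regions:
        raise ValueError("connectome and healthy reference must share region order")
    if parcellation.abbreviations != connectome.regions:
        raise ValueError("parcellation region order does not match the connectome")
    n = connectome.n_regions
    direct = network_deconvolution(connectome, tol=tol)
    cc_pre = connectomic_similarity(connectome, healthy_ref)

    # lean inner loop: one eigendecomposition per combination, similarity
    # computed directly on the upper-triangle vectors
    iu = np.triu_indices(n, k=1)
    ref = healthy_ref.matrix[iu]
    ref_centered = ref - ref.mean()
    ref_norm = float(np.linalg.norm(ref_centered))
    d = direct.matrix
    records: list[OutcomeRecord] = []
    for pair_id in protocol.target_pair_ids:
        left, right = parcellation.pair_members(pair_id)
        rows = [left.index - 1, right.index - 1]
        for s in protocol.strength_grid:
            dp = d.copy()
            dp[rows, :] *= s
            dp[:, rows] *= s
            dp[np.ix_(rows, rows)] /= s  # intersection entries receive s once
            eta, v = np.linalg.eigh(dp)
            if eta[-1] >= 1.0 - tol:
                records.append(
                    OutcomeRecord(
                        subject_id=subject_id,
                        target_pair_id=pair_id,
                        strength=s,
                        cc_pre=cc_pre,
                        cc_post=float("nan"),
                        relative_change_pct=float("nan"),
                        feasible=False,
                    )
                )
                continue
            post = (v * (eta / (1.0 - eta))) @ v.T
            x = post[iu]
            x = x - x.mean()
            cc_post = float(x @ ref_centered / (np.linalg.norm(x) * ref_norm))
            cc_post = min(1.0, max(-1.0, cc_post))  # guard float overshoot
            records.append(
                OutcomeRecord(
                    subject_id=subject_id,
                    target_pair_id=pair_id,
                    strength=s,
                    cc_pre=cc_pre,
                    cc_post=cc_post,
                    relative_change_pct=relative_change(cc_pre, cc_post),
                    feasible=True,
                )
            )
    return records
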