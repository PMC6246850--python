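"""Synthetic cohorts with known ground truth.

Generators follow the model's own forward direction: a shared direct
network prototype, per-subject noise on the direct network, and observed
connectomes produced by transitive closure.  Patient cohorts implant known
multiplicative lesions into the direct network before closure, so the
pipeline's output on noiseless data is exactly predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .connectome import CohortData, Parcellation, Region, RegionTimeSeries
from .transforms import DirectNetwork, FunctionalConnectome, transitive_closure

__all__ = [
    "LesionSpec",
    "SyntheticCohortSpec",
    "synthetic_parcellation",
    "generate_prototype",
    "generate_healthy_cohort",
    "generate_patient_cohort",
    "generate_timeseries",
    "generate_synthetic_atlas",
]


@dataclass(frozen=True)
class LesionSpec:
    """One implanted lesion: pair, multiplicative depth, carrier fraction."""

    pair_id: int
    strength: float
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError("lesion strength must be positive")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("carrier fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_regions: int = 92
    n_healthy: int = 10
    n_patients: int = 10
    prototype_density: float = 0.3
    weight_scale: float = 0.3
    prototype_radius: float = 0.4
    subject_noise_sd: float = 0.0
    lesions: tuple[LesionSpec, ...] = ()
    planted_edge_shift: tuple[tuple[tuple[int, int], ...], float] | None = None
    severity_model: tuple[float, float, float] | None = None  # (base, slope, noise sd)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 4 or self.n_regions % 2:
            raise ValueError("n_regions must be an even integer >= 4")
        if not 0.0 < self.prototype_density <= 1.0:
            raise ValueError("prototype_density must lie in (0, 1]")
        if not 0.0 < self.prototype_radius < 1.0:
            raise ValueError("prototype_radius must lie in (0, 1)")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be non-negative")
        object.__setattr__(self, "lesions", tuple(self.lesions))


def synthetic_parcellation(n_regions: int) -> Parcellation:
    """Generic even parcellation: pair k owns regions 2k-1 (L) and 2k (R)."""
    if n_regions % 2:
        raise ValueError("n_regions must be even")
    regions = []
    for k in range(1, n_regions // 2 + 1):
        for hemi, idx in (("L", 2 * k - 1), ("R", 2 * k)):
            regions.append(
                Region(
                    index=idx,
                    abbreviation=f"R{k:03d}.{hemi}",
                    description=f"synthetic region pair {k}",
                    lobe="Synthetic",
                    hemisphere=hemi,
                    pair_id=k,
                )
            )
    return Parcellation(tuple(regions))


def _symmetric_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    noise = np.zeros((n, n))
    if sd > 0:
        iu = np.triu_indices(n, k=1)
        vals = rng.normal(0.0, sd, size=len(iu[0]))
        noise[iu] = vals
        noise = noise + noise.T
    return noise


def _rescale_radius(matrix: np.ndarray, target: float) -> np.ndarray:
    radius = float(np.max(np.abs(np.linalg.eigvalsh(matrix))))
    if radius == 0.0:
        raise ValueError("matrix has zero spectrum; cannot rescale spectral radius")
    return matrix * (target / radius)


def generate_prototype(spec: SyntheticCohortSpec) -> DirectNetwork:
    """Shared direct-network prototype: sparse symmetric support, half-normal
    weights, spectral radius rescaled to ``spec.prototype_radius``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    iu = np.triu_indices(n, k=1)
    support = rng.random(len(iu[0])) < spec.prototype_density
    weights = np.abs(rng.normal(0.0, spec.weight_scale, size=len(iu[0]))) * support
    d0 = np.zeros((n, n))
    d0[iu] = weights
    d0 = d0 + d0.T
    d0 = _rescale_radius(d0, spec.prototype_radius)
    regions = synthetic_parcellation(n).abbreviations
    return DirectNetwork(d0, regions)


def _subject_direct(
    prototype: np.ndarray, sd: float, rng: np.random.Generator, cap: float = 0.8
) -> np.ndarray:
    d = prototype + _symmetric_noise(prototype.shape[0], sd, rng)
    radius = float(np.max(np.abs(np.linalg.eigvalsh(d))))
    if radius > cap:  # keep closure well inside convergence
        d = d * (cap / radius)
    return d


def generate_healthy_cohort(
    spec: SyntheticCohortSpec, prototype: DirectNetwork | None = None
) -> CohortData:
    """Healthy subjects: prototype + symmetric noise on D, then closure."""
    if prototype is None:
        prototype = generate_prototype(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    subjects = []
    for i in range(spec.n_healthy):
        d = _subject_direct(prototype.matrix, spec.subject_noise_sd, rng)
        f = transitive_closure(DirectNetwork(d, prototype.regions))
        subjects.append((f"hc{i + 1:03d}", "healthy", f))
    return CohortData(tuple(subjects))


def _lesion_operator(
    parcellation: Parcellation, pair_id: int, strength: float, n: int
) -> np.ndarray:
    left, right = parcellation.pair_members(pair_id)
    p = np.ones((n, n))
    rows = (left.index - 1, right.index - 1)
    p[rows, :] = strength
    p[:, rows] = strength
    return p


def generate_patient_cohort(
    spec: SyntheticCohortSpec, prototype: DirectNetwork | None = None
) -> tuple[CohortData, dict[str, dict]]:
    """Patients with implanted lesions, plus a ground-truth ledger.

    The ledger maps subject id to the lesions it carries, each with the
    implied corrective strength ``1 / s0``.  Carriers are drawn without
    replacement per lesion (a subject may carry several lesions).
    """
    if prototype is None:
        prototype = generate_prototype(spec)
    parcellation = synthetic_parcellation(spec.n_regions)
    for lesion in spec.lesions:
        parcellation.pair_members(lesion.pair_id)  # raises on unknown pair
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    n = spec.n_regions
    carriers: dict[int, list[LesionSpec]] = {i: [] for i in range(spec.n_patients)}
    for lesion in spec.lesions:
        n_carriers = int(round(lesion.fraction * spec.n_patients))
        chosen = rng.choice(spec.n_patients, size=n_carriers, replace=False)
        for i in chosen:
            carriers[int(i)].append(lesion)
    subjects = []
    ledger: dict[str, dict] = {}
    clinical: dict[str, float] = {}
    for i in range(spec.n_patients):
        sid = f"pd{i + 1:03d}"
        d = _subject_direct(prototype.matrix, spec.subject_noise_sd, rng)
        depth = 0.0
        for lesion in carriers[i]:
            d = d * _lesion_operator(parcellation, lesion.pair_id, lesion.strength, n)
            depth += abs(np.log(lesion.strength))
        eta_max = float(np.max(np.linalg.eigvalsh(d)))
        if eta_max >= 1.0:
            raise ValueError(
                f"lesion pushes subject {sid} past the convergence bound "
                f"(max eigenvalue {eta_max:.3f})"
            )
        f = transitive_closure(DirectNetwork(d, prototype.regions))
        if spec.planted_edge_shift is not None:
            edges, shift = spec.planted_edge_shift
            m = f.matrix.copy()
            for a, b in edges:
                m[a, b] += shift
                m[b, a] += shift
            f = FunctionalConnectome(m, f.regions)
        subjects.append((sid, "patient", f))
        ledger[sid] = {
            "lesions": [
                {
                    "pair_id": lesion.pair_id,
                    "strength": lesion.strength,
                    "corrective_strength": 1.0 / lesion.strength,
                }
                for lesion in carriers[i]
            ],
            "lesion_depth": depth,
        }
        if spec.severity_model is not None:
            base, slope, noise_sd = spec.severity_model
            clinical[sid] = base + slope * depth + (
                rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            )
    cohort = CohortData(tuple(subjects), clinical or None)
    return cohort, ledger


def generate_timeseries(
    target: FunctionalConnectome,
    n_timepoints: int,
    seed: int,
    *,
    max_repair: float = 0.1,
) -> RegionTimeSeries:
    """Multivariate-normal series whose correlation matrix is tanh(F).

    ``tanh`` inverts the Fisher z-transform; the implied correlation matrix
    is repaired to the nearest positive-definite correlation matrix by
    eigenvalue clipping, and generation fails if the repair moves any entry
    by more than ``max_repair``.
    """
    c = np.tanh(target.matrix.copy())
    np.fill_diagonal(c, 1.0)
    if np.max(np.abs(c)) > 1.0:
        raise ValueError("tanh of the target matrix exceeds 1 in magnitude")
    lam, u = np.linalg.eigh(c)
    repaired = (u * np.clip(lam, 1e-6, None)) @ u.T
    scale = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(scale, scale)
    repair = float(np.max(np.abs(repaired - c)))
    if repair > max_repair:
        raise ValueError(
            f"nearest-correlation repair moved an entry by {repair:.4f} "
            f"(> {max_repair}); target is too far from a valid correlation matrix"
        )
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(repaired + 1e-12 * np.eye(len(repaired)))
    data = rng.standard_normal((n_timepoints, len(repaired))) @ chol.T
    return RegionTimeSeries(data, target.regions)


def generate_synthetic_atlas(
    n_regions: int, volume_shape: tuple[int, int, int], seed: int
) -> tuple[np.ndarray, Parcellation]:
    """Voronoi-style labelled volume split left/right at the x midline.

    Seeds are drawn in the left half and mirrored to the right, so paired
    regions have (approximately) mirrored shapes; labels follow the odd/even
    hemisphere convention (pair k -> regions 2k-1 L, 2k R).
    """
    if n_regions % 2:
        raise ValueError("n_regions must be even")
    nx, ny, nz = volume_shape
    half = nx // 2
    n_half = n_regions // 2
    left_voxels = np.array([(x, y, z) for x in range(half) for y in range(ny) for z in range(nz)])
    if len(left_voxels) < n_half:
        raise ValueError(
            f"volume {volume_shape} has only {len(left_voxels)} left-hemisphere "
            f"voxels for {n_half} regions"
        )
    rng = np.random.default_rng(seed)
    seed_idx = rng.choice(len(left_voxels), size=n_half, replace=False)
    left_seeds = left_voxels[seed_idx].astype(float)
    atlas = np.zeros(volume_shape, dtype=np.int32)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if x < half:
                    pos = np.array([x, y, z], dtype=float)
                    k = int(np.argmin(((left_seeds - pos) ** 2).sum(axis=1)))
                    atlas[x, y, z] = 2 * k + 1
                else:
                    mirrored = np.array([nx - 1 - x, y, z], dtype=float)
                    k = int(np.argmin(((left_seeds - mirrored) ** 2).sum(axis=1)))
                    atlas[x, y, z] = 2 * k + 2
    parcellation = synthetic_parcellation(n_regions)
    present = set(np.unique(atlas).tolist())
    missing = set(range(1, n_regions + 1)) - present
    if missing:
        raise ValueError(f"labels missing from the synthetic atlas: {sorted(missing)}")
    return atlas, parcellation
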