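"""Connectome and parcellation handling.

Builds Fisher-z connectivity matrices from regional time series, averages
them by group, reads/writes the plain-text interchange formats (TSV
matrices, parcellation tables, time-series tables, NIfTI label volumes),
and subdivides a parcellation into a high-resolution template by
volume-proportional seeding plus per-region k-means.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transforms import FunctionalConnectome

__all__ = [
    "Region",
    "Parcellation",
    "RegionTimeSeries",
    "CohortData",
    "build_connectome",
    "group_average",
    "subdivide_parcellation",
    "default_parcellation",
    "read_parcellation",
    "write_parcellation",
    "read_connectome",
    "write_connectome",
    "read_timeseries",
    "write_timeseries",
    "read_atlas",
    "write_atlas",
]

PARCELLATION_COLUMNS = ("index", "abbreviation", "description", "lobe", "hemisphere", "pair_id")


@dataclass(frozen=True)
class Region:
    index: int  # 1-based
    abbreviation: str
    description: str
    lobe: str
    hemisphere: str  # "L" or "R"
    pair_id: int


@dataclass(frozen=True)
class Parcellation:
    """Ordered region table with homologous left/right pairing."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.regions]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("region indices must be unique and contiguous from 1")
        if len({r.abbreviation for r in self.regions}) != len(self.regions):
            raise ValueError("region abbreviations must be unique")
        pairs: dict[int, dict[str, Region]] = {}
        for r in self.regions:
            if r.hemisphere not in ("L", "R"):
                raise ValueError(f"hemisphere must be L or R, got {r.hemisphere!r}")
            side = pairs.setdefault(r.pair_id, {})
            if r.hemisphere in side:
                raise ValueError(f"pair {r.pair_id} has two {r.hemisphere} members")
            side[r.hemisphere] = r
        for pid, side in pairs.items():
            if set(side) != {"L", "R"}:
                raise ValueError(f"pair {pid} is missing a hemisphere partner")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(r.abbreviation for r in self.regions)

    @property
    def pair_ids(self) -> tuple[int, ...]:
        """Sorted unique homologous-pair IDs."""
        return tuple(sorted({r.pair_id for r in self.regions}))

    def pair_members(self, pair_id: int) -> tuple[Region, Region]:
        """(left, right) members of one homologous pair."""
        members = {r.hemisphere: r for r in self.regions if r.pair_id == pair_id}
        if not members:
            raise KeyError(f"unknown pair id {pair_id}")
        return members["L"], members["R"]

    def pair_label(self, pair_id: int) -> str:
        left, _ = self.pair_members(pair_id)
        abbrev = left.abbreviation
        return abbrev[:-2] if abbrev.endswith((".L", ".R")) else abbrev

    def pair_id_by_label(self, label: str) -> int:
        for pid in self.pair_ids:
            if self.pair_label(pid) == label:
                return pid
        raise KeyError(f"no homologous pair labelled {label!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.regions], columns=PARCELLATION_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Parcellation":
        missing = set(PARCELLATION_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"parcellation table is missing columns {sorted(missing)}")
        regions = tuple(
            Region(
                index=int(row["index"]),
                abbreviation=str(row["abbreviation"]),
                description=str(row["description"]),
                lobe=str(row["lobe"]),
                hemisphere=str(row["hemisphere"]),
                pair_id=int(row["pair_id"]),
            )
            for _, row in frame.sort_values("index").iterrows()
        )
        return cls(regions)


def default_parcellation() -> Parcellation:
    """The shipped 92-region scheme (AAL cortical/subcortical regions + bilateral STN)."""
    ref = importlib.resources.files("connstim.data").joinpath("parcellation_92.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_parcellation(path)


def read_parcellation(path: str | Path) -> Parcellation:
    return Parcellation.from_frame(pd.read_csv(path, sep="\t"))


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    parcellation.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RegionTimeSeries:
    """time x region signal table; ``tr_seconds`` is metadata only."""

    data: np.ndarray
    regions: tuple[str, ...]
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("time series must be a 2-D (time x region) array")
        if data.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if data.shape[1] != len(self.regions):
            raise ValueError("column count must match the number of region IDs")
        if not np.all(np.isfinite(data)):
            raise ValueError("time series contains NaN/inf; preprocessing is out of scope")
        constant = np.ptp(data, axis=0) == 0
        if np.any(constant):
            bad = [self.regions[i] for i in np.flatnonzero(constant)]
            raise ValueError(f"constant-valued columns have undefined correlation: {bad}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        data.flags.writeable = False
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "regions", tuple(self.regions))


@dataclass(frozen=True)
class CohortData:
    """Subject connectomes with group labels and optional clinical scores."""

    subjects: tuple[tuple[str, str, FunctionalConnectome], ...]
    clinical: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("cohort must contain at least one subject")
        ids = [s[0] for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject IDs must be unique")
        regions = self.subjects[0][2].regions
        for sid, label, conn in self.subjects:
            if label not in ("patient", "healthy"):
                raise ValueError(f"group label must be 'patient' or 'healthy', got {label!r}")
            if conn.regions != regions:
                raise ValueError(f"subject {sid} has a different region order")
        object.__setattr__(self, "subjects", tuple(self.subjects))

    @property
    def regions(self) -> tuple[str, ...]:
        return self.subjects[0][2].regions

    def select(self, label: str) -> tuple[tuple[str, str, FunctionalConnectome], ...]:
        return tuple(s for s in self.subjects if s[1] == label)

    def connectomes(self, label: str) -> list[FunctionalConnectome]:
        return [s[2] for s in self.select(label)]

    def subset(self, subject_ids: Iterable[str]) -> "CohortData":
        wanted = set(subject_ids)
        kept = tuple(s for s in self.subjects if s[0] in wanted)
        clinical = None
        if self.clinical is not None:
            clinical = {k: v for k, v in self.clinical.items() if k in wanted}
        return CohortData(kept, clinical)


def build_connectome(ts: RegionTimeSeries) -> FunctionalConnectome:
    """Pearson correlation between regional time series, Fisher z-transformed.

    The diagonal is defined as exactly 0 (self-correlation would be infinite
    under the z-transform and never enters any downstream statistic).
    """
    r = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(r, 0.0)
    degenerate = np.abs(r) >= 1.0
    if np.any(degenerate):
        i, j = np.argwhere(degenerate)[0]
        raise ValueError(
            f"|r| = 1 between regions {ts.regions[i]!r} and {ts.regions[j]!r}; "
            "Fisher z is infinite"
        )
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return FunctionalConnectome.from_measurement((z + z.T) / 2.0, ts.regions)


def group_average(cohort: CohortData, label: str) -> FunctionalConnectome:
    """Entrywise mean of the Fisher-z matrices carrying ``label``."""
    mats = cohort.connectomes(label)
    if not mats:
        raise ValueError(f"no subjects with group label {label!r}")
    mean = np.mean([m.matrix for m in mats], axis=0)
    return FunctionalConnectome(mean, cohort.regions)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_connectome(connectome: FunctionalConnectome, path: str | Path) -> None:
    """TSV square matrix; first row and column are the region abbreviations."""
    frame = pd.DataFrame(
        connectome.matrix, index=list(connectome.regions), columns=list(connectome.regions)
    )
    frame.to_csv(path, sep="\t", index_label="region")


def read_connectome(
    path: str | Path, parcellation: Parcellation | None = None
) -> FunctionalConnectome:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column region labels disagree")
    regions = tuple(str(c) for c in frame.columns)
    if parcellation is not None and regions != parcellation.abbreviations:
        raise ValueError(f"{path}: region order does not match the parcellation")
    matrix = frame.to_numpy(dtype=float)
    asym = np.max(np.abs(matrix - matrix.T)) if matrix.size else 0.0
    if asym > 1e-8:
        raise ValueError(f"{path}: matrix is asymmetric (max |M - M^T| = {asym:g})")
    return FunctionalConnectome((matrix + matrix.T) / 2.0, regions)


def read_atlas(path: str | Path, parcellation: Parcellation | None = None) -> np.ndarray:
    """Integer-labelled NIfTI-1 atlas volume; labels match parcellation indices."""
    import nibabel as nib

    volume = np.asarray(nib.load(str(path)).dataobj).astype(np.int32)
    if parcellation is not None:
        labels = set(np.unique(volume)) - {0}
        wanted = {r.index for r in parcellation.regions}
        if not labels <= wanted:
            raise ValueError(
                f"{path}: atlas labels {sorted(labels - wanted)} not in the parcellation"
            )
    return volume


def write_atlas(volume: np.ndarray, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(volume, dtype=np.int32), affine=np.eye(4))
    nib.save(img, str(path))


def write_timeseries(ts: RegionTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=list(ts.regions)).to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path, tr_seconds: float = 1.0) -> RegionTimeSeries:
    frame = pd.read_csv(path, sep="\t")
    return RegionTimeSeries(
        frame.to_numpy(dtype=float), tuple(str(c) for c in frame.columns), tr_seconds
    )


# ---------------------------------------------------------------------------
# parcellation subdivision
# ---------------------------------------------------------------------------

def _allocate_seeds(
    volumes: dict[int, int],
    parcellation: Parcellation,
    n_target: int,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Seed count per region: volume-proportional, >= 1 each, hemispheres equal.

    Seeds are drawn per homologous pair (the same count goes to both members),
    which satisfies the equal-hemisphere constraint exactly for even totals.
    """
    pair_ids = list(parcellation.pair_ids)
    members = {pid: parcellation.pair_members(pid) for pid in pair_ids}
    pair_volume = np.array(
        [volumes[members[pid][0].index] + volumes[members[pid][1].index] for pid in pair_ids],
        dtype=float,
    )
    n_pairs_seeds = n_target // 2
    counts = rng.multinomial(n_pairs_seeds - len(pair_ids), pair_volume / pair_volume.sum())
    counts = counts + 1  # >= 1 seed per region (per pair member)
    # guard: multinomial already sums correctly, but keep the floor-stealing
    # rule explicit in case of future allocation changes
    while counts.sum() > n_pairs_seeds:
        counts[np.argmax(counts)] -= 1
    per_region: dict[int, int] = {}
    for pid, c in zip(pair_ids, counts):
        left, right = members[pid]
        per_region[left.index] = int(c)
        per_region[right.index] = int(c)
    return per_region


def subdivide_parcellation(
    atlas: np.ndarray,
    parcellation: Parcellation,
    n_target: int,
    seed: int,
) -> tuple[np.ndarray, Parcellation]:
    """Split a labelled atlas volume into ``n_target`` subregions.

    Seeds are distributed across regions with probability proportional to
    regional voxel volume (>= 1 per region, equal totals per hemisphere);
    each region's voxels are then clustered into its seed count by k-means
    on voxel coordinates.  Subregions never cross parent-region boundaries.
    """
    from sklearn.cluster import KMeans

    atlas = np.asarray(atlas)
    n_orig = parcellation.n_regions
    if n_target < n_orig:
        raise ValueError(f"n_target = {n_target} < {n_orig} original regions")
    if n_target % 2 != 0:
        raise ValueError("n_target must be even to split seeds equally by hemisphere")
    volumes = {
        r.index: int(np.count_nonzero(atlas == r.index)) for r in parcellation.regions
    }
    empty = [r.abbreviation for r in parcellation.regions if volumes[r.index] == 0]
    if empty:
        raise ValueError(f"regions with no voxels in the atlas: {empty}")
    rng = np.random.default_rng(seed)
    seeds_per_region = _allocate_seeds(volumes, parcellation, n_target, rng)
    for r in parcellation.regions:
        if seeds_per_region[r.index] > volumes[r.index]:
            raise ValueError(
                f"region {r.abbreviation} got {seeds_per_region[r.index]} seeds "
                f"but has only {volumes[r.index]} voxels"
            )

    new_atlas = np.zeros_like(atlas, dtype=np.int32)
    new_regions: list[Region] = []
    next_index = 0
    next_pair = 0
    pair_of_sub: dict[tuple[int, int], int] = {}  # (parent pair, subcluster) -> new pair id
    for r in parcellation.regions:
        k = seeds_per_region[r.index]
        coords = np.argwhere(atlas == r.index)
        if k == 1:
            labels = np.zeros(len(coords), dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=1,
                max_iter=100,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            labels = km.fit_predict(coords.astype(float))
        # order clusters deterministically by centroid coordinates
        order = np.lexsort(
            tuple(
                np.array([coords[labels == c].mean(axis=0)[ax] for c in range(k)])
                for ax in reversed(range(coords.shape[1]))
            )
        )
        rank = {int(c): i for i, c in enumerate(order)}
        for sub in range(k):
            key = (r.pair_id, sub)
            if key not in pair_of_sub:
                next_pair += 1
                pair_of_sub[key] = next_pair
        for sub in range(k):
            next_index += 1
            sel = np.array([rank[int(lab)] == sub for lab in labels])
            new_atlas[tuple(coords[sel].T)] = next_index
            new_regions.append(
                Region(
                    index=next_index,
                    abbreviation=f"{r.abbreviation[:-2]}_{sub + 1:03d}.{r.hemisphere}"
                    if r.abbreviation.endswith((".L", ".R"))
                    else f"{r.abbreviation}_{sub + 1:03d}",
                    description=f"{r.description} (subregion {sub + 1})",
                    lobe=r.lobe,
                    hemisphere=r.hemisphere,
                    pair_id=pair_of_sub[(r.pair_id, sub)],
                )
            )
    assert next_index == n_target
    return new_atlas, Parcellation(tuple(new_regions))
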