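"""Outcome evaluation: similarity objective, optimisation, ranking,
cross-validation and clinical correlation.

The objective is the Pearson correlation between the vectorised strict
upper triangles of two connectomes ("connectomic similarity"); a simulated
stimulation is scored by the percent change of that similarity against a
group-averaged healthy reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import CohortData, Parcellation, group_average
from .transforms import FunctionalConnectome, compute_scaling_factor, apply_scaling

__all__ = [
    "OutcomeRecord",
    "TargetRanking",
    "CrossValResult",
    "connectomic_similarity",
    "relative_change",
    "optimize_strength",
    "rank_targets",
    "occurrence_summary",
    "rank_connectome",
    "rank_subjects",
    "subsample_cross_validation",
    "null_target_validation",
    "rank_severity_correlation",
    "compute_discrimination_auc",
    "write_outcomes",
]


@dataclass(frozen=True)
class OutcomeRecord:
    """One (subject/group, target, strength) simulation result."""

    subject_id: str
    target_pair_id: int
    strength: float
    cc_pre: float
    cc_post: float
    relative_change_pct: float
    feasible: bool

    def __post_init__(self) -> None:
        if not -1.0 <= self.cc_pre <= 1.0:
            raise ValueError(f"cc_pre = {self.cc_pre} outside [-1, 1]")
        if self.feasible:
            if not -1.0 <= self.cc_post <= 1.0:
                raise ValueError(f"cc_post = {self.cc_post} outside [-1, 1]")
            expected = (self.cc_post - self.cc_pre) / self.cc_pre * 100.0
            if abs(expected - self.relative_change_pct) > 1e-12 * max(1.0, abs(expected)):
                raise ValueError("relative_change_pct inconsistent with cc values")


@dataclass(frozen=True)
class TargetRanking:
    """Per subject (or group): targets ordered best-first.

    ``entries`` rows are (target_pair_id, best_strength, best_relative_change,
    rank) with rank 1 = best; relative change is non-increasing with rank.
    """

    subject_id: str
    entries: tuple[tuple[int, float, float, int], ...]

    def __post_init__(self) -> None:
        ranks = [e[3] for e in self.entries]
        if sorted(ranks) != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be a permutation of 1..n_targets")
        ordered = sorted(self.entries, key=lambda e: e[3])
        changes = [e[2] for e in ordered]
        if any(b > a + 1e-12 for a, b in zip(changes, changes[1:])):
            raise ValueError("relative change must be non-increasing with rank")
        object.__setattr__(self, "entries", tuple(self.entries))

    def rank_of(self, pair_id: int) -> int:
        for pid, _, _, rank in self.entries:
            if pid == pair_id:
                return rank
        raise KeyError(f"pair {pair_id} not in ranking")

    def best(self) -> tuple[int, float, float]:
        """(pair_id, best_strength, best_relative_change) of the rank-1 target."""
        for pid, s, rc, rank in self.entries:
            if rank == 1:
                return pid, s, rc
        raise AssertionError("no rank-1 entry")

    def top(self, k: int) -> tuple[int, ...]:
        return tuple(
            pid for pid, _, _, rank in sorted(self.entries, key=lambda e: e[3])[:k]
        )


def connectomic_similarity(a: FunctionalConnectome, b: FunctionalConnectome) -> float:
    """Pearson r between the strict upper triangles (row-major order)."""
    if a.regions != b.regions:
        raise ValueError("connectomes must share region order")
    n = a.n_regions
    if n < 3:
        raise ValueError("need at least 3 regions for a meaningful similarity")
    iu = np.triu_indices(n, k=1)
    x, y = a.matrix[iu], b.matrix[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance upper triangle; similarity undefined")
    return float(np.corrcoef(x, y)[0, 1])


def relative_change(cc_pre: float, cc_post: float) -> float:
    """Percent change of similarity relative to the pre-stimulation value."""
    if cc_pre == 0:
        raise ValueError("relative change is undefined for cc_pre = 0")
    if cc_pre < 0:
        warnings.warn(
            "cc_pre < 0: the sign of 'improvement' is inverted", stacklevel=2
        )
    return (cc_post - cc_pre) / cc_pre * 100.0


def optimize_strength(records: Sequence[OutcomeRecord]) -> tuple[float, float]:
    """Best (strength, relative change) among feasible records of one target.

    Ties in relative change are broken toward the strength closest to 1,
    then toward the smaller strength.
    """
    feasible = [r for r in records if r.feasible]
    if not feasible:
        raise ValueError("no feasible record for this target")
    pairs = {r.target_pair_id for r in records}
    if len(pairs) != 1:
        raise ValueError(f"records span several targets: {sorted(pairs)}")
    best = max(
        feasible,
        key=lambda r: (r.relative_change_pct, -abs(r.strength - 1.0), -r.strength),
    )
    return best.strength, best.relative_change_pct


def rank_targets(
    optima: Mapping[int, tuple[float, float]], *, subject_id: str = "group"
) -> TargetRanking:
    """Descending sort by best relative change; ties broken by pair id."""
    if not optima:
        raise ValueError("need at least one target")
    order = sorted(optima.items(), key=lambda kv: (-kv[1][1], kv[0]))
    entries = tuple(
        (pid, s, rc, rank)
        for rank, (pid, (s, rc)) in enumerate(order, start=1)
    )
    return TargetRanking(subject_id, entries)


def rank_connectome(
    connectome: FunctionalConnectome,
    healthy_ref: FunctionalConnectome,
    parcellation: Parcellation,
    protocol,
    *,
    subject_id: str = "group",
) -> tuple[TargetRanking, list[OutcomeRecord]]:
    """Sweep one (scaled) connectome and rank all targets.

    Targets with no feasible strength are excluded from the ranking.
    """
    from .stimulation import sweep  # local import to avoid a module cycle

    records = sweep(
        connectome, protocol, healthy_ref, parcellation, subject_id=subject_id
    )
    optima: dict[int, tuple[float, float]] = {}
    for pid in protocol.target_pair_ids:
        target_records = [r for r in records if r.target_pair_id == pid]
        try:
            optima[pid] = optimize_strength(target_records)
        except ValueError:
            continue  # target infeasible at every strength
    return rank_targets(optima, subject_id=subject_id), records


def rank_subjects(
    cohort: CohortData,
    parcellation: Parcellation,
    protocol,
    *,
    beta: float = 0.5,
    label: str = "patient",
) -> dict[str, TargetRanking]:
    """Per-subject rankings against the group-averaged healthy reference.

    One pooled scaling factor (computed over every subject connectome in the
    cohort) is applied to all matrices before simulation.
    """
    params = compute_scaling_factor([s[2] for s in cohort.subjects], beta)
    healthy_ref = apply_scaling(group_average(cohort, "healthy"), params)
    rankings: dict[str, TargetRanking] = {}
    for sid, lab, conn in cohort.select(label):
        ranking, _ = rank_connectome(
            apply_scaling(conn, params), healthy_ref, parcellation, protocol,
            subject_id=sid,
        )
        rankings[sid] = ranking
    return rankings


def occurrence_summary(rankings: Iterable[TargetRanking]) -> pd.DataFrame:
    """Counts per target of rank-1 ("best") and rank<=5 ("top-five") occurrences."""
    rankings = list(rankings)
    if not rankings:
        raise ValueError("no rankings given")
    target_sets = {frozenset(pid for pid, *_ in r.entries) for r in rankings}
    if len(target_sets) != 1:
        raise ValueError("rankings do not share one target set")
    targets = sorted(next(iter(target_sets)))
    n_best = {t: 0 for t in targets}
    n_top5 = {t: 0 for t in targets}
    for ranking in rankings:
        for pid, _, _, rank in ranking.entries:
            if rank == 1:
                n_best[pid] += 1
            if rank <= 5:
                n_top5[pid] += 1
    return pd.DataFrame(
        {
            "target_pair_id": targets,
            "n_best": [n_best[t] for t in targets],
            "n_top5": [n_top5[t] for t in targets],
        }
    )


@dataclass(frozen=True)
class CrossValResult:
    """Aggregate of repeated subsampled group-level rankings."""

    rankings: tuple[TargetRanking, ...]
    occurrence: pd.DataFrame  # target_pair_id, n_best, n_top5
    per_target: pd.DataFrame  # target_pair_id, mean/SD of best relative change


def _aggregate_crossval(rankings: list[TargetRanking]) -> CrossValResult:
    occ = occurrence_summary(rankings)
    targets = sorted({pid for r in rankings for pid, *_ in r.entries})
    changes = {t: [] for t in targets}
    for r in rankings:
        for pid, _, rc, _ in r.entries:
            changes[pid].append(rc)
    per_target = pd.DataFrame(
        {
            "target_pair_id": targets,
            "mean_relative_change_pct": [float(np.mean(changes[t])) for t in targets],
            "sd_relative_change_pct": [
                float(np.std(changes[t], ddof=1)) if len(changes[t]) > 1 else 0.0
                for t in targets
            ],
        }
    )
    return CrossValResult(tuple(rankings), occ, per_target)


def _group_iteration(
    patients: list[FunctionalConnectome],
    healthy: list[FunctionalConnectome],
    parcellation: Parcellation,
    protocol,
    beta: float,
    subject_id: str,
) -> TargetRanking:
    params = compute_scaling_factor(patients + healthy, beta)
    regions = patients[0].regions
    patient_avg = FunctionalConnectome(
        np.mean([m.matrix for m in patients], axis=0), regions
    )
    healthy_avg = FunctionalConnectome(
        np.mean([m.matrix for m in healthy], axis=0), regions
    )
    ranking, _ = rank_connectome(
        apply_scaling(patient_avg, params),
        apply_scaling(healthy_avg, params),
        parcellation,
        protocol,
        subject_id=subject_id,
    )
    return ranking


def subsample_cross_validation(
    cohort: CohortData,
    parcellation: Parcellation,
    protocol,
    *,
    n_iter: int,
    fraction: float = 0.5,
    seed: int = 0,
    beta: float = 0.5,
) -> CrossValResult:
    """Repeatedly subsample both groups and recompute the group ranking.

    Each iteration draws ``floor(fraction * n)`` subjects per group without
    replacement, recomputes the group averages and the pooled scaling
    factor, and ranks all targets for the subsampled patient average.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    patients = cohort.select("patient")
    healthy = cohort.select("healthy")
    if len(patients) < 2 or len(healthy) < 2:
        raise ValueError("need at least 2 subjects per group")
    n_pat = max(1, math.floor(fraction * len(patients)))
    n_hc = max(1, math.floor(fraction * len(healthy)))
    rng = np.random.default_rng(seed)
    rankings = []
    for it in range(n_iter):
        pat_idx = rng.choice(len(patients), size=n_pat, replace=False)
        hc_idx = rng.choice(len(healthy), size=n_hc, replace=False)
        rankings.append(
            _group_iteration(
                [patients[i][2] for i in pat_idx],
                [healthy[i][2] for i in hc_idx],
                parcellation,
                protocol,
                beta,
                subject_id=f"iter{it}",
            )
        )
    return _aggregate_crossval(rankings)


def null_target_validation(
    healthy_cohort: CohortData,
    parcellation: Parcellation,
    protocol,
    *,
    n_iter: int,
    fraction: float = 0.5,
    seed: int = 0,
    beta: float = 0.5,
) -> CrossValResult:
    """Bias check: treat random halves of the healthy group as 'patients'.

    Pseudo-patients are a without-replacement sample of the healthy group;
    the healthy reference is the complementary remainder, so the two sides
    never share a subject (``fraction`` must leave a nonempty remainder).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(
            f"fraction must lie in (0, 1): with fraction = {fraction} the "
            "pseudo-patients and the reference would coincide"
        )
    healthy = healthy_cohort.select("healthy")
    if len(healthy) < 4:
        raise ValueError("need at least 4 healthy subjects")
    n_pseudo = max(1, math.floor(fraction * len(healthy)))
    if n_pseudo >= len(healthy):
        raise ValueError("fraction leaves no subjects for the healthy reference")
    rng = np.random.default_rng(seed)
    rankings = []
    for it in range(n_iter):
        idx = rng.permutation(len(healthy))
        pseudo = [healthy[i][2] for i in idx[:n_pseudo]]
        reference = [healthy[i][2] for i in idx[n_pseudo:]]
        rankings.append(
            _group_iteration(
                pseudo, reference, parcellation, protocol, beta,
                subject_id=f"null{it}",
            )
        )
    return _aggregate_crossval(rankings)


def rank_severity_correlation(
    rankings: Mapping[str, TargetRanking],
    clinical: Mapping[str, float],
    target_pair_id: int,
) -> tuple[float, float]:
    """Kendall tau-b between one target's per-subject rank and a clinical score."""
    subjects = sorted(set(rankings) & set(clinical))
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects with both a ranking and a score")
    ranks = [rankings[s].rank_of(target_pair_id) for s in subjects]
    scores = [clinical[s] for s in subjects]
    if len(set(ranks)) == 1 or len(set(scores)) == 1:
        raise ValueError("all-tied input: Kendall tau is undefined")
    tau, p = stats.kendalltau(ranks, scores, variant="b")
    return float(tau), float(p)


def compute_discrimination_auc(
    cohort: CohortData, *, scaling_beta: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Similarity of every subject to the healthy reference, and the group AUC.

    Healthy subjects are compared against the leave-one-out healthy average
    (self-inclusion would inflate their similarity); patients against the
    full healthy average.  The AUC is the Mann-Whitney probability that a
    healthy subject scores a higher similarity than a patient.
    """
    patients = cohort.select("patient")
    healthy = cohort.select("healthy")
    if not patients or not healthy:
        raise ValueError("both groups must be nonempty")
    hc_mats = np.array([s[2].matrix for s in healthy])
    regions = cohort.regions
    hc_mean = FunctionalConnectome(hc_mats.mean(axis=0), regions)
    rows = []
    for sid, _, conn in patients:
        rows.append((sid, "patient", connectomic_similarity(conn, hc_mean)))
    n_hc = len(healthy)
    for i, (sid, _, conn) in enumerate(healthy):
        if n_hc > 1:
            loo = FunctionalConnectome(
                (hc_mats.sum(axis=0) - hc_mats[i]) / (n_hc - 1), regions
            )
        else:
            loo = hc_mean
        rows.append((sid, "healthy", connectomic_similarity(conn, loo)))
    frame = pd.DataFrame(rows, columns=["subject_id", "group", "similarity"])
    sim_hc = frame.loc[frame["group"] == "healthy", "similarity"].to_numpy()
    sim_pat = frame.loc[frame["group"] == "patient", "similarity"].to_numpy()
    u, _ = stats.mannwhitneyu(sim_hc, sim_pat, alternative="two-sided")
    auc = float(u) / (len(sim_hc) * len(sim_pat))
    return frame, auc


def write_outcomes(
    records: Iterable[OutcomeRecord], parcellation: Parcellation, path
) -> None:
    """Sweep output TSV (one row per subject x target x strength)."""
    frame = pd.DataFrame(
        [
            (
                r.subject_id,
                parcellation.pair_label(r.target_pair_id),
                r.strength,
                r.cc_pre,
                r.cc_post,
                r.relative_change_pct,
                r.feasible,
            )
            for r in records
        ],
        columns=[
            "subject_id",
            "target_abbrev",
            "strength",
            "similarity_pre",
            "similarity_post",
            "relative_change_pct",
            "feasible",
        ],
    )
    frame.to_csv(path, sep="\t", index=False)
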