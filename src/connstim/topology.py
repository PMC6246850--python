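"""Edge-wise group statistics and categorisation of topological change.

Each strict-upper-triangle edge is tested with a two-sample t-test on the
Fisher-z values and Bonferroni-corrected over all R(R-1)/2 edges.  Running
the test before and after a simulated stimulation partitions the edges
into removed / newly-emerged / unchanged abnormal connections (plus the
never-abnormal remainder).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import json
import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Parcellation
from .transforms import FunctionalConnectome

__all__ = [
    "EdgeTestResult",
    "EdgeCategoryMap",
    "CATEGORIES",
    "edgewise_group_test",
    "categorize_edges",
    "write_edge_table",
]

CATEGORIES = ("removed_abnormal", "new_abnormal", "unchanged_abnormal", "never_abnormal")


@dataclass(frozen=True)
class EdgeTestResult:
    """Per-edge two-sample t-test over the strict upper triangle."""

    edges: tuple[tuple[int, int], ...]  # 0-based (i, j), i < j, row-major
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray  # Bonferroni-corrected at the stored alpha
    degenerate: np.ndarray  # zero within-group variance in both groups
    alpha: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def corrected_threshold(self) -> float:
        return self.alpha / self.n_edges


def _upper_vectors(group: Sequence[FunctionalConnectome]) -> tuple[np.ndarray, int]:
    n = group[0].n_regions
    iu = np.triu_indices(n, k=1)
    return np.array([c.matrix[iu] for c in group]), n


def edgewise_group_test(
    group_a: Sequence[FunctionalConnectome],
    group_b: Sequence[FunctionalConnectome],
    alpha: float = 0.05,
    *,
    welch: bool = False,
) -> EdgeTestResult:
    """t-test per edge (group_a vs group_b), Bonferroni-corrected.

    Pooled-variance t by default; ``welch=True`` switches to Welch's t.
    Edges with zero variance in both groups are flagged degenerate and
    never significant.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    regions = group_a[0].regions
    for c in list(group_a) + list(group_b):
        if c.regions != regions:
            raise ValueError("all connectomes must share region order")
    a, n = _upper_vectors(group_a)
    b, _ = _upper_vectors(group_b)
    degenerate = (np.ptp(a, axis=0) == 0) & (np.ptp(b, axis=0) == 0)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (zero-variance) edges are excluded below; silence the
        # precision-loss warning they trigger inside the t-test
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    n_edges = a.shape[1]
    significant = np.zeros(n_edges, dtype=bool)
    ok = ~degenerate & np.isfinite(p)
    significant[ok] = p[ok] < alpha / n_edges
    iu = np.triu_indices(n, k=1)
    edges = tuple(zip(iu[0].tolist(), iu[1].tolist()))
    return EdgeTestResult(edges, t, p, significant, degenerate, alpha)


@dataclass(frozen=True)
class EdgeCategoryMap:
    """Mutually exclusive, exhaustive edge categories from pre/post tests."""

    edges: tuple[tuple[int, int], ...]
    categories: tuple[str, ...]
    pre: EdgeTestResult
    post: EdgeTestResult

    def counts(self) -> dict[str, int]:
        return {c: self.categories.count(c) for c in CATEGORIES}

    def lobe_pair_counts(self, parcellation: Parcellation) -> dict[str, dict[str, int]]:
        """Category counts per unordered lobe pair (category -> 'LobeA|LobeB' -> n)."""
        lobes = [r.lobe for r in parcellation.regions]
        out: dict[str, dict[str, int]] = {c: {} for c in CATEGORIES}
        for (i, j), cat in zip(self.edges, self.categories):
            key = "|".join(sorted((lobes[i], lobes[j])))
            out[cat][key] = out[cat].get(key, 0) + 1
        return out


def categorize_edges(pre: EdgeTestResult, post: EdgeTestResult) -> EdgeCategoryMap:
    """removed = significant pre only; new = post only; unchanged = both."""
    if pre.edges != post.edges:
        raise ValueError("pre and post tests cover different edge sets")
    categories = []
    for sig_pre, sig_post in zip(pre.significant, post.significant):
        if sig_pre and not sig_post:
            categories.append("removed_abnormal")
        elif not sig_pre and sig_post:
            categories.append("new_abnormal")
        elif sig_pre and sig_post:
            categories.append("unchanged_abnormal")
        else:
            categories.append("never_abnormal")
    return EdgeCategoryMap(pre.edges, tuple(categories), pre, post)


def write_edge_table(
    category_map: EdgeCategoryMap,
    parcellation: Parcellation,
    table_path,
    summary_path=None,
) -> None:
    """TSV edge table plus optional JSON summary of counts by lobe pair."""
    regions = parcellation.regions
    rows = []
    for k, (i, j) in enumerate(category_map.edges):
        rows.append(
            (
                regions[i].abbreviation,
                regions[j].abbreviation,
                regions[i].lobe,
                regions[j].lobe,
                category_map.pre.t[k],
                category_map.pre.p[k],
                category_map.post.t[k],
                category_map.post.p[k],
                category_map.categories[k],
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "region_i", "region_j", "lobe_i", "lobe_j",
            "t_pre", "p_pre", "t_post", "p_post", "category",
        ],
    ).to_csv(table_path, sep="\t", index=False)
    if summary_path is not None:
        summary = {
            "counts": category_map.counts(),
            "by_lobe_pair": category_map.lobe_pair_counts(parcellation),
        }
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
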