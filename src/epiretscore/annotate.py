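"""Interval overlap statistics, CpG-context annotation, pathway-set
arithmetic and hierarchical clustering of samples."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy

from .errors import ConfigError
from .io import Region, RegionSet

__all__ = ["OverlapStats", "CpGContext", "intersect_regions",
           "annotate_cpg_context", "set_overlap_stats", "cluster_samples",
           "ClusterResult"]

CONTEXT_LABELS = ("island", "shore", "shelf", "open_sea")


@dataclass(frozen=True)
class OverlapStats:
    """Overlap summary between two sets (of regions or of names).

    ``n_shared`` / ``n_shared_b`` count distinct members of A / B with at
    least one partner in the other set (for name sets the two coincide
    and equal |A ∩ B|).  Percentages are kept at full precision; round to
    one decimal for reporting.
    """

    n_a: int
    n_b: int
    n_shared: int
    n_shared_b: int
    jaccard: float

    @property
    def pct_a_shared(self) -> float:
        return 100.0 * self.n_shared / self.n_a if self.n_a else 0.0

    @property
    def pct_b_shared(self) -> float:
        return 100.0 * self.n_shared_b / self.n_b if self.n_b else 0.0

    def rounded(self) -> tuple[float, float]:
        """The two shared-percentages at the one-decimal reporting precision."""
        return round(self.pct_a_shared, 1), round(self.pct_b_shared, 1)


def _trees(rs: RegionSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(rs):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, i)
    return trees


def intersect_regions(a: RegionSet, b: RegionSet, min_overlap_bp: int = 1
                      ) -> tuple[list[tuple[Region, Region]], OverlapStats]:
    """All (a-region, b-region) pairs sharing >= ``min_overlap_bp`` bases.

    Counting is region-wise: ``n_shared`` is the number of distinct
    a-regions with at least one partner (and symmetrically for b), which
    matches how "% of DMRs also found in ..." is reported.
    """
    trees = _trees(b)
    pairs: list[tuple[Region, Region]] = []
    hit_a: set[int] = set()
    hit_b: set[int] = set()
    for ia, ra in enumerate(a):
        tree = trees.get(ra.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(ra.start, ra.end)):
            if min(ra.end, iv.end) - max(ra.start, iv.begin) >= min_overlap_bp:
                pairs.append((ra, b[iv.data]))
                hit_a.add(ia)
                hit_b.add(iv.data)
    shared_a, shared_b = len(hit_a), len(hit_b)
    denom = len(a) + len(b) - (shared_a + shared_b) / 2.0
    jac = (shared_a + shared_b) / 2.0 / denom if denom else 0.0
    return pairs, OverlapStats(len(a), len(b), shared_a, shared_b, jac)


def set_overlap_stats(list_a: Iterable[str], list_b: Iterable[str]) -> OverlapStats:
    """Exact set-intersection stats on case-normalized name lists."""
    a = {str(x).strip().lower() for x in list_a}
    b = {str(x).strip().lower() for x in list_b}
    shared = len(a & b)
    union = len(a | b)
    return OverlapStats(len(a), len(b), shared, shared,
                        shared / union if union else 0.0)


# ---------------------------------------------------------------------------
# CpG context
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpGContext:
    """Per-region island/shore/shelf/open-sea labels and their fractions."""

    labels: tuple[str, ...]
    fractions: dict[str, float]


def annotate_cpg_context(dmrs: RegionSet, islands: RegionSet,
                         shore_bp: int = 2000, shelf_bp: int = 2000,
                         collapse_flanks: bool = False) -> CpGContext:
    """Label each region by its CpG-island context.

    Precedence is island > shore > shelf > open_sea: a region touching an
    island (>= 1 bp) is an island region; otherwise within ``shore_bp``
    of an island it is shore; within a further ``shelf_bp`` it is shelf;
    everything else is open sea.  ``collapse_flanks`` folds shores and
    shelves into open_sea, giving the two-bucket island/open-sea summary
    some reports use.
    """
    if len(islands) == 0:
        warnings.warn("empty islands set: all regions labelled open_sea",
                      stacklevel=2)
    trees = _trees(islands)
    labels = []
    for r in dmrs:
        tree = trees.get(r.chrom)
        label = "open_sea"
        if tree is not None:
            if tree.overlap(r.start, r.end):
                label = "island"
            elif tree.overlap(r.start - shore_bp, r.end + shore_bp):
                label = "shore"
            elif tree.overlap(r.start - shore_bp - shelf_bp,
                              r.end + shore_bp + shelf_bp):
                label = "shelf"
        if collapse_flanks and label in ("shore", "shelf"):
            label = "open_sea"
        labels.append(label)
    n = len(labels)
    fractions = {lab: (labels.count(lab) / n if n else 0.0)
                 for lab in CONTEXT_LABELS}
    return CpGContext(tuple(labels), fractions)


# ---------------------------------------------------------------------------
# hierarchical clustering (Manhattan distance, Ward linkage)
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray               # scipy linkage matrix
    samples: tuple[str, ...]
    distances: np.ndarray             # condensed pairwise Manhattan distances

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels for a k-cluster cut."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.samples, (int(v) for v in flat)))


def cluster_samples(table: pd.DataFrame) -> ClusterResult:
    """Ward-linkage hierarchical clustering of samples (columns) under
    pairwise-complete Manhattan distance.

    Missing cells are handled by computing the mean absolute difference
    over sites where both samples are observed and rescaling to the full
    site count, so sparsely-covered samples are comparable to dense ones.
    A sample pair with zero jointly-observed sites has no defined
    distance and raises, naming the pair.
    """
    samples = tuple(str(c) for c in table.columns)
    if len(samples) < 2:
        raise ConfigError("need >= 2 samples to cluster")
    x = table.to_numpy(dtype=float).T          # samples x sites
    n, p = x.shape
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            m = both.sum()
            if m == 0:
                raise ValueError(
                    f"samples {samples[i]!r} and {samples[j]!r} share no "
                    "observed sites; distance undefined")
            cond.append(np.abs(x[i, both] - x[j, both]).sum() * (p / m))
    cond = np.asarray(cond)
    Z = hierarchy.linkage(cond, method="ward")
    return ClusterResult(linkage=Z, samples=samples, distances=cond)
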