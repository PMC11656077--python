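"""Differentially methylated region calling between two sample groups.

The caller is a deliberately simple two-stage procedure:

1. *Segmentation* — CpGs passing coverage and per-group sample-count
   filters are split into runs broken wherever consecutive retained CpGs
   are more than ``max_gap`` apart; within a run, maximal stretches of
   CpGs whose per-CpG group-mean differences share one sign become
   candidates if they contain at least ``min_cpgs`` CpGs and their mean
   |delta beta| reaches ``min_abs_delta``.  With ``min_abs_delta = 0`` the
   sign/effect filter is disabled and each run is a single candidate,
   which makes candidate selection independent of the group labels (the
   configuration used for type-I-error calibration).
2. *Significance* — each candidate is tested with a two-sided
   Mann-Whitney U test comparing the per-CpG group-A means against the
   per-CpG group-B means over the candidate's CpGs; candidates with
   p < alpha are emitted as DMRs, labelled hyper (delta > 0, B relative
   to A) or hypo.

No multiple-testing correction is applied by default — the significance
gate is the raw p < 0.05 filter — but Benjamini-Hochberg adjustment can
be switched on.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io import MethylationMatrix

__all__ = ["DMR", "DmrParams", "Candidate", "segment_candidates",
           "test_region_mwu", "call_dmrs", "mwu_exact_p"]


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region (0-based half-open coordinates).

    ``mean_delta_beta`` is mean(group B) - mean(group A) over the region's
    CpGs; ``direction`` is "hyper" iff that difference is positive.
    """

    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_delta_beta: float
    p_value: float
    direction: str
    mean_beta_a: Optional[float] = None
    mean_beta_b: Optional[float] = None

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class DmrParams:
    min_cpgs: int = 10
    max_gap: int = 300
    min_abs_delta: float = 0.1
    alpha: float = 0.05
    min_coverage: int = 1
    min_samples_per_group: int = 2
    fdr: bool = False                 # optional Benjamini-Hochberg gate

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha={self.alpha} outside (0, 1)")
        if self.min_cpgs < 2:
            raise ConfigError("min_cpgs must be >= 2")
        if self.min_abs_delta < 0 or self.max_gap < 1:
            raise ConfigError("min_abs_delta >= 0 and max_gap >= 1 required")


@dataclass(frozen=True)
class Candidate:
    """A candidate region: CpG positions plus per-group per-CpG means."""

    chrom: str
    positions: tuple[int, ...]        # 1-based CpG positions
    means_a: np.ndarray
    means_b: np.ndarray

    @property
    def start(self) -> int:
        return self.positions[0] - 1

    @property
    def end(self) -> int:
        return self.positions[-1]

    @property
    def n_cpg(self) -> int:
        return len(self.positions)

    @property
    def mean_delta_beta(self) -> float:
        return float(np.mean(self.means_b) - np.mean(self.means_a))


def _group_means(matrix: MethylationMatrix, group: Sequence[str],
                 params: DmrParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG unweighted mean beta over samples passing the coverage
    filter, plus the contributing sample count per CpG."""
    beta = matrix.beta[list(group)].to_numpy(dtype=float)
    ok = ~np.isnan(beta)
    if matrix.coverage is not None and params.min_coverage > 1:
        cov = matrix.coverage[list(group)].to_numpy()
        ok &= cov >= params.min_coverage
    vals = np.where(ok, beta, 0.0)
    n = ok.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, vals.sum(axis=1) / np.maximum(n, 1), np.nan)
    return means, n


def _check_groups(matrix: MethylationMatrix, group_a: Sequence[str],
                  group_b: Sequence[str]) -> None:
    if len(group_a) == 0 or len(group_b) == 0:
        raise ConfigError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ConfigError("groups must be disjoint")
    unknown = (set(group_a) | set(group_b)) - set(matrix.samples)
    if unknown:
        raise KeyError(f"unknown sample ids: {sorted(unknown)}")


def segment_candidates(matrix: MethylationMatrix, group_a: Sequence[str],
                       group_b: Sequence[str],
                       params: DmrParams) -> list[Candidate]:
    """Deterministic left-to-right candidate segmentation (see module doc)."""
    params.validate()
    _check_groups(matrix, group_a, group_b)
    means_a, n_a = _group_means(matrix, group_a, params)
    means_b, n_b = _group_means(matrix, group_b, params)
    retained = ((n_a >= params.min_samples_per_group) &
                (n_b >= params.min_samples_per_group))

    chroms = matrix.beta.index.get_level_values(0).to_numpy()
    poss = matrix.beta.index.get_level_values(1).to_numpy()
    candidates: list[Candidate] = []
    order = np.arange(len(poss))[retained]
    for chrom in pd.unique(chroms[retained]):
        idx = order[chroms[order] == chrom]
        if len(idx) == 0:
            continue
        # split into runs at gaps > max_gap
        breaks = np.where(np.diff(poss[idx]) > params.max_gap)[0]
        for run in np.split(idx, breaks + 1):
            if len(run) < params.min_cpgs:
                continue
            delta = means_b[run] - means_a[run]
            if params.min_abs_delta == 0:
                stretches = [run]
            else:
                signs = np.sign(delta)
                cut = np.where(np.diff(signs) != 0)[0]
                stretches = np.split(run, cut + 1)
            for stretch in stretches:
                if len(stretch) < params.min_cpgs:
                    continue
                d = float(np.mean(means_b[stretch] - means_a[stretch]))
                if abs(d) < params.min_abs_delta:
                    continue
                candidates.append(Candidate(
                    chrom=str(chrom),
                    positions=tuple(int(p) for p in poss[stretch]),
                    means_a=means_a[stretch].copy(),
                    means_b=means_b[stretch].copy()))
    candidates.sort(key=lambda c: (c.chrom, c.start))
    return candidates


# ---------------------------------------------------------------------------
# Mann-Whitney U significance gate
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 12  # combined sample size up to which the exact branch is used


def mwu_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by exhaustive enumeration.

    All C(n1+n2, n1) assignments of the pooled (mid-ranked) observations
    are enumerated; ties are kept as-is.  The two-sided p-value is the
    probability of a U statistic at least as far from its null mean
    n1*n2/2 as the observed one.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    center = n1 * n2 / 2.0
    offset = n1 * (n1 + 1) / 2.0
    dev = abs(ranks[:n1].sum() - offset - center)
    count = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - offset
        if abs(u - center) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def test_region_mwu(means_a: np.ndarray, means_b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value for one region.

    Compares the vector of per-CpG group-A means against the per-CpG
    group-B means.  For combined n <= 12 the exact enumeration branch is
    used (ties as-is); above that, the normal approximation with midrank
    tie correction and continuity correction.
    """
    x = np.asarray(means_a, dtype=float)
    y = np.asarray(means_b, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("a group has no testable CpGs in this region")
    if len(x) + len(y) <= _EXACT_MAX_N:
        return mwu_exact_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(min(res.pvalue, 1.0))


def call_dmrs(matrix: MethylationMatrix, group_a: Sequence[str],
              group_b: Sequence[str], params: Optional[DmrParams] = None
              ) -> list[DMR]:
    """Segment, test and filter: the full DMR call between two groups."""
    params = params or DmrParams()
    candidates = segment_candidates(matrix, group_a, group_b, params)
    tested: list[tuple[Candidate, float]] = []
    for cand in candidates:
        try:
            p = test_region_mwu(cand.means_a, cand.means_b)
        except ValueError:
            continue  # untestable candidate: every CpG missing in a group
        tested.append((cand, p))
    if params.fdr and tested:
        qs = stats.false_discovery_control([p for _, p in tested], method="bh")
        keep = [(c, p) for (c, p), q in zip(tested, qs) if q < params.alpha]
    else:
        keep = [(c, p) for c, p in tested if p < params.alpha]
    dmrs = []
    for cand, p in keep:
        d = cand.mean_delta_beta
        if abs(d) < params.min_abs_delta:
            continue
        dmrs.append(DMR(
            chrom=cand.chrom, start=cand.start, end=cand.end,
            n_cpg=cand.n_cpg, mean_delta_beta=d, p_value=p,
            direction="hyper" if d > 0 else "hypo",
            mean_beta_a=float(np.mean(cand.means_a)),
            mean_beta_b=float(np.mean(cand.means_b))))
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs
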