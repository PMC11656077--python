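"""Signature derivation and the min-max anchored epigenomic score.

The score quantifies where a sample sits along the degeneration
trajectory of the retina.  A *signature* is a set of direction-labelled
regions — degeneration DMRs (untreated P21 vs P60) that are also touched
by treatment DMRs — each carrying two anchor values: the untreated-group
mean beta at P21 (pre-degenerate) and at P60 (fully degenerate).

For a sample with region-mean beta ``b_i`` in signature region *i*::

    r_i = (b_i - anchor_p21_i) / (anchor_p60_i - anchor_p21_i)

The denominator is negative for hypomethylated regions, so the single
formula implements the "reversed min/max" convention automatically.
The epigenomic score is the arithmetic mean of the ``r_i`` over the
regions computable for that sample; it is *not* clipped to [0, 1] —
a treated sample may legitimately score below 0 (healthier than the P21
anchors) and a degenerated one above 1.

Signatures are sex-specific; scoring samples of the other sex is refused
unless explicitly forced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dmr import DMR
from .errors import ConfigError
from .io import MethylationMatrix, Region, RegionSet, SampleMeta

__all__ = ["Signature", "SignatureRegion", "ScoreReport", "derive_signature",
           "compute_anchors", "score_samples", "score_sample", "score_cfdna"]

log = logging.getLogger(__name__)

DEFAULT_MIN_ANCHOR_SPAN = 0.01


@dataclass(frozen=True)
class SignatureRegion:
    chrom: str
    start: int
    end: int
    direction: str                    # {hyper, hypo}
    anchor_p21: float
    anchor_p60: float

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Signature:
    """Direction-labelled regions with P21/P60 anchor means, for one sex."""

    regions: tuple[SignatureRegion, ...]
    sex: Optional[str] = None

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def region_set(self) -> RegionSet:
        return RegionSet([(r.chrom, r.start, r.end, r.name) for r in self.regions])


@dataclass
class ScoreReport:
    """Per-sample epigenomic scores plus the per-region audit trail.

    ``per_sample`` has columns sample_id, score, n_regions_used; samples
    with no computable region are reported with NaN score and
    n_regions_used = 0.  ``per_region`` holds each sample's normalized
    region values (NaN where a region was not computable).
    """

    per_sample: pd.DataFrame
    per_region: pd.DataFrame

    def score_of(self, sample_id: str) -> float:
        row = self.per_sample.loc[self.per_sample["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return float(row["score"].iloc[0])


# ---------------------------------------------------------------------------
# signature derivation
# ---------------------------------------------------------------------------

def _overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return min(a_end, b_end) - max(a_start, b_start)


def derive_signature(degeneration_dmrs: Sequence[DMR],
                     treatment_dmrs: Sequence[DMR],
                     min_overlap_bp: int = 1) -> list[DMR]:
    """Intersect disease-progression DMRs with treatment DMRs.

    Returns the degeneration DMRs (coordinates *and* direction, i.e. the
    sign of the P60-vs-P21 change) that overlap at least one treatment
    DMR by >= ``min_overlap_bp``, deduplicated and sorted.  Both lists
    must come from the same sex; that bookkeeping is the caller's.
    """
    by_chrom: dict[str, list[DMR]] = {}
    for t in treatment_dmrs:
        by_chrom.setdefault(t.chrom, []).append(t)
    picked: dict[tuple, DMR] = {}
    for d in degeneration_dmrs:
        for t in by_chrom.get(d.chrom, ()):
            if _overlap_bp(d.start, d.end, t.start, t.end) >= min_overlap_bp:
                picked[(d.chrom, d.start, d.end)] = d
                break
    out = sorted(picked.values(), key=lambda d: (d.chrom, d.start))
    if not out:
        warnings.warn("empty signature: no degeneration DMR overlaps a "
                      "treatment DMR", stacklevel=2)
    return out


def _region_mean_beta(matrix: MethylationMatrix, chrom: str, start: int,
                      end: int, samples: Sequence[str],
                      min_cov: int = 1) -> np.ndarray:
    """Per-sample region-mean beta: mean over the region's CpGs of cells
    passing the coverage filter (NaN when no CpG is usable)."""
    block = matrix.region_slice(chrom, start, end)[list(samples)]
    vals = block.to_numpy(dtype=float)
    if min_cov > 1 and matrix.coverage is not None:
        cov = matrix.region_coverage_slice(chrom, start, end)[list(samples)].to_numpy()
        vals = np.where(cov >= min_cov, vals, np.nan)
    if vals.shape[0] == 0:
        return np.full(len(samples), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals, axis=0)


def compute_anchors(regions: Sequence, matrix: MethylationMatrix,
                    p21_samples: Sequence[str], p60_samples: Sequence[str],
                    min_cov: int = 1,
                    min_anchor_span: float = DEFAULT_MIN_ANCHOR_SPAN,
                    sex: Optional[str] = None) -> Signature:
    """Attach P21/P60 anchor means to direction-labelled regions.

    ``regions`` are DMRs (or any objects with chrom/start/end/direction).
    The anchors are the unweighted mean beta over region CpGs, then over
    the untreated anchor-group samples.  Regions whose computed anchors
    contradict their direction label, or whose anchor span is below
    ``min_anchor_span`` (guarding the normalization against division by
    a near-zero span), are dropped with a logged reason.
    """
    if len(p21_samples) == 0 or len(p60_samples) == 0:
        raise ConfigError("both anchor groups must be non-empty")
    kept = []
    for r in regions:
        m21 = _region_mean_beta(matrix, r.chrom, r.start, r.end, p21_samples, min_cov)
        m60 = _region_mean_beta(matrix, r.chrom, r.start, r.end, p60_samples, min_cov)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a21, a60 = float(np.nanmean(m21)), float(np.nanmean(m60))
        name = f"{r.chrom}:{r.start}-{r.end}"
        if np.isnan(a21) or np.isnan(a60):
            log.info("anchor region %s dropped: no retained CpGs", name)
            continue
        span = a60 - a21
        if abs(span) < min_anchor_span:
            log.info("anchor region %s dropped: span %.4f < %.4f",
                     name, abs(span), min_anchor_span)
            continue
        if (r.direction == "hyper") != (span > 0):
            log.info("anchor region %s dropped: anchors inconsistent with "
                     "direction %s", name, r.direction)
            continue
        kept.append(SignatureRegion(r.chrom, r.start, r.end, r.direction,
                                    a21, a60))
    return Signature(tuple(kept), sex=sex)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_samples(matrix: MethylationMatrix, signature: Signature,
                  samples: Optional[Sequence[str]] = None,
                  meta: Optional[Sequence[SampleMeta]] = None,
                  min_cov: int = 1, normalization: str = "per_region",
                  force_cross_sex: bool = False) -> ScoreReport:
    """Epigenomic score for each sample.

    ``normalization`` selects between the primary per-region
    normalize-then-average definition and the ``"stratum"`` variant that
    first averages region-mean betas (and anchors) within each direction
    stratum and normalizes the aggregates.  Both are exactly 0 at the P21
    anchor profile and 1 at the P60 profile.
    """
    if len(signature) == 0:
        raise ConfigError("cannot score against an empty signature")
    if normalization not in ("per_region", "stratum"):
        raise ConfigError(f"unknown normalization {normalization!r}")
    samples = list(samples) if samples is not None else matrix.samples
    if meta is not None and signature.sex is not None and not force_cross_sex:
        sex_of = {m.sample_id: m.sex for m in meta}
        bad = [s for s in samples if sex_of.get(s) not in (None, signature.sex)]
        if bad:
            raise ConfigError(
                f"signature is {signature.sex}-specific; refusing to score "
                f"{bad[:3]}{'...' if len(bad) > 3 else ''} "
                "(pass force_cross_sex=True to override)")

    names = [r.name for r in signature]
    betas = np.vstack([
        _region_mean_beta(matrix, r.chrom, r.start, r.end, samples, min_cov)
        for r in signature])                     # regions x samples
    a21 = np.array([r.anchor_p21 for r in signature])
    a60 = np.array([r.anchor_p60 for r in signature])
    norm = (betas - a21[:, None]) / (a60 - a21)[:, None]

    n_used = (~np.isnan(norm)).sum(axis=0)
    scores = np.full(len(samples), np.nan)
    if normalization == "per_region":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scores = np.where(n_used > 0, np.nanmean(norm, axis=0), np.nan)
    else:
        hyper = np.array([r.direction == "hyper" for r in signature])
        for j in range(len(samples)):
            parts, weights = [], []
            for mask in (hyper, ~hyper):
                usable = mask & ~np.isnan(betas[:, j])
                if not usable.any():
                    continue
                agg_b = betas[usable, j].mean()
                agg21, agg60 = a21[usable].mean(), a60[usable].mean()
                parts.append((agg_b - agg21) / (agg60 - agg21))
                weights.append(usable.sum())
            if parts:
                scores[j] = float(np.average(parts, weights=weights))
    for s, n in zip(samples, n_used):
        if n == 0:
            log.warning("sample %s: no computable signature region; no score", s)
    per_sample = pd.DataFrame({"sample_id": samples,
                               "score": scores,
                               "n_regions_used": n_used.astype(int)})
    per_region = pd.DataFrame(norm, index=names, columns=samples)
    return ScoreReport(per_sample=per_sample, per_region=per_region)


def score_sample(matrix: MethylationMatrix, signature: Signature,
                 sample_id: str, **kwargs) -> tuple[float, int]:
    """Score a single sample; returns (score, n_regions_used)."""
    rep = score_samples(matrix, signature, samples=[sample_id], **kwargs)
    row = rep.per_sample.iloc[0]
    return float(row["score"]), int(row["n_regions_used"])


def score_cfdna(cfdna: MethylationMatrix, signature: Signature,
                tissue_detectable_regions: Optional[RegionSet] = None,
                min_cov: int = 1, **kwargs) -> ScoreReport:
    """Score cfDNA samples on the tissue-detectable subset of the signature.

    Only signature regions overlapping ``tissue_detectable_regions`` (by
    >= 1 bp) enter the computation; regions without a covered CpG in a
    given cfDNA sample then drop out per-sample, and the per-sample
    subset size is reported as ``n_regions_used``.
    """
    regions = list(signature)
    if tissue_detectable_regions is not None:
        dets = list(tissue_detectable_regions)
        regions = [r for r in regions
                   if any(r.chrom == d.chrom and
                          _overlap_bp(r.start, r.end, d.start, d.end) >= 1
                          for d in dets)]
    if not regions:
        raise ConfigError("no signature region is detectable in the cfDNA subset")
    sub = Signature(tuple(regions), sex=signature.sex)
    return score_samples(cfdna, sub, min_cov=min_cov, **kwargs)
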