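"""Readers and writers for the on-disk formats used throughout the package.

Conventions
-----------
* Per-CpG positions are 1-based (bedGraph / metilene matrix convention);
  BED intervals are 0-based half-open.  A CpG at 1-based position ``p``
  lies inside region ``[s, e)`` iff ``s <= p - 1 < e``.
* The missing-value token in methylation matrices is ``"."``.  Missing
  cells are excluded from all downstream means and tests, never imputed.
* Strand is ignored; CpGs are treated as strand-collapsed positions.
"""

from __future__ import annotations

import dataclasses
import glob
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, IntegrityError

__all__ = [
    "Region",
    "RegionSet",
    "MethylationMatrix",
    "SampleMeta",
    "read_methylation_table",
    "write_methylation_table",
    "read_region_bed",
    "write_region_bed",
    "read_sample_meta",
    "write_sample_meta",
    "write_dmr_table",
    "read_dmr_table",
    "write_score_table",
]

SEXES = frozenset({"female", "male"})
GROUPS = frozenset({"sham", "low", "high", "untreated"})
TISSUES = frozenset({"retina", "superior_colliculus", "cfdna"})


class Region(NamedTuple):
    """A genomic interval, 0-based half-open, with an optional name."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None


@dataclass(frozen=True)
class RegionSet:
    """An ordered, validated collection of genomic regions (BED content)."""

    regions: tuple[Region, ...]

    def __init__(self, regions: Iterable[Sequence]) -> None:
        regs = []
        for r in regions:
            reg = Region(str(r[0]), int(r[1]), int(r[2]),
                         r[3] if len(r) > 3 else None)
            if reg.start >= reg.end:
                raise IntegrityError(
                    f"region {reg.chrom}:{reg.start}-{reg.end}: start >= end")
            regs.append(reg)
        regs.sort(key=lambda r: (r.chrom, r.start, r.end))
        object.__setattr__(self, "regions", tuple(regs))

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotations: who the sample is and which arm it belongs to.

    ``pool_n`` is 1 for single-animal samples and >1 for pooled material
    (plasma cfDNA libraries are built from pools of 3-4 animals).
    """

    sample_id: str
    sex: str
    timepoint: int
    group: str
    tissue: str = "retina"
    pool_n: int = 1

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigError(f"{self.sample_id}: unknown sex {self.sex!r}")
        if self.group not in GROUPS:
            raise ConfigError(f"{self.sample_id}: unknown group {self.group!r}")
        if self.tissue not in TISSUES:
            raise ConfigError(f"{self.sample_id}: unknown tissue {self.tissue!r}")
        if not 21 <= int(self.timepoint) <= 60:
            raise ConfigError(
                f"{self.sample_id}: timepoint P{self.timepoint} outside the "
                "declared study range P21-P60")
        if self.pool_n < 1:
            raise ConfigError(f"{self.sample_id}: pool_n must be >= 1")


class MethylationMatrix:
    """Per-CpG beta values (and optional coverage) for a set of samples.

    Parameters
    ----------
    beta
        DataFrame indexed by a (chrom, pos) MultiIndex — ``pos`` 1-based —
        with one float column per sample.  Values in [0, 1]; NaN = missing.
    coverage
        Optional integer DataFrame with the same shape.  Cells with zero
        coverage are forced to missing beta.
    """

    def __init__(self, beta: pd.DataFrame,
                 coverage: Optional[pd.DataFrame] = None) -> None:
        if beta.index.nlevels != 2:
            raise IntegrityError("beta index must be a (chrom, pos) MultiIndex")
        beta = beta.copy()
        beta.index = beta.index.set_names(["chrom", "pos"])
        if beta.index.has_duplicates:
            dup = beta.index[beta.index.duplicated()][0]
            raise IntegrityError(f"duplicate site {dup[0]}:{dup[1]}")
        beta = beta.sort_index()
        vals = beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.nansum(bad):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            site = beta.index[i]
            raise ValueError(
                f"beta value {vals[i, j]} outside [0, 1] at "
                f"{site[0]}:{site[1]}, sample {beta.columns[j]}")
        if coverage is not None:
            coverage = coverage.copy()
            coverage.index = coverage.index.set_names(["chrom", "pos"])
            coverage = coverage.sort_index()
            if not coverage.index.equals(beta.index) or \
                    list(coverage.columns) != list(beta.columns):
                raise IntegrityError("coverage shape does not match beta")
            if (coverage.to_numpy() < 0).any():
                raise ValueError("negative coverage")
            beta = beta.mask(coverage == 0)
        self.beta = beta
        self.coverage = coverage

    # -- basic introspection ------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def sites(self) -> list[tuple[str, int]]:
        return list(self.beta.index)

    @property
    def n_sites(self) -> int:
        return len(self.beta.index)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MethylationMatrix):
            return NotImplemented
        same_beta = self.beta.equals(other.beta)
        if self.coverage is None or other.coverage is None:
            return same_beta and (self.coverage is None) == (other.coverage is None)
        return same_beta and self.coverage.equals(other.coverage)

    # -- region access ------------------------------------------------------

    def region_slice(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Beta rows for CpGs inside ``[start, end)`` (0-based half-open)."""
        try:
            return self.beta.loc[(chrom, slice(start + 1, end)), :]
        except KeyError:
            return self.beta.iloc[0:0]

    def region_coverage_slice(self, chrom: str, start: int,
                              end: int) -> Optional[pd.DataFrame]:
        if self.coverage is None:
            return None
        try:
            return self.coverage.loc[(chrom, slice(start + 1, end)), :]
        except KeyError:
            return self.coverage.iloc[0:0]


# ---------------------------------------------------------------------------
# methylation matrices
# ---------------------------------------------------------------------------

def read_methylation_table(path: str, fmt: str = "metilene_tsv") -> MethylationMatrix:
    """Read a per-CpG beta matrix.

    ``metilene_tsv`` is a TSV with header ``chrom``, ``pos`` and one beta
    column per sample (missing token ``"."``).  ``bedgraph_dir`` is a
    directory of per-sample bedGraph files (``chrom start end beta%`` with
    optional methylated/unmethylated count columns); the sample id is the
    file stem.
    """
    if fmt == "metilene_tsv":
        return _read_metilene_tsv(path)
    if fmt == "bedgraph_dir":
        return _read_bedgraph_dir(path)
    raise ConfigError(f"unknown matrix format {fmt!r}")


def _read_metilene_tsv(path: str) -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=True)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "chrom" or cols[1] != "pos":
        offending = cols[:2] if len(cols) >= 2 else cols
        raise FormatError(
            f"{path}: header must start with 'chrom', 'pos'; got {offending}")
    sample_cols = cols[2:]
    for c in sample_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df[~df[c].isna() & pd.to_numeric(df[c], errors="coerce").isna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise FormatError(f"{path}: non-numeric beta in column {c!r}, line {line}")
    vals = df[sample_cols].to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: beta value {vals[i, j]} outside [0, 1] at line {i + 2}, "
            f"column {sample_cols[j]!r}")
    idx = pd.MultiIndex.from_arrays(
        [df["chrom"].astype(str), df["pos"].astype(int)], names=["chrom", "pos"])
    return MethylationMatrix(pd.DataFrame(vals, index=idx, columns=sample_cols))


def _read_bedgraph_dir(path: str) -> MethylationMatrix:
    files = sorted(glob.glob(os.path.join(path, "*.bedgraph")) +
                   glob.glob(os.path.join(path, "*.bedGraph")))
    if not files:
        raise FormatError(f"{path}: no .bedgraph files found")
    betas, covs = {}, {}
    for f in files:
        sample = os.path.splitext(os.path.basename(f))[0]
        df = pd.read_csv(f, sep="\t", header=None, comment="t",
                         names=["chrom", "start", "end", "pct", "meth", "unmeth"],
                         usecols=range(6), engine="python")
        if df["pct"].isna().any():
            raise FormatError(f"{f}: missing beta% column")
        pos = df["start"].astype(int) + 1  # 1-based CpG position
        idx = pd.MultiIndex.from_arrays([df["chrom"].astype(str), pos],
                                        names=["chrom", "pos"])
        betas[sample] = pd.Series(df["pct"].to_numpy(float) / 100.0, index=idx)
        if df["meth"].notna().all() and df["unmeth"].notna().all():
            covs[sample] = pd.Series(
                df["meth"].to_numpy(float) + df["unmeth"].to_numpy(float), index=idx)
    beta = pd.DataFrame(betas)
    coverage = None
    if len(covs) == len(betas):
        coverage = pd.DataFrame(covs).reindex(beta.index).fillna(0).astype(int)
    return MethylationMatrix(beta, coverage)


def write_methylation_table(matrix: MethylationMatrix, path: str) -> None:
    """Write a matrix in metilene TSV form (missing cells as ``"."``)."""
    df = matrix.beta.reset_index()
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns.astype(str)) + "\n")
        for row in df.itertuples(index=False):
            cells = [str(row[0]), str(row[1])]
            for v in row[2:]:
                cells.append("." if pd.isna(v) else format(float(v), ".6g"))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# BED region sets
# ---------------------------------------------------------------------------

def read_region_bed(path: str) -> RegionSet:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates {s!r}, {e!r}") from exc
            if start >= end:
                raise IntegrityError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            regions.append((chrom, start, end, name))
    return RegionSet(regions)


def write_region_bed(rs: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for r in rs:
            if r.name is None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "sex", "timepoint", "group", "tissue", "pool_n"]


def read_sample_meta(path: str) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    metas = [SampleMeta(r.sample_id, r.sex, int(r.timepoint), r.group,
                        r.tissue, int(r.pool_n))
             for r in df.itertuples(index=False)]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise IntegrityError(f"{path}: duplicate sample_id {dup!r}")
    return metas


def write_sample_meta(metas: Sequence[SampleMeta], path: str) -> None:
    df = pd.DataFrame([dataclasses.asdict(m) for m in metas], columns=_META_COLS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DMR and score tables
# ---------------------------------------------------------------------------

_DMR_COLS = ["chrom", "start", "end", "n_cpg", "mean_delta_beta",
             "p_value", "direction"]


def write_dmr_table(dmrs, path: str) -> None:
    """Write DMRs as a 7-column TSV sorted by (chrom, start)."""
    rows = sorted(dmrs, key=lambda d: (d.chrom, d.start))
    with open(path, "w") as fh:
        fh.write("\t".join(_DMR_COLS) + "\n")
        for d in rows:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.n_cpg}\t"
                     f"{d.mean_delta_beta:.6g}\t{d.p_value:.6g}\t{d.direction}\n")


def read_dmr_table(path: str):
    from .dmr import DMR  # local import to avoid a module cycle

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DMR_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing DMR columns {missing}")
    return [DMR(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                n_cpg=int(r.n_cpg), mean_delta_beta=float(r.mean_delta_beta),
                p_value=float(r.p_value), direction=str(r.direction))
            for r in df.itertuples(index=False)]


def write_score_table(report, path: str) -> None:
    """Write a per-sample score report (sample_id, score, n_regions_used)."""
    report.per_sample.to_csv(path, sep="\t", index=False, float_format="%.6g")
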