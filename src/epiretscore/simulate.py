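"""Synthetic RRBS-like cohorts with known differentially methylated regions.

The generator emulates the statistical structure of a progressive
retinal-degeneration study in the RCS rat: untreated animals sampled at
postnatal days P21-P60 show a linear hyper-/hypomethylation drift inside
designated "true" regions, electrically-treated animals at the final day
show an amplitude-dependent partial reversal of that drift, and regions
may be sex-specific.  cfDNA is modelled as a two-component mixture of
pooled tissue signal and a neutral background, with region dropout.

Linearity of the drift in postnatal day is a deliberate choice: it makes
the expected epigenomic score of an untreated sample at day ``t`` exactly
``(t - 21) / (t_max - 21)``, so every downstream stage has a closed-form
oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import MethylationMatrix, Region, RegionSet, SampleMeta

__all__ = ["SimConfig", "TruthSet", "simulate_cohort", "simulate_cfdna"]

_EPS = 1e-9


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    The untreated arm is sampled at every timepoint; the treatment arms
    (sham / low / high) exist at the final timepoint only, mirroring a
    weekly-treatment design assessed at endpoint.
    """

    n_chrom: int = 2
    cpgs_per_chrom: int = 300          # background (null) CpGs per chromosome
    n_true_regions: int = 30
    cpgs_per_region: int = 12
    frac_hyper: float = 0.6
    timepoints: tuple[int, ...] = (21, 35, 42, 49, 60)
    n_per_group_per_sex: int = 4
    drift_max: float = 0.3             # |delta beta| reached at the final day
    treatment_effect: Mapping[str, float] = field(
        default_factory=lambda: {"sham": 0.0, "low": 0.2, "high": 0.6})
    sex_overlap: float = 0.5           # fraction of true regions shared by sexes
    noise_kappa: Optional[float] = 50.0  # beta-distribution precision; None = noiseless
    mean_coverage: float = 30.0
    seed: int = 0
    # layout and baseline knobs
    cpg_spacing: int = 100             # background CpG spacing (<= max_gap -> one run)
    region_cpg_spacing: int = 50
    region_flank_gap: int = 2000       # isolates true regions from background runs
    null_baseline: float = 0.5         # single baseline shared by all null CpGs
    hyper_baseline_range: tuple[float, float] = (0.2, 0.6)
    hypo_baseline_range: tuple[float, float] = (0.4, 0.8)

    def validate(self) -> None:
        for name in ("frac_hyper", "sex_overlap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.drift_max <= 1:
            raise ConfigError(f"drift_max={self.drift_max} outside [0, 1]")
        eff = dict(self.treatment_effect)
        if eff.get("sham", 0.0) != 0.0:
            raise ConfigError("treatment_effect['sham'] must be 0")
        lo, hi = eff.get("low", 0.0), eff.get("high", 0.0)
        if not 0 <= lo <= hi <= 1:
            raise ConfigError("treatment_effect must satisfy 0 <= low <= high <= 1")
        if self.hyper_baseline_range[1] + self.drift_max > 1 + _EPS:
            raise ConfigError(
                "infeasible: hyper baseline + drift_max exceeds 1")
        if self.hypo_baseline_range[0] - self.drift_max < -_EPS:
            raise ConfigError(
                "infeasible: hypo baseline - drift_max is negative")
        if len(self.timepoints) < 2 or sorted(self.timepoints) != list(self.timepoints):
            raise ConfigError("timepoints must be an increasing list of >= 2 days")
        if self.cpgs_per_region < 2 or self.n_per_group_per_sex < 1:
            raise ConfigError("cpgs_per_region >= 2 and n_per_group_per_sex >= 1 required")


@dataclass
class TruthSet:
    """Ground truth for one simulated cohort.

    ``expected`` holds, per region, the noise-free group-mean beta of a
    sex-matched sample, indexed by region name with (group, timepoint)
    columns.  Samples of a non-matching sex sit at the region baseline.
    """

    regions: RegionSet
    direction: dict[str, str]          # region name -> {hyper, hypo}
    sex: dict[str, str]                # region name -> {female, male, both}
    baseline: dict[str, float]
    expected: pd.DataFrame

    def assert_monotone(self) -> None:
        """Hyper regions drift up, hypo regions drift down (untreated arm)."""
        unt = self.expected["untreated"]
        for name, d in self.direction.items():
            diffs = np.diff(unt.loc[name].to_numpy())
            ok = (diffs >= -_EPS).all() if d == "hyper" else (diffs <= _EPS).all()
            if not ok:
                raise AssertionError(f"truth region {name} not monotone ({d})")


def _progress(t: float, timepoints: Sequence[int]) -> float:
    t0, t1 = timepoints[0], timepoints[-1]
    return (t - t0) / (t1 - t0)


def simulate_cohort(cfg: SimConfig) -> tuple[MethylationMatrix, list[SampleMeta], TruthSet]:
    """Draw one cohort: beta matrix, sample metadata and ground truth.

    Identical configs (including seed) give byte-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    eff = {"untreated": 0.0, **dict(cfg.treatment_effect)}

    # -- region ground truth -------------------------------------------------
    n = cfg.n_true_regions
    n_hyper = int(round(cfg.frac_hyper * n))
    directions = np.array(["hyper"] * n_hyper + ["hypo"] * (n - n_hyper))
    rng.shuffle(directions)
    n_both = int(round(cfg.sex_overlap * n))
    n_f = (n - n_both) // 2
    n_m = n - n_both - n_f
    sexes = np.array(["both"] * n_both + ["female"] * n_f + ["male"] * n_m)
    rng.shuffle(sexes)
    baselines = np.where(
        directions == "hyper",
        rng.uniform(*cfg.hyper_baseline_range, size=n),
        rng.uniform(*cfg.hypo_baseline_range, size=n))

    # -- genome layout -------------------------------------------------------
    chrom_of = [i % cfg.n_chrom for i in range(n)]
    site_chrom: list[str] = []
    site_pos: list[int] = []
    site_region: list[int] = []        # -1 for background CpGs
    region_bounds: dict[int, tuple[str, int, int]] = {}
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        my_regions = [i for i in range(n) if chrom_of[i] == c]
        blocks = len(my_regions) + 1
        base, extra = divmod(cfg.cpgs_per_chrom, blocks)
        pos = 1000
        for b in range(blocks):
            n_null = base + (1 if b < extra else 0)
            for _ in range(n_null):
                site_chrom.append(chrom); site_pos.append(pos); site_region.append(-1)
                pos += cfg.cpg_spacing
            if b < len(my_regions):
                ridx = my_regions[b]
                pos += cfg.region_flank_gap
                start = pos - 1            # 0-based start covering first CpG
                for _ in range(cfg.cpgs_per_region):
                    site_chrom.append(chrom); site_pos.append(pos)
                    site_region.append(ridx)
                    pos += cfg.region_cpg_spacing
                end = site_pos[-1]         # half-open end covering last CpG
                region_bounds[ridx] = (chrom, start, end)
                pos += cfg.region_flank_gap

    # -- sample plan ---------------------------------------------------------
    metas: list[SampleMeta] = []
    t_max = cfg.timepoints[-1]
    for sex in ("female", "male"):
        for t in cfg.timepoints:
            for i in range(cfg.n_per_group_per_sex):
                metas.append(SampleMeta(f"{sex[0]}_untreated_P{t}_r{i + 1}",
                                        sex, t, "untreated"))
        for grp in ("sham", "low", "high"):
            for i in range(cfg.n_per_group_per_sex):
                metas.append(SampleMeta(f"{sex[0]}_{grp}_P{t_max}_r{i + 1}",
                                        sex, t_max, grp))

    # -- expected betas ------------------------------------------------------
    n_sites, n_samples = len(site_pos), len(metas)
    expected = np.full((n_sites, n_samples), cfg.null_baseline)
    site_region_arr = np.asarray(site_region)
    dirsign = {"hyper": 1.0, "hypo": -1.0}
    for ridx in range(n):
        # sex-mismatched samples sit at the region baseline (no drift)
        expected[site_region_arr == ridx, :] = baselines[ridx]
    for j, m in enumerate(metas):
        prog = _progress(m.timepoint, cfg.timepoints)
        for ridx in range(n):
            if sexes[ridx] not in ("both", m.sex):
                continue
            rows = site_region_arr == ridx
            drift = dirsign[directions[ridx]] * cfg.drift_max * prog * (1 - eff[m.group])
            expected[rows, j] = baselines[ridx] + drift
    expected = np.clip(expected, 0.0, 1.0)

    # -- observation noise and coverage -------------------------------------
    if cfg.noise_kappa is None or np.isinf(cfg.noise_kappa):
        beta_obs = expected.copy()
    else:
        m = np.clip(expected, 1e-6, 1 - 1e-6)
        beta_obs = rng.beta(m * cfg.noise_kappa, (1 - m) * cfg.noise_kappa)
    coverage = rng.poisson(cfg.mean_coverage, size=(n_sites, n_samples))

    idx = pd.MultiIndex.from_arrays([site_chrom, site_pos], names=["chrom", "pos"])
    cols = [m.sample_id for m in metas]
    matrix = MethylationMatrix(
        pd.DataFrame(beta_obs, index=idx, columns=cols),
        pd.DataFrame(coverage, index=idx, columns=cols))

    # -- truth table ---------------------------------------------------------
    names = [f"r{ridx:03d}" for ridx in range(n)]
    regions = RegionSet([(region_bounds[r][0], region_bounds[r][1],
                          region_bounds[r][2], names[r]) for r in range(n)])
    groups = ["untreated", "sham", "low", "high"]
    cols_mi = pd.MultiIndex.from_product([groups, cfg.timepoints],
                                         names=["group", "timepoint"])
    exp_rows = []
    for ridx in range(n):
        row = []
        for g in groups:
            for t in cfg.timepoints:
                drift = (dirsign[directions[ridx]] * cfg.drift_max *
                         _progress(t, cfg.timepoints) * (1 - eff[g]))
                row.append(float(np.clip(baselines[ridx] + drift, 0, 1)))
        exp_rows.append(row)
    truth = TruthSet(
        regions=regions,
        direction={names[r]: str(directions[r]) for r in range(n)},
        sex={names[r]: str(sexes[r]) for r in range(n)},
        baseline={names[r]: float(baselines[r]) for r in range(n)},
        expected=pd.DataFrame(exp_rows, index=names, columns=cols_mi))
    truth.assert_monotone()
    return matrix, metas, truth


def simulate_cfdna(
    tissue: MethylationMatrix,
    tissue_fraction: float,
    background_beta: Union[float, np.ndarray],
    dropout: float,
    pools: Mapping[str, Sequence[str]],
    seed: int,
    noise_kappa: Optional[float] = None,
    regions: Optional[RegionSet] = None,
) -> MethylationMatrix:
    """Mix pooled tissue methylation with background into cfDNA-like samples.

    Each pool's beta at a retained site is
    ``f * mean(tissue beta over the pool) + (1 - f) * background``, with
    optional beta-distributed noise of precision ``noise_kappa``.  A
    fraction ``dropout`` of the signal is set missing: whole regions when
    ``regions`` is given (cfDNA libraries lose loci coherently, which is
    what makes only a subset of tissue regions detectable in plasma),
    independent sites otherwise.
    """
    if not 0 <= tissue_fraction <= 1:
        raise ConfigError(f"tissue_fraction={tissue_fraction} outside [0, 1]")
    if not 0 <= dropout <= 1:
        raise ConfigError(f"dropout={dropout} outside [0, 1]")
    seen: set[str] = set()
    for name, members in pools.items():
        if len(members) == 0:
            raise ConfigError(f"pool {name!r} is empty")
        unknown = set(members) - set(tissue.samples)
        if unknown:
            raise KeyError(f"pool {name!r}: unknown tissue samples {sorted(unknown)}")
        if seen & set(members):
            raise ConfigError(f"pool {name!r} overlaps another pool")
        seen |= set(members)

    rng = np.random.default_rng(seed)
    bg = np.asarray(background_beta, dtype=float)
    if bg.ndim == 1 and bg.shape[0] != tissue.n_sites:
        raise ConfigError("per-site background length does not match matrix")

    out = {}
    site_index = tissue.beta.index
    for name in pools:
        pooled = tissue.beta[list(pools[name])].mean(axis=1, skipna=True).to_numpy()
        mixed = tissue_fraction * pooled + (1 - tissue_fraction) * bg
        if noise_kappa is not None and np.isfinite(noise_kappa):
            m = np.clip(mixed, 1e-6, 1 - 1e-6)
            drawn = rng.beta(m * noise_kappa, (1 - m) * noise_kappa)
            mixed = np.where(np.isnan(mixed), np.nan, drawn)
        if regions is not None:
            keep_region = rng.random(len(regions)) >= dropout
            drop_mask = np.zeros(len(site_index), dtype=bool)
            in_any = np.zeros(len(site_index), dtype=bool)
            chroms = site_index.get_level_values(0).to_numpy()
            poss = site_index.get_level_values(1).to_numpy()
            for k, r in enumerate(regions):
                rows = (chroms == r.chrom) & (poss >= r.start + 1) & (poss <= r.end)
                in_any |= rows
                if not keep_region[k]:
                    drop_mask |= rows
            drop_mask |= (~in_any) & (rng.random(len(site_index)) < dropout)
        else:
            drop_mask = rng.random(len(site_index)) < dropout
        mixed = np.where(drop_mask, np.nan, mixed)
        out[name] = mixed
    return MethylationMatrix(pd.DataFrame(out, index=site_index))
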