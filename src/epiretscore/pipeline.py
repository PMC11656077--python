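"""End-to-end orchestration: simulate or load a cohort, call DMRs per
timepoint comparison, derive the signature, score every arm, and write
deterministic TSV outputs plus a run manifest."""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from .dmr import DMR, DmrParams, call_dmrs
from .errors import ConfigError
from .io import MethylationMatrix, SampleMeta
from .scoring import Signature, compute_anchors, derive_signature, score_samples
from .simulate import SimConfig, simulate_cohort

__all__ = ["RunConfig", "select_samples", "run_progression_analysis",
           "run_treatment_analysis", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run on a simulated cohort."""

    sim: SimConfig = field(default_factory=SimConfig)
    dmr_params: DmrParams = field(default_factory=DmrParams)
    sexes: tuple[str, ...] = ("female", "male")
    treatment_group: str = "high"       # arm used to derive the signature
    min_overlap_bp: int = 1
    min_anchor_span: float = 0.01
    normalization: str = "per_region"
    seed: int = 0


def select_samples(meta: Sequence[SampleMeta], *, sex: Optional[str] = None,
                   group: Optional[str] = None,
                   timepoint: Optional[int] = None,
                   tissue: Optional[str] = None) -> list[str]:
    """Sample ids matching every given criterion."""
    out = []
    for m in meta:
        if sex is not None and m.sex != sex:
            continue
        if group is not None and m.group != group:
            continue
        if timepoint is not None and m.timepoint != timepoint:
            continue
        if tissue is not None and m.tissue != tissue:
            continue
        out.append(m.sample_id)
    return out


def run_progression_analysis(matrix: MethylationMatrix,
                             meta: Sequence[SampleMeta], *, sex: str,
                             treatment_dmrs: Sequence[DMR],
                             params: Optional[DmrParams] = None,
                             min_overlap_bp: int = 1,
                             min_anchor_span: float = 0.01) -> dict:
    """Disease-progression arm: P21 vs each later timepoint, then the
    signature from the P21-vs-P60 comparison intersected with treatment
    DMRs, with anchors from the untreated P21/P60 groups."""
    params = params or DmrParams()
    tps = sorted({m.timepoint for m in meta if m.group == "untreated"})
    if len(tps) < 2 or 21 not in tps:
        raise ConfigError("need untreated samples at P21 and >= 1 later timepoint")
    t0, t_final = tps[0], tps[-1]
    p21 = select_samples(meta, sex=sex, group="untreated", timepoint=t0)
    if not p21:
        raise ConfigError(f"no untreated {sex} samples at P{t0}")
    dmr_tables: dict[str, list[DMR]] = {}
    for t in tps[1:]:
        grp = select_samples(meta, sex=sex, group="untreated", timepoint=t)
        if not grp:
            raise ConfigError(f"no untreated {sex} samples at P{t}")
        dmr_tables[f"P{t0}_vs_P{t}"] = call_dmrs(matrix, p21, grp, params)
    degeneration = dmr_tables[f"P{t0}_vs_P{t_final}"]
    sig_regions = derive_signature(degeneration, treatment_dmrs,
                                   min_overlap_bp=min_overlap_bp)
    p60 = select_samples(meta, sex=sex, group="untreated", timepoint=t_final)
    signature = compute_anchors(sig_regions, matrix, p21, p60,
                                min_cov=params.min_coverage,
                                min_anchor_span=min_anchor_span, sex=sex)
    counts = {name: len(d) for name, d in dmr_tables.items()}
    return {"dmr_tables": dmr_tables, "counts": counts,
            "signature": signature, "degeneration_dmrs": degeneration}


def run_treatment_analysis(matrix: MethylationMatrix,
                           meta: Sequence[SampleMeta], *, sex: str,
                           signature: Signature,
                           params: Optional[DmrParams] = None,
                           normalization: str = "per_region") -> dict:
    """Treatment arm at endpoint: sham-vs-treated DMR tables plus scores
    (and sham-vs-arm t-tests) for every arm present at the final day."""
    params = params or DmrParams()
    t_max = max(m.timepoint for m in meta)
    sham = select_samples(meta, sex=sex, group="sham", timepoint=t_max)
    if not sham:
        raise ConfigError(f"no sham {sex} samples at P{t_max}")
    dmr_tables = {}
    arms = {}
    for grp in ("low", "high"):
        treated = select_samples(meta, sex=sex, group=grp, timepoint=t_max)
        if treated:
            dmr_tables[f"sham_vs_{grp}"] = call_dmrs(matrix, sham, treated, params)
            arms[grp] = treated
    arms = {"sham": sham, **arms,
            "untreated": select_samples(meta, sex=sex, group="untreated",
                                        timepoint=t_max)}
    arms = {k: v for k, v in arms.items() if v}

    scores = {}
    comparisons = {}
    for name, samples in arms.items():
        rep = score_samples(matrix, signature, samples=samples, meta=meta,
                            min_cov=params.min_coverage,
                            normalization=normalization)
        scores[name] = rep
    sham_scores = scores["sham"].per_sample["score"].dropna().to_numpy()
    for name in arms:
        if name == "sham":
            continue
        arm_scores = scores[name].per_sample["score"].dropna().to_numpy()
        if len(arm_scores) < 2 or len(sham_scores) < 2:
            import warnings
            warnings.warn(f"arm {name}: fewer than 2 scored samples; "
                          "t-test skipped", stacklevel=2)
            comparisons[f"sham_vs_{name}"] = {"t_welch_p": None, "t_student_p": None}
            continue
        welch = stats.ttest_ind(sham_scores, arm_scores, equal_var=False)
        student = stats.ttest_ind(sham_scores, arm_scores, equal_var=True)
        comparisons[f"sham_vs_{name}"] = {
            "t_welch_p": float(welch.pvalue),
            "t_student_p": float(student.pvalue)}
    means = {name: float(np.nanmean(rep.per_sample["score"]))
             for name, rep in scores.items()}
    return {"dmr_tables": dmr_tables, "scores": scores,
            "mean_scores": means, "comparisons": comparisons}


def run_all(cfg: RunConfig, out_dir: str) -> dict:
    """Simulate a cohort and run the full per-sex analysis, writing every
    table (and a JSON run manifest) under ``out_dir``.

    The manifest records the full configuration and every derived count
    so that a run is auditable; outputs are byte-identical across
    repeated runs with the same config.
    """
    os.makedirs(out_dir, exist_ok=True)
    matrix, meta, truth = simulate_cohort(cfg.sim)
    mio.write_methylation_table(matrix, os.path.join(out_dir, "matrix.tsv"))
    mio.write_sample_meta(meta, os.path.join(out_dir, "meta.tsv"))
    mio.write_region_bed(truth.regions, os.path.join(out_dir, "truth_regions.bed"))

    manifest: dict = {
        "config": {
            "sim": dataclasses.asdict(cfg.sim),
            "dmr_params": dataclasses.asdict(cfg.dmr_params),
            "sexes": list(cfg.sexes),
            "treatment_group": cfg.treatment_group,
            "min_overlap_bp": cfg.min_overlap_bp,
            "min_anchor_span": cfg.min_anchor_span,
            "normalization": cfg.normalization,
            "seed": cfg.seed,
        },
        "per_sex": {},
    }
    results: dict = {"matrix": matrix, "meta": meta, "truth": truth, "per_sex": {}}
    t_max = max(m.timepoint for m in meta)
    for sex in cfg.sexes:
        sham = select_samples(meta, sex=sex, group="sham", timepoint=t_max)
        treated = select_samples(meta, sex=sex, group=cfg.treatment_group,
                                 timepoint=t_max)
        treatment_dmrs = call_dmrs(matrix, sham, treated, cfg.dmr_params)
        prog = run_progression_analysis(
            matrix, meta, sex=sex, treatment_dmrs=treatment_dmrs,
            params=cfg.dmr_params, min_overlap_bp=cfg.min_overlap_bp,
            min_anchor_span=cfg.min_anchor_span)
        treat = run_treatment_analysis(
            matrix, meta, sex=sex, signature=prog["signature"],
            params=cfg.dmr_params, normalization=cfg.normalization)

        for name, dmrs in {**prog["dmr_tables"], **treat["dmr_tables"],
                           f"sham_vs_{cfg.treatment_group}_signature_input":
                               treatment_dmrs}.items():
            mio.write_dmr_table(dmrs, os.path.join(out_dir, f"{sex}_{name}.dmr.tsv"))
        sig_rows = [{"chrom": r.chrom, "start": r.start, "end": r.end,
                     "direction": r.direction, "anchor_p21": r.anchor_p21,
                     "anchor_p60": r.anchor_p60}
                    for r in prog["signature"]]
        pd.DataFrame(sig_rows, columns=["chrom", "start", "end", "direction",
                                        "anchor_p21", "anchor_p60"]).to_csv(
            os.path.join(out_dir, f"{sex}_signature.tsv"), sep="\t",
            index=False, float_format="%.6g")
        for arm, rep in treat["scores"].items():
            mio.write_score_table(rep, os.path.join(out_dir,
                                                    f"{sex}_{arm}_scores.tsv"))
        manifest["per_sex"][sex] = {
            "dmr_counts": {**prog["counts"],
                           **{k: len(v) for k, v in treat["dmr_tables"].items()},
                           "treatment_signature_input": len(treatment_dmrs)},
            "signature_size": len(prog["signature"]),
            "mean_scores": treat["mean_scores"],
            "score_comparisons": treat["comparisons"],
        }
        results["per_sex"][sex] = {"progression": prog, "treatment": treat}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
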