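"""Simulate a degeneration cohort and call DMRs against the P21 baseline.

The synthetic cohort plants hyper- and hypomethylated regions whose
group-mean beta drifts linearly from P21 to P60 in untreated animals.
DMRs are called per timepoint comparison with the Mann-Whitney p < 0.05
gate, so the DMR count and mean |delta beta| should both grow with age.
"""

import numpy as np

import epiretscore as e

cfg = e.SimConfig(seed=7, sex_overlap=1.0)
matrix, meta, truth = e.simulate_cohort(cfg)
print(f"cohort: {matrix.n_sites} CpGs x {len(meta)} samples, "
      f"{len(truth.regions)} planted regions "
      f"({sum(d == 'hyper' for d in truth.direction.values())} hyper)")

p21 = e.select_samples(meta, sex="female", group="untreated", timepoint=21)
for t in (35, 42, 49, 60):
    grp = e.select_samples(meta, sex="female", group="untreated", timepoint=t)
    dmrs = e.call_dmrs(matrix, p21, grp)
    mean_abs_delta = np.mean([abs(d.mean_delta_beta) for d in dmrs]) if dmrs else 0
    n_hyper = sum(d.direction == "hyper" for d in dmrs)
    print(f"P21 vs P{t}: {len(dmrs):3d} DMRs "
          f"({n_hyper} hyper), mean |delta beta| = {mean_abs_delta:.3f}")

print("\nBoth the number of significant regions and their effect size grow")
print("as degeneration progresses, mirroring the planted linear drift.")
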