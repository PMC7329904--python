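"""Simes/Benjamini-Hochberg discovery against two BMD summary-stat sets.

The step-up procedure yields a data-dependent p-value threshold (k/m)*q;
a SNP passing for either femoral-neck or lumbar-spine BMD is carried
forward.  With the printed test counts of a large meta-analysis
(m = 23204 and k = 630 at q = 0.05) the reported threshold reproduces
1.4e-3.
"""

from pleioscan import SimulationConfig, bh_threshold, run_discovery, step_up_threshold
from pleioscan.simulate import (
    simulate_catalog,
    simulate_reference_panel,
    simulate_summary_stats,
)

# the threshold formula at a published scale
print(f"step-up threshold at m=23204, k=630, q=0.05: "
      f"{step_up_threshold(630, 23204, 0.05):.2g}")

# a worked small example: rank bounds 0.0125, 0.025, 0.0375, 0.05
res = bh_threshold([0.001, 0.01, 0.02, 0.5], q=0.05)
print(f"toy vector: k={res.k}, p_threshold={res.p_threshold}, "
      f"significant={res.significant}")

# discovery on synthetic stats with 2 planted signals among nulls
cfg = SimulationConfig(seed=9, n_blocks=200, n_panel_samples=400,
                       n_planted_pleiotropic=2, effect_size_sd=0.15)
panel = simulate_reference_panel(cfg)
_, truth = simulate_catalog(cfg, panel)
fn = simulate_summary_stats(cfg, panel, truth, "FN")
ls = simulate_summary_stats(cfg, panel, truth, "LS")
outcome = run_discovery(truth.candidate_rsids, None, fn, ls, q=0.05)
sig = [r.rsid for r in outcome.results if r.significant]
print(f"FN: m={outcome.fdr_fn.m}, threshold={outcome.fdr_fn.p_threshold:.2e}")
print(f"discovered {sig} (planted: {truth.planted_rsids})")
# Both planted SNPs pass; the thresholds adapt to how many signals exist.
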