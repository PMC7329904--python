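"""Generate the four synthetic pipeline inputs and inspect the ground truth.

The simulator builds a reference panel with LD blocks (each containing a
perfect-proxy pair), a GWAS-catalog-style table, two BMD summary-statistic
sets, and an individual-level ultrasound cohort, all from one seeded config.
"""

from pleioscan import (
    SimulationConfig,
    simulate_biobank,
    simulate_catalog,
    simulate_reference_panel,
    simulate_summary_stats,
)

cfg = SimulationConfig(seed=1, n_blocks=20, n_panel_samples=400,
                       n_biobank_samples=1000, n_planted_pleiotropic=2,
                       n_related_pairs=5, n_background_markers=200)

panel = simulate_reference_panel(cfg)
catalog, truth = simulate_catalog(cfg, panel)
stats_fn = simulate_summary_stats(cfg, panel, truth, "FN")
cohort, truth = simulate_biobank(cfg, panel, truth)

print(f"panel: {panel.n_samples} samples x {panel.n_variants} variants")
print(f"catalog: {len(catalog)} SNP-trait rows "
      f"({sum(truth.catalog_expected.values())} injected for curation rules)")
print(f"summary stats (FN-BMD): {len(stats_fn)} SNPs, "
      f"min p = {stats_fn['p'].min():.2e}")
print(f"cohort: {cohort.n_samples} participants, "
      f"{int(truth.biobank['expected_excluded'].sum())} expected QC outliers, "
      f"{len(truth.pairs)} planted related pairs")
print("planted pleiotropic SNPs:", truth.planted_rsids)
# The planted SNPs carry a true effect in both the GWAS statistics and the
# cohort phenotype; every other block anchor is a pure null candidate.
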