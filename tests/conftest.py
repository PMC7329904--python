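import numpy as np
import pandas as pd
import pytest

from pleioscan.ld import ReferencePanel
from pleioscan.simulate import (
    SimulationConfig,
    simulate_biobank,
    simulate_catalog,
    simulate_reference_panel,
    simulate_summary_stats,
)


def make_panel(dosage_columns: dict, chrom="1", spacing=1000) -> ReferencePanel:
    """Panel from explicit dosage vectors keyed by rsid (test helper)."""
    rsids = list(dosage_columns)
    mat = np.column_stack([np.asarray(dosage_columns[r], dtype=np.int8) for r in rsids])
    variants = pd.DataFrame(
        dict(rsid=rsids, chrom=chrom, pos=[spacing * (i + 1) for i in range(len(rsids))],
             ref="A", alt="G")
    )
    samples = [f"P{i}" for i in range(mat.shape[0])]
    return ReferencePanel(samples, variants, mat)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=42, n_blocks=12, snps_per_block=3, n_panel_samples=400,
        n_biobank_samples=600, n_planted_pleiotropic=2, n_planted_decoy=1,
        n_related_pairs=5, n_background_markers=100, effect_size_sd=0.3,
        gwas_n=50_000, qc_outlier_fraction=0.02,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_reference_panel(small_config)


@pytest.fixture(scope="session")
def small_catalog(small_config, small_panel):
    return simulate_catalog(small_config, small_panel)


@pytest.fixture(scope="session")
def small_stats(small_config, small_panel, small_catalog):
    _, truth = small_catalog
    fn = simulate_summary_stats(small_config, small_panel, truth, "FN")
    ls = simulate_summary_stats(small_config, small_panel, truth, "LS")
    return fn, ls


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel, small_catalog):
    _, truth = small_catalog
    return simulate_biobank(small_config, small_panel, truth)
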