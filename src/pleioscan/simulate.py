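"""Synthetic inputs for the pleiotropy-scan pipeline, with ground truth.

The generator emulates the four data sources the scan consumes:

* a genotype **reference panel** with LD-block structure (a haplotype-copy
  scheme: each block has an anchor SNP, one perfect proxy — an identical
  or allele-flipped copy — and further members that copy the anchor
  haplotype with probability sqrt(within_block_r2)), plus optional
  independent "background array markers" used for kinship estimation;
* a GWAS-**catalog**-style association table containing one
  genome-wide-significant non-bone record per block anchor, plus records
  that each curation rule must remove, with their counts recorded;
* two **summary-statistics** sets (femoral-neck and lumbar-spine BMD)
  where planted SNPs carry a true standardized effect, proxies inherit
  r-attenuated effects, and the sampling noise is correlated across a
  block according to the panel's realized dosage correlation (perfect
  proxies get sign-harmonized, bit-identical statistics);
* an individual-level **biobank cohort** with heel-ultrasound measures
  generated so that 0.002592*(BUA + SOS) - 3.687 returns the latent eBMD
  exactly, covariate effects of age, age², weight and sex, planted
  genetic effects, related sample pairs sharing haplotypes
  identical-by-descent, and a configurable fraction of records placed on
  or outside the ultrasound QC bounds.

Every generated truth (planted SNPs, expected catalog removals, expected
QC exclusions, true relationships) is recorded in a :class:`TruthTable`
for parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import DEFAULT_DIALECT
from .ld import MISSING, ReferencePanel
from .replication import (
    BiobankCohort,
    EBMD_INTERCEPT,
    EBMD_SLOPE,
    N_PCS,
    QCThresholds,
    derive_ebmd,
)

logger = logging.getLogger(__name__)

RELATIONSHIPS = ("duplicate", "parent_offspring", "full_sib", "second_degree", "third_degree")
EXPECTED_PHI = {
    "duplicate": 0.5,
    "parent_offspring": 0.25,
    "full_sib": 0.25,
    "second_degree": 0.125,
    "third_degree": 0.0625,
}
#: probability a haplotype is copied identical-by-descent, per haplotype slot
_SHARE_SCHEME = {
    # (p_share_hap1, p_share_hap2); duplicate/parent-offspring are forced
    "duplicate": (1.0, 1.0),
    "parent_offspring": (1.0, 0.0),
    "full_sib": (0.5, 0.5),
    "second_degree": (0.5, 0.0),
    "third_degree": (0.25, 0.0),
}

NONBONE_TRAITS = (
    "Height", "Parkinson's disease", "Atopic dermatitis", "Magnesium levels",
    "Coffee consumption", "Educational attainment", "Waist circumference",
    "Blood protein levels", "Male-pattern baldness", "Reticulocyte count",
    "Urinary electrolyte excretion", "Inflammatory bowel disease",
    "Type 2 diabetes", "Systolic blood pressure", "Asthma",
    "Rheumatoid arthritis", "Triglyceride levels", "Body mass index",
    "Age-related macular degeneration", "Chronotype", "Platelet count",
    "Allergic disease", "Gastric cancer", "Serum urate levels",
)

DEFAULT_KNOWN_BMD_SNPS = ("rs2941740", "rs3801387")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs."""

    seed: int = 0
    n_panel_samples: int = 500
    n_biobank_samples: int = 5000
    n_blocks: int = 50
    snps_per_block: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    within_block_r2: float = 0.8
    n_catalog_traits: int = 20
    n_planted_pleiotropic: int = 3
    n_planted_decoy: int = 0
    effect_size_sd: float = 0.1
    gwas_n: int = 50_000
    n_related_pairs: int = 20
    relationship_mix: dict = field(
        default_factory=lambda: {r: 0.2 for r in RELATIONSHIPS}
    )
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": -0.002, "age2": -1.0e-5, "weight": 0.0015, "sex_male": 0.03,
        }
    )
    noise_sd: float = 0.09
    n_background_markers: int = 0
    qc_outlier_fraction: float = 0.01
    mean_ebmd: float = 0.54

    def __post_init__(self) -> None:
        for name in ("n_panel_samples", "n_biobank_samples", "n_blocks",
                     "snps_per_block", "n_catalog_traits", "gwas_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError(f"within_block_r2 must be in [0,1], got {self.within_block_r2}")
        if self.n_planted_pleiotropic + self.n_planted_decoy > self.n_blocks:
            raise ValueError(
                "n_planted_pleiotropic + n_planted_decoy must not exceed n_blocks "
                "(at most one planted causal SNP per block)"
            )
        bad = set(self.relationship_mix) - set(RELATIONSHIPS)
        if bad:
            raise ValueError(f"unknown relationship class(es): {sorted(bad)}")
        total = sum(self.relationship_mix.values())
        if self.n_related_pairs > 0 and abs(total - 1.0) > 1e-6:
            raise ValueError(f"relationship_mix proportions must sum to 1, got {total}")
        if any(v < 0 for v in self.relationship_mix.values()):
            raise ValueError("relationship_mix proportions must be non-negative")
        if self.n_related_pairs < 0:
            raise ValueError("n_related_pairs must be non-negative")
        if 2 * self.n_related_pairs > self.n_biobank_samples:
            raise ValueError("n_related_pairs too large for n_biobank_samples")
        if not 0.0 <= self.qc_outlier_fraction < 1.0:
            raise ValueError("qc_outlier_fraction must be in [0,1)")

    def rng(self, stage: int) -> np.random.Generator:
        """Named substream so stages are independently reproducible."""
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class TruthTable:
    """Ground truth of a simulation run.

    ``snps`` has one row per panel variant: block, role, generating MAF,
    planted/decoy flags, the true effect carried in the GWAS summary
    statistics (``beta_gwas``, r-attenuated for proxies) and in the
    biobank cohort (``beta_cohort``), and catalog-candidacy.  ``pairs``
    lists the planted relationships, ``biobank`` the per-sample latent
    eBMD and expected QC exclusions, ``catalog_expected`` the injected
    counts each curation rule must remove.
    """

    snps: pd.DataFrame
    catalog_expected: dict = field(default_factory=dict)
    known_bmd_snps: tuple = DEFAULT_KNOWN_BMD_SNPS
    pairs: pd.DataFrame | None = None
    biobank: pd.DataFrame | None = None

    @property
    def planted_rsids(self) -> list[str]:
        return list(self.snps.loc[self.snps["planted"] & self.snps["is_anchor"], "rsid"])

    @property
    def decoy_rsids(self) -> list[str]:
        return list(self.snps.loc[self.snps["decoy"] & self.snps["is_anchor"], "rsid"])

    @property
    def candidate_rsids(self) -> list[str]:
        return list(self.snps.loc[self.snps["is_candidate"], "rsid"])

    def perfect_group(self, rsid: str) -> frozenset:
        """The rsID together with its exact-copy proxies (same block, role
        anchor/perfect) — statistically indistinguishable variants."""
        row = self.snps.set_index("rsid").loc[rsid]
        block = row["block"]
        grp = self.snps[(self.snps["block"] == block) & self.snps["role"].isin(("anchor", "perfect"))]
        return frozenset(grp["rsid"])

    def matches_planted(self, rsids) -> bool:
        """True iff ``rsids`` equals the planted set up to perfect-proxy
        substitution (one representative per planted block, no extras)."""
        rsids = set(rsids)
        blocks = set()
        planted_blocks = set(
            self.snps.loc[self.snps["planted"] & self.snps["is_anchor"], "block"]
        )
        idx = self.snps.set_index("rsid")
        for r in rsids:
            if r not in idx.index:
                return False
            row = idx.loc[r]
            if not row["planted"] or row["role"] not in ("anchor", "perfect"):
                return False
            if row["block"] in blocks:
                return False
            blocks.add(row["block"])
        return blocks == planted_blocks


# ------------------------------------------------------------------ genotypes


def _make_variant_plan(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-variant generating plan: unit (LD-sharing block), role,
    generating MAF, complement flag, genomic coordinates, rsIDs."""
    rows = []
    spb = config.snps_per_block
    c = float(np.sqrt(config.within_block_r2))
    for b in range(config.n_blocks):
        chrom = str(b % 22 + 1)
        base = 1_000_000 + (b // 22) * 10_000_000
        maf_anchor = rng.uniform(*config.maf_range)
        complement_block = bool(b % 2)  # alternate copy vs allele-flip proxies
        for j in range(spb):
            if j == 0:
                role, fresh, comp = "anchor", maf_anchor, False
            elif j == 1:
                role, fresh, comp = "perfect", maf_anchor, complement_block
            else:
                role, fresh, comp = "member", rng.uniform(*config.maf_range), False
            # marginal allele frequency implied by the copy scheme
            maf = c * maf_anchor + (1.0 - c) * fresh if role == "member" else fresh
            rows.append(dict(
                rsid=f"rs{1_000_000 + b * 100 + j}", chrom=chrom, pos=base + j * 1_000,
                ref="A", alt="G", unit=b, block=b, role=role, gen_maf=maf,
                fresh_maf=fresh, complement=comp,
            ))
    for k in range(config.n_background_markers):
        chrom = str(k % 22 + 1)
        pos = 100_000_000 + (k // 22) * 50_000
        maf = rng.uniform(*config.maf_range)
        rows.append(dict(
            rsid=f"rs{9_000_000 + k}", chrom=chrom, pos=pos, ref="C", alt="T",
            unit=config.n_blocks + k, block=-1, role="background",
            gen_maf=maf, fresh_maf=maf, complement=False,
        ))
    return pd.DataFrame(rows)


def _draw_dosages(
    plan: pd.DataFrame,
    n: int,
    copy_prob: float,
    rng: np.random.Generator,
    related_plan: list | None = None,
    unit_chunk: int = 400,
) -> np.ndarray:
    """Draw an (n, m) dosage matrix following the haplotype-copy scheme.

    ``related_plan`` is a list of dicts (base index, derived index,
    per-unit share masks / parental-haplotype choices) produced by
    :func:`_relatedness_plan`; derived samples get the base sample's
    haplotypes identical-by-descent at the shared units.
    """
    m = len(plan)
    unit = plan["unit"].to_numpy()
    gen_maf = plan["fresh_maf"].to_numpy()
    role = plan["role"].to_numpy()
    comp = plan["complement"].to_numpy()
    n_units = int(unit.max()) + 1
    dosages = np.empty((n, m), dtype=np.int8)

    for u0 in range(0, n_units, unit_chunk):
        u1 = min(u0 + unit_chunk, n_units)
        vmask = (unit >= u0) & (unit < u1)
        vidx = np.flatnonzero(vmask)
        uloc = unit[vidx] - u0
        # anchor MAF per unit in this chunk
        anchor_maf = np.empty(u1 - u0)
        is_anchor_like = np.isin(role[vidx], ("anchor", "background"))
        anchor_maf[uloc[is_anchor_like]] = gen_maf[vidx[is_anchor_like]]

        H = np.empty((2, n, len(vidx)), dtype=np.int8)
        A = (rng.random((2, n, u1 - u0)) < anchor_maf).astype(np.int8)
        for local_i, (v, ul) in enumerate(zip(vidx, uloc)):
            r = role[v]
            if r in ("anchor", "background"):
                H[:, :, local_i] = A[:, :, ul]
            elif r == "perfect":
                H[:, :, local_i] = (1 - A[:, :, ul]) if comp[v] else A[:, :, ul]
            else:  # member: copy anchor haplotype with prob copy_prob
                fresh = (rng.random((2, n)) < gen_maf[v]).astype(np.int8)
                take = rng.random((2, n)) < copy_prob
                H[:, :, local_i] = np.where(take, A[:, :, ul], fresh)
        if related_plan:
            for rp in related_plan:
                units_here = np.arange(u0, u1)
                sh1 = rp["share1"][units_here]  # hap-1 IBD with base?
                sh2 = rp["share2"][units_here]
                src1 = rp["src_hap"][units_here]  # which base hap seeds hap 1
                v_sh1 = sh1[uloc]
                v_sh2 = sh2[uloc]
                v_src1 = src1[uloc]
                b_i, d_i = rp["base"], rp["derived"]
                base_h = np.where(v_src1 == 0, H[0, b_i, :], H[1, b_i, :])
                H[0, d_i, :] = np.where(v_sh1, base_h, H[0, d_i, :])
                H[1, d_i, :] = np.where(v_sh2, H[1, b_i, :], H[1, d_i, :])
        dosages[:, vidx] = H[0] + H[1]
    return dosages


def _relatedness_plan(config: SimulationConfig, n_units: int, rng: np.random.Generator):
    """Assign relationship classes to pairs (largest-remainder rounding of
    the mix) and draw per-unit IBD-sharing masks."""
    n_pairs = config.n_related_pairs
    if n_pairs == 0:
        return [], pd.DataFrame(columns=["sample_a", "sample_b", "relationship", "expected_phi"])
    quotas = {r: config.relationship_mix.get(r, 0.0) * n_pairs for r in RELATIONSHIPS}
    counts = {r: int(np.floor(q)) for r, q in quotas.items()}
    short = n_pairs - sum(counts.values())
    for r in sorted(RELATIONSHIPS, key=lambda r: quotas[r] - counts[r], reverse=True)[:short]:
        counts[r] += 1
    plan, rows = [], []
    pair_id = 0
    for rel in RELATIONSHIPS:
        p1, p2 = _SHARE_SCHEME[rel]
        for _ in range(counts[rel]):
            base = pair_id  # base samples are the first n_pairs cohort members
            derived = config.n_biobank_samples - n_pairs + pair_id
            share1 = rng.random(n_units) < p1 if 0 < p1 < 1 else np.full(n_units, bool(p1))
            share2 = rng.random(n_units) < p2 if 0 < p2 < 1 else np.full(n_units, bool(p2))
            if rel == "parent_offspring":
                # the transmitted haplotype is a random one of the parent's two
                src_hap = rng.integers(0, 2, n_units).astype(np.int8)
            else:
                # hap slots act as parental origins: slot 1 pairs with slot 1
                src_hap = np.zeros(n_units, dtype=np.int8)
            plan.append(dict(base=base, derived=derived, share1=share1, share2=share2,
                             src_hap=src_hap, relationship=rel))
            rows.append(dict(sample_a=f"S{base:06d}", sample_b=f"S{derived:06d}",
                             relationship=rel, expected_phi=EXPECTED_PHI[rel]))
            pair_id += 1
    return plan, pd.DataFrame(rows)


def simulate_reference_panel(config: SimulationConfig) -> ReferencePanel:
    """Generate the genotype reference panel (no related samples)."""
    rng = config.rng(1)
    plan = _make_variant_plan(config, rng)
    copy_prob = float(np.sqrt(config.within_block_r2))
    dosages = _draw_dosages(plan, config.n_panel_samples, copy_prob, rng)
    samples = [f"P{i:05d}" for i in range(config.n_panel_samples)]
    variants = plan[["rsid", "chrom", "pos", "ref", "alt"]].copy()
    sim_params = {"plan": plan, "copy_prob": copy_prob, "config": config}
    return ReferencePanel(samples, variants, dosages, sim_params=sim_params)


# -------------------------------------------------------------------- catalog


def simulate_catalog(
    config: SimulationConfig, panel: ReferencePanel
) -> tuple[pd.DataFrame, TruthTable]:
    """Catalog-style association table plus the simulation truth table.

    Every block anchor enters as one genome-wide-significant non-bone
    record (the catalog candidates); the first ``n_planted_pleiotropic``
    blocks carry a true BMD effect, the next ``n_planted_decoy`` blocks
    carry an effect in the summary statistics only.  Records exercising
    each curation rule are injected with known counts.
    """
    if panel.sim_params is None:
        raise ValueError("panel must come from simulate_reference_panel")
    rng = config.rng(2)
    plan = panel.sim_params["plan"].copy()

    snps = plan.copy()
    snps["is_anchor"] = snps["role"] == "anchor"
    snps["planted"] = False
    snps["decoy"] = False
    snps["beta_cohort"] = 0.0
    snps["beta_gwas_anchor"] = 0.0
    snps["is_candidate"] = False

    planted_blocks = list(range(config.n_planted_pleiotropic))
    decoy_blocks = list(range(config.n_planted_pleiotropic,
                              config.n_planted_pleiotropic + config.n_planted_decoy))
    signs = rng.choice([-1.0, 1.0], size=len(planted_blocks) + len(decoy_blocks))
    for i, b in enumerate(planted_blocks + decoy_blocks):
        in_block = snps["block"] == b
        beta = float(signs[i]) * config.effect_size_sd
        snps.loc[in_block, "planted"] = b in planted_blocks
        snps.loc[in_block, "decoy"] = b in decoy_blocks
        snps.loc[in_block, "beta_gwas_anchor"] = beta
        if b in planted_blocks:
            snps.loc[in_block & (snps["role"] == "anchor"), "beta_cohort"] = beta
    snps.loc[snps["is_anchor"] & (snps["block"] >= 0), "is_candidate"] = True

    traits = [NONBONE_TRAITS[i % len(NONBONE_TRAITS)] if i < len(NONBONE_TRAITS)
              else f"Quantitative trait {i + 1}"
              for i in range(config.n_catalog_traits)]

    def gws_p():
        return float(10.0 ** -rng.uniform(8.5, 20.0))

    anchors = snps[snps["is_candidate"]]
    records = []
    for i, (_, v) in enumerate(anchors.iterrows()):
        records.append(dict(
            rsid=v["rsid"], chrom=v["chrom"], pos=v["pos"],
            trait=traits[i % len(traits)], trait_category=traits[i % len(traits)].lower(),
            p_value=gws_p(), effect_allele="G",
            effect_size=round(float(rng.normal(0.05, 0.02)), 4), eaf=round(v["gen_maf"], 3),
            ancestry="European", study_id=f"GCST{900000 + i}",
            is_haplotype=False, is_interaction=False,
        ))

    def injected(rsid, trait, p, **kw):
        rec = dict(rsid=rsid, chrom="1", pos=1, trait=trait, trait_category=trait.lower(),
                   p_value=p, effect_allele="A", effect_size=0.03, eaf=0.2,
                   ancestry="European", study_id="GCST000000",
                   is_haplotype=False, is_interaction=False)
        rec.update(kw)
        return rec

    extras = []
    # non-genome-wide-significant rows (one exactly at p = 6e-8)
    extras.append(injected("rs77000001", "Height", 6e-8))
    for i in range(4):
        extras.append(injected(f"rs7700001{i}", "Asthma", float(10.0 ** -rng.uniform(3, 7))))
    for i in range(3):
        extras.append(injected(f"rs7700002{i}", "Height", gws_p(), is_interaction=True))
    for i in range(3):
        extras.append(injected(f"rs7700003{i}", "Height", gws_p(), is_haplotype=True))
    extras.append(injected("", "Height", gws_p()))
    extras.append(injected("chr2:12345", "Asthma", gws_p()))
    for trait in ("Osteoporosis", "Bone mineral density", "Fracture risk", "Calcium levels"):
        extras.append(injected(f"rs770004{len(extras)}", trait, gws_p()))
    for r in DEFAULT_KNOWN_BMD_SNPS:
        extras.append(injected(r, "Height", gws_p()))
    for i in range(2):
        extras.append(injected(f"rs7700005{i}", "Vitamin D levels", gws_p()))
    duplicates = [dict(records[i], trait=traits[(i + 1) % len(traits)]) for i in range(min(3, len(records)))]

    catalog_expected = {
        "non_gws": 5, "interaction": 3, "haplotype": 3, "missing_rsid": 2,
        "bone_trait": 4, "known_bmd_snp": 2, "pleiotropy_rule": 2,
        "duplicate": len(duplicates),
    }

    body = records + extras
    order = rng.permutation(len(body))
    catalog = pd.DataFrame([body[i] for i in order] + duplicates)
    truth = TruthTable(snps=snps, catalog_expected=catalog_expected,
                       known_bmd_snps=DEFAULT_KNOWN_BMD_SNPS)
    return catalog, truth


def write_catalog(catalog: pd.DataFrame, path) -> None:
    """Write a catalog table using the default export column headers."""
    out = pd.DataFrame({col: catalog[fld] for fld, col in DEFAULT_DIALECT.items()})
    out.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- summary stats

_TRAIT_STREAMS = {"FN": 3, "LS": 4}


def simulate_summary_stats(
    config: SimulationConfig,
    panel: ReferencePanel,
    truth: TruthTable,
    trait: str,
) -> pd.DataFrame:
    """GWAS summary statistics for one BMD trait (``"FN"`` or ``"LS"``).

    For each non-background panel variant the true marginal effect is
    the block anchor's planted effect attenuated by the realized signed
    dosage correlation r with the anchor; the estimate adds Gaussian
    noise with SE = 1/sqrt(2*EAF*(1-EAF)*gwas_n), correlated within a
    block according to the panel's realized dosage correlation.  Exact
    perfect proxies receive sign-harmonized, bit-identical statistics.
    """
    if trait not in _TRAIT_STREAMS:
        raise ValueError(f"trait must be 'FN' or 'LS', got {trait!r}")
    if panel.sim_params is None:
        raise ValueError("panel must come from simulate_reference_panel")
    missing_truth = set(truth.snps["rsid"]) - set(panel.variants["rsid"])
    if missing_truth:
        raise ValueError(f"truth table references SNPs absent from panel: {sorted(missing_truth)[:5]}")
    rng = config.rng(_TRAIT_STREAMS[trait])
    plan = panel.sim_params["plan"]
    eaf = panel.alt_freq
    snp_truth = truth.snps.set_index("rsid")

    rows = []
    for b in range(config.n_blocks):
        vidx = np.flatnonzero((plan["block"] == b).to_numpy())
        D = panel.dosages[:, vidx].astype(float)
        sd = D.std(axis=0)
        if (sd == 0).any():
            mono = plan["rsid"].iloc[vidx[sd == 0]].tolist()
            raise ValueError(f"monomorphic panel variant(s) {mono}: EAF of 0 or 1 rejected")
        C = np.corrcoef(D, rowvar=False)
        C = np.atleast_2d(C)
        r_anchor = C[:, 0]
        beta_anchor = float(snp_truth.loc[plan["rsid"].iloc[vidx[0]], "beta_gwas_anchor"])
        true_beta = r_anchor * beta_anchor
        p_alt = eaf[vidx]
        if np.any((p_alt <= 0.0) | (p_alt >= 1.0)):
            raise ValueError("EAF of 0 or 1 rejected")
        se = 1.0 / np.sqrt(2.0 * p_alt * (1.0 - p_alt) * config.gwas_n)
        # within-block correlated sampling noise from the realized LD
        w, V = np.linalg.eigh(C)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        eps = se * (L @ rng.standard_normal(len(vidx)))
        beta_hat = true_beta + eps
        # exact perfect proxies: identical genotypes => identical statistics
        for local_j, v in enumerate(vidx):
            if plan["role"].iloc[v] == "perfect":
                g_a = panel.dosages[:, vidx[0]]
                g_p = panel.dosages[:, v]
                if np.array_equal(g_p, g_a):
                    beta_hat[local_j] = beta_hat[0]
                elif np.array_equal(g_p, 2 - g_a):
                    beta_hat[local_j] = -beta_hat[0]
        z = beta_hat / se
        p_val = 2.0 * sps.norm.sf(np.abs(z))
        for local_j, v in enumerate(vidx):
            meta = plan.iloc[v]
            rows.append(dict(
                rsid=meta["rsid"], chrom=meta["chrom"], pos=int(meta["pos"]),
                ea=meta["alt"], oa=meta["ref"], eaf=float(p_alt[local_j]),
                beta=float(beta_hat[local_j]), se=float(se[local_j]),
                p=float(max(p_val[local_j], 5e-324)), n=int(config.gwas_n),
            ))
    return pd.DataFrame(rows)


def simulate_null_summary_stats(
    m: int, gwas_n: int, rng: np.random.Generator, maf_range=(0.05, 0.5)
) -> pd.DataFrame:
    """Fully null, independent summary statistics (true beta 0 for all SNPs).

    A lightweight path for calibration studies of the discovery stage.
    """
    maf = rng.uniform(*maf_range, size=m)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * gwas_n)
    beta = rng.standard_normal(m) * se
    p = 2.0 * sps.norm.sf(np.abs(beta / se))
    return pd.DataFrame(dict(
        rsid=[f"rs{i + 1}" for i in range(m)], chrom="1",
        pos=np.arange(1, m + 1) * 1000, ea="G", oa="A", eaf=maf,
        beta=beta, se=se, p=np.maximum(p, 5e-324), n=gwas_n,
    ))


# -------------------------------------------------------------------- biobank

#: QC-outlier placements cycled through for the expected-excluded records:
#: (measure, side, exact-on-boundary?)
_OUTLIER_CYCLE = (
    ("sos", "low", True), ("sos", "high", False), ("bua", "low", False),
    ("bua", "high", False), ("bmd", "low", False), ("bmd", "high", False),
    ("sos", "low", False), ("bua", "low", True),
)


def simulate_biobank(
    config: SimulationConfig,
    panel: ReferencePanel,
    truth: TruthTable,
) -> tuple[BiobankCohort, TruthTable]:
    """Individual-level cohort with ultrasound phenotypes and genotypes.

    The latent eBMD is ``mean_ebmd + genetic score + covariate effects +
    noise`` (device units, g/cm²); SOS and BUA are generated so the
    printed formula returns the latent value exactly.  Related pairs
    share haplotypes identical-by-descent per their relationship class.
    A ``qc_outlier_fraction`` of records is placed on or outside the
    ultrasound QC bounds, recorded in the truth table.
    """
    if panel.sim_params is None:
        raise ValueError("panel must come from simulate_reference_panel")
    rng = config.rng(5)
    plan = panel.sim_params["plan"]
    copy_prob = panel.sim_params["copy_prob"]
    n = config.n_biobank_samples
    n_units = int(plan["unit"].max()) + 1

    related_plan, pairs = _relatedness_plan(config, n_units, rng)
    dosages = _draw_dosages(plan, n, copy_prob, rng, related_plan=related_plan)
    sample_ids = [f"S{i:06d}" for i in range(n)]

    sex = np.where(rng.random(n) < 0.5, "male", "female")
    age = rng.uniform(40.0, 69.0, size=n)
    weight = sps.truncnorm.rvs((30.0 - 78.0) / 15.0, np.inf, loc=78.0, scale=15.0,
                               size=n, random_state=rng)
    ce = config.covariate_effects
    cov_term = (ce.get("age", 0.0) * age + ce.get("age2", 0.0) * age ** 2
                + ce.get("weight", 0.0) * weight + ce.get("sex_male", 0.0) * (sex == "male"))
    base = config.mean_ebmd - (
        ce.get("age", 0.0) * 54.5 + ce.get("age2", 0.0) * 54.5 ** 2
        + ce.get("weight", 0.0) * 78.0 + ce.get("sex_male", 0.0) * 0.5
    )
    snp_truth = truth.snps
    causal = snp_truth[snp_truth["beta_cohort"] != 0.0]
    genetic = np.zeros(n)
    if len(causal):
        rsid_to_col = {r: j for j, r in enumerate(plan["rsid"])}
        cols = [rsid_to_col[r] for r in causal["rsid"]]
        # per-allele effect in device units: standardized beta x residual SD
        betas = causal["beta_cohort"].to_numpy() * config.noise_sd
        genetic = dosages[:, cols].astype(float) @ betas
    latent = base + cov_term + genetic + rng.normal(0.0, config.noise_sd, size=n)

    thresholds = QCThresholds()
    n_outliers = int(np.floor(config.qc_outlier_fraction * n))
    # outliers are drawn from cohort members not used as relatedness bases
    outlier_idx = np.arange(config.n_related_pairs,
                            config.n_related_pairs + n_outliers) % n
    qc_reason = np.array([""] * n, dtype=object)
    for k, i in enumerate(outlier_idx):
        measure, side, exact = _OUTLIER_CYCLE[k % len(_OUTLIER_CYCLE)]
        lo, hi = getattr(thresholds, measure)[sex[i]]
        target = (lo if side == "low" else hi) if exact else (lo - 5 * 0.01 if side == "low" else hi + 5 * 0.01)
        if measure == "bmd":
            target = lo - 0.02 if side == "low" else hi + 0.02
            if exact:
                target = lo if side == "low" else hi
            latent[i] = target
        qc_reason[i] = f"{measure}_{side}{'_boundary' if exact else ''}"

    # SOS ~ N(1550, 30^2) truncated so that both SOS and the implied BUA
    # stay strictly inside the sex-specific bounds; the formula then
    # returns the latent eBMD exactly.
    total = (latent - EBMD_INTERCEPT) / EBMD_SLOPE  # required BUA + SOS
    eps = 0.5
    male = sex == "male"
    s_lo = np.where(male, thresholds.sos["male"][0], thresholds.sos["female"][0])
    s_hi = np.where(male, thresholds.sos["male"][1], thresholds.sos["female"][1])
    b_lo = np.where(male, thresholds.bua["male"][0], thresholds.bua["female"][0])
    b_hi = np.where(male, thresholds.bua["male"][1], thresholds.bua["female"][1])
    lo = np.maximum(s_lo + eps, total - (b_hi - eps))
    hi = np.minimum(s_hi - eps, total - (b_lo + eps))
    ok = lo < hi
    sos = 0.5 * (s_lo + s_hi)  # fallback when no in-bounds split exists
    if ok.any():
        a = (lo[ok] - 1550.0) / 30.0
        b_ = (hi[ok] - 1550.0) / 30.0
        draws = sps.truncnorm.rvs(a, b_, loc=1550.0, scale=30.0,
                                  size=int(ok.sum()), random_state=rng)
        sos = np.where(ok, 0.0, sos)
        sos[ok] = draws
    bua = total - sos

    # deliberate SOS/BUA outliers override the split, preserving the sum
    for k, i in enumerate(outlier_idx):
        measure, side, exact = _OUTLIER_CYCLE[k % len(_OUTLIER_CYCLE)]
        lo, hi = getattr(thresholds, measure)[sex[i]]
        if measure == "sos":
            sos[i] = (lo if side == "low" else hi) if exact else (lo - 10.0 if side == "low" else hi + 10.0)
            bua[i] = total[i] - sos[i]
        elif measure == "bua":
            bua[i] = (lo if side == "low" else hi) if exact else (lo - 3.0 if side == "low" else hi + 3.0)
            sos[i] = total[i] - bua[i]

    # ground-truth exclusion flags re-derived from the final values
    expected_excluded = np.zeros(n, dtype=bool)
    for i in range(n):
        flags = []
        for measure, val in (("sos", sos[i]), ("bua", bua[i]), ("bmd", latent[i])):
            if thresholds.excluded(measure, sex[i], val):
                flags.append(measure)
        if flags:
            expected_excluded[i] = True
            if not qc_reason[i]:
                qc_reason[i] = "+".join(flags) + "_accidental"

    pcs = rng.standard_normal((n, N_PCS))
    covariates = pd.DataFrame(dict(
        sample_id=sample_ids, sex=sex, age=age, weight=weight, sos=sos, bua=bua,
        bmd_device=latent, entry_mode=np.where(rng.random(n) < 0.02, "manual", "direct"),
    ))
    for j in range(N_PCS):
        covariates[f"pc{j + 1}"] = pcs[:, j]

    cohort = BiobankCohort(covariates, dosages, list(plan["rsid"]))
    truth.pairs = pairs
    truth.biobank = pd.DataFrame(dict(
        sample_id=sample_ids, latent_ebmd=latent,
        expected_excluded=expected_excluded, qc_reason=qc_reason,
    ))
    return cohort, truth


def simulate_related_pair(
    relationship: str,
    n_variants: int,
    rng: np.random.Generator,
    maf_range=(0.05, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Two dosage vectors with the stated pedigree relationship at
    independent variants — an oracle for kinship-estimator tests."""
    if relationship not in _SHARE_SCHEME and relationship != "unrelated":
        raise ValueError(f"unknown relationship {relationship!r}")
    maf = rng.uniform(*maf_range, size=n_variants)
    h = (rng.random((4, n_variants)) < maf).astype(np.int8)  # a1,a2,fresh1,fresh2
    a = h[0] + h[1]
    if relationship == "unrelated":
        return a, h[2] + h[3]
    if relationship == "duplicate":
        return a, a.copy()
    p1, p2 = _SHARE_SCHEME[relationship]
    if relationship == "parent_offspring":
        src = np.where(rng.integers(0, 2, n_variants) == 0, h[0], h[1])
    else:
        src = h[0]
    b1 = np.where(rng.random(n_variants) < p1, src, h[2])
    b2 = np.where(rng.random(n_variants) < p2, h[1], h[3])
    return a, (b1 + b2).astype(np.int8)
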