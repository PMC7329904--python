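"""End-to-end orchestration: simulate/load -> curate -> proxies ->
discover -> replicate -> report.

A single :class:`PipelineConfig` holds every threshold the scan uses
(genome-wide significance 5e-8, perfect-proxy r² = 1, independence
r² < 0.2, FDR 5%, kinship cutoff 2^(-9/2), Z bound 4) plus either a
:class:`~pleioscan.simulate.SimulationConfig` or paths to real input
files.  All analysis artifacts (curation report, FDR reports, discovery
table, QC report, kinship pairs, association and concordance tables,
final report) are persisted to the output directory; rerunning with the
same config and seed reproduces them byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as catalog_mod
from . import discovery as discovery_mod
from . import replication as repl
from . import simulate as sim
from .ld import ReferencePanel, find_proxies

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and input locations for one pipeline run."""

    output_dir: str = "pleioscan_output"
    seed: int = 0
    # stage thresholds
    proxy_r2: float = 1.0
    proxy_window_bp: int = 500_000
    prune_r2: float = 0.2
    fdr_q: float = 0.05
    gws_p: float = repl.GWS_P
    kinship_cutoff: float = repl.KINSHIP_CUTOFF
    z_bound: float = repl.Z_BOUND
    use_ebmd: bool = False
    write_inputs: bool = False
    # curation
    known_bmd_snps: tuple = ()
    bone_trait_keywords: tuple = catalog_mod.BONE_TRAIT_KEYWORDS
    pleiotropy_rules: tuple = catalog_mod.PLEIOTROPY_RULE_KEYWORDS
    # either a simulation...
    simulation: sim.SimulationConfig | None = None
    # ...or file inputs
    catalog_path: str | None = None
    panel_path: str | None = None
    panel_format: str = "vcf"  # or "dosage_tsv"
    stats_fn_path: str | None = None
    stats_ls_path: str | None = None
    cohort_covariates_path: str | None = None
    cohort_dosages_path: str | None = None

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("proxy_r2", 0.0, 1.0 + 1e-12), ("prune_r2", 0.0, 1.0),
            ("fdr_q", 0.0, 1.0), ("gws_p", 0.0, 1.0), ("kinship_cutoff", 0.0, 0.5),
        ):
            v = getattr(self, name)
            if not lo < v < hi and not (name == "proxy_r2" and v == 1.0):
                raise ValueError(f"{name} out of range: {v}")
        if self.z_bound <= 0:
            raise ValueError(f"z_bound must be positive, got {self.z_bound}")
        if self.proxy_window_bp <= 0:
            raise ValueError("proxy_window_bp must be positive")
        if self.simulation is None and not (self.catalog_path and self.panel_path
                                            and self.stats_fn_path and self.stats_ls_path):
            raise ValueError("either a simulation block or all input paths are required")

    # ------------------------------------------------------------- round-trip

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        for k in ("known_bmd_snps", "bone_trait_keywords", "pleiotropy_rules"):
            d[k] = list(d[k])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("simulation") is not None:
            simd = dict(d["simulation"])
            if "maf_range" in simd:
                simd["maf_range"] = tuple(simd["maf_range"])
            d["simulation"] = sim.SimulationConfig(**simd)
        for k in ("known_bmd_snps", "bone_trait_keywords", "pleiotropy_rules"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @property
    def curation_config(self) -> catalog_mod.CurationConfig:
        return catalog_mod.CurationConfig(
            bone_trait_keywords=tuple(self.bone_trait_keywords),
            known_bmd_snps=frozenset(self.known_bmd_snps),
            pleiotropy_rules=tuple(self.pleiotropy_rules),
        )


@dataclass
class PleiotropyReport:
    """Final report: one row per replicated SNP-phenotype pair, plus the
    per-stage audit counts."""

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)

    REPORT_COLUMNS = [
        "rsid", "chrom", "pos", "phenotype", "direction_phenotype",
        "direction_bmd", "p_fn", "p_ls", "beta", "se", "p_replication",
        "n_used", "ci_low", "ci_high", "source", "concordance_status",
    ]


def _stage(name: str, **counts) -> None:
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig, truth: sim.TruthTable | None = None):
    """Execute the full two-stage scan and write all artifacts.

    Returns ``(report, artifacts)`` where ``artifacts`` is a dict of the
    in-memory per-stage outputs (curation report, proxy map, discovery
    outcome, QC report, kinship pairs, association results, concordance
    table, and — for simulated runs — the truth table).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # ---------------------------------------------------------------- inputs
    if config.simulation is not None:
        sc = dataclasses.replace(config.simulation, seed=config.seed)
        panel = sim.simulate_reference_panel(sc)
        catalog_df, truth = sim.simulate_catalog(sc, panel)
        stats_fn = sim.simulate_summary_stats(sc, panel, truth, "FN")
        stats_ls = sim.simulate_summary_stats(sc, panel, truth, "LS")
        cohort, truth = sim.simulate_biobank(sc, panel, truth)
        known_bmd = frozenset(config.known_bmd_snps) | frozenset(truth.known_bmd_snps)
        if config.write_inputs:
            panel.to_dosage_tsv(out / "panel_dosages.tsv")
            sim.write_catalog(catalog_df, out / "catalog.tsv")
            discovery_mod.write_summary_stats(stats_fn, out / "stats_fn.tsv")
            discovery_mod.write_summary_stats(stats_ls, out / "stats_ls.tsv")
            cohort.covariates.to_csv(out / "cohort_covariates.tsv", sep="\t", index=False)
            truth.snps.to_csv(out / "truth_snps.tsv", sep="\t", index=False)
        artifacts["truth"] = truth
    else:
        catalog_df = catalog_mod.read_catalog(config.catalog_path)
        if config.panel_format == "vcf":
            panel = ReferencePanel.from_vcf(config.panel_path)
        else:
            panel = ReferencePanel.from_dosage_tsv(config.panel_path)
        stats_fn = discovery_mod.read_summary_stats(config.stats_fn_path)
        stats_ls = discovery_mod.read_summary_stats(config.stats_ls_path)
        cohort = None
        if config.cohort_covariates_path and config.cohort_dosages_path:
            cohort = repl.BiobankCohort.from_tsv(
                config.cohort_covariates_path, config.cohort_dosages_path)
        known_bmd = frozenset(config.known_bmd_snps)
    _stage("inputs", catalog_rows=len(catalog_df), panel_variants=panel.n_variants,
           panel_samples=panel.n_samples)

    # ---------------------------------------------------------------- curate
    cur_cfg = config.curation_config
    if config.simulation is not None:
        cur_cfg = dataclasses.replace(cur_cfg, known_bmd_snps=known_bmd)
    candidates, cur_report = catalog_mod.curate(catalog_df, cur_cfg)
    (out / "curation_report.json").write_text(json.dumps(cur_report.to_dict(), indent=1))
    _stage("curate", n_input=cur_report.n_input, n_retained=cur_report.n_retained)

    # --------------------------------------------------------------- proxies
    proxies, unresolved = find_proxies(panel, candidates, r2_min=config.proxy_r2,
                                       window_bp=config.proxy_window_bp)
    proxy_rows = [
        dict(index_rsid=ps.rsid, proxy_rsid=r, r2=r2)
        for ps in proxies.values() for r, r2 in ps.proxies
    ]
    pd.DataFrame(proxy_rows).to_csv(out / "proxies.tsv", sep="\t", index=False)
    n_proxies = sum(len(ps.proxies) - 1 for ps in proxies.values())
    _stage("proxies", n_index=len(proxies), n_proxies=n_proxies, n_unresolved=len(unresolved))

    # -------------------------------------------------------------- discover
    outcome = discovery_mod.run_discovery(candidates, proxies, stats_fn, stats_ls,
                                          q=config.fdr_q)
    outcome = discovery_mod.mark_independent(outcome, panel, r2_max=config.prune_r2)
    outcome = discovery_mod.drop_known_bmd(outcome, known_bmd, proxies)
    fdr_json = {t: f.to_dict() for t, f in
                (("FN", outcome.fdr_fn), ("LS", outcome.fdr_ls)) if f is not None}
    (out / "fdr_report.json").write_text(json.dumps(fdr_json, indent=1))
    outcome.to_frame().to_csv(out / "discovery.tsv", sep="\t", index=False)
    pleio = outcome.pleiotropic_rsids
    _stage("discover",
           n_tested=len(outcome.results),
           n_significant=sum(r.significant for r in outcome.results),
           n_independent=sum(r.significant and r.independent for r in outcome.results),
           n_pleiotropic=len(pleio))
    artifacts.update(curation=cur_report, proxies=proxies, discovery=outcome)

    # ------------------------------------------------------------- replicate
    assoc_results: list[repl.AssociationResult] = []
    conc_table = pd.DataFrame()
    conc_fraction = float("nan")
    if cohort is not None and pleio:
        qc_cohort, qc_report = repl.apply_qc(cohort, use_ebmd=config.use_ebmd)
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        pairs = repl.kinship_scan(qc_cohort.dosages, qc_cohort.covariates["sample_id"],
                                  cutoff=config.kinship_cutoff)
        pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
            out / "kinship_pairs.tsv", sep="\t", index=False)
        unrelated = repl.select_unrelated(qc_cohort.covariates["sample_id"], pairs,
                                          threshold=config.kinship_cutoff)
        keep = qc_cohort.covariates["sample_id"].isin(unrelated).to_numpy()
        unrel = qc_cohort.subset(keep)
        _stage("kinship", n_pairs=len(pairs), n_after_qc=qc_cohort.n_samples,
               n_unrelated=unrel.n_samples)

        values = (repl.derive_ebmd(unrel.covariates["sos"], unrel.covariates["bua"])
                  if config.use_ebmd else None)
        z, z_excluded = repl.zscore_phenotype(unrel.covariates, values=values,
                                              z_bound=config.z_bound)
        zmask = unrel.covariates["sample_id"].isin(z.index).to_numpy()
        final = unrel.subset(zmask)
        zv = z.loc[final.covariates["sample_id"]].to_numpy()
        pcs = final.covariates[repl.PC_COLUMNS].to_numpy(float)
        stats_by_rsid = pd.concat([stats_fn, stats_ls]).drop_duplicates("rsid").set_index("rsid")
        for rsid in pleio:
            if rsid not in final._index:
                logger.warning("pleiotropic SNP %s absent from cohort genotypes", rsid)
                continue
            ea, oa = ("", "")
            if rsid in stats_by_rsid.index:
                ea, oa = stats_by_rsid.loc[rsid, "ea"], stats_by_rsid.loc[rsid, "oa"]
            try:
                res = repl.snp_association(zv, final.dosage(rsid), pcs, rsid=rsid,
                                           effect_allele=str(ea), other_allele=str(oa))
            except repl.MonomorphicError:
                logger.warning("SNP %s monomorphic in cohort; skipped", rsid)
                continue
            assoc_results.append(res)
        assoc_df = pd.DataFrame([
            dict(rsid=r.rsid, ea=r.effect_allele, beta=r.beta, se=r.se, p=r.p_value,
                 n=r.n_used, ci_low=r.ci95[0], ci_high=r.ci95[1],
                 replicated=r.p_value < config.gws_p)
            for r in assoc_results
        ])
        assoc_df.to_csv(out / "association.tsv", sep="\t", index=False)
        _stage("replicate", n_tested=len(assoc_results),
               n_replicated=int(assoc_df["replicated"].sum()) if len(assoc_df) else 0,
               n_z_excluded=len(z_excluded))

        replicated = [r for r in assoc_results if r.p_value < config.gws_p]
        disc_stats = pd.concat([stats_fn, stats_ls]).sort_values("p").drop_duplicates("rsid")
        conc_table, conc_fraction = repl.direction_concordance(disc_stats, replicated)
        conc_table.to_csv(out / "concordance.tsv", sep="\t", index=False)
        artifacts.update(qc_report=qc_report, kinship_pairs=pairs,
                         association=assoc_results, concordance=conc_table)

    # ---------------------------------------------------------------- report
    report = build_report(config, catalog_df, outcome, assoc_results, conc_table,
                          conc_fraction, cur_report)
    render_report(report, "tsv", out / "pleiotropy_report.tsv")
    render_report(report, "json", out / "pleiotropy_report.json")
    render_report(report, "markdown", out / "pleiotropy_report.md")
    return report, artifacts


def build_report(config, catalog_df, outcome, assoc_results, conc_table,
                 conc_fraction, cur_report) -> PleiotropyReport:
    """Assemble the final per-SNP/phenotype table and summary counts."""
    disc_by_rsid = {r.rsid: r for r in outcome.results}
    cat = catalog_df[catalog_df["rsid"].astype(bool)]
    conc_status = (conc_table.set_index("rsid")["status"].to_dict()
                   if len(conc_table) else {})
    rows = []
    for res in assoc_results:
        if res.p_value >= config.gws_p:
            continue
        d = disc_by_rsid.get(res.rsid)
        phenos = cat[cat["rsid"] == res.rsid][["trait", "effect_size"]]
        if not len(phenos):
            phenos = pd.DataFrame([dict(trait="(proxy of catalog SNP)", effect_size=np.nan)])
        for _, ph in phenos.iterrows():
            es = ph["effect_size"]
            rows.append(dict(
                rsid=res.rsid, chrom="", pos=np.nan, phenotype=ph["trait"],
                direction_phenotype=("up" if es > 0 else "down") if pd.notna(es) else "NR",
                direction_bmd="up" if res.beta > 0 else "down",
                p_fn=d.p_fn if d else np.nan, p_ls=d.p_ls if d else np.nan,
                beta=res.beta, se=res.se, p_replication=res.p_value,
                n_used=res.n_used, ci_low=res.ci95[0], ci_high=res.ci95[1],
                source=d.source if d else "", concordance_status=conc_status.get(res.rsid, ""),
            ))
    table = pd.DataFrame(rows, columns=PleiotropyReport.REPORT_COLUMNS)
    summary = dict(
        n_catalog_rows=cur_report.n_input,
        n_candidates=cur_report.n_retained,
        n_tested=len(outcome.results),
        n_discovered=sum(r.significant for r in outcome.results),
        n_independent_pleiotropic=len(outcome.pleiotropic_rsids),
        n_replication_tested=len(assoc_results),
        n_replicated=len({r["rsid"] for r in rows}),
        concordant_fraction=conc_fraction,
    )
    return PleiotropyReport(table=table, summary=summary)


def render_report(report: PleiotropyReport, fmt: str, path) -> None:
    """Write the report as ``tsv``, ``json`` or ``markdown`` with
    deterministic (rsid, phenotype) row ordering."""
    table = report.table.sort_values(["rsid", "phenotype"]).reset_index(drop=True)
    path = Path(path)
    if fmt == "tsv":
        table.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        summary = {k: (None if isinstance(v, float) and np.isnan(v) else v)
                   for k, v in report.summary.items()}
        payload = dict(summary=summary,
                       rows=json.loads(table.to_json(orient="records")))
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif fmt == "markdown":
        cols = ["rsid", "phenotype", "direction_phenotype", "direction_bmd",
                "beta", "p_replication"]
        lines = ["| " + " | ".join(cols) + " |",
                 "|" + "---|" * len(cols)]
        for _, r in table.iterrows():
            lines.append("| " + " | ".join(
                f"{r[c]:.3g}" if isinstance(r[c], float) else str(r[c]) for c in cols) + " |")
        lines.append("")
        lines.append("Summary: " + ", ".join(f"{k}={v}" for k, v in report.summary.items()))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
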