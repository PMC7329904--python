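"""Discovery stage: FDR-thresholded association of candidate SNPs with
two sets of BMD summary statistics.

Candidate SNPs from catalog curation, expanded with their perfect LD
proxies, are intersected with each trait's summary statistics (femoral
neck and lumbar spine BMD).  Within each trait the Simes/Benjamini-
Hochberg step-up procedure at a nominal false-discovery rate q yields a
data-dependent p-value threshold (k/m)*q; a SNP discovered for either
trait is carried forward.  The combined set is then LD-pruned to
independent SNPs (r^2 < 0.2, best-p-first) and SNPs that are themselves
— or whose perfect proxies are — already-established BMD loci are
flagged and removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import ProxySet, ReferencePanel, prune_independent

logger = logging.getLogger(__name__)

SUMMARY_STAT_COLUMNS = ["rsid", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]


def read_summary_stats(path) -> pd.DataFrame:
    """Read a summary-statistics TSV (rsid, chr, pos, ea, oa, eaf, beta, se, p, n)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str, "ea": str, "oa": str})
    missing = set(SUMMARY_STAT_COLUMNS) - set(df.columns)
    if missing:
        raise KeyError(f"summary-statistics file lacks columns: {sorted(missing)}")
    return df


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SUMMARY_STAT_COLUMNS)


def validate_summary_stats(df: pd.DataFrame, rel_tol: float = 0.1) -> list[str]:
    """Sanity-check a stat set; returns warning strings (never raises).

    Flags non-positive SEs and p-values inconsistent with the two-sided
    normal test of beta/se by more than ``rel_tol`` relative.
    """
    from scipy import stats

    warnings = []
    bad_se = df["se"] <= 0
    if bad_se.any():
        warnings.append(f"{int(bad_se.sum())} records with non-positive SE")
    ok = ~bad_se
    z = np.abs(df.loc[ok, "beta"] / df.loc[ok, "se"])
    expect = 2.0 * stats.norm.sf(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(df.loc[ok, "p"] - expect) / np.maximum(expect, 1e-300)
    n_bad = int(((rel > rel_tol) & (expect > 1e-280)).sum())
    if n_bad:
        warnings.append(f"{n_bad} records with p inconsistent with beta/se (> {rel_tol:.0%} relative)")
    for w in warnings:
        logger.warning("summary-stat validation: %s", w)
    return warnings


@dataclass
class FDRResult:
    """Outcome of the Simes/BH step-up procedure for one trait."""

    trait: str
    m: int
    q: float
    k: int
    p_threshold: float
    significant: list[str]

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "m": self.m,
            "q": self.q,
            "k": self.k,
            "p_threshold": self.p_threshold,
            "n_significant": len(self.significant),
        }


def step_up_threshold(k: int, m: int, q: float) -> float:
    """The BH step-up bound (k/m)*q at discovery count ``k`` of ``m`` tests.

    This is the quantity reported as "the FDR threshold" for a trait.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    return (k / m) * q


def bh_threshold(p_values, q: float = 0.05, rsids=None, trait: str = "") -> FDRResult:
    """Benjamini-Hochberg / Simes step-up procedure at FDR level ``q``.

    Sorts the p-values ascending, finds the largest rank k with
    p_(k) <= (k/m)*q, and declares every p <= p_(k) significant (step-up
    semantics: smaller p-values are carried even if they miss their own
    rank bound).  ``p_threshold`` is p_(k), or 0.0 when nothing passes.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0,1), got {q}")
    bad = np.flatnonzero(~((p > 0.0) & (p <= 1.0)))
    if bad.size:
        raise ValueError(f"p-value out of (0,1] at index {bad[0]}: {p[bad[0]]!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    bounds = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(ps <= bounds)
    if passing.size == 0:
        k, p_thr = 0, 0.0
        sig_mask = np.zeros(m, dtype=bool)
    else:
        k = int(passing[-1] + 1)
        p_thr = float(ps[k - 1])
        sig_mask = p <= p_thr
    if rsids is None:
        rsids = [str(i) for i in range(m)]
    significant = [r for r, s in zip(rsids, sig_mask) if s]
    return FDRResult(trait=trait, m=m, q=q, k=k, p_threshold=p_thr, significant=significant)


@dataclass
class DiscoveryResult:
    """Per-SNP outcome of the discovery stage."""

    rsid: str
    p_fn: float | None
    p_ls: float | None
    significant_fn: bool
    significant_ls: bool
    source: str  # "catalog" or "proxy"
    independent: bool = False
    known_bmd_proxy: bool = False

    @property
    def significant(self) -> bool:
        return self.significant_fn or self.significant_ls

    @property
    def pleiotropic(self) -> bool:
        return self.significant and self.independent and not self.known_bmd_proxy

    @property
    def min_p(self) -> float:
        ps = [p for p in (self.p_fn, self.p_ls) if p is not None]
        return min(ps) if ps else float("nan")


@dataclass
class DiscoveryOutcome:
    """All per-SNP results plus the per-trait FDR reports."""

    results: list[DiscoveryResult]
    fdr_fn: FDRResult | None
    fdr_ls: FDRResult | None

    @property
    def pleiotropic_rsids(self) -> list[str]:
        return [r.rsid for r in self.results if r.pleiotropic]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    rsid=r.rsid, p_fn=r.p_fn, p_ls=r.p_ls,
                    significant_fn=r.significant_fn, significant_ls=r.significant_ls,
                    independent=r.independent, known_bmd_proxy=r.known_bmd_proxy,
                    source=r.source, pleiotropic=r.pleiotropic,
                )
                for r in self.results
            ]
        )


def run_discovery(
    candidates,
    proxies: dict[str, ProxySet] | None,
    stats_fn: pd.DataFrame,
    stats_ls: pd.DataFrame,
    q: float = 0.05,
) -> DiscoveryOutcome:
    """FDR-based discovery of candidate (and proxy) SNPs against two
    BMD summary-statistic sets.

    The per-trait test set is ``(candidates ∪ proxies) ∩ stats``,
    deduplicated; ``m`` for the step-up bound is the size of that set.
    A SNP significant for either trait is discovery-significant.
    """
    candidates = list(dict.fromkeys(candidates))
    proxy_rsids: list[str] = []
    if proxies:
        for ps in proxies.values():
            proxy_rsids.extend(ps.proxy_rsids)
    cand_set = set(candidates)
    test_rsids = candidates + [r for r in dict.fromkeys(proxy_rsids) if r not in cand_set]
    if not test_rsids:
        logger.warning("empty candidate set; discovery returns no results")
        return DiscoveryOutcome([], None, None)

    def trait_pvals(stats: pd.DataFrame) -> dict[str, float]:
        sub = stats.drop_duplicates("rsid").set_index("rsid")["p"]
        return {r: float(sub[r]) for r in test_rsids if r in sub.index}

    p_fn = trait_pvals(stats_fn)
    p_ls = trait_pvals(stats_ls)
    if not p_fn and not p_ls:
        logger.warning("no candidate SNP present in either summary-statistic set")
        return DiscoveryOutcome([], None, None)

    fdr_fn = fdr_ls = None
    sig_fn: set[str] = set()
    sig_ls: set[str] = set()
    if p_fn:
        rs = list(p_fn)
        fdr_fn = bh_threshold([p_fn[r] for r in rs], q, rsids=rs, trait="FN-BMD")
        sig_fn = set(fdr_fn.significant)
    if p_ls:
        rs = list(p_ls)
        fdr_ls = bh_threshold([p_ls[r] for r in rs], q, rsids=rs, trait="LS-BMD")
        sig_ls = set(fdr_ls.significant)

    results = [
        DiscoveryResult(
            rsid=r,
            p_fn=p_fn.get(r),
            p_ls=p_ls.get(r),
            significant_fn=r in sig_fn,
            significant_ls=r in sig_ls,
            source="catalog" if r in cand_set else "proxy",
        )
        for r in test_rsids
        if r in p_fn or r in p_ls
    ]
    return DiscoveryOutcome(results, fdr_fn, fdr_ls)


def mark_independent(
    outcome: DiscoveryOutcome,
    panel: ReferencePanel,
    r2_max: float = 0.2,
) -> DiscoveryOutcome:
    """LD-prune the discovery-significant set to independent SNPs.

    The per-trait significant sets are united; each SNP enters the greedy
    prune with its minimum p across traits; survivors get
    ``independent=True``.
    """
    sig = [(r.rsid, r.min_p) for r in outcome.results if r.significant]
    kept = set(prune_independent(sig, panel, r2_max=r2_max).kept)
    for r in outcome.results:
        r.independent = r.rsid in kept
    return outcome


def drop_known_bmd(
    outcome: DiscoveryOutcome,
    known_bmd,
    proxies: dict[str, ProxySet] | None = None,
) -> DiscoveryOutcome:
    """Flag results whose rsID — or any perfect proxy of it — is an
    already-established BMD locus; flagged SNPs leave the pleiotropic set.
    """
    known = set(known_bmd)
    for r in outcome.results:
        hit = r.rsid in known
        if not hit and proxies and r.rsid in proxies:
            hit = any(p in known for p in proxies[r.rsid].proxy_rsids)
        r.known_bmd_proxy = hit
    return outcome
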