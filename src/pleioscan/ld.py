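"""Linkage-disequilibrium utilities on a genotype reference panel.

The panel is a samples x variants allele-dosage matrix (0/1/2, missing
allowed).  r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples ("composite" LD) — phase-free, symmetric and
invariant to swapping which allele is counted (g -> 2 - g).

Three operations are built on it:

* :func:`compute_r2` — r² for one variant pair;
* :func:`find_proxies` — all variants within a physical window whose r²
  with a query variant reaches a threshold (r² = 1 gives the "perfect
  proxies" used to expand a candidate SNP list);
* :func:`prune_independent` — greedy best-p-first clumping down to a set
  whose pairwise r² stays below a threshold (default 0.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: numeric code for a missing dosage in :attr:`ReferencePanel.dosages`
MISSING = -1

#: tolerance when comparing r² against a threshold such as 1.0 — exact
#: duplicate columns yield a correlation of 1 only up to float rounding
R2_ATOL = 1e-9


class LDUndefinedError(ValueError):
    """r² is undefined (a variant is monomorphic over the complete samples)."""


@dataclass
class ReferencePanel:
    """Sample x variant dosage matrix with variant metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    variants
        One row per variant with columns ``rsid, chrom, pos, ref, alt``;
        rsIDs must be unique.
    dosages
        ``(n_samples, n_variants)`` integer array of alternate-allele
        counts in {0, 1, 2}; :data:`MISSING` marks a missing call.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    sim_params: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.dosages[~valid].ravel()[0]
            raise ValueError(f"dosages must be in {{0,1,2,{MISSING}}}; found {bad!r}")
        rsids = self.variants["rsid"]
        if rsids.duplicated().any():
            dup = rsids[rsids.duplicated()].iloc[0]
            raise ValueError(f"duplicate rsID in panel: {dup}")
        self._index = {r: i for i, r in enumerate(rsids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def variant_index(self, rsid: str) -> int:
        try:
            return self._index[rsid]
        except KeyError:
            raise KeyError(f"variant {rsid!r} not in panel") from None

    def dosage(self, rsid: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(rsid)]

    @property
    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency over non-missing calls."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        af = d.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(af, 1.0 - af)

    @property
    def alt_freq(self) -> np.ndarray:
        d = np.ma.masked_equal(self.dosages, MISSING)
        return d.mean(axis=0).filled(np.nan) / 2.0

    # ------------------------------------------------------------------ IO

    def to_vcf(self, path) -> None:
        """Write the panel as an uncompressed VCF with hard genotype calls."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in pd.unique(self.variants["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for j, v in self.variants.iterrows():
                calls = "\t".join(gt_codes[int(g)] for g in self.dosages[:, j])
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{calls}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "ReferencePanel":
        """Read a panel from a VCF; biallelic SNVs only, others skipped."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, cols = [], []
        for rec in vcf:
            if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                logger.warning("skipping non-biallelic-SNV record %s", rec.ID)
                continue
            gts = rec.genotype.array()
            dos = gts[:, 0] + gts[:, 1]
            dos = np.where((gts[:, 0] < 0) | (gts[:, 1] < 0), MISSING, dos)
            rows.append(
                dict(rsid=rec.ID, chrom=str(rec.CHROM), pos=rec.POS,
                     ref=rec.REF, alt=rec.ALT[0])
            )
            cols.append(dos.astype(np.int8))
        if not rows:
            raise ValueError(f"no biallelic SNVs found in {path}")
        return cls(samples, pd.DataFrame(rows), np.column_stack(cols))

    def to_dosage_tsv(self, path) -> None:
        """PLINK-style text dosage: one variant per row, samples as columns."""
        df = self.variants.copy()
        mat = pd.DataFrame(self.dosages.T, columns=self.samples)
        pd.concat([df, mat], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dosage_tsv(cls, path) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta_cols = ["rsid", "chrom", "pos", "ref", "alt"]
        samples = [c for c in df.columns if c not in meta_cols]
        return cls(samples, df[meta_cols], df[samples].to_numpy(dtype=np.int8).T)


@dataclass
class ProxySet:
    """Variants in LD with an index SNP at or above a query threshold."""

    rsid: str
    proxies: list[tuple[str, float]]

    @property
    def proxy_rsids(self) -> list[str]:
        return [r for r, _ in self.proxies]


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = (x != MISSING) & (y != MISSING)
    return x[keep], y[keep]


def compute_r2(panel: ReferencePanel, a: str, b: str) -> float:
    """Squared Pearson correlation of the dosage vectors of ``a`` and ``b``.

    Raises
    ------
    LDUndefinedError
        If either variant is monomorphic over the pairwise-complete
        samples, or fewer than two complete samples remain.
    """
    x, y = _pairwise_complete(panel.dosage(a), panel.dosage(b))
    if len(x) < 2:
        raise LDUndefinedError(f"fewer than 2 complete samples for ({a}, {b})")
    sx = x.astype(float).std()
    sy = y.astype(float).std()
    if sx == 0.0 or sy == 0.0:
        raise LDUndefinedError(f"monomorphic variant in pair ({a}, {b})")
    r = np.corrcoef(x.astype(float), y.astype(float))[0, 1]
    return min(float(r * r), 1.0)


def _bulk_r2(panel: ReferencePanel, j: int, cand: np.ndarray) -> np.ndarray:
    """r² of variant column ``j`` against columns ``cand`` (NaN if undefined)."""
    D = panel.dosages
    if (D[:, j] == MISSING).any() or (D[:, cand] == MISSING).any():
        out = np.empty(len(cand))
        a = panel.variants["rsid"].iloc[j]
        for i, c in enumerate(cand):
            try:
                out[i] = compute_r2(panel, a, panel.variants["rsid"].iloc[c])
            except LDUndefinedError:
                out[i] = np.nan
        return out
    x = D[:, j].astype(float)
    Y = D[:, cand].astype(float)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((Yc * Yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / (sx * sy)
    r2 = np.minimum(r * r, 1.0)
    r2[(sx == 0) | (sy == 0)] = np.nan
    return r2


def find_proxies(
    panel: ReferencePanel,
    snps,
    r2_min: float = 1.0,
    window_bp: int = 500_000,
) -> tuple[dict[str, ProxySet], list[str]]:
    """Find all panel variants within ``window_bp`` of each query SNP with
    r² >= ``r2_min``.

    Returns a map rsid -> :class:`ProxySet` (the query SNP is always its
    own proxy with r² = 1) and the list of query SNPs absent from the
    panel, which are unresolvable rather than silently dropped.
    """
    if not 0.0 < r2_min <= 1.0:
        raise ValueError(f"r2_min must be in (0, 1], got {r2_min}")
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    out: dict[str, ProxySet] = {}
    unresolvable: list[str] = []
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    rsids = panel.variants["rsid"].to_numpy()
    for snp in snps:
        if snp not in panel:
            unresolvable.append(snp)
            continue
        j = panel.variant_index(snp)
        near = np.flatnonzero(
            (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window_bp) & (np.arange(len(pos)) != j)
        )
        proxies = [(snp, 1.0)]
        if len(near):
            r2 = _bulk_r2(panel, j, near)
            hit = np.flatnonzero(np.nan_to_num(r2, nan=-1.0) >= r2_min - R2_ATOL)
            proxies += [(rsids[k], float(min(r2[i], 1.0))) for i, k in zip(hit, near[hit])]
        proxies = [proxies[0]] + sorted(proxies[1:], key=lambda t: (-t[1], t[0]))
        out[snp] = ProxySet(snp, proxies)
    if unresolvable:
        logger.warning("%d query SNPs absent from panel: %s", len(unresolvable),
                       ", ".join(unresolvable[:10]))
    return out, unresolvable


@dataclass
class PruneResult:
    """Outcome of greedy LD clumping."""

    kept: list[str]
    unassessed: list[str]  # kept but absent from the panel (LD unknown)
    dropped: list[str]


def prune_independent(
    candidates,
    panel: ReferencePanel,
    r2_max: float = 0.2,
) -> PruneResult:
    """Greedy best-p-first selection of variants with pairwise r² < ``r2_max``.

    ``candidates`` is an iterable of ``(rsid, p_value)``.  Candidates are
    visited in ascending p (ties broken by chromosome, position, rsid); a
    candidate is kept iff its r² with every already-kept same-chromosome
    variant is below ``r2_max``.  Candidates absent from the panel are
    kept with a warning (their LD cannot be assessed).  Monomorphic pairs
    are treated as r² = 0.
    """
    if not 0.0 < r2_max < 1.0:
        raise ValueError(f"r2_max must be in (0, 1), got {r2_max}")

    def sort_key(item):
        rsid, p = item
        if rsid in panel:
            v = panel.variants.iloc[panel.variant_index(rsid)]
            return (p, str(v.chrom), int(v.pos), rsid)
        return (p, "", -1, rsid)

    kept: list[str] = []
    unassessed: list[str] = []
    dropped: list[str] = []
    kept_by_chrom: dict[str, list[str]] = {}
    for rsid, _p in sorted(candidates, key=sort_key):
        if rsid not in panel:
            logger.warning("candidate %s absent from panel; kept, LD unassessable", rsid)
            kept.append(rsid)
            unassessed.append(rsid)
            continue
        chrom = str(panel.variants["chrom"].iloc[panel.variant_index(rsid)])
        independent = True
        for other in kept_by_chrom.get(chrom, ()):
            try:
                r2 = compute_r2(panel, rsid, other)
            except LDUndefinedError:
                r2 = 0.0
            if r2 >= r2_max - R2_ATOL:
                independent = False
                break
        if independent:
            kept.append(rsid)
            kept_by_chrom.setdefault(chrom, []).append(rsid)
        else:
            dropped.append(rsid)
    return PruneResult(kept, unassessed, dropped)
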