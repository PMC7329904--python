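"""Replication of candidate SNPs in an individual-level cohort with
heel-ultrasound-derived bone mineral density.

The stage mirrors a biobank replication analysis:

1. per-sex outlier QC on speed of sound (SOS), broadband ultrasound
   attenuation (BUA) and the device-calculated BMD, with boundary values
   excluded (the printed bounds use "<=" and ">=");
2. optional re-derivation of BMD from the ultrasound measures,
   eBMD = 0.002592 * (BUA + SOS) - 3.687  (g·cm⁻²);
3. relatedness screening with the KING-robust kinship estimator and
   greedy reduction to an unrelated set at the degree-3 cutoff
   phi >= 2^(-9/2);
4. per-sex standardized residual Z-scores of BMD after adjustment for
   age, age² and weight, discarding |Z| > 4;
5. per-SNP linear regression of Z on allele dosage adjusted for the
   first 15 ancestry principal components, declaring replication at the
   genome-wide significance level p < 5e-8;
6. allele-harmonized direction-of-effect concordance with the discovery
   summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: degree-3 relatedness cutoff on the kinship coefficient
KINSHIP_CUTOFF = 2.0 ** (-9.0 / 2.0)
#: genome-wide significance level for replication
GWS_P = 5e-8
#: standardized-phenotype exclusion bound
Z_BOUND = 4.0
#: number of ancestry principal components adjusted for
N_PCS = 15

EBMD_SLOPE = 0.002592
EBMD_INTERCEPT = -3.687

#: KING kinship intervals by relationship degree: (label, lower, upper)
KING_DEGREE_INTERVALS = (
    ("duplicate", 2.0 ** -1.5, np.inf),
    ("first", 2.0 ** -2.5, 2.0 ** -1.5),
    ("second", 2.0 ** -3.5, 2.0 ** -2.5),
    ("third", 2.0 ** -4.5, 2.0 ** -3.5),
    ("unrelated", -np.inf, 2.0 ** -4.5),
)

PC_COLUMNS = [f"pc{i}" for i in range(1, N_PCS + 1)]
COVARIATE_COLUMNS = [
    "sample_id", "sex", "age", "weight", "sos", "bua", "bmd_device", "entry_mode",
] + PC_COLUMNS


class MonomorphicError(ValueError):
    """The dosage vector is constant; no association can be estimated."""


# --------------------------------------------------------------------- cohort


@dataclass
class BiobankCohort:
    """Participant covariates/ultrasound plus a sample x SNP dosage matrix."""

    covariates: pd.DataFrame
    dosages: np.ndarray
    variant_rsids: list[str]

    def __post_init__(self) -> None:
        self.covariates = self.covariates.reset_index(drop=True)
        missing = set(COVARIATE_COLUMNS) - set(self.covariates.columns)
        if missing:
            raise ValueError(f"cohort covariates lack columns: {sorted(missing)}")
        if self.dosages.shape != (len(self.covariates), len(self.variant_rsids)):
            raise ValueError("dosage matrix does not match covariates x variants")
        self._index = {r: j for j, r in enumerate(self.variant_rsids)}

    @property
    def n_samples(self) -> int:
        return len(self.covariates)

    def dosage(self, rsid: str) -> np.ndarray:
        return self.dosages[:, self._index[rsid]]

    def subset(self, mask) -> "BiobankCohort":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return BiobankCohort(self.covariates.iloc[idx], self.dosages[idx], self.variant_rsids)

    def to_tsv(self, covariates_path, dosages_path) -> None:
        self.covariates.to_csv(covariates_path, sep="\t", index=False)
        d = pd.DataFrame(self.dosages, columns=self.variant_rsids)
        d.insert(0, "sample_id", self.covariates["sample_id"].to_numpy())
        d.to_csv(dosages_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, covariates_path, dosages_path) -> "BiobankCohort":
        cov = pd.read_csv(covariates_path, sep="\t")
        dos = pd.read_csv(dosages_path, sep="\t")
        dos = dos.set_index("sample_id").loc[cov["sample_id"]]
        return cls(cov, dos.to_numpy(dtype=np.int16), list(dos.columns))


# ------------------------------------------------------------------ eBMD & QC


def derive_ebmd(sos, bua):
    """Estimated BMD (g·cm⁻²) from heel ultrasound:
    ``0.002592 * (bua + sos) - 3.687``.
    """
    sos = np.asarray(sos, dtype=float)
    bua = np.asarray(bua, dtype=float)
    if not (np.isfinite(sos).all() and np.isfinite(bua).all()):
        raise ValueError("sos and bua must be finite")
    out = EBMD_SLOPE * (bua + sos) + EBMD_INTERCEPT
    return float(out) if out.ndim == 0 else out


@dataclass
class QCThresholds:
    """Per-sex exclusion bounds; a value <= lower or >= upper is excluded."""

    sos: dict = field(default_factory=lambda: {"male": (1450.0, 1750.0), "female": (1455.0, 1700.0)})
    bua: dict = field(default_factory=lambda: {"male": (27.0, 138.0), "female": (22.0, 138.0)})
    bmd: dict = field(default_factory=lambda: {"male": (0.18, 1.06), "female": (0.12, 1.025)})

    def __post_init__(self) -> None:
        for measure in ("sos", "bua", "bmd"):
            for sex, (lo, hi) in getattr(self, measure).items():
                if not lo < hi:
                    raise ValueError(f"{measure}/{sex}: lower bound {lo} not below upper {hi}")

    def excluded(self, measure: str, sex: str, value: float) -> bool:
        try:
            lo, hi = getattr(self, measure)[sex]
        except KeyError:
            raise ValueError(f"unknown sex label {sex!r}") from None
        return value <= lo or value >= hi


def apply_qc(
    cohort: BiobankCohort,
    thresholds: QCThresholds | None = None,
    use_ebmd: bool = False,
) -> tuple[BiobankCohort, pd.DataFrame]:
    """Per-sex ultrasound outlier exclusion.

    A record is excluded iff any of SOS, BUA or BMD sits at or outside
    its sex-specific bounds.  With ``use_ebmd`` the BMD bound is applied
    to :func:`derive_ebmd`(sos, bua) instead of the device value
    (sensitivity analysis).  Returns the retained cohort and a per
    (sex, measure) exclusion-count report; a record violating several
    measures is counted under each but excluded once.
    """
    thresholds = thresholds or QCThresholds()
    cov = cohort.covariates
    unknown = set(cov["sex"].unique()) - {"male", "female"}
    if unknown:
        raise ValueError(f"unknown sex label(s): {sorted(unknown)}")
    bmd_vals = derive_ebmd(cov["sos"], cov["bua"]) if use_ebmd else cov["bmd_device"].to_numpy(float)
    values = {"sos": cov["sos"].to_numpy(float), "bua": cov["bua"].to_numpy(float), "bmd": bmd_vals}
    excluded = np.zeros(len(cov), dtype=bool)
    rows = []
    for sex in ("male", "female"):
        sex_mask = (cov["sex"] == sex).to_numpy()
        for measure in ("sos", "bua", "bmd"):
            lo, hi = getattr(thresholds, measure)[sex]
            bad = sex_mask & ((values[measure] <= lo) | (values[measure] >= hi))
            rows.append(dict(sex=sex, measure=measure, n_excluded=int(bad.sum())))
            excluded |= bad
    report = pd.DataFrame(rows)
    logger.info("QC excluded %d of %d records", int(excluded.sum()), len(cov))
    return cohort.subset(~excluded), report


# ------------------------------------------------------------------- kinship


def estimate_kinship(dosages_a, dosages_b, min_shared: int = 100) -> float:
    """KING-robust kinship coefficient between two samples.

    phi = (N_het,het - 2 * N_opposite_hom) / (N_het(a) + N_het(b)),
    counted over shared non-missing variants (missing coded as a
    negative dosage or NaN).  Returns NaN — unassessable, treated as
    unrelated by callers — when fewer than ``min_shared`` variants are
    shared.  Symmetric and invariant to flipping the counted allele at
    any subset of sites.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    shared = (a >= 0) & (b >= 0) & ~np.isnan(a) & ~np.isnan(b)
    if shared.sum() < min_shared:
        logger.warning("only %d shared variants (< %d); kinship unassessable",
                       int(shared.sum()), min_shared)
        return float("nan")
    a, b = a[shared], b[shared]
    het_a = a == 1
    het_b = b == 1
    n_hh = int((het_a & het_b).sum())
    n_opp = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    denom = int(het_a.sum() + het_b.sum())
    if denom == 0:
        return float("nan")
    return (n_hh - 2.0 * n_opp) / denom


def classify_degree(phi: float) -> str:
    """KING relationship class from the kinship coefficient."""
    if np.isnan(phi):
        return "unrelated"
    for label, lo, hi in KING_DEGREE_INTERVALS:
        if lo <= phi < hi if np.isfinite(hi) else phi >= lo:
            return label
    return "unrelated"


@dataclass
class KinshipPair:
    sample_a: str
    sample_b: str
    phi: float

    @property
    def degree(self) -> str:
        return classify_degree(self.phi)

    @property
    def related(self) -> bool:
        return not np.isnan(self.phi) and self.phi >= KINSHIP_CUTOFF


def kinship_scan(
    dosages: np.ndarray,
    sample_ids,
    cutoff: float = KINSHIP_CUTOFF,
    chunk: int = 4000,
) -> list[KinshipPair]:
    """All-pairs KING-robust scan; returns pairs with phi >= ``cutoff``.

    Runs on complete (no-missing) dosage matrices via blocked float32
    matrix products, so biobank-scale sample counts stay tractable;
    falls back to the per-pair estimator when missing calls are present.
    """
    n, m = dosages.shape
    sample_ids = list(sample_ids)
    if (dosages < 0).any():
        logger.info("missing dosages present; kinship scan falling back to per-pair loop")
        pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                phi = estimate_kinship(dosages[i], dosages[j])
                if not np.isnan(phi) and phi >= cutoff:
                    pairs.append(KinshipPair(sample_ids[i], sample_ids[j], phi))
        return pairs

    het = (dosages == 1).astype(np.float32)
    hom0 = (dosages == 0).astype(np.float32)
    hom2 = (dosages == 2).astype(np.float32)
    het_count = het.sum(axis=1)
    pairs: list[KinshipPair] = []
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        for j0 in range(i0, n, chunk):
            j1 = min(j0 + chunk, n)
            n_hh = het[i0:i1] @ het[j0:j1].T
            n_opp = hom0[i0:i1] @ hom2[j0:j1].T + hom2[i0:i1] @ hom0[j0:j1].T
            denom = het_count[i0:i1, None] + het_count[None, j0:j1]
            with np.errstate(invalid="ignore", divide="ignore"):
                phi = (n_hh - 2.0 * n_opp) / denom
            ii, jj = np.nonzero(np.nan_to_num(phi, nan=-1.0) >= cutoff)
            for a, b in zip(ii, jj):
                gi, gj = i0 + a, j0 + b
                if gi < gj:
                    pairs.append(KinshipPair(sample_ids[gi], sample_ids[gj], float(phi[a, b])))
    return pairs


def select_unrelated(sample_ids, pairs, threshold: float = KINSHIP_CUTOFF) -> list[str]:
    """Greedy reduction to a set with no pair at or above ``threshold``.

    While related pairs remain, removes the sample with the largest
    number of related partners (ties broken by removing the
    lexicographically larger sample ID).  Deterministic.
    """
    retained = set(sample_ids)
    edges = {
        frozenset((p.sample_a, p.sample_b))
        for p in pairs
        if not np.isnan(p.phi) and p.phi >= threshold
        and p.sample_a in retained and p.sample_b in retained
        and p.sample_a != p.sample_b
    }
    adj: dict[str, set[str]] = {}
    for e in edges:
        a, b = tuple(e)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    while adj:
        victim = max(adj, key=lambda s: (len(adj[s]), s))
        for nb in adj.pop(victim):
            adj[nb].discard(victim)
            if not adj[nb]:
                del adj[nb]
        retained.discard(victim)
    return [s for s in sample_ids if s in retained]


# ------------------------------------------------------------- phenotype & GWAS


def zscore_phenotype(
    covariates: pd.DataFrame,
    values=None,
    z_bound: float = Z_BOUND,
) -> tuple[pd.Series, list[str]]:
    """Per-sex standardized residual of BMD on age, age² and weight.

    Within each sex an ordinary least-squares fit of the BMD value on an
    intercept, age, age² and weight is residualized; the residual is
    divided by its standard deviation, giving a Z with mean 0 and SD 1
    per sex.  Samples with |Z| > ``z_bound`` are excluded.  Returns the
    retained Z (indexed by sample_id) and the excluded sample IDs.
    """
    y_all = covariates["bmd_device"].to_numpy(float) if values is None else np.asarray(values, float)
    z = pd.Series(index=covariates["sample_id"], dtype=float)
    for sex in ("male", "female"):
        mask = (covariates["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        sub = covariates.loc[mask]
        age = sub["age"].to_numpy(float)
        X = np.column_stack([np.ones(len(sub)), age, age ** 2, sub["weight"].to_numpy(float)])
        if len(sub) <= X.shape[1]:
            raise ValueError(f"too few {sex} samples ({len(sub)}) for the covariate fit")
        y = y_all[mask]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = resid.std(ddof=1)
        if sd == 0:
            raise ValueError(f"degenerate (zero-variance) residual in {sex} stratum")
        z.loc[sub["sample_id"].to_numpy()] = resid / sd
    z = z.dropna()
    keep = z.abs() <= z_bound
    excluded = list(z.index[~keep])
    if excluded:
        logger.info("excluded %d samples with |Z| > %g", len(excluded), z_bound)
    return z[keep], excluded


@dataclass
class AssociationResult:
    """Per-SNP replication regression outcome (Z-score units per allele)."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p_value: float
    n_used: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def replicated(self) -> bool:
        return self.p_value < GWS_P


def snp_association(
    z: np.ndarray,
    dosage: np.ndarray,
    pcs: np.ndarray,
    rsid: str = "",
    effect_allele: str = "",
    other_allele: str = "",
    missing: str = "impute",
) -> AssociationResult:
    """OLS of the Z-score on allele dosage plus ancestry PCs.

    Model: Z ~ intercept + dosage + PC1..PC15.  The dosage coefficient's
    two-sided p comes from the t distribution with n - p degrees of
    freedom.  Missing dosages (negative or NaN) are mean-imputed by
    default (``missing="drop"`` analyses complete cases instead).
    """
    z = np.asarray(z, dtype=float)
    g = np.asarray(dosage, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim != 2:
        raise ValueError("pcs must be a 2-D (samples x components) array")
    miss = np.isnan(g) | (g < 0)
    if miss.any():
        if missing == "impute":
            g = g.copy()
            g[miss] = g[~miss].mean()
        elif missing == "drop":
            z, g, pcs = z[~miss], g[~miss], pcs[~miss]
        else:
            raise ValueError(f"unknown missing-dosage policy {missing!r}")
    n = len(z)
    X = np.column_stack([np.ones(n), g, pcs])
    p = X.shape[1]
    if n < p + 2:
        raise ValueError(f"too few samples ({n}) for {p} regression parameters")
    if np.ptp(g) == 0:
        raise MonomorphicError(f"constant dosage for {rsid or 'SNP'}")
    beta_hat, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design matrix (collinear covariates)")
    resid = z - X @ beta_hat
    df = n - p
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(beta_hat[1])
    t_stat = beta / se
    p_val = float(2.0 * stats.t.sf(abs(t_stat), df))
    eaf = float(np.mean(g) / 2.0)
    return AssociationResult(rsid, effect_allele, other_allele, eaf, beta, se, p_val, n)


# ---------------------------------------------------------------- concordance

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


def direction_concordance(
    discovery: pd.DataFrame,
    replication: list[AssociationResult],
    ambiguous_maf: float = 0.4,
) -> tuple[pd.DataFrame, float]:
    """Direction-of-effect agreement between discovery and replication.

    Each replicated SNP's beta is harmonized to the discovery effect
    allele (sign flipped when effect/other alleles are swapped; an
    allele-mismatch entry is recorded when the allele sets disagree).
    Palindromic SNPs (A/T or C/G) with minor-allele frequency above
    ``ambiguous_maf`` are flagged strand-ambiguous.  Mismatched and
    ambiguous SNPs leave the concordance denominator.  Returns the
    per-SNP table and the overall concordant fraction.
    """
    disc = discovery.drop_duplicates("rsid").set_index("rsid")
    rows = []
    for res in replication:
        entry = dict(rsid=res.rsid, beta_replication=res.beta, status=None, concordant=None)
        if res.rsid not in disc.index:
            entry["status"] = "missing_from_discovery"
            rows.append(entry)
            continue
        d = disc.loc[res.rsid]
        d_ea, d_oa = str(d["ea"]).upper(), str(d["oa"]).upper()
        r_ea, r_oa = res.effect_allele.upper(), res.other_allele.upper()
        entry["beta_discovery"] = float(d["beta"])
        maf = min(float(d["eaf"]), 1.0 - float(d["eaf"]))
        if frozenset((d_ea, d_oa)) in _PALINDROMIC and maf > ambiguous_maf:
            entry["status"] = "ambiguous_palindromic"
            rows.append(entry)
            continue
        if (r_ea, r_oa) == (d_ea, d_oa):
            beta_rep = res.beta
        elif (r_ea, r_oa) == (d_oa, d_ea):
            beta_rep = -res.beta
        elif (_COMPLEMENT.get(r_ea), _COMPLEMENT.get(r_oa)) == (d_ea, d_oa):
            beta_rep = res.beta  # same strandedness after complementing
        elif (_COMPLEMENT.get(r_ea), _COMPLEMENT.get(r_oa)) == (d_oa, d_ea):
            beta_rep = -res.beta
        else:
            entry["status"] = "allele_mismatch"
            rows.append(entry)
            continue
        entry["beta_replication"] = beta_rep
        entry["status"] = "compared"
        entry["concordant"] = bool(np.sign(beta_rep) == np.sign(d["beta"]))
        rows.append(entry)
    columns = ["rsid", "beta_replication", "status", "concordant", "beta_discovery"]
    table = pd.DataFrame(rows, columns=columns)
    compared = table[table["status"] == "compared"]
    fraction = float(compared["concordant"].mean()) if len(compared) else float("nan")
    return table, fraction
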