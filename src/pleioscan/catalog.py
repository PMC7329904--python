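"""Curation of a GWAS-catalog-style association table.

The input is one row per reported SNP-trait association.  Curation
removes, in a fixed first-match order, associations that cannot seed a
bone-pleiotropy scan: entries below genome-wide significance
(p > 5e-8), gene-gene interaction and haplotype-based entries, rows
without an rsID, bone-related traits, SNPs already established for bone
mineral density, and trait labels excluded by declarative pleiotropy
rules (phenotype pairs that are pathophysiological counterparts, subsets,
derived measures, near-duplicates, or known causal factors of the bone
phenotype).  Surviving rsIDs are deduplicated keeping the first
occurrence in file order.

Every removal is attributed to exactly one rule, so the report partitions
the input: ``retained + sum(removed per rule) == n input rows``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

GWS_THRESHOLD = 5e-8

#: default case-insensitive keywords marking a bone-related trait
BONE_TRAIT_KEYWORDS = (
    "bone mineral density",
    "bmd",
    "osteoporosis",
    "fracture",
    "calcium",
    "bone",
    "heel ultrasound",
)

#: default trait keywords removed under the pleiotropy criteria: the
#: scanned phenotype must not be a counterpart, subset, derived measure
#: or known causal factor of the bone phenotype
PLEIOTROPY_RULE_KEYWORDS = (
    "vitamin d",
    "parathyroid",
    "phosphate levels",
    "lean body mass",
)

#: removal rules in attribution order
RULES = (
    "non_gws",
    "interaction",
    "haplotype",
    "missing_rsid",
    "bone_trait",
    "known_bmd_snp",
    "pleiotropy_rule",
    "duplicate",
)

# default column mapping: catalog export header -> canonical field
DEFAULT_DIALECT = {
    "rsid": "SNPS",
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    "trait": "DISEASE/TRAIT",
    "trait_category": "MAPPED_TRAIT",
    "p_value": "P-VALUE",
    "effect_allele": "EFFECT_ALLELE",
    "effect_size": "OR or BETA",
    "eaf": "RISK ALLELE FREQUENCY",
    "ancestry": "INITIAL SAMPLE SIZE",
    "study_id": "STUDY ACCESSION",
    "is_haplotype": "IS_HAPLOTYPE",
    "is_interaction": "IS_INTERACTION",
}

MANDATORY_FIELDS = ("rsid", "trait", "p_value")


@dataclass
class CurationConfig:
    """Thresholds, keyword lists and rule tables driving :func:`curate`."""

    gws_threshold: float = GWS_THRESHOLD
    bone_trait_keywords: tuple[str, ...] = BONE_TRAIT_KEYWORDS
    known_bmd_snps: frozenset = frozenset()
    pleiotropy_rules: tuple[str, ...] = PLEIOTROPY_RULE_KEYWORDS

    def __post_init__(self) -> None:
        if not 0.0 < self.gws_threshold < 1.0:
            raise ValueError(f"gws_threshold must be in (0,1), got {self.gws_threshold}")
        if not self.bone_trait_keywords:
            raise ValueError("bone_trait_keywords must be non-empty")
        self.known_bmd_snps = frozenset(self.known_bmd_snps)


@dataclass
class CurationReport:
    """Accounting of a curation run; partitions the input rows."""

    n_input: int
    removed: dict[str, int]
    retained: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "n_retained": self.n_retained,
            "retained": list(self.retained),
        }


def _parse_float(value) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        return math.nan
    return x


def read_catalog(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a catalog-style TSV into the canonical record schema.

    ``dialect`` maps canonical field names to the file's column headers
    (defaults follow GWAS Catalog exports).  Unparseable p-values or
    positions become NaN with a per-row warning; a missing mandatory
    column raises ``KeyError`` naming the canonical field.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fld in MANDATORY_FIELDS:
        if dialect[fld] not in raw.columns:
            raise KeyError(
                f"catalog file lacks mandatory column {dialect[fld]!r} (field {fld!r})"
            )
    out = pd.DataFrame(index=raw.index)
    for fld, col in dialect.items():
        out[fld] = raw[col] if col in raw.columns else ""
    for fld in ("p_value", "eaf", "effect_size"):
        parsed = out[fld].map(_parse_float)
        bad = parsed.isna() & (out[fld].str.strip() != "")
        for i in out.index[bad]:
            logger.warning("row %d: unparseable %s %r; treated as missing", i, fld, out.loc[i, fld])
        out[fld] = parsed
    out["pos"] = pd.to_numeric(out["pos"], errors="coerce")
    for fld in ("is_haplotype", "is_interaction"):
        out[fld] = out[fld].str.strip().str.lower().isin(("1", "true", "yes", "y"))
    out["rsid"] = out["rsid"].str.strip()
    return out


def _matches_any(text: str, keywords) -> bool:
    t = str(text).lower()
    return any(k.lower() in t for k in keywords)


def curate(records: pd.DataFrame, config: CurationConfig | None = None) -> tuple[list[str], CurationReport]:
    """Apply the exclusion rules in order and return the candidate rsID set.

    Rule order (first match wins): (1) p > genome-wide-significance
    threshold, (2) interaction entry, (3) haplotype entry, (4) missing
    rsID, (5) bone-related trait keyword, (6) known BMD SNP, (7)
    pleiotropy-rule keyword, (8) duplicate rsID (first occurrence kept).
    """
    config = config or CurationConfig()
    removed = {rule: 0 for rule in RULES}
    retained: list[str] = []
    seen: set[str] = set()
    for _, rec in records.iterrows():
        p = rec["p_value"]
        trait_text = f"{rec.get('trait', '')} {rec.get('trait_category', '')}"
        if not (p <= config.gws_threshold):  # NaN p also fails significance
            removed["non_gws"] += 1
        elif rec.get("is_interaction", False):
            removed["interaction"] += 1
        elif rec.get("is_haplotype", False):
            removed["haplotype"] += 1
        elif not str(rec["rsid"]).startswith("rs"):
            removed["missing_rsid"] += 1
        elif _matches_any(trait_text, config.bone_trait_keywords):
            removed["bone_trait"] += 1
        elif rec["rsid"] in config.known_bmd_snps:
            removed["known_bmd_snp"] += 1
        elif _matches_any(trait_text, config.pleiotropy_rules):
            removed["pleiotropy_rule"] += 1
        elif rec["rsid"] in seen:
            removed["duplicate"] += 1
        else:
            seen.add(rec["rsid"])
            retained.append(rec["rsid"])
    report = CurationReport(n_input=len(records), removed=removed, retained=retained)
    assert report.n_retained + sum(removed.values()) == len(records)
    return retained, report
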