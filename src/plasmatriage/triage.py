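"""Triage of plasma-only variants into pathogenicity/confirmation tiers.

Variants seen in ccfDNA but absent (or nearly absent) from the matched
germline are candidate tumor-derived signals even when the resected tumor
fragment does not carry them — diffuse gliomas are regionally heterogeneous
and plasma integrates DNA from the whole lesion. Each selected record is
assigned exactly one tier by the first matching rule:

1. CTDNA_CONFIRMED      — matched in the same patient's tumor somatic calls;
2. COHORT_CURRENT_CONFIRMED — same identity called somatic in another
   patient of the current cohort;
3. COHORT_PRIOR_CONFIRMED   — identity catalogued as somatic in a previously
   sequenced cohort;
4. PATHOGENIC_CCFDNA_ONLY   — clinically pathogenic-like annotation, or a
   COSMIC-registered variant that is rare in the population;
5. CARRIER_BENIGN       — benign annotation (a germline carrier allele seen
   through the plasma compartment);
6. DISCARDED            — nothing above applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .types import (AnnotationRecord, ClinSig, PATHOGENIC_LIKE, TrioRecord,
                    VariantId, format_af)

TIERS = ("CTDNA_CONFIRMED", "COHORT_CURRENT_CONFIRMED", "COHORT_PRIOR_CONFIRMED",
         "PATHOGENIC_CCFDNA_ONLY", "CARRIER_BENIGN", "DISCARDED")


@dataclass
class TriageConfig:
    # plasma evidence floor for the ccfDNA-only selection
    min_plasma_alt: int = 2
    # strict germline absence (alt = 0) vs relaxed tolerance for the
    # cohort-confirmed comparison, which admits a few stray germline reads
    gdna_strict: bool = True
    max_gdna_alt_relaxed: int = 3
    max_gdna_af_relaxed: float = 0.10
    rare_af_max: float = 0.001


@dataclass
class CatalogEntry:
    variant: VariantId
    source: str  # prior_study | current_study
    somatic_af: Optional[float] = None
    n_patients: int = 1
    patient_id: Optional[str] = None  # current-study evidence carrier


class CohortCatalog:
    """Variant identities with somatic evidence from prior/current cohorts."""

    def __init__(self, entries: Iterable[CatalogEntry] = ()):
        self._by_coord: dict[tuple, CatalogEntry] = {}
        self._by_site: dict[tuple, CatalogEntry] = {}
        self._by_rsid: dict[str, CatalogEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: CatalogEntry) -> None:
        ck = entry.variant.coord_key()
        if ck is not None:
            self._by_coord[ck] = entry
            self._by_site[entry.variant.site_key()] = entry
        if entry.variant.rsid:
            self._by_rsid[entry.variant.rsid] = entry

    def lookup(self, variant: VariantId, source: str) -> Optional[CatalogEntry]:
        for table, key in ((self._by_coord, variant.coord_key()),
                           (self._by_site, variant.site_key()),
                           (self._by_rsid, variant.rsid)):
            if key is not None:
                hit = table.get(key)
                if hit is not None and hit.source == source:
                    return hit
        return None


@dataclass
class TriageCall:
    record: TrioRecord
    annotation: Optional[AnnotationRecord]
    tier: str
    trail: list = field(default_factory=list)


def _gdna_absent(record: TrioRecord, cfg: TriageConfig, strict: bool) -> bool:
    g = record.gdna
    if g is None:
        return False
    if strict:
        return g.alt == 0
    return g.alt <= cfg.max_gdna_alt_relaxed and (g.depth == 0 or g.af < cfg.max_gdna_af_relaxed)


def select_ccfdna_only(records: Iterable[TrioRecord],
                       config: TriageConfig | None = None) -> list[TrioRecord]:
    """Retain records with plasma alt evidence and a (near-)clean germline."""
    cfg = config or TriageConfig()
    out = []
    for r in records:
        if r.ccfdna is None or r.ccfdna.alt < cfg.min_plasma_alt:
            continue
        if _gdna_absent(r, cfg, strict=cfg.gdna_strict):
            out.append(r)
    return out


def classify_tier(record: TrioRecord,
                  annotation: Optional[AnnotationRecord],
                  cohort_catalog: CohortCatalog | None = None,
                  current_somatic_keys: set | None = None,
                  config: TriageConfig | None = None) -> TriageCall:
    """Assign one tier to a ccfDNA-only record by the fixed rule order.

    ``current_somatic_keys`` holds (patient_id, coordinate-or-rsid key)
    pairs for the current cohort's tumor somatic calls; the same-patient
    match yields CTDNA_CONFIRMED, an other-patient match yields
    COHORT_CURRENT_CONFIRMED.
    """
    cfg = config or TriageConfig()
    catalog = cohort_catalog or CohortCatalog()
    current = current_somatic_keys or set()
    trail = []
    ann = annotation or AnnotationRecord(variant=record.variant)

    keys = [k for k in (record.variant.coord_key(), record.variant.site_key(),
                        record.variant.rsid) if k is not None]

    if any((record.patient_id, k) in current for k in keys):
        trail.append(("same_patient_tumor", "match", ""))
        return TriageCall(record, annotation, "CTDNA_CONFIRMED", trail)
    trail.append(("same_patient_tumor", "no_match", ""))

    other = {k for pid, k in current if pid != record.patient_id}
    hit = catalog.lookup(record.variant, "current_study")
    if hit is not None or any(k in other for k in keys):
        trail.append(("current_cohort", "match", ""))
        return TriageCall(record, annotation, "COHORT_CURRENT_CONFIRMED", trail)
    trail.append(("current_cohort", "no_match", ""))

    if catalog.lookup(record.variant, "prior_study") is not None:
        trail.append(("prior_cohort", "match", ""))
        return TriageCall(record, annotation, "COHORT_PRIOR_CONFIRMED", trail)
    trail.append(("prior_cohort", "no_match", ""))

    pop_af = ann.max_population_af()
    rare = pop_af is None or pop_af <= cfg.rare_af_max
    if ann.clinsig in PATHOGENIC_LIKE or (ann.cosmic_registered and rare):
        trail.append(("pathogenicity", "match",
                      f"clinsig={ann.clinsig.value}, cosmic={ann.cosmic_registered}"))
        return TriageCall(record, annotation, "PATHOGENIC_CCFDNA_ONLY", trail)
    trail.append(("pathogenicity", "no_match", ""))

    if ann.clinsig is ClinSig.BENIGN:
        trail.append(("benign_carrier", "match", ""))
        return TriageCall(record, annotation, "CARRIER_BENIGN", trail)
    trail.append(("benign_carrier", "no_match", ""))
    return TriageCall(record, annotation, "DISCARDED", trail)


def triage_records(records: Iterable[TrioRecord], annotations: dict,
                   cohort_catalog: CohortCatalog | None = None,
                   current_somatic_keys: set | None = None,
                   config: TriageConfig | None = None) -> list[TriageCall]:
    """Select ccfDNA-only records and tier-classify each of them.

    ``annotations`` maps coordinate keys / site keys / rsIDs to
    :class:`AnnotationRecord`.
    """
    from .somatic import lookup_annotation

    cfg = config or TriageConfig()
    selected = select_ccfdna_only(records, cfg)
    return [classify_tier(r, lookup_annotation(annotations, r.variant),
                          cohort_catalog, current_somatic_keys, cfg)
            for r in selected]


def count_patients_tiered(calls: Iterable[TriageCall], tiers: Iterable[str]) -> int:
    """Distinct patients having >= 1 call in the requested tier set."""
    wanted = set(tiers)
    unknown = wanted - set(TIERS)
    if unknown:
        raise ValueError(f"unknown tiers: {sorted(unknown)}")
    return len({c.record.patient_id for c in calls if c.tier in wanted})


def emit_triage_tables(calls: Iterable[TriageCall]) -> dict[str, pd.DataFrame]:
    """One table per tier (report layout) plus a gene x patient summary."""
    calls = list(calls)
    per_tier = {}
    for tier in TIERS:
        rows = []
        for c in calls:
            if c.tier != tier:
                continue
            r = c.record
            ann = c.annotation
            rows.append({
                "gene": r.gene, "chrom": r.variant.chrom, "pos": r.variant.pos,
                "patient_id": r.patient_id, "rsid": r.variant.rsid,
                "clinsig": ann.clinsig.value if ann else "none",
                "diagnosis": r.diagnosis,
                "gdna_all": r.gdna.depth if r.gdna else None,
                "gdna_alt": r.gdna.alt if r.gdna else None,
                "ccfdna_all": r.ccfdna.depth, "ccfdna_alt": r.ccfdna.alt,
                "ccfdna_af": format_af(r.ccfdna.alt, r.ccfdna.depth, 4),
            })
        per_tier[tier] = pd.DataFrame(rows, columns=[
            "gene", "chrom", "pos", "patient_id", "rsid", "clinsig", "diagnosis",
            "gdna_all", "gdna_alt", "ccfdna_all", "ccfdna_alt", "ccfdna_af"])

    summary_rows = [{"gene": c.record.gene, "patient_id": c.record.patient_id,
                     "tier": c.tier,
                     "alteration": _alteration_class(c.record.variant)}
                    for c in calls if c.tier != "DISCARDED"]
    per_tier["summary"] = pd.DataFrame(
        summary_rows, columns=["gene", "patient_id", "tier", "alteration"])
    return per_tier


def _alteration_class(v: VariantId) -> str:
    if v.ref is None or v.alt is None:
        return "SNP"
    if len(v.ref) == len(v.alt) == 1:
        return "SNP"
    return "ins" if len(v.alt) > len(v.ref) else "del"
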