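"""Packaged report-table fixtures.

Raw patient sequencing data for this analysis is controlled-access, so the
published report tables are the public reference surface. This package
ships faithful TSV transcriptions of those tables (blank continuation cells
forward-filled) plus a small synthetic annotation-filler catalog, and
parses them into the pipeline's domain types. Files are checksummed at load
time so silent edits are caught.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from ..triage import CatalogEntry, CohortCatalog
from ..types import AnnotationRecord, SiteCounts, TrioRecord, VariantId, parse_clinsig

CHECKSUMS = {
    "table1_concordance.tsv": "da6aaa426ef2b31323aa87f6086dae365461b3ed7cb11a0e24db61649809304e",
    "table2_ccfdna_only.tsv": "04b8753d7a7495009c621c6e1dd833ec78becdcc5174185e6a6ed8530c214ac6",
    "table3_prior_cohort.tsv": "f0388e519b870bb644d6294e84f8454e0f99ff5c1e2aa4d62ddde6595709de00",
    "table4_current_cohort.tsv": "30c4775d5f21a52b21bfcc65ac75089b9d9010a45edc191a29c2756e426388a1",
    "annotation_fillers.tsv": "b26ce8e7cf8b3ede2b33a293a7bd27eb9fcb1b9c81bbfc0e0b7e81d4a7fe9a3d",
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files(__package__) / "data" / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != CHECKSUMS[name]:
        raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype=str)


def _num(value):
    if value is None or pd.isna(value) or str(value).strip() in ("-", ""):
        return None
    return float(value)


def _flag(value) -> bool:
    return str(value).strip().lower() in ("yes", "true", "1")


def load_table(n: int) -> pd.DataFrame:
    names = {1: "table1_concordance.tsv", 2: "table2_ccfdna_only.tsv",
             3: "table3_prior_cohort.tsv", 4: "table4_current_cohort.tsv"}
    return _read(names[n])


def concordance_records() -> list[TrioRecord]:
    """Tumor-somatic variants with matched trio counts (17 rows, 8 patients)."""
    out = []
    for r in load_table(1).itertuples(index=False):
        out.append(TrioRecord(
            patient_id=r.patient_id, diagnosis=r.diagnosis, gene=r.gene,
            variant=VariantId(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt),
            gdna=SiteCounts(int(r.gdna_all), int(r.gdna_alt)),
            tdna=SiteCounts(int(r.tumor_all), int(r.tumor_alt)),
            ccfdna=SiteCounts(int(r.ccfdna_all), int(r.ccfdna_alt)),
        ))
    return out


def _table2_variant(r) -> VariantId:
    return VariantId(chrom=r.chrom, pos=int(r.pos), rsid=r.rsid)


def ccfdna_only_records() -> list[TrioRecord]:
    """Plasma-only candidate variants with annotations (36 rows, 25 patients)."""
    out = []
    for r in load_table(2).itertuples(index=False):
        out.append(TrioRecord(
            patient_id=r.patient_id, diagnosis=r.diagnosis, gene=r.gene,
            variant=_table2_variant(r),
            gdna=SiteCounts(int(r.gdna_all), int(r.gdna_alt)),
            ccfdna=SiteCounts(int(r.ccfdna_all), int(r.ccfdna_alt)),
        ))
    return out


def ccfdna_only_annotations() -> dict:
    """Annotation records for the plasma-only table, keyed by site and rsID.

    Every variant in this table is COSMIC-registered (that is the table's
    selection rule), so ``cosmic_registered`` is True throughout.
    """
    catalog: dict = {}
    for r in load_table(2).itertuples(index=False):
        v = _table2_variant(r)
        ann = AnnotationRecord(
            variant=v, maf=_num(r.maf), af_1000g=_num(r.af_1000g),
            af_gnomad=_num(r.af_gnomad), clinsig=parse_clinsig(r.clinsig),
            cosmic_registered=True)
        catalog[v.site_key()] = ann
        catalog[v.rsid] = ann
    return catalog


def prior_cohort_records() -> list[TrioRecord]:
    """Plasma variants confirmed somatic in a previously sequenced cohort."""
    out = []
    for r in load_table(3).itertuples(index=False):
        out.append(TrioRecord(
            patient_id=r.patient_id, diagnosis=r.diagnosis, gene=r.gene,
            variant=VariantId(rsid=r.rsid),
            gdna=SiteCounts(int(r.gdna_all), int(r.gdna_alt)),
            ccfdna=SiteCounts(int(r.ccfdna_all), int(r.ccfdna_alt)),
        ))
    return out


def current_cohort_records() -> list[TrioRecord]:
    """Plasma variants confirmed somatic in the current cohort's tumors."""
    out = []
    for r in load_table(4).itertuples(index=False):
        rsid = None if str(r.rsid).strip() in ("-", "") else r.rsid
        out.append(TrioRecord(
            patient_id=r.patient_id, diagnosis=r.diagnosis, gene=r.gene,
            variant=VariantId(chrom=r.chrom, pos=int(r.pos), ref=r.ref,
                              alt=r.alt, rsid=rsid),
            gdna=SiteCounts(int(r.gdna_all), int(r.gdna_alt)),
            ccfdna=SiteCounts(int(r.ccfdna_all), int(r.ccfdna_alt)),
        ))
    return out


def cohort_catalog() -> CohortCatalog:
    """Prior- and current-cohort somatic evidence keyed by variant identity."""
    catalog = CohortCatalog()
    seen = set()
    for r in load_table(3).itertuples(index=False):
        if r.rsid in seen:
            continue
        seen.add(r.rsid)
        catalog.add(CatalogEntry(variant=VariantId(rsid=r.rsid), source="prior_study",
                                 somatic_af=_num(r.somatic_af_other)))
    for r in load_table(4).itertuples(index=False):
        rsid = None if str(r.rsid).strip() in ("-", "") else r.rsid
        catalog.add(CatalogEntry(
            variant=VariantId(chrom=r.chrom, pos=int(r.pos), ref=r.ref,
                              alt=r.alt, rsid=rsid),
            source="current_study", n_patients=int(r.n_patients_somatic),
            patient_id=r.patient_id))
    return catalog


def triage_annotations() -> dict:
    """Annotations for the prior/current confirmation tables, keyed by rsID/site."""
    catalog: dict = {}
    for r in load_table(3).itertuples(index=False):
        ann = AnnotationRecord(
            variant=VariantId(rsid=r.rsid), maf=_num(r.gmaf),
            clinsig=parse_clinsig(r.clinsig),
            cosmic_registered=_num(r.cosmic_cns_count) is not None,
            cosmic_cns_count=int(_num(r.cosmic_cns_count) or 0))
        catalog[r.rsid] = ann
    for r in load_table(4).itertuples(index=False):
        v = VariantId(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt)
        ann = AnnotationRecord(
            variant=v, clinsig=parse_clinsig(r.clinsig),
            cosmic_registered=_flag(r.cosmic_registered))
        catalog[v.coord_key()] = ann
        catalog[v.site_key()] = ann
    return catalog


def annotation_catalog() -> dict:
    """Full annotation catalog: all table variants plus synthetic fillers.

    The fillers sit on the simulator's synthetic contigs and exercise the
    population-AF / coding / SIFT filters; their identifiers are synthetic.
    """
    catalog = ccfdna_only_annotations()
    catalog.update(triage_annotations())
    for r in _read("annotation_fillers.tsv").itertuples(index=False):
        v = VariantId(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt, rsid=r.rsid)
        ann = AnnotationRecord(
            variant=v, maf=_num(r.maf), af_1000g=_num(r.af_1000g),
            af_gnomad=_num(r.af_gnomad), clinsig=parse_clinsig(r.clinsig),
            cosmic_registered=_flag(r.cosmic_registered),
            cosmic_cns_count=int(_num(r.cosmic_cns_count) or 0),
            sift=_num(r.sift), coding=_flag(r.coding))
        catalog[v.coord_key()] = ann
        catalog[v.site_key()] = ann
        catalog[v.rsid] = ann
    return catalog
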