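"""ctDNA detection: UMI consensus collapsing and plasma concordance calls.

A tumor-somatic variant counts as detected in plasma when enough distinct
consensus molecules (UMI families) support the alt allele in the ccfDNA
compartment. There is deliberately no minimum plasma allele-fraction floor:
true ctDNA signals routinely sit below 1% AF at deep consensus coverage.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .types import SiteCounts, TrioRecord, UMIFamily, classify_diagnosis, format_af


@dataclass
class DetectionConfig:
    min_plasma_alt: int = 3      # consensus molecules supporting alt
    max_gdna_af: float = 0.01    # plasma evidence only counts on a clean germline


@dataclass
class ConcordanceCall:
    record: TrioRecord
    detected: bool
    ccfdna_af: float
    evidence: int  # alt consensus reads
    trail: list = field(default_factory=list)


def collapse_umi(families: Iterable[UMIFamily]) -> SiteCounts:
    """Collapse UMI families at one site to consensus counts.

    Depth is the number of families with an unambiguous majority allele;
    alt is the number whose consensus is the alt allele. Tied families are
    excluded entirely.
    """
    depth = 0
    alt = 0
    for fam in families:
        consensus = fam.consensus
        if consensus is None:
            continue
        depth += 1
        if consensus == "alt":
            alt += 1
    return SiteCounts(depth=depth, alt=alt)


def collapse_umi_by_site(families: Iterable[UMIFamily]) -> dict[tuple, SiteCounts]:
    grouped: dict[tuple, list] = defaultdict(list)
    for fam in families:
        grouped[fam.site_key].append(fam)
    return {k: collapse_umi(v) for k, v in grouped.items()}


def detect_ctdna(record: TrioRecord, config: DetectionConfig | None = None) -> ConcordanceCall:
    """Test one tumor-somatic variant for presence in the plasma compartment."""
    cfg = config or DetectionConfig()
    trail = []
    cc = record.ccfdna
    if cc is None or cc.depth == 0:
        trail.append(("plasma_coverage", "fail", "no_coverage"))
        return ConcordanceCall(record, False, float("nan"), 0, trail)
    trail.append(("plasma_coverage", "pass", f"depth {cc.depth}"))
    if (record.gdna is not None and record.gdna.depth > 0
            and record.gdna.af >= cfg.max_gdna_af):
        trail.append(("gdna_clean", "fail", f"gdna af {record.gdna.af:.4f}"))
        return ConcordanceCall(record, False, cc.af, cc.alt, trail)
    trail.append(("gdna_clean", "pass", ""))
    detected = cc.alt >= cfg.min_plasma_alt
    trail.append(("min_plasma_alt", "pass" if detected else "fail", f"alt {cc.alt}"))
    return ConcordanceCall(record, detected, cc.af, cc.alt, trail)


def detect_cohort(records: Iterable[TrioRecord],
                  config: DetectionConfig | None = None) -> list[ConcordanceCall]:
    return [detect_ctdna(r, config) for r in records]


def emit_concordance_report(calls: Iterable[ConcordanceCall]) -> pd.DataFrame:
    """One row per detected variant with all three compartments' counts and AFs.

    AFs are formatted at report precision: 2 decimals for gDNA/tumor, 3 for
    the deep plasma compartment.
    """
    rows = []
    for call in calls:
        if not call.detected:
            continue
        r = call.record
        rows.append({
            "gene": r.gene, "chrom": r.variant.chrom, "pos": r.variant.pos,
            "patient_id": r.patient_id, "ref": r.variant.ref, "alt": r.variant.alt,
            "diagnosis": r.diagnosis,
            "gdna_all": r.gdna.depth if r.gdna else None,
            "gdna_alt": r.gdna.alt if r.gdna else None,
            "gdna_af": format_af(r.gdna.alt, r.gdna.depth, 2) if r.gdna else "NA",
            "tumor_all": r.tdna.depth if r.tdna else None,
            "tumor_alt": r.tdna.alt if r.tdna else None,
            "tumor_af": format_af(r.tdna.alt, r.tdna.depth, 2) if r.tdna else "NA",
            "ccfdna_all": r.ccfdna.depth, "ccfdna_alt": r.ccfdna.alt,
            "ccfdna_af": format_af(r.ccfdna.alt, r.ccfdna.depth, 3),
        })
    cols = ["gene", "chrom", "pos", "patient_id", "ref", "alt", "diagnosis",
            "gdna_all", "gdna_alt", "gdna_af", "tumor_all", "tumor_alt", "tumor_af",
            "ccfdna_all", "ccfdna_alt", "ccfdna_af"]
    return pd.DataFrame(rows, columns=cols)


def count_detected_patients(calls: Iterable[ConcordanceCall],
                            diagnosis_class: Optional[str] = None) -> int:
    """Distinct patients with >= 1 detected call, optionally by diagnosis class."""
    patients = set()
    for call in calls:
        if not call.detected:
            continue
        if (diagnosis_class is not None
                and classify_diagnosis(call.record.diagnosis) != diagnosis_class):
            continue
        patients.add(call.record.patient_id)
    return len(patients)
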