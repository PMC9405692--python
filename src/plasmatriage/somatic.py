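"""Tumor/germline somatic variant calling from per-site counts.

Classification follows the paired-sample convention popularized by VarScan2:
each site's tumor and germline allele counts form a 2x2 table tested with
Fisher's exact test, and the status (somatic / germline / LOH / unknown)
falls out of the test together with the two allele fractions. High-confidence
somatic calls must then survive a cascade of literal retention filters
(coverage, alt-read support, allele-fraction bounds, strand balance) and
annotation-based filters (common population variants, non-coding, predicted
benign). Every rule outcome is recorded on the call's trail, so
retained + discarded = input at every stage and each discarded call can
explain itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .stats import fisher_exact_counts
from .types import (AnnotationRecord, SiteCounts, TrioRecord, VariantId,
                    allele_frequency)


@dataclass
class FilterConfig:
    """Thresholds of the somatic retention cascade.

    Boundary semantics are literal: "at least" is >=, "less than" is <.
    """

    min_coverage: int = 10
    min_alt_tumor: int = 3
    min_tumor_af: float = 0.01
    max_gdna_af: float = 0.01
    somatic_p: float = 0.05
    strand_bias_p: float = 0.05
    strand_bias_min_skew: float = 0.9
    sift_damaging_max: float = 0.05
    sift_inverted: bool = False  # select SIFT > threshold as damaging instead
    population_af_max: float = 0.001
    loh_band: tuple = (0.25, 0.75)

    def validate(self) -> None:
        if not (0 <= self.min_tumor_af <= 1 and 0 <= self.max_gdna_af <= 1):
            raise ValueError("allele-fraction thresholds must lie in [0, 1]")
        if self.min_coverage < 0 or self.min_alt_tumor < 0:
            raise ValueError("count thresholds must be nonnegative")


@dataclass
class SomaticCall:
    """A classified tumor/germline site plus its filter trail."""

    variant: VariantId
    gene: str
    patient_id: str
    tumor: SiteCounts
    germline: SiteCounts
    status: str  # somatic | germline | LOH | unknown
    fisher_p: float
    tumor_af: float
    gdna_af: float
    retained: bool = True
    filter_trail: list = field(default_factory=list)
    diagnosis: str = ""

    def fail(self, rule: str, detail: str = "") -> "SomaticCall":
        self.filter_trail.append((rule, "fail", detail))
        self.retained = False
        return self

    def ok(self, rule: str, detail: str = "") -> "SomaticCall":
        self.filter_trail.append((rule, "pass", detail))
        return self


def fisher_exact_2x2(tumor: SiteCounts, germline: SiteCounts) -> float:
    """Two-sided Fisher exact p for the alt/ref x tumor/germline table."""
    return fisher_exact_counts(tumor.alt, tumor.ref, germline.alt, germline.ref)


def strand_bias_p(counts: SiteCounts) -> float:
    """Fisher exact p for the allele x strand table (same exact core)."""
    if not counts.has_strand:
        return 1.0
    return fisher_exact_counts(counts.alt_fwd, counts.alt_rev,
                               counts.ref_fwd, counts.ref_rev)


def classify_site(tumor: SiteCounts, germline: SiteCounts,
                  config: FilterConfig | None = None,
                  variant: VariantId | None = None, gene: str = "",
                  patient_id: str = "", diagnosis: str = "") -> SomaticCall:
    """Assign somatic / germline / LOH / unknown status to one site.

    somatic: significant tumor-vs-germline difference with the alt allele
    effectively absent from germline and present in tumor. germline: both
    compartments in the heterozygous band with no significant difference.
    LOH: germline heterozygous but tumor allele fraction departed toward 0
    or 1 with a significant test.
    """
    cfg = config or FilterConfig()
    p = fisher_exact_2x2(tumor, germline)
    t_af = allele_frequency(tumor)
    g_af = allele_frequency(germline)
    lo, hi = cfg.loh_band
    if (not np.isnan(g_af) and not np.isnan(t_af)
            and g_af < cfg.max_gdna_af and t_af >= cfg.min_tumor_af
            and p <= cfg.somatic_p):
        status = "somatic"
    elif not np.isnan(g_af) and lo <= g_af <= hi:
        if p <= cfg.somatic_p and not np.isnan(t_af) and (t_af < lo or t_af > hi):
            status = "LOH"
        elif not np.isnan(t_af) and t_af >= lo:
            status = "germline"
        else:
            status = "unknown"
    else:
        status = "unknown"
    call = SomaticCall(variant=variant or VariantId(), gene=gene,
                       patient_id=patient_id, diagnosis=diagnosis,
                       tumor=tumor, germline=germline, status=status,
                       fisher_p=p, tumor_af=t_af, gdna_af=g_af)
    call.ok("classify", status)
    return call


def apply_retention_filters(call: SomaticCall, config: FilterConfig | None = None) -> SomaticCall:
    """Apply the literal coverage / support / AF / strand-balance filters."""
    cfg = config or FilterConfig()
    t, g = call.tumor, call.germline
    if t.depth < cfg.min_coverage or g.depth < cfg.min_coverage:
        return call.fail("min_coverage", f"tumor {t.depth}, gdna {g.depth}")
    call.ok("min_coverage")
    if t.alt < cfg.min_alt_tumor:
        return call.fail("min_alt_tumor", f"alt {t.alt}")
    call.ok("min_alt_tumor")
    if not call.tumor_af >= cfg.min_tumor_af:
        return call.fail("min_tumor_af", f"af {call.tumor_af:.4f}")
    call.ok("min_tumor_af")
    if not call.gdna_af < cfg.max_gdna_af:
        return call.fail("max_gdna_af", f"af {call.gdna_af:.4f}")
    call.ok("max_gdna_af")
    if t.has_strand and t.alt > 0:
        sp = strand_bias_p(t)
        skew = max(t.alt_fwd, t.alt_rev) / t.alt
        if sp < cfg.strand_bias_p and skew >= cfg.strand_bias_min_skew:
            return call.fail("strand_bias", f"p {sp:.3g}, skew {skew:.2f}")
    call.ok("strand_bias")
    return call


def filter_population_and_effect(call: SomaticCall,
                                 annotation: Optional[AnnotationRecord],
                                 config: FilterConfig | None = None) -> SomaticCall:
    """Drop catalogued common variants, non-coding sites, and predicted-benign ones.

    A variant absent from the catalog is retained: absence of evidence of
    commonness is not evidence of commonness.
    """
    cfg = config or FilterConfig()
    if annotation is None:
        call.ok("population_af", "not in catalog")
        call.ok("coding")
        call.ok("sift")
        return call
    pop_af = annotation.max_population_af()
    if pop_af is not None and pop_af > cfg.population_af_max:
        return call.fail("population_af", f"af {pop_af:g}")
    call.ok("population_af")
    if not annotation.coding:
        return call.fail("coding", "non-coding")
    call.ok("coding")
    if annotation.sift is not None:
        damaging = (annotation.sift > cfg.sift_damaging_max if cfg.sift_inverted
                    else annotation.sift < cfg.sift_damaging_max)
        if not damaging:
            return call.fail("sift", f"score {annotation.sift:g}")
    call.ok("sift")
    return call


def call_somatic(records: Iterable[TrioRecord],
                 catalog: dict | None = None,
                 config: FilterConfig | None = None) -> list[SomaticCall]:
    """Full cascade over trio records: classify, retain, annotate-filter.

    ``catalog`` maps variant coordinate keys (and rsIDs) to
    :class:`AnnotationRecord`. Returns every call (retained and discarded);
    select with ``[c for c in calls if c.retained and c.status == 'somatic']``.
    """
    cfg = config or FilterConfig()
    cfg.validate()
    catalog = catalog or {}
    calls = []
    for rec in records:
        if rec.tdna is None or rec.gdna is None:
            continue
        call = classify_site(rec.tdna, rec.gdna, cfg, variant=rec.variant,
                             gene=rec.gene, patient_id=rec.patient_id,
                             diagnosis=rec.diagnosis)
        if call.status != "somatic":
            call.fail("status", call.status)
            calls.append(call)
            continue
        call = apply_retention_filters(call, cfg)
        if call.retained:
            ann = lookup_annotation(catalog, rec.variant)
            call = filter_population_and_effect(call, ann, cfg)
        calls.append(call)
    return calls


def lookup_annotation(catalog: dict, variant: VariantId) -> Optional[AnnotationRecord]:
    for key in (variant.coord_key(), variant.site_key(), variant.rsid):
        if key is not None and key in catalog:
            return catalog[key]
    return None


def somatic_set(calls: Iterable[SomaticCall]) -> list[SomaticCall]:
    return [c for c in calls if c.retained and c.status == "somatic"]


def summarize_gene_frequencies(calls: Iterable[SomaticCall]) -> pd.DataFrame:
    """Distinct-patient mutation counts per gene, most-mutated first."""
    rows = [(c.gene, c.patient_id) for c in somatic_set(calls)]
    if not rows:
        return pd.DataFrame(columns=["gene", "n_patients", "rank"])
    df = pd.DataFrame(rows, columns=["gene", "patient_id"]).drop_duplicates()
    out = (df.groupby("gene").size().rename("n_patients").reset_index()
           .sort_values(["n_patients", "gene"], ascending=[False, True])
           .reset_index(drop=True))
    out["rank"] = out["n_patients"].rank(method="min", ascending=False).astype(int)
    return out


def vaf_by_gene(calls: Iterable[SomaticCall]) -> dict[str, np.ndarray]:
    """Per-gene arrays of tumor variant allele fractions among somatic calls."""
    out: dict[str, list] = {}
    for c in somatic_set(calls):
        out.setdefault(c.gene, []).append(c.tumor_af)
    return {g: np.sort(np.array(v)) for g, v in out.items()}
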