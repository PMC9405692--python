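"""Somatic classification and the literal retention-filter cascade."""

import numpy as np
import pytest

from plasmatriage.somatic import (FilterConfig, apply_retention_filters,
                                  call_somatic, classify_site,
                                  filter_population_and_effect, somatic_set,
                                  summarize_gene_frequencies, vaf_by_gene)
from plasmatriage.synthetic import CohortSpec, simulate_trio
from plasmatriage.types import (AnnotationRecord, ClinSig, SiteCounts,
                                TrioRecord, VariantId, allele_frequency)


def sc(depth, alt, **kw):
    return SiteCounts(depth=depth, alt=alt, **kw)


# --- allele frequency -----------------------------------------------------

@pytest.mark.parametrize("alt,depth,expected,places", [
    (144, 149, 0.97, 2),       # near-clonal tumor variant
    (0, 106, 0.0, 2),          # clean germline
    (454, 1979, 0.229409, 6),  # deep plasma consensus
    (23, 55, 0.42, 2),
])
def test_allele_frequency_printed_precision(alt, depth, expected, places):
    assert round(allele_frequency(sc(depth, alt)), places) == expected


def test_zero_depth_af_is_missing():
    assert np.isnan(allele_frequency(sc(0, 0)))


# --- classification -------------------------------------------------------

def test_clear_somatic_call():
    call = classify_site(sc(128, 76), sc(324, 0))
    assert call.status == "somatic"
    assert call.fisher_p < 1e-10


def test_balanced_heterozygous_is_germline():
    call = classify_site(sc(1000, 500), sc(1000, 498))
    assert call.status == "germline"


def test_loh_detected_when_tumor_leaves_het_band():
    call = classify_site(sc(1000, 950), sc(1000, 500))
    assert call.status == "LOH"


def test_ambiguous_low_depth_is_unknown():
    call = classify_site(sc(10, 1), sc(10, 1))
    assert call.status == "unknown"


# --- retention filters ----------------------------------------------------

def make_call(tumor, germline, **kw):
    call = classify_site(tumor, germline, **kw)
    return call


def test_coverage_boundary_literal():
    cfg = FilterConfig()
    fail = apply_retention_filters(make_call(sc(9, 6), sc(100, 0)), cfg)
    assert not fail.retained
    assert any(rule == "min_coverage" and out == "fail"
               for rule, out, _ in fail.filter_trail)
    keep = apply_retention_filters(make_call(sc(10, 6), sc(100, 0)), cfg)
    assert keep.retained


def test_min_alt_and_af_boundaries_inclusive():
    # exactly 3 alt reads at exactly 1% AF passes ("at least" semantics)
    call = apply_retention_filters(make_call(sc(300, 3), sc(300, 0)))
    assert call.retained
    call = apply_retention_filters(make_call(sc(300, 2), sc(300, 0)))
    assert not call.retained


def test_gdna_af_boundary_exclusive():
    # gDNA AF exactly 1% fails "less than 1%"
    call = apply_retention_filters(make_call(sc(200, 60), sc(100, 1)))
    assert not call.retained
    assert any(rule == "max_gdna_af" and out == "fail"
               for rule, out, _ in call.filter_trail)


def test_strand_bias_discards_one_sided_alt():
    tumor = sc(90, 20, alt_fwd=20, alt_rev=0, ref_fwd=35, ref_rev=35)
    call = apply_retention_filters(make_call(tumor, sc(100, 0)))
    assert not call.retained
    assert any(rule == "strand_bias" for rule, out, _ in call.filter_trail if out == "fail")


def test_balanced_strands_retained():
    tumor = sc(90, 20, alt_fwd=10, alt_rev=10, ref_fwd=35, ref_rev=35)
    call = apply_retention_filters(make_call(tumor, sc(100, 0)))
    assert call.retained


# --- annotation filters ---------------------------------------------------

def ann(**kw):
    return AnnotationRecord(variant=VariantId(chrom="ctg1", pos=1), **kw)


def test_common_population_variant_excluded():
    call = filter_population_and_effect(make_call(sc(100, 40), sc(100, 0)),
                                        ann(af_1000g=0.16, clinsig=ClinSig.BENIGN))
    assert not call.retained


def test_uncatalogued_variant_retained():
    call = filter_population_and_effect(make_call(sc(100, 40), sc(100, 0)), None)
    assert call.retained


def test_sift_threshold_standard_and_inverted():
    tolerated = filter_population_and_effect(
        make_call(sc(100, 40), sc(100, 0)), ann(sift=0.5))
    assert not tolerated.retained
    damaging = filter_population_and_effect(
        make_call(sc(100, 40), sc(100, 0)), ann(sift=0.01))
    assert damaging.retained
    # the inverted convention flips both outcomes
    cfg = FilterConfig(sift_inverted=True)
    assert filter_population_and_effect(
        make_call(sc(100, 40), sc(100, 0)), ann(sift=0.5), cfg).retained
    assert not filter_population_and_effect(
        make_call(sc(100, 40), sc(100, 0)), ann(sift=0.01), cfg).retained


def test_noncoding_dropped():
    call = filter_population_and_effect(make_call(sc(100, 40), sc(100, 0)),
                                        ann(coding=False))
    assert not call.retained


# --- cascade properties ---------------------------------------------------

def _trio_records(seed=0, n=3):
    spec = CohortSpec(n_patients=n, seed=seed, ctdna_fraction_range=(0.05, 0.2))
    recs = []
    for i in range(n):
        recs.extend(simulate_trio(spec, i).records)
    return recs


def test_filter_conservation_every_discard_has_reason():
    records = _trio_records(seed=1)
    calls = call_somatic(records)
    assert len(calls) == len(records)
    for c in calls:
        if not c.retained:
            assert any(out == "fail" for _, out, _ in c.filter_trail)


def test_monotone_in_min_tumor_af():
    records = _trio_records(seed=2)
    keys = lambda cfg: {(c.patient_id, c.variant.coord_key())
                        for c in somatic_set(call_somatic(records, config=cfg))}
    loose = keys(FilterConfig(min_tumor_af=0.005))
    tight = keys(FilterConfig(min_tumor_af=0.05))
    assert tight <= loose


def test_recovers_simulated_somatic_truth():
    records = _trio_records(seed=3, n=4)
    calls = call_somatic(records)
    som = {(c.patient_id, c.variant.coord_key()) for c in somatic_set(calls)}
    truth = {(r.patient_id, r.variant.coord_key())
             for r in records if r.truth_label == "somatic"}
    germline = {(r.patient_id, r.variant.coord_key())
                for r in records if r.truth_label == "germline"}
    assert len(som & truth) / len(truth) >= 0.9
    assert len(som & germline) == 0


# --- summaries ------------------------------------------------------------

def _call(gene, patient, t_alt=40, t_depth=100):
    c = classify_site(sc(t_depth, t_alt), sc(200, 0), gene=gene, patient_id=patient)
    return apply_retention_filters(c)


def test_gene_frequency_counts_distinct_patients():
    calls = [_call("TP53", "P1"), _call("TP53", "P2"), _call("TP53", "P2"),
             _call("PTEN", "P3")]
    table = summarize_gene_frequencies(calls)
    assert table.iloc[0]["gene"] == "TP53"
    assert int(table.iloc[0]["n_patients"]) == 2
    assert int(table[table.gene == "PTEN"]["n_patients"].iloc[0]) == 1


def test_empty_call_set_gives_empty_table():
    assert summarize_gene_frequencies([]).empty


def test_vaf_by_gene_collects_afs():
    calls = [_call("SMARCA4", "P1", t_alt=23, t_depth=55)]
    vafs = vaf_by_gene(calls)
    assert set(vafs) == {"SMARCA4"}
    assert vafs["SMARCA4"][0] == pytest.approx(23 / 55)
    # homozygous-like injections push the gene median up
    high = [_call("ATRX", f"P{i}", t_alt=90, t_depth=100) for i in range(5)]
    assert np.median(vaf_by_gene(high)["ATRX"]) > 0.75
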