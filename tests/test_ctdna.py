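"""Plasma concordance detection and UMI consensus collapsing."""

import numpy as np
import pytest

from plasmatriage import fixtures
from plasmatriage.ctdna import (DetectionConfig, collapse_umi,
                                count_detected_patients, detect_cohort,
                                detect_ctdna, emit_concordance_report)
from plasmatriage.synthetic import simulate_umi_reads
from plasmatriage.types import SiteCounts, TrioRecord, UMIFamily, VariantId


def trio(ccf_depth, ccf_alt, gdna=(200, 0), patient="P1", diagnosis="Glioblastoma, Grade 4"):
    return TrioRecord(
        patient_id=patient, diagnosis=diagnosis, gene="TP53",
        variant=VariantId(chrom="chr17", pos=7577120, ref="C", alt="T"),
        gdna=SiteCounts(*gdna), tdna=SiteCounts(149, 144),
        ccfdna=SiteCounts(ccf_depth, ccf_alt))


# --- UMI collapse ---------------------------------------------------------

def fam(alleles):
    return UMIFamily(umi="u", site_key=("1", 1), members=list(alleles))


def test_collapse_all_ref():
    counts = collapse_umi([fam("rr"), fam("r"), fam("rrr")])
    assert (counts.depth, counts.alt) == (3, 0)


def test_collapse_counts_alt_consensus_families():
    families = [fam("aa") for _ in range(100)] + [fam("rr") for _ in range(900)]
    for f in families:
        f.members = ["alt" if m == "a" else "ref" for m in f.members]
    counts = collapse_umi(families)
    assert (counts.depth, counts.alt) == (1000, 100)


def test_tied_families_excluded():
    tie = UMIFamily(umi="t", site_key=("1", 1), members=["ref", "alt"])
    counts = collapse_umi([tie, UMIFamily("u", ("1", 1), ["alt", "alt", "ref"])])
    assert (counts.depth, counts.alt) == (1, 1)


def test_noisy_umi_collapse_within_enumeration_bounds():
    """Collapsing error-injected families recovers the true alt count within
    binomial bounds derived from the exact per-family majority probability."""
    q, dups, n_alt, n_ref = 0.2, 3, 300, 700
    rec = trio(n_alt + n_ref, n_alt)
    rng = np.random.default_rng(77)
    fams = simulate_umi_reads(rec, mean_duplicates=float(dups),
                              duplicate_error=q, seed=rng)
    counts = collapse_umi(fams)
    # family sizes are 1 + Poisson(2); enumerate the majority-vote outcome
    # over sizes with nontrivial mass to bound the expected alt-consensus count
    from scipy.stats import poisson

    def p_alt_consensus(true_alt: bool):
        total = 0.0
        for extra in range(12):
            size = 1 + extra
            w = poisson.pmf(extra, dups - 1)
            p_maj = _majority_prob(size, q if true_alt else 1 - q)
            total += w * p_maj
        return total

    exp_alt = n_alt * p_alt_consensus(True) + n_ref * p_alt_consensus(False)
    sd = np.sqrt(n_alt + n_ref)  # loose binomial-style bound
    assert abs(counts.alt - exp_alt) < 5 * sd


def _majority_prob(size, flip_q):
    """P(majority of `size` votes is the original allele is kept) with per-vote
    flip probability flip_q; ties count as not-alt (excluded families)."""
    from math import comb
    # probability that strictly more than half the votes keep the allele
    return sum(comb(size, k) * (1 - flip_q) ** k * flip_q ** (size - k)
               for k in range(size // 2 + 1, size + 1))


# --- detection ------------------------------------------------------------

def test_low_af_plasma_signal_detected():
    call = detect_ctdna(trio(1219, 11))
    assert call.detected
    assert f"{call.ccfdna_af:.3f}" == "0.009"


def test_no_alt_reads_not_detected():
    assert not detect_ctdna(trio(2000, 0)).detected


def test_high_burden_plasma_detected():
    call = detect_ctdna(trio(1979, 454))
    assert call.detected
    assert f"{call.ccfdna_af:.3f}" == "0.229"


def test_zero_coverage_reports_reason():
    call = detect_ctdna(trio(0, 0))
    assert not call.detected
    assert ("plasma_coverage", "fail", "no_coverage") in call.trail


def test_dirty_germline_blocks_detection():
    call = detect_ctdna(trio(1000, 50, gdna=(200, 10)))
    assert not call.detected


def test_detection_monotone_in_threshold():
    records = [trio(1000, k, patient=f"P{k}") for k in range(0, 12)]
    detected_at = lambda thr: {c.record.patient_id for c in detect_cohort(
        records, DetectionConfig(min_plasma_alt=thr)) if c.detected}
    for thr in range(1, 10):
        assert detected_at(thr + 1) <= detected_at(thr)


def test_patient_counting_idempotent_order_independent():
    records = [trio(1000, 50, patient="A"), trio(900, 40, patient="A"),
               trio(800, 30, patient="B")]
    calls = detect_cohort(records)
    assert count_detected_patients(calls) == 2
    assert count_detected_patients(list(reversed(calls))) == 2
    assert count_detected_patients(calls + calls) == 2


def test_consensus_detection_sensitivity_and_false_rate():
    """End-to-end through UMI collapse: with ctDNA fraction >= 0.05 and
    consensus depth 1000, detection sensitivity >= 0.9; at truth-negative
    sites the duplicate-level error (1e-3) is suppressed by majority vote
    and the per-site false detection rate stays <= 0.01."""
    rng = np.random.default_rng(505)
    f, a, err, depth = 0.05, 0.2, 1e-3, 1000
    tp = fp = n = 200
    tp_hits = fp_hits = 0
    for _ in range(n):
        alt_mol = rng.binomial(depth, f * a)
        pos = trio(depth, alt_mol)
        fams = simulate_umi_reads(pos, mean_duplicates=3.0, duplicate_error=err,
                                  seed=rng)
        pos.ccfdna = collapse_umi(fams)
        tp_hits += detect_ctdna(pos).detected
        neg = trio(depth, 0)
        fams = simulate_umi_reads(neg, mean_duplicates=3.0, duplicate_error=err,
                                  seed=rng)
        neg.ccfdna = collapse_umi(fams)
        fp_hits += detect_ctdna(neg).detected
    assert tp_hits / tp >= 0.9
    assert fp_hits / fp <= 0.01


# --- report-table fixture -------------------------------------------------

def test_concordance_table_reproduced():
    calls = detect_cohort(fixtures.concordance_records())
    report = emit_concordance_report(calls)
    assert len(report) == 17
    assert count_detected_patients(calls) == 8
    assert count_detected_patients(calls, diagnosis_class="glioma") == 5
    raw = fixtures.load_table(1)
    # every printed plasma AF is alt/depth at 3 decimals
    assert list(report["ccfdna_af"]) == list(raw["ccfdna_af"].map(lambda s: f"{float(s):.3f}"))


def test_empty_input_empty_report():
    report = emit_concordance_report([])
    assert report.empty and "ccfdna_af" in report.columns
    assert count_detected_patients([]) == 0
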