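"""Synthetic cohort generator: mixture law, determinism, UMI accounting."""

from itertools import product
from math import comb

import numpy as np
import pytest
from scipy.stats import binom

from plasmatriage.ctdna import collapse_umi
from plasmatriage.synthetic import (CohortSpec, FragmentLengthModel,
                                    cohort_to_frame, default_panel,
                                    plasma_alt_rate, read_cohort_counts,
                                    simulate_cohort, simulate_fragment_profile,
                                    simulate_trio, simulate_umi_reads,
                                    write_cohort)


def _somatic_records(trio):
    return [r for r in trio.records if r.truth_label == "somatic"]


def test_no_signal_no_error_gives_zero_plasma_alt():
    spec = CohortSpec(n_patients=1, seed=5, error_rate=0.0,
                      ctdna_fraction_range=(0.0, 0.0))
    trio = simulate_trio(spec, 0)
    for rec in _somatic_records(trio):
        assert rec.ccfdna.alt == 0
        assert rec.gdna.alt == 0


def test_germline_sites_near_half_in_all_compartments():
    spec = CohortSpec(n_patients=1, seed=7, error_rate=0.0,
                      depth_gdna=1000, depth_tdna=1000, depth_ccfdna=1000)
    trio = simulate_trio(spec, 0)
    # 99% binomial band at n=1000, p=0.5, with slack for Poisson depth
    lo, hi = binom.ppf([0.005, 0.995], 1000, 0.5) / 1000
    margin = 0.03
    for rec in trio.records:
        if rec.truth_label != "germline":
            continue
        for counts in (rec.gdna, rec.tdna, rec.ccfdna):
            assert lo - margin <= counts.af <= hi + margin


def test_plasma_mixture_law_monte_carlo():
    """Mean plasma AF over many replicates follows f*a + (1-f)*e."""
    f, a, e, depth = 0.1, 0.5, 0.001, 2000
    expected = plasma_alt_rate(f, a, e)
    assert expected == pytest.approx(0.0509)
    rng = np.random.default_rng(2024)
    afs = rng.binomial(depth, expected, size=1000) / depth
    assert abs(afs.mean() - expected) < 0.005
    # and the generator itself obeys the law within 3 standard errors
    spec = CohortSpec(n_patients=1, germline_het_sites_per_patient=0,
                      plasma_only_sites_per_patient=0,
                      somatic_sites_per_patient=1, somatic_af_range=(a, a),
                      ctdna_fraction_range=(f, f), error_rate=e,
                      depth_ccfdna=depth)
    sample = []
    for seed in range(500):
        spec.seed = seed
        rec = _somatic_records(simulate_trio(spec, 0))[0]
        sample.append(rec.ccfdna.af)
    sample = np.array(sample)
    se = sample.std(ddof=1) / np.sqrt(len(sample))
    assert abs(sample.mean() - expected) < 3 * se + 1e-12


def test_determinism_and_label_conservation():
    spec = CohortSpec(n_patients=3, seed=42)
    c1, c2 = simulate_cohort(spec), simulate_cohort(spec)
    f1, f2 = cohort_to_frame(c1), cohort_to_frame(c2)
    assert f1.equals(f2)
    labels = f1.groupby("patient_id")["label"].value_counts()
    for pid in f1["patient_id"].unique():
        assert labels[pid]["germline"] == spec.germline_het_sites_per_patient
        assert labels[pid]["somatic"] == spec.somatic_sites_per_patient
        assert labels[pid]["plasma_only"] == spec.plasma_only_sites_per_patient


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        CohortSpec(depth_ccfdna=0).validate()
    with pytest.raises(ValueError):
        CohortSpec(error_rate=1.5).validate()
    with pytest.raises(ValueError):
        CohortSpec(diagnoses=[("GBM", 0.5)]).validate()


# --- UMI families ---------------------------------------------------------

def _one_site_record(depth, alt):
    from plasmatriage.types import SiteCounts, TrioRecord, VariantId
    return TrioRecord(patient_id="P0", diagnosis="GBM", gene="TP53",
                      variant=VariantId(chrom="ctg1", pos=100, ref="A", alt="T"),
                      ccfdna=SiteCounts(depth=depth, alt=alt))


def test_umi_single_molecule_no_error():
    fams = simulate_umi_reads(_one_site_record(1, 0), mean_duplicates=5.0,
                              duplicate_error=0.0, seed=0)
    assert len(fams) == 1
    assert all(m == "ref" for m in fams[0].members)


def test_umi_error_free_collapse_recovers_truth():
    fams = simulate_umi_reads(_one_site_record(1000, 100), mean_duplicates=3.0,
                              duplicate_error=0.0, seed=1)
    assert len(fams) == 1000
    counts = collapse_umi(fams)
    assert counts.depth == 1000 and counts.alt == 100


def test_umi_accounting():
    fams = simulate_umi_reads(_one_site_record(200, 40), mean_duplicates=4.0,
                              duplicate_error=0.05, seed=3)
    assert len(fams) == 200  # distinct families == consensus depth
    assert all(f.size >= 1 for f in fams)


def test_umi_majority_vote_matches_enumeration():
    """Exact-size-3 families with flip probability q: majority recovers the
    alt allele with probability computed by enumerating Binomial(3, q)."""
    q = 0.4
    # alt family: majority stays alt when <= 1 of 3 duplicates flip
    p_correct = sum(comb(3, k) * q**k * (1 - q) ** (3 - k) for k in (0, 1))
    rng = np.random.default_rng(12345)
    n = 4000
    correct = 0
    for _ in range(n):
        flips = rng.random(3) < q
        alleles = ["ref" if f else "alt" for f in flips]
        if sum(a == "alt" for a in alleles) > 1:
            correct += 1
    se = np.sqrt(p_correct * (1 - p_correct) / n)
    assert abs(correct / n - p_correct) < 4 * se


# --- fragment profiles ----------------------------------------------------

def test_fragment_contaminant_only_fails_downstream_qc():
    from plasmatriage.qc import classify_qc
    model = FragmentLengthModel(dimer_weight=0, trimer_weight=0, contaminant_weight=1.0)
    prof = simulate_fragment_profile(model, 5000, seed=0)
    assert (prof.histogram.index > 2000).all()
    assert classify_qc(prof).reason == "genomic_contamination"


def test_fragment_modal_bin_at_mononucleosome_peak():
    prof = simulate_fragment_profile(FragmentLengthModel(), 100_000, seed=9)
    binned = prof.histogram.groupby(prof.histogram.index // 10 * 10).sum()
    mode_lo = binned.idxmax()
    assert mode_lo <= 167 < mode_lo + 10


def test_fragment_window_mass_matches_weights():
    model = FragmentLengthModel(dimer_weight=0, trimer_weight=0, contaminant_weight=0.5)
    prof = simulate_fragment_profile(model, 100_000, seed=4)
    in_window = prof.histogram[(prof.histogram.index >= 100)
                               & (prof.histogram.index <= 500)].sum()
    assert in_window / prof.total == pytest.approx(0.5, abs=0.01)


# --- serialization --------------------------------------------------------

def test_write_cohort_roundtrip_and_byte_determinism(tmp_path, small_spec):
    cohort = simulate_cohort(small_spec)
    p1 = write_cohort(cohort, tmp_path / "a")
    p2 = write_cohort(simulate_cohort(small_spec), tmp_path / "b")
    assert p1["counts"].read_bytes() == p2["counts"].read_bytes()
    assert p1["vcfs"][0].read_bytes() == p2["vcfs"][0].read_bytes()
    back = read_cohort_counts(p1["counts"])
    orig = [r for t in cohort.trios for r in t.records]
    assert len(back) == len(orig)
    for a, b in zip(orig, back):
        assert (a.gdna, a.tdna, a.ccfdna) == (b.gdna, b.tdna, b.ccfdna)
        assert a.variant == b.variant


def test_empty_cohort_writes_valid_headers(tmp_path):
    spec = CohortSpec(n_patients=0, seed=0)
    paths = write_cohort(simulate_cohort(spec), tmp_path)
    assert read_cohort_counts(paths["counts"]) == []


def test_vcf_roundtrip_counts(tmp_path, small_spec):
    from plasmatriage.io import read_trio_vcf, write_trio_vcf
    trio = simulate_trio(small_spec, 0)
    path = tmp_path / "trio.vcf"
    write_trio_vcf(trio.records, path)
    back = read_trio_vcf(path, patient_id=trio.patient_id)
    assert len(back) == len(trio.records)
    by_key = {r.variant.coord_key(): r for r in trio.records}
    for rec in back:
        orig = by_key[rec.variant.coord_key()]
        assert (rec.gdna.depth, rec.gdna.alt) == (orig.gdna.depth, orig.gdna.alt)
        assert (rec.ccfdna.depth, rec.ccfdna.alt) == (orig.ccfdna.depth, orig.ccfdna.alt)
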