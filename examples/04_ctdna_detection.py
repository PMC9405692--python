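"""UMI consensus collapsing and plasma ctDNA detection.

First shows why UMI families matter: duplicate-level sequencing errors are
removed by majority vote, so three consensus molecules are trustworthy
evidence. Then reproduces the packaged tumor-plasma concordance table.
"""

from plasmatriage import fixtures
from plasmatriage.ctdna import (collapse_umi, count_detected_patients,
                                detect_cohort, emit_concordance_report)
from plasmatriage.synthetic import simulate_umi_reads
from plasmatriage.types import SiteCounts, TrioRecord, VariantId

site = TrioRecord(patient_id="P0", diagnosis="Glioblastoma, Grade 4", gene="TP53",
                  variant=VariantId(chrom="ctg1", pos=500, ref="C", alt="T"),
                  ccfdna=SiteCounts(depth=1000, alt=10))
families = simulate_umi_reads(site, mean_duplicates=3.0, duplicate_error=0.02, seed=4)
consensus = collapse_umi(families)
print(f"1000 molecules (10 alt) -> {len(families)} UMI families -> consensus "
      f"{consensus.alt}/{consensus.depth} alt after majority vote "
      f"(2% duplicate error suppressed)\n")

calls = detect_cohort(fixtures.concordance_records())
report = emit_concordance_report(calls)
print(report[["gene", "patient_id", "diagnosis", "ccfdna_alt", "ccfdna_all",
              "ccfdna_af"]].to_string(index=False))
print(f"\nctDNA detected in {count_detected_patients(calls)} patients "
      f"({count_detected_patients(calls, 'glioma')} gliomas): every variant "
      "with >= 3 alt consensus molecules and a clean germline counts, with "
      "no plasma AF floor (detections run down to AF 0.009).")
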