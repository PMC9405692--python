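"""Tier triage of plasma-only variants against the packaged catalogs.

Variants present in ccfDNA but absent from germline DNA are classified into
tiers: pathogenic plasma-only (ClinVar pathogenic-like, or COSMIC-registered
and population-rare), cohort-confirmed (somatic in a prior or the current
cohort), or benign carrier.
"""

from plasmatriage import fixtures
from plasmatriage.triage import (TriageConfig, count_patients_tiered,
                                 emit_triage_tables, triage_records)

pathogenic = triage_records(fixtures.ccfdna_only_records(),
                            fixtures.ccfdna_only_annotations())
tables = emit_triage_tables(pathogenic)
print(tables["PATHOGENIC_CCFDNA_ONLY"].head(8)[
    ["gene", "patient_id", "rsid", "clinsig", "ccfdna_alt", "ccfdna_all",
     "ccfdna_af"]].to_string(index=False))
n25 = count_patients_tiered(pathogenic, ["PATHOGENIC_CCFDNA_ONLY"])
print(f"... {len(pathogenic)} variants; potentially pathogenic plasma-only "
      f"variants in {n25} distinct patients\n")

records = fixtures.prior_cohort_records() + fixtures.current_cohort_records()
confirmed = triage_records(records, fixtures.triage_annotations(),
                           cohort_catalog=fixtures.cohort_catalog(),
                           config=TriageConfig(gdna_strict=False))
for tier in ("COHORT_PRIOR_CONFIRMED", "COHORT_CURRENT_CONFIRMED"):
    n = sum(c.tier == tier for c in confirmed)
    print(f"{tier:<26} {n} variants")
n16 = count_patients_tiered(confirmed, ["COHORT_PRIOR_CONFIRMED",
                                        "COHORT_CURRENT_CONFIRMED",
                                        "CARRIER_BENIGN"])
print(f"cohort-confirmed plasma variants in {n16} distinct patients — "
      "plasma integrates tumor regions the resected fragment missed.")
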