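"""One-config orchestration of the full triage pipeline.

Two run modes share one report structure:

* ``simulate`` — generate a synthetic matched-trio cohort, then run QC,
  somatic calling, plasma detection and triage over it;
* ``fixtures`` — run the detection and triage stages over the packaged
  report-table fixtures, reproducing the published patient-level counts.

Every stage records input / retained / discarded counts, and the validated
configuration is hashed into the report so identical hash implies identical
results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from . import ctdna, fixtures, somatic, synthetic, triage
from .qc import QCThresholds, classify_qc
from .synthetic import CohortSpec, FragmentLengthModel

logger = logging.getLogger("plasmatriage")


class SimulationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = 12
    seed: int = 0
    germline_het_sites_per_patient: int = 20
    somatic_sites_per_patient: int = 8
    plasma_only_sites_per_patient: int = 2
    somatic_af_range: tuple[float, float] = (0.2, 0.7)
    ctdna_fraction_range: tuple[float, float] = (0.0, 0.2)
    error_rate: float = 1e-3
    depth_gdna: float = 150.0
    depth_tdna: float = 150.0
    depth_ccfdna: float = 1500.0

    def to_spec(self) -> CohortSpec:
        return CohortSpec(**self.model_dump())


class FilterSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_coverage: int = 10
    min_alt_tumor: int = 3
    min_tumor_af: float = 0.01
    max_gdna_af: float = 0.01
    somatic_p: float = 0.05
    strand_bias_p: float = 0.05
    strand_bias_min_skew: float = 0.9
    sift_damaging_max: float = 0.05
    sift_inverted: bool = False
    population_af_max: float = 0.001

    def to_config(self) -> somatic.FilterConfig:
        return somatic.FilterConfig(**self.model_dump())


class DetectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_plasma_alt: int = 3
    max_gdna_af: float = 0.01

    def to_config(self) -> ctdna.DetectionConfig:
        return ctdna.DetectionConfig(**self.model_dump())


class TriageSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_plasma_alt: int = 2
    gdna_strict: bool = True
    max_gdna_alt_relaxed: int = 3
    max_gdna_af_relaxed: float = 0.10
    rare_af_max: float = 0.001

    def to_config(self) -> triage.TriageConfig:
        return triage.TriageConfig(**self.model_dump())


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    mode: str = Field(default="simulate", pattern="^(simulate|fixtures)$")
    out_dir: Optional[str] = None
    run_qc: bool = True
    simulation: SimulationSettings = SimulationSettings()
    filters: FilterSettings = FilterSettings()
    detection: DetectionSettings = DetectionSettings()
    triage: TriageSettings = TriageSettings()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StageRecord:
    stage: str
    n_input: int
    n_retained: int
    n_discarded: int
    detail: dict = field(default_factory=dict)


@dataclass
class RunReport:
    config_hash: str
    mode: str
    stages: list = field(default_factory=list)
    detection_counts: dict = field(default_factory=dict)
    tier_patient_counts: dict = field(default_factory=dict)

    def add(self, stage: str, n_input: int, n_retained: int, **detail) -> None:
        rec = StageRecord(stage, n_input, n_retained, n_input - n_retained, detail)
        logger.info("stage=%s input=%d retained=%d discarded=%d",
                    stage, n_input, n_retained, rec.n_discarded)
        self.stages.append(rec)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash, "mode": self.mode,
            "stages": [vars(s) for s in self.stages],
            "detection_counts": self.detection_counts,
            "tier_patient_counts": self.tier_patient_counts,
        }


def run_pipeline(config: RunConfig) -> RunReport:
    report = RunReport(config_hash=config.config_hash(), mode=config.mode)
    if config.mode == "fixtures":
        _run_fixtures(config, report)
    else:
        _run_simulation(config, report)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=str)
    return report


def _run_fixtures(config: RunConfig, report: RunReport) -> None:
    # tumor-concordant ctDNA detection over the trio table
    trios = fixtures.concordance_records()
    calls = ctdna.detect_cohort(trios, config.detection.to_config())
    detected = [c for c in calls if c.detected]
    report.add("detect_ctdna", len(calls), len(detected))
    report.detection_counts = {
        "patients_detected": ctdna.count_detected_patients(calls),
        "glioma_patients_detected": ctdna.count_detected_patients(calls, "glioma"),
    }

    # plasma-only pathogenic triage
    tri_cfg = config.triage.to_config()
    path_calls = triage.triage_records(
        fixtures.ccfdna_only_records(), fixtures.ccfdna_only_annotations(),
        config=tri_cfg)
    report.add("triage_pathogenic", len(fixtures.ccfdna_only_records()), len(path_calls))

    # cohort-confirmed triage needs the relaxed germline rule
    relaxed = triage.TriageConfig(**{**tri_cfg.__dict__, "gdna_strict": False})
    catalog = fixtures.cohort_catalog()
    annotations = fixtures.triage_annotations()
    confirm_records = fixtures.prior_cohort_records() + fixtures.current_cohort_records()
    confirm_calls = triage.triage_records(confirm_records, annotations,
                                          cohort_catalog=catalog, config=relaxed)
    report.add("triage_cohort_confirmed", len(confirm_records), len(confirm_calls))

    report.tier_patient_counts = {
        "pathogenic_ccfdna_only": triage.count_patients_tiered(
            path_calls, ["PATHOGENIC_CCFDNA_ONLY"]),
        "cohort_confirmed": triage.count_patients_tiered(
            confirm_calls, ["COHORT_PRIOR_CONFIRMED", "COHORT_CURRENT_CONFIRMED",
                            "CARRIER_BENIGN"]),
    }


def _run_simulation(config: RunConfig, report: RunReport) -> None:
    spec = config.simulation.to_spec()
    cohort = synthetic.simulate_cohort(spec)
    records = [r for trio in cohort.trios for r in trio.records]
    report.add("simulate", spec.n_patients, spec.n_patients,
               n_sites=len(records))

    if config.run_qc:
        model = FragmentLengthModel()
        verdicts = []
        for i, trio in enumerate(cohort.trios):
            prof = synthetic.simulate_fragment_profile(
                model, 20_000, seed=spec.seed * 100_003 + i, sample_id=trio.patient_id)
            verdicts.append(classify_qc(prof, QCThresholds()))
        report.add("qc", len(verdicts), sum(v.passed for v in verdicts))

    catalog = fixtures.annotation_catalog()
    calls = somatic.call_somatic(records, catalog, config.filters.to_config())
    som = somatic.somatic_set(calls)
    report.add("call_somatic", len(calls), len(som))

    som_keys = {(c.patient_id, c.variant.coord_key()) for c in som}
    som_records = [r for trio in cohort.trios for r in trio.records
                   if (r.patient_id, r.variant.coord_key()) in som_keys]
    det = ctdna.detect_cohort(som_records, config.detection.to_config())
    report.add("detect_ctdna", len(det), sum(c.detected for c in det))
    report.detection_counts = {
        "patients_detected": ctdna.count_detected_patients(det),
        "glioma_patients_detected": ctdna.count_detected_patients(det, "glioma"),
    }

    tri = triage.triage_records(records, catalog,
                                current_somatic_keys=som_keys,
                                config=config.triage.to_config())
    report.add("triage", len(records), len(tri))
    report.tier_patient_counts = {
        tier: triage.count_patients_tiered(tri, [tier]) for tier in triage.TIERS}
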