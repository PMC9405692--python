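"""Synthetic matched-trio cohort generator.

Emulates the statistical structure the downstream analysis assumes, so every
stage is exercisable without patient data:

* germline heterozygous variants at allele fraction ~0.5 in every compartment;
* clonal tumor somatic variants at a stated AF, absent from germline except
  for per-base sequencing error;
* plasma counts as a binomial mixture: the expected plasma alt fraction at a
  somatic site is ``f * a + (1 - f) * e`` for ctDNA fraction ``f``, tumor AF
  ``a`` and per-base error rate ``e``;
* plasma-only variants (tumor heterogeneity shed into blood but missed by
  the resected fragment), present in plasma at the same mixture rate but at
  error level in both tumor and germline;
* UMI read families: each plasma consensus molecule expanded into PCR
  duplicates sharing one UMI tag, with per-duplicate base errors;
* ccfDNA fragment lengths as a categorical mixture over mono-/di-/tri-
  nucleosomal peaks plus an optional long genomic contaminant.

All sampling is driven by explicit seeds threaded through
``numpy.random.Generator``; identical spec + seed gives identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .qc import FragmentProfile
from .types import SiteCounts, TrioRecord, UMIFamily, VariantId

_BASES = "ACGT"


# --- panel ----------------------------------------------------------------

@dataclass(frozen=True)
class PanelRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    gene: str
    exon: int


def default_panel(n_genes: int = 10, exons_per_gene: int = 4,
                  exon_len: int = 150, gap: int = 2000) -> list[PanelRegion]:
    """A small targeted panel on synthetic contigs, named after genes
    recurrently altered in diffuse glioma."""
    genes = ["TP53", "PTEN", "EGFR", "ATRX", "IDH1", "NF1",
             "SMARCA4", "BRAF", "PIK3CA", "CDKN2A"][:n_genes]
    regions = []
    for gi, gene in enumerate(genes):
        chrom = f"ctg{gi % 3 + 1}"
        base = 10_000 + (gi // 3) * 100_000
        for e in range(exons_per_gene):
            start = base + gi * 10_000 + e * (exon_len + gap)
            regions.append(PanelRegion(chrom, start, start + exon_len - 1, gene, e + 1))
    return regions


def write_panel_bed(panel: Sequence[PanelRegion], path) -> None:
    with open(path, "w") as fh:
        for r in panel:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene}\t{r.exon}\n")


# --- cohort specification -------------------------------------------------

def _default_diagnoses() -> list[tuple[str, float]]:
    # 84-patient study mix: 80 gliomas (mostly grade 4), 2 PCNSL, 2 metastases
    return [
        ("Glioblastoma, Grade 4", 64 / 84),
        ("Astrocytoma Anaplasticum, Grade 3", 16 / 84),
        ("Primary Central Nervous System Lymphoma", 2 / 84),
        ("Anaplastic Thyroid Cancer Metastasis", 2 / 84),
    ]


@dataclass
class CohortSpec:
    """Parameters of a simulated matched-trio cohort.

    Depth means follow the study's sequencing design: moderate coverage for
    gDNA/tDNA panels, deep coverage for the plasma panel.
    """

    n_patients: int = 84
    diagnoses: list = field(default_factory=_default_diagnoses)
    panel: list = field(default_factory=default_panel)
    seed: int = 0
    germline_het_sites_per_patient: int = 20
    somatic_sites_per_patient: int = 8
    plasma_only_sites_per_patient: int = 2
    somatic_af_range: tuple = (0.2, 0.7)
    ctdna_fraction_range: tuple = (0.0, 0.2)
    error_rate: float = 1e-3
    depth_gdna: float = 150.0
    depth_tdna: float = 150.0
    depth_ccfdna: float = 1500.0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        props = [p for _, p in self.diagnoses]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("diagnosis proportions must sum to 1")
        for lo, hi in (self.somatic_af_range, self.ctdna_fraction_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("rate intervals must lie in [0, 1]")
        if not (0 <= self.error_rate <= 1):
            raise ValueError("error_rate must lie in [0, 1]")
        if min(self.depth_gdna, self.depth_tdna, self.depth_ccfdna) <= 0:
            raise ValueError("mean depths must be positive")
        if not self.panel:
            raise ValueError("panel must be non-empty")


@dataclass
class SimulatedTrio:
    patient_id: str
    diagnosis: str
    records: list  # list[TrioRecord] with truth labels
    ctdna_fraction: float
    fragment_profile: Optional[FragmentProfile] = None


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    trios: list


# --- count sampling -------------------------------------------------------

def _draw_counts(rng: np.random.Generator, mean_depth: float, p: float) -> SiteCounts:
    depth = int(max(1, rng.poisson(mean_depth)))
    alt = int(rng.binomial(depth, p))
    alt_fwd = int(rng.binomial(alt, 0.5))
    ref_fwd = int(rng.binomial(depth - alt, 0.5))
    return SiteCounts(depth=depth, alt=alt, alt_fwd=alt_fwd, alt_rev=alt - alt_fwd,
                      ref_fwd=ref_fwd, ref_rev=depth - alt - ref_fwd)


def plasma_alt_rate(ctdna_fraction: float, tumor_af: float, error_rate: float) -> float:
    """Expected plasma alt fraction under the linear ctDNA mixture model."""
    return ctdna_fraction * tumor_af + (1.0 - ctdna_fraction) * error_rate


def simulate_trio(spec: CohortSpec, patient_index: int) -> SimulatedTrio:
    """Simulate one patient's matched gDNA/tDNA/ccfDNA count trio.

    Reproducible per patient: the per-patient RNG is spawned from
    ``(spec.seed, patient_index)`` so trios are independent of cohort size.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, patient_index)))
    patient_id = f"P{patient_index:03d}"
    labels = [d for d, _ in spec.diagnoses]
    props = np.array([p for _, p in spec.diagnoses], dtype=float)
    diagnosis = str(rng.choice(labels, p=props / props.sum()))
    f = float(rng.uniform(*spec.ctdna_fraction_range))

    n_sites = (spec.germline_het_sites_per_patient + spec.somatic_sites_per_patient
               + spec.plasma_only_sites_per_patient)
    positions = _draw_positions(rng, spec.panel, n_sites)
    records: list[TrioRecord] = []

    def add(region: PanelRegion, pos: int, label: str, p_g: float, p_t: float,
            p_c: float, true_af: Optional[float]) -> None:
        ref, alt = rng.choice(4, size=2, replace=False)
        records.append(TrioRecord(
            patient_id=patient_id, diagnosis=diagnosis, gene=region.gene,
            variant=VariantId(chrom=region.chrom, pos=pos,
                              ref=_BASES[ref], alt=_BASES[alt]),
            gdna=_draw_counts(rng, spec.depth_gdna, p_g),
            tdna=_draw_counts(rng, spec.depth_tdna, p_t),
            ccfdna=_draw_counts(rng, spec.depth_ccfdna, p_c),
            truth_label=label, true_af_tumor=true_af, true_ctdna_fraction=f,
        ))

    i = 0
    for _ in range(spec.germline_het_sites_per_patient):
        region, pos = positions[i]; i += 1
        add(region, pos, "germline", 0.5, 0.5, 0.5, None)
    for _ in range(spec.somatic_sites_per_patient):
        region, pos = positions[i]; i += 1
        a = float(rng.uniform(*spec.somatic_af_range))
        add(region, pos, "somatic", spec.error_rate, a,
            plasma_alt_rate(f, a, spec.error_rate), a)
    for _ in range(spec.plasma_only_sites_per_patient):
        region, pos = positions[i]; i += 1
        a = float(rng.uniform(*spec.somatic_af_range))
        add(region, pos, "plasma_only", spec.error_rate, spec.error_rate,
            plasma_alt_rate(f, a, spec.error_rate), a)

    return SimulatedTrio(patient_id, diagnosis, records, f)


def _draw_positions(rng, panel, n_sites):
    """Distinct (region, position) pairs across the panel."""
    sized = [(r, r.end - r.start + 1) for r in panel]
    total = sum(s for _, s in sized)
    if n_sites > total:
        raise ValueError("panel too small for requested site count")
    offsets = rng.choice(total, size=n_sites, replace=False)
    out = []
    for off in sorted(int(o) for o in offsets):
        for region, size in sized:
            if off < size:
                out.append((region, region.start + off))
                break
            off -= size
    return out


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    spec.validate()
    return SimulatedCohort(spec, [simulate_trio(spec, i) for i in range(spec.n_patients)])


# --- UMI read families ----------------------------------------------------

def simulate_umi_reads(record: TrioRecord, mean_duplicates: float = 3.0,
                       duplicate_error: float = 0.0,
                       seed: int | np.random.Generator = 0) -> list[UMIFamily]:
    """Expand a plasma consensus count into UMI read families.

    One family per consensus molecule (so distinct families == consensus
    depth); each family carries >= 1 PCR duplicates sharing a UMI tag, and
    each duplicate's observed allele flips with probability
    ``duplicate_error``, making majority-vote collapsing non-trivial.
    """
    if record.ccfdna is None:
        raise ValueError("record has no plasma counts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    site_key = record.variant.site_key() or ("NA", 0)
    counts = record.ccfdna
    families = []
    for j in range(counts.depth):
        true_allele = "alt" if j < counts.alt else "ref"
        size = 1 + int(rng.poisson(max(mean_duplicates - 1.0, 0.0)))
        members = []
        for _ in range(size):
            allele = true_allele
            if duplicate_error > 0 and rng.random() < duplicate_error:
                allele = "ref" if allele == "alt" else "alt"
            members.append(allele)
        families.append(UMIFamily(umi=f"UMI{j:06d}", site_key=site_key, members=members))
    return families


# --- fragment-length profiles ---------------------------------------------

@dataclass
class FragmentLengthModel:
    """Categorical mixture over nucleosomal peaks plus a genomic contaminant.

    Mono-, di- and trinucleosomal peaks sit at ~167, ~334 and ~501 bp; the
    contaminant models lysed-cell genomic DNA at > 2 kb.
    """

    mono_peak_bp: int = 167
    mono_range_bp: tuple = (120, 220)
    mono_sd_bp: float = 18.0
    dimer_weight: float = 0.15
    trimer_weight: float = 0.05
    long_contaminant_bp: int = 2500
    contaminant_weight: float = 0.0

    @property
    def mono_weight(self) -> float:
        return 1.0 - self.dimer_weight - self.trimer_weight - self.contaminant_weight

    def validate(self) -> None:
        w = [self.mono_weight, self.dimer_weight, self.trimer_weight, self.contaminant_weight]
        if any(x < -1e-12 for x in w):
            raise ValueError("mixture weights must be nonnegative and sum to <= 1")


def simulate_fragment_profile(model: FragmentLengthModel, n_fragments: int,
                              seed: int | np.random.Generator = 0,
                              sample_id: str = "") -> FragmentProfile:
    """Sample a fragment-length histogram from the mixture model."""
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    model.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = np.array([model.mono_weight, model.dimer_weight,
                        model.trimer_weight, model.contaminant_weight])
    comp = rng.choice(4, size=n_fragments, p=weights / weights.sum())
    lengths = np.empty(n_fragments, dtype=int)
    peaks = {0: model.mono_peak_bp, 1: 2 * model.mono_peak_bp, 2: 3 * model.mono_peak_bp}
    for k, peak in peaks.items():
        mask = comp == k
        if mask.any():
            sd = model.mono_sd_bp * (k + 1)
            vals = np.rint(rng.normal(peak, sd, size=mask.sum())).astype(int)
            lengths[mask] = np.clip(vals, 50, None)
    mask = comp == 3
    if mask.any():
        vals = np.rint(rng.normal(model.long_contaminant_bp, 150.0, size=mask.sum())).astype(int)
        lengths[mask] = np.clip(vals, 2001, None)
    hist = pd.Series(lengths).value_counts().sort_index().astype(float)
    return FragmentProfile(hist, sample_id=sample_id)


# --- exon coverage for CNA ------------------------------------------------

def simulate_exon_coverage(panel: Sequence[PanelRegion], copy_number: dict,
                           mean_depth: float = 300.0,
                           germline_copy_number: dict | None = None,
                           seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-exon depths for test / matched-normal / reference-normal tracks.

    ``copy_number`` maps gene -> integer copies in the test compartment
    (default 2); ``germline_copy_number`` likewise for the matched normal
    (shared by the test track, since the test genome inherits the germline).
    A per-exon lognormal capture-efficiency bias is shared across tracks, as
    it is in a real capture panel.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    germline_copy_number = germline_copy_number or {}
    rows = []
    for r in panel:
        bias = rng.lognormal(0.0, 0.25)
        cn_g = germline_copy_number.get(r.gene, 2)
        cn_t = copy_number.get(r.gene, cn_g)
        lam = mean_depth * bias
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "gene": r.gene, "exon": r.exon,
            "depth_test": int(rng.poisson(lam * cn_t / 2.0)),
            "depth_matched": int(rng.poisson(lam * cn_g / 2.0)),
            "depth_reference": int(rng.poisson(lam)),
        })
    return pd.DataFrame(rows)


# --- serialization --------------------------------------------------------

_COUNT_COLS = ["depth", "alt", "alt_fwd", "alt_rev", "ref_fwd", "ref_rev"]


def cohort_to_frame(cohort: SimulatedCohort) -> pd.DataFrame:
    """Flatten a cohort into one row per site with per-compartment counts."""
    rows = []
    for trio in cohort.trios:
        for rec in trio.records:
            row = {"patient_id": rec.patient_id, "diagnosis": rec.diagnosis,
                   "gene": rec.gene, "chrom": rec.variant.chrom, "pos": rec.variant.pos,
                   "ref": rec.variant.ref, "alt": rec.variant.alt,
                   "label": rec.truth_label,
                   "true_af_tumor": rec.true_af_tumor,
                   "true_ctdna_fraction": rec.true_ctdna_fraction}
            for comp, counts in (("gdna", rec.gdna), ("tdna", rec.tdna),
                                 ("ccfdna", rec.ccfdna)):
                for c in _COUNT_COLS:
                    row[f"{comp}_{c}"] = getattr(counts, c)
            rows.append(row)
    cols = (["patient_id", "diagnosis", "gene", "chrom", "pos", "ref", "alt", "label",
             "true_af_tumor", "true_ctdna_fraction"]
            + [f"{comp}_{c}" for comp in ("gdna", "tdna", "ccfdna") for c in _COUNT_COLS])
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(df: pd.DataFrame) -> list[TrioRecord]:
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        counts = {}
        for comp in ("gdna", "tdna", "ccfdna"):
            counts[comp] = SiteCounts(**{c: int(d[f"{comp}_{c}"]) for c in _COUNT_COLS})
        records.append(TrioRecord(
            patient_id=str(d["patient_id"]), diagnosis=str(d["diagnosis"]),
            gene=str(d["gene"]),
            variant=VariantId(chrom=str(d["chrom"]), pos=int(d["pos"]),
                              ref=str(d["ref"]), alt=str(d["alt"])),
            gdna=counts["gdna"], tdna=counts["tdna"], ccfdna=counts["ccfdna"],
            truth_label=None if pd.isna(d["label"]) else str(d["label"]),
            true_af_tumor=None if pd.isna(d["true_af_tumor"]) else float(d["true_af_tumor"]),
            true_ctdna_fraction=(None if pd.isna(d["true_ctdna_fraction"])
                                 else float(d["true_ctdna_fraction"])),
        ))
    return records


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict:
    """Write a cohort as counts TSV + truth TSV + one trio VCF per patient.

    Deterministic ordering throughout; returns the written paths.
    """
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = cohort_to_frame(cohort)
    counts_path = out / "trio_counts.tsv"
    df.to_csv(counts_path, sep="\t", index=False)
    truth_path = out / "truth.tsv"
    df[["patient_id", "chrom", "pos", "ref", "alt", "label",
        "true_af_tumor", "true_ctdna_fraction"]].to_csv(truth_path, sep="\t", index=False)
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    vcf_paths = []
    contigs = sorted({r.chrom for r in cohort.spec.panel})
    for trio in cohort.trios:
        p = vcf_dir / f"{trio.patient_id}.vcf"
        _io.write_trio_vcf(trio.records, p, contigs=contigs)
        vcf_paths.append(p)
    return {"counts": counts_path, "truth": truth_path, "vcfs": vcf_paths}


def read_cohort_counts(path) -> list[TrioRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))
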