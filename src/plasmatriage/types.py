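"""Core domain types shared across the pipeline.

The atoms of the analysis are per-site, per-compartment read counts: every
filter, test, and tier decision downstream consumes a :class:`SiteCounts`
for one or more of the three compartments sequenced per patient — tumor DNA
(tDNA), whole-blood germline DNA (gDNA), and plasma cell-free DNA (ccfDNA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so 'chr19' and '19' compare equal."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class SiteCounts:
    """Read counts at one genomic site in one compartment.

    ``depth`` is the total read (or UMI-consensus) depth and ``alt`` the
    number of alt-supporting reads. Strand-split counts are optional; when
    present they must be consistent with the totals.
    """

    depth: int
    alt: int
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None
    ref_fwd: Optional[int] = None
    ref_rev: Optional[int] = None

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt < 0 or self.alt > self.depth:
            raise ValueError(f"invalid counts: alt={self.alt}, depth={self.depth}")
        if self.has_strand:
            if self.alt_fwd + self.alt_rev != self.alt:
                raise ValueError("alt_fwd + alt_rev must equal alt")
            if self.ref_fwd + self.ref_rev != self.depth - self.alt:
                raise ValueError("ref_fwd + ref_rev must equal depth - alt")

    @property
    def has_strand(self) -> bool:
        return None not in (self.alt_fwd, self.alt_rev, self.ref_fwd, self.ref_rev)

    @property
    def ref(self) -> int:
        return self.depth - self.alt

    @property
    def af(self) -> float:
        """Alt allele frequency alt/depth; NaN at zero depth (missing)."""
        if self.depth == 0:
            return math.nan
        return self.alt / self.depth


def allele_frequency(counts: SiteCounts) -> float:
    """Variant allele frequency alt/depth (NaN if depth is 0)."""
    return counts.af


def format_af(alt: int, depth: int, decimals: int) -> str:
    """Render alt/depth at a fixed number of decimals, as report tables print it."""
    if depth == 0:
        return "NA"
    return f"{alt / depth:.{decimals}f}"


@dataclass(frozen=True)
class VariantId:
    """Variant identity: coordinates when known, rsID as a fallback key.

    Report tables sometimes omit ref/alt or coordinates; matching between a
    record and a catalog therefore tries the coordinate key first and falls
    back to the rsID key.
    """

    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    rsid: Optional[str] = None

    def coord_key(self) -> Optional[tuple]:
        if self.chrom is None or self.pos is None:
            return None
        return (normalize_chrom(self.chrom), int(self.pos), self.ref, self.alt)

    def site_key(self) -> Optional[tuple]:
        """Coordinate key ignoring alleles (for tables that omit ref/alt)."""
        if self.chrom is None or self.pos is None:
            return None
        return (normalize_chrom(self.chrom), int(self.pos))


@dataclass
class TrioRecord:
    """One candidate variant with counts in up to three compartments."""

    patient_id: str
    diagnosis: str
    gene: str
    variant: VariantId
    gdna: Optional[SiteCounts] = None
    tdna: Optional[SiteCounts] = None
    ccfdna: Optional[SiteCounts] = None
    # ground truth, populated only by the simulator
    truth_label: Optional[str] = None  # germline | somatic | plasma_only
    true_af_tumor: Optional[float] = None
    true_ctdna_fraction: Optional[float] = None


class ClinSig(str, Enum):
    """Controlled vocabulary for clinical significance annotations."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC_LIKELY = "pathogenic/likely_pathogenic"
    UNCERTAIN = "uncertain"
    BENIGN = "benign"
    NONE = "none"


_CLINSIG_ALIASES = {
    "pathogenic": ClinSig.PATHOGENIC,
    "pathogenic fda recognized": ClinSig.PATHOGENIC,
    "likely pathogenic": ClinSig.LIKELY_PATHOGENIC,
    "likely_pathogenic": ClinSig.LIKELY_PATHOGENIC,
    "pathogenic/likely pathogenic": ClinSig.PATHOGENIC_LIKELY,
    "pathogenic/likely_pathogenic": ClinSig.PATHOGENIC_LIKELY,
    "uncertain significance": ClinSig.UNCERTAIN,
    "uncertain": ClinSig.UNCERTAIN,
    "benign": ClinSig.BENIGN,
    "likely benign": ClinSig.BENIGN,
    "-": ClinSig.NONE,
    "": ClinSig.NONE,
    "none": ClinSig.NONE,
}

PATHOGENIC_LIKE = {ClinSig.PATHOGENIC, ClinSig.LIKELY_PATHOGENIC, ClinSig.PATHOGENIC_LIKELY}


def parse_clinsig(value) -> ClinSig:
    if value is None:
        return ClinSig.NONE
    key = str(value).strip().lower()
    if key in ("nan",):
        return ClinSig.NONE
    try:
        return _CLINSIG_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown clinical significance label: {value!r}")


@dataclass
class AnnotationRecord:
    """Catalog entry for a variant: population AFs, clinical and somatic evidence."""

    variant: VariantId
    maf: Optional[float] = None
    af_1000g: Optional[float] = None
    af_gnomad: Optional[float] = None
    clinsig: ClinSig = ClinSig.NONE
    cosmic_registered: bool = False
    cosmic_cns_count: int = 0
    sift: Optional[float] = None
    coding: bool = True

    def max_population_af(self) -> Optional[float]:
        afs = [a for a in (self.maf, self.af_1000g, self.af_gnomad) if a is not None]
        return max(afs) if afs else None


@dataclass
class UMIFamily:
    """Reads sharing one unique molecular identifier at one site.

    ``members`` are allele observations ('ref'/'alt'), one per PCR duplicate.
    The consensus is the strict majority vote; an exact tie is ambiguous and
    the family is excluded from consensus counts.
    """

    umi: str
    site_key: tuple
    members: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def consensus(self) -> Optional[str]:
        n_alt = sum(1 for m in self.members if m == "alt")
        n_ref = self.size - n_alt
        if n_alt > n_ref:
            return "alt"
        if n_ref > n_alt:
            return "ref"
        return None


# --- diagnosis vocabulary -------------------------------------------------

GLIOMA_MARKERS = (
    "glioma",
    "glioblastoma",
    "astrocytoma",
    "oligodendroglioma",
    "oligoastrocytoma",
    "xanthoastrocytoma",
    "xantoastrocytoma",  # spelling as it appears in clinical records
)


def classify_diagnosis(label: str) -> str:
    """Map a free-text diagnosis to a class: glioma | pcnsl | metastasis | other.

    WHO-graded gliomas of any histology count as glioma; primary CNS lymphoma
    and metastatic carcinomas are separate classes.
    """
    text = str(label).lower()
    if "lymphoma" in text:
        return "pcnsl"
    if "metastasis" in text or "metastatic" in text:
        return "metastasis"
    if any(m in text for m in GLIOMA_MARKERS):
        return "glioma"
    return "other"
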