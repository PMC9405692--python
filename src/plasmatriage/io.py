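"""VCF serialization of trio count records (via pysam/htslib).

The dialect is deliberately minimal: one multi-sample VCF per patient with
sample columns gDNA, tDNA, ccfDNA and FORMAT fields DP (total depth) and AD
(ref, alt depths). Positions are 1-based, as in VCF.
"""

from __future__ import annotations

from typing import Sequence

import pysam

from .types import SiteCounts, TrioRecord, VariantId

_SAMPLES = ("gDNA", "tDNA", "ccfDNA")


def _trio_header(contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in contigs:
        header.contigs.add(c)
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.info.add("GENE", 1, "String", "Panel gene label")
    for s in _SAMPLES:
        header.add_sample(s)
    return header


def write_trio_vcf(records: Sequence[TrioRecord], path, contigs: Sequence[str] | None = None) -> None:
    if contigs is None:
        contigs = sorted({r.variant.chrom for r in records})
    header = _trio_header(contigs)
    ordered = sorted(records, key=lambda r: (r.variant.chrom, r.variant.pos,
                                             r.variant.ref or "", r.variant.alt or ""))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in ordered:
            rec = vcf.new_record(contig=r.variant.chrom, start=r.variant.pos - 1,
                                 alleles=(r.variant.ref, r.variant.alt))
            rec.info["GENE"] = r.gene
            for sample, counts in zip(_SAMPLES, (r.gdna, r.tdna, r.ccfdna)):
                if counts is None:
                    continue
                rec.samples[sample]["DP"] = counts.depth
                rec.samples[sample]["AD"] = (counts.ref, counts.alt)
            vcf.write(rec)


def read_trio_vcf(path, patient_id: str = "", diagnosis: str = "") -> list[TrioRecord]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            counts = {}
            for sample in _SAMPLES:
                fmt = rec.samples[sample]
                dp = fmt.get("DP")
                ad = fmt.get("AD")
                if dp is None or ad is None:
                    counts[sample] = None
                else:
                    counts[sample] = SiteCounts(depth=int(dp), alt=int(ad[1]))
            out.append(TrioRecord(
                patient_id=patient_id, diagnosis=diagnosis,
                gene=str(rec.info.get("GENE", "")),
                variant=VariantId(chrom=rec.contig, pos=rec.pos,
                                  ref=rec.ref, alt=rec.alts[0] if rec.alts else None),
                gdna=counts["gDNA"], tdna=counts["tDNA"], ccfdna=counts["ccfDNA"],
            ))
    return out
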