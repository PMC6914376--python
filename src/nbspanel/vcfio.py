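"""File I/O: FASTA reference contigs, VCF v4.2 call sets, depth tables.

VCF handling is backed by pysam (htslib); FASTA by Biopython. Site metadata
the package owns is carried in FORMAT fields: GT, AF (allele fraction,
4 d.p.), DP (depth), SAF/SAR (per-strand depths) and STB (strand bias,
4 d.p.). QUAL holds the caller's variant score. Values are quantized to
those precisions on read so that write -> read round-trips records exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import MalformedInputError
from .reference import ReferenceSequence
from .variants import HET, HOM, UNKNOWN, RawVariantCall, VariantRecord


def write_fasta(refs: Mapping[str, ReferenceSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=name, description="") for name, r in refs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, ReferenceSequence]:
    return {
        rec.id: ReferenceSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    }


_HEADER_LINES = [
    '##INFO=<ID=FR,Number=1,Type=String,Description="Filter reason for rejected calls">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=SAF,Number=1,Type=Integer,Description="Forward-strand depth">',
    '##FORMAT=<ID=SAR,Number=1,Type=Integer,Description="Reverse-strand depth">',
    '##FORMAT=<ID=STB,Number=1,Type=Float,Description="Strand bias">',
]


def _build_header(contigs: Mapping[str, int], sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    for line in _HEADER_LINES:
        header.add_line(line)
    header.add_sample(sample_id)
    return header


_GT_BY_GENOTYPE = {HET: (0, 1), HOM: (1, 1), UNKNOWN: (None, None)}


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    contigs: Mapping[str, int],
    sample_id: str = "SAMPLE",
    filter_reasons: Mapping[tuple[str, int, str, str], str] | None = None,
) -> None:
    """Write biallelic records as a single-sample VCF.

    ``filter_reasons`` optionally maps a record key to a rejection reason,
    written into the FILTER column (used for rejected-call output).
    """
    header = _build_header(contigs, sample_id)
    if filter_reasons:
        for reason in sorted(set(filter_reasons.values())):
            header.add_line(f'##FILTER=<ID={reason},Description="Rejected: {reason}">')
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in records:
            rec = vf.new_record(
                contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt), qual=v.qual
            )
            sample = rec.samples[sample_id]
            sample["GT"] = _GT_BY_GENOTYPE[v.genotype]
            sample["AF"] = (v.allele_fraction,)
            sample["DP"] = v.depth
            sample["SAF"], sample["SAR"] = v.depth_per_strand
            sample["STB"] = v.strand_bias
            if filter_reasons and v.key in filter_reasons:
                rec.filter.add(filter_reasons[v.key])
            vf.write(rec)


def _q(x: float | None, ndigits: int, default: float) -> float:
    return default if x is None else round(float(x), ndigits)


def read_vcf(path: str | Path) -> list[RawVariantCall]:
    """Read a (possibly multi-allelic) single-sample VCF into raw calls."""
    out: list[RawVariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise MalformedInputError(f"expected a single-sample VCF, found {len(samples)} samples")
        for rec in vf:
            if rec.alts is None:
                continue
            sample = rec.samples[samples[0]]
            gt = sample.get("GT", (None, None))
            af = sample.get("AF")
            saf = sample.get("SAF")
            sar = sample.get("SAR")
            out.append(
                RawVariantCall(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts),
                    genotype_indices=tuple(gt) if gt is not None else (None, None),
                    qual=_q(rec.qual, 3, 0.0),
                    allele_fractions=(
                        tuple(_q(a, 4, 0.5) for a in af) if af is not None else None
                    ),
                    depth=int(sample.get("DP") or 0),
                    depth_per_strand=(int(saf or 0), int(sar or 0)),
                    strand_bias=_q(sample.get("STB"), 4, 0.0),
                )
            )
    return out


def read_vcf_records(path: str | Path) -> list[VariantRecord]:
    """Read a VCF whose rows are already biallelic into VariantRecords."""
    from .variants import decompose

    out: list[VariantRecord] = []
    for raw in read_vcf(path):
        if len(raw.alts) != 1:
            raise MalformedInputError(
                f"expected biallelic records, found {len(raw.alts)} alts at {raw.contig}:{raw.pos}"
            )
        out.extend(decompose(raw))
    return out


def contig_lengths(refs: Mapping[str, ReferenceSequence]) -> dict[str, int]:
    return {name: len(r) for name, r in refs.items()}
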