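"""Variant decomposition and left-align/trim normalization.

Builds a tiny contig with a CA repeat and a poly-T run, then shows how
different written forms of the same edit converge to one canonical record.
"""

from nbspanel import RawVariantCall, ReferenceSequence, VariantRecord, decompose, normalize

ref = ReferenceSequence("demo", "GGGCACACACTTTTTTC")

# a multi-allelic row splits into one biallelic record per alternate allele
raw = RawVariantCall("demo", 4, "C", ("A", "T"), genotype_indices=(1, 2))
for rec in decompose(raw):
    print(f"decomposed: {rec.contig}:{rec.pos} {rec.ref}>{rec.alt} ({rec.genotype})")

# two offsets of the same repeat-tract deletion normalize to the same key
for pos in (4, 6):
    v = VariantRecord("demo", pos, "CACA", "CA")
    n = normalize(v, ref)
    print(f"{v.pos}:{v.ref}>{v.alt}  ->  {n.pos}:{n.ref}>{n.alt}")

# The printed records share position 3 and alleles GCA>G: equivalent
# representations become identical, so call sets can be compared key-by-key.
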