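"""Decomposition, normalization and homopolymer context."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbspanel import (
    RawVariantCall,
    ReferenceSequence,
    VariantRecord,
    apply_variant,
    decompose,
    homopolymer_length,
    normalize,
    normalize_records,
    split_mnp,
)
from nbspanel.errors import (
    BoundsError,
    LeftExtensionError,
    MalformedInputError,
    ReferenceMismatchError,
)

from oracle import canonical_by_enumeration, apply_edit


class TestDecompose:
    def test_multiallelic_split(self):
        raw = RawVariantCall("c", 100, "A", ("G", "T"), genotype_indices=(1, 2))
        out = decompose(raw)
        assert [(v.pos, v.ref, v.alt, v.genotype) for v in out] == [
            (100, "A", "G", "het"),
            (100, "A", "T", "het"),
        ]

    def test_biallelic_hom_identity(self):
        out = decompose(RawVariantCall("c", 100, "A", ("G",), genotype_indices=(1, 1)))
        assert [(v.pos, v.ref, v.alt, v.genotype) for v in out] == [(100, "A", "G", "hom")]

    def test_alts_carried_through_unchanged(self):
        # normalization is a separate step: each alt keeps the shared ref
        out = decompose(RawVariantCall("c", 50, "AC", ("GC", "A"), genotype_indices=(1, 2)))
        assert [(v.pos, v.ref, v.alt, v.genotype) for v in out] == [
            (50, "AC", "GC", "het"),
            (50, "AC", "A", "het"),
        ]

    def test_absent_allele_is_unknown(self):
        out = decompose(RawVariantCall("c", 10, "A", ("G", "T"), genotype_indices=(1, 1)))
        assert [v.genotype for v in out] == ["hom", "unknown"]

    def test_genotype_index_out_of_range(self):
        with pytest.raises(MalformedInputError):
            decompose(RawVariantCall("c", 10, "A", ("G",), genotype_indices=(1, 2)))

    def test_allele_multiset_preserved(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 4))
            alts = tuple(
                "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
                for _ in range(n)
            )
            alts = tuple(a if a != "A" else "AC" for a in alts)  # keep alt != ref
            raw = RawVariantCall("c", 5, "A", alts,
                                 genotype_indices=(int(rng.integers(0, n + 1)),
                                                   int(rng.integers(0, n + 1))))
            assert [v.alt for v in decompose(raw)] == list(alts)


class TestNormalize:
    def test_snv_fixed_point(self, polyt_contig):
        v = VariantRecord("c1", 2, "T", "A")
        assert normalize(v, polyt_contig) == v

    def test_left_align_deletion_in_repeat(self):
        # frozen from the enumeration oracle over contig GGGCACACACT
        ref = ReferenceSequence("c", "GGGCACACACT")
        got = normalize(VariantRecord("c", 4, "CACA", "CA"), ref)
        assert (got.pos, got.ref, got.alt) == (3, "GCA", "G")
        assert canonical_by_enumeration("GGGCACACACT", 4, "CACA", "CA") == (3, "GCA", "G")

    def test_left_align_insertion_in_polyt(self, polyt_contig):
        got = normalize(VariantRecord("c1", 7, "T", "TT"), polyt_contig)
        assert (got.pos, got.ref, got.alt) == (1, "G", "GT")
        assert canonical_by_enumeration("GTTTTTTC", 7, "T", "TT") == (1, "G", "GT")

    def test_reference_mismatch(self, polyt_contig):
        with pytest.raises(ReferenceMismatchError):
            normalize(VariantRecord("c1", 2, "A", "G"), polyt_contig)

    def test_left_extension_error_at_contig_start(self):
        ref = ReferenceSequence("c", "TTTTA")
        with pytest.raises(LeftExtensionError):
            normalize(VariantRecord("c", 2, "T", "TT"), ref)

    def test_idempotent_and_equivalent_on_random_indels(self, rng):
        """Apply-and-compare: the normalized record produces the identical
        edited sequence, twice normalizing changes nothing, and the result is
        the leftmost minimal representation by exhaustive enumeration."""
        checked = 0
        for _ in range(300):
            alphabet = ["ACGT", "AT", "CT"][int(rng.integers(3))]
            contig = "".join(rng.choice(list(alphabet), size=int(rng.integers(10, 40))))
            pos = int(rng.integers(2, len(contig) - 3))
            kind = int(rng.integers(3))
            if kind == 0:  # SNV
                r = contig[pos - 1]
                a = str(rng.choice([b for b in "ACGT" if b != r]))
            elif kind == 1:  # insertion
                r = contig[pos - 1]
                a = r + "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            else:  # deletion
                dlen = int(rng.integers(1, min(4, len(contig) - pos)))
                r = contig[pos - 1 : pos + dlen]
                a = r[0]
            v = VariantRecord("c", pos, r, a)
            ref = ReferenceSequence("c", contig)
            expected = canonical_by_enumeration(contig, pos, r, a)
            try:
                got = normalize(v, ref)
            except LeftExtensionError:
                assert expected is None
                continue
            assert apply_variant(contig, got.pos, got.ref, got.alt) == apply_edit(
                contig, pos, r, a
            )
            assert normalize(got, ref) == got
            assert (got.pos, got.ref, got.alt) == expected
            checked += 1
        assert checked > 200

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(data=st.data())
    def test_property_apply_and_compare(self, data):
        contig = data.draw(st.text(alphabet="ACT", min_size=8, max_size=25))
        pos = data.draw(st.integers(2, len(contig) - 2))
        r = contig[pos - 1]
        a = data.draw(st.sampled_from([r + "A", r + "T", "G" if r != "G" else "C"]))
        ref = ReferenceSequence("c", contig)
        v = VariantRecord("c", pos, r, a)
        try:
            got = normalize(v, ref)
        except LeftExtensionError:
            assert canonical_by_enumeration(contig, pos, r, a) is None
            return
        assert apply_variant(contig, got.pos, got.ref, got.alt) == apply_variant(
            contig, pos, r, a
        )
        assert (got.pos, got.ref, got.alt) == canonical_by_enumeration(contig, pos, r, a)


class TestSplitMnp:
    def test_mnp_becomes_per_base_snvs(self):
        v = VariantRecord("c", 10, "ACG", "ATG", genotype="het")
        out = split_mnp(v)
        assert [(x.pos, x.ref, x.alt) for x in out] == [(11, "C", "T")]

    def test_full_mnp(self):
        out = split_mnp(VariantRecord("c", 5, "AC", "GT"))
        assert [(x.pos, x.ref, x.alt) for x in out] == [(5, "A", "G"), (6, "C", "T")]

    def test_indel_untouched(self):
        v = VariantRecord("c", 5, "AC", "A")
        assert split_mnp(v) == [v]

    def test_normalize_records_canonicalizes_mnp(self):
        ref = ReferenceSequence("c", "AACGTT")
        out = normalize_records([VariantRecord("c", 2, "ACG", "ATG")], ref)
        assert [(x.pos, x.ref, x.alt) for x in out] == [(3, "C", "T")]


class TestHomopolymerLength:
    @pytest.mark.parametrize(
        "seq,pos,expected",
        [("GTTTTTTC", 4, 6), ("ACGT", 2, 1), ("AAAA", 1, 4), ("GTTTTTTC", 1, 1), ("GTTTTTTC", 8, 1)],
    )
    def test_run_lengths(self, seq, pos, expected):
        assert homopolymer_length(ReferenceSequence("c", seq), pos) == expected

    def test_out_of_range(self):
        with pytest.raises(BoundsError):
            homopolymer_length(ReferenceSequence("c", "ACGT"), 5)
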