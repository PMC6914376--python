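"""Synthetic-cohort generator: determinism, ledger consistency, scale."""

import dataclasses

import pytest

from nbspanel import (
    build_panel,
    compare_to_truth,
    homopolymer_length,
    make_reference,
    make_truth_and_calls,
    normalize,
    write_cohort,
)
from nbspanel.errors import ConfigError
from nbspanel.simulate import SimulationConfig


class TestReference:
    def test_deterministic_under_seed(self, small_config):
        a = make_reference(small_config)
        b = make_reference(small_config)
        assert {k: r.sequence for k, r in a.references.items()} == {
            k: r.sequence for k, r in b.references.items()
        }
        assert a.exons == b.exons and a.str_regions == b.str_regions

    def test_declared_tracts_present(self, small_config):
        synref = make_reference(small_config)
        # intronic poly-T run has exactly the configured length
        hp = [iv for iv in synref.homopolymer_regions
              if iv.length == small_config.polyt_intronic_len][0]
        ref = synref.references[hp.contig]
        assert homopolymer_length(ref, hp.start + 1) == small_config.polyt_intronic_len
        # exonic poly-T run is exactly the configured (filter-passing) length
        contig, pos1, length = synref.polyt_site
        assert homopolymer_length(synref.references[contig], pos1) == length
        # STR region contains the repeated unit
        (str_iv,) = synref.str_regions
        seq = synref.references[str_iv.contig].sequence[str_iv.start:str_iv.end]
        assert seq == small_config.str_unit * small_config.str_repeats

    def test_no_accidental_long_homopolymers(self, small_config):
        synref = make_reference(small_config)
        declared = {(iv.contig, p) for iv in synref.homopolymer_regions
                    for p in range(iv.start, iv.end)}
        for name, ref in synref.references.items():
            run = 1
            for i in range(1, len(ref)):
                run = run + 1 if ref.sequence[i] == ref.sequence[i - 1] else 1
                assert run <= 6 or (name, i) in declared

    def test_panel_scale_contract(self):
        cfg = SimulationConfig(seed=5)
        synref = make_reference(cfg)
        panel = build_panel(synref.exons, cfg.panel_padding)
        assert abs(panel.total_bases - cfg.target_panel_bases) <= 0.05 * cfg.target_panel_bases

    def test_gc_fraction_plausible(self, small_config):
        synref = make_reference(small_config)
        seq = "".join(r.sequence for r in synref.references.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.45 <= gc <= 0.55


class TestCohort:
    def test_truth_records_are_normalized(self, small_cohort):
        for v in small_cohort.truth:
            ref = small_cohort.reference.references[v.contig]
            assert normalize(v, ref) == v

    def test_calls_equal_truth_minus_fn_plus_fp(self, small_cohort):
        truth_keys = {v.key for v in small_cohort.truth}
        for sid, calls in small_cohort.calls.items():
            entry = small_cohort.ledger.samples[sid]
            fn_keys = {tuple(d["key"]) for d in entry["fn"]}
            fp_keys = {tuple(d["key"]) for d in entry["fp"]}
            assert {v.key for v in calls} == (truth_keys - fn_keys) | fp_keys

    def test_compare_to_truth_recovers_ledger(self, small_cohort):
        for sid, calls in small_cohort.calls.items():
            entry = small_cohort.ledger.samples[sid]
            cm = compare_to_truth(calls, small_cohort.truth, small_cohort.panel)
            assert cm.fn == len(entry["fn"])
            assert cm.fp == len(entry["fp"])
            assert cm.tp == len(small_cohort.truth) - cm.fn

    def test_error_free_config_gives_identical_calls(self, small_config):
        cfg = dataclasses.replace(small_config, p_fn_low=0.0, p_fn_high=0.0,
                                  p_fp_snv=0.0, p_fp_indel_polyt=0.0, n_pairs=1)
        synref = make_reference(cfg)
        panel = build_panel(synref.exons, cfg.panel_padding)
        cohort = make_truth_and_calls(cfg, synref, panel)
        truth_keys = {v.key for v in cohort.truth}
        for calls in cohort.calls.values():
            assert {v.key for v in calls} == truth_keys

    def test_emitted_fp_representations_normalize_back(self, small_cohort):
        for sid, emitted in small_cohort.emitted_calls.items():
            canonical = {v.key for v in small_cohort.calls[sid]}
            got = set()
            for v in emitted:
                ref = small_cohort.reference.references[v.contig]
                got.add(normalize(v, ref).key)
            assert got == canonical

    def test_capacity_error(self):
        cfg = SimulationConfig(
            seed=0, n_genes=1, exons_per_gene=(3,), target_panel_bases=600,
            n_truth_snvs=200, n_truth_indels=0, n_pairs=1,
        )
        with pytest.raises(ConfigError):
            synref = make_reference(cfg)
            panel = build_panel(synref.exons, cfg.panel_padding)
            make_truth_and_calls(cfg, synref, panel)


class TestEmission:
    def test_files_byte_identical_across_reruns(self, small_config, tmp_path):
        from nbspanel import make_truth_and_calls

        cfg = dataclasses.replace(small_config, n_pairs=1)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            synref = make_reference(cfg)
            panel = build_panel(synref.exons, cfg.panel_padding)
            write_cohort(make_truth_and_calls(cfg, synref, panel), out)
        for rel in ["reference.fasta", "panel.bed", "truth.vcf", "ledger.json",
                    "calls/DBS01.vcf", "depth/VB01.depth.tsv"]:
            assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes(), rel

    def test_ledger_round_trip_and_consistency(self, small_config, tmp_path):
        """Re-parsing the emitted files and recomputing set differences
        against truth reproduces the ledger exactly."""
        from nbspanel import GroundTruthLedger, make_truth_and_calls
        from nbspanel.pipeline import prepare_calls
        from nbspanel import vcfio
        from nbspanel.panel import read_bed

        cfg = dataclasses.replace(small_config, n_pairs=2)
        synref = make_reference(cfg)
        panel = build_panel(synref.exons, cfg.panel_padding)
        cohort = make_truth_and_calls(cfg, synref, panel)
        write_cohort(cohort, tmp_path)
        ledger = GroundTruthLedger.from_json((tmp_path / "ledger.json").read_text())
        refs = vcfio.read_fasta(tmp_path / "reference.fasta")
        panel_back = read_bed(tmp_path / "panel.bed")
        truth_keys = {tuple(k) for k in ledger.truth_keys}
        for sid in cohort.calls:
            records = prepare_calls(
                vcfio.read_vcf(tmp_path / "calls" / f"{sid}.vcf"), refs, panel_back,
                label=sid,
            )
            keys = {v.key for v in records}
            entry = ledger.samples[sid]
            assert truth_keys - keys == {tuple(d["key"]) for d in entry["fn"]}
            assert keys - truth_keys == {tuple(d["key"]) for d in entry["fp"]}
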