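"""Paired-sample concordance and coverage stratification."""

import numpy as np
import pytest

from nbspanel import (
    ConcordancePolicy,
    CoverageTrack,
    VariantRecord,
    cohort_concordance,
    compare_pair,
)
from nbspanel.errors import ConfigError, DataIntegrityError


def snv(pos, alt="G"):
    return VariantRecord("c", pos, "A", alt)


def track(depth=100, size=200, sample_id="s", overrides=()):
    arr = np.full(size, depth, dtype=np.int64)
    for pos0, d in dict(overrides).items():
        arr[int(pos0)] = d
    return CoverageTrack(sample_id, {"c": arr})


class TestComparePair:
    def test_union_denominator(self):
        a = [snv(1), snv(2), snv(3)]
        b = [snv(1), snv(2), snv(4)]
        pc = compare_pair(a, b, track(), track())
        assert pc.concordance_all_pct == 50.0  # 2 of 4 union variants
        assert len(pc.events) == 2
        assert pc.n_calls_total == 6

    def test_identical_sets(self):
        a = [snv(1), snv(2)]
        pc = compare_pair(a, list(a), track(), track())
        assert pc.concordance_all_pct == 100.0 and pc.events == []

    def test_low_coverage_variant_excluded_from_high_stratum(self):
        a = [snv(1), snv(2)]
        b = [snv(2)]
        ta = track(overrides={0: 10})  # v1 at depth 10 in A
        pc = compare_pair(a, b, ta, track())
        assert pc.concordance_all_pct == 50.0
        assert pc.concordance_high_cov_pct == 100.0
        (e,) = pc.events
        assert e.stratum == "low" and e.direction == "only_in_A"
        assert (e.coverage_a, e.coverage_b) == (10, 100)

    def test_stratum_uses_minimum_of_both_depths(self):
        pc = compare_pair([snv(5)], [], track(overrides={4: 100}), track(overrides={4: 20}))
        assert pc.events[0].stratum == "low"

    def test_symmetry(self):
        a = [snv(1), snv(2), snv(3)]
        b = [snv(2), snv(4)]
        ab = compare_pair(a, b, track(), track())
        ba = compare_pair(b, a, track(), track())
        assert ab.concordance_all_pct == ba.concordance_all_pct
        assert ab.concordance_high_cov_pct == ba.concordance_high_cov_pct
        flipped = {"only_in_A": "only_in_B", "only_in_B": "only_in_A"}
        assert [flipped[e.direction] for e in ab.events] == [e.direction for e in ba.events]

    def test_missing_depth_errors(self):
        other = CoverageTrack("s", {"other_contig": np.full(10, 50)})
        with pytest.raises(DataIntegrityError):
            compare_pair([snv(1)], [], other, track())

    def test_mean_denominator_option(self):
        a = [snv(1), snv(2), snv(3)]
        b = [snv(1)]
        pc = compare_pair(a, b, track(), track(), ConcordancePolicy(denominator="mean"))
        assert pc.concordance_all_pct == pytest.approx(100 * 2 * 1 / 4)

    def test_per_category_counts_sum_to_events(self):
        a = [snv(1), snv(2), VariantRecord("c", 9, "AT", "A")]
        b = [snv(2), snv(7)]
        pc = compare_pair(a, b, track(overrides={0: 5}), track())
        assert sum(pc.per_category_counts.values()) == len(pc.events) == 3
        assert pc.per_category_counts[("only_in_A", "indel", "high")] == 1


class TestCohort:
    def test_mean_of_pairs(self):
        p1 = compare_pair([snv(1)], [snv(1)], track(), track(), pair_id="p1")
        p2 = compare_pair([snv(1), snv(2)], [snv(1), snv(3)], track(), track(), pair_id="p2")
        summary = cohort_concordance([p1, p2])
        assert summary["mean_concordance_all_pct"] == pytest.approx((100.0 + 100 / 3) / 2)
        assert summary["n_pairs"] == 2

    def test_single_pair_identity(self):
        p = compare_pair([snv(1), snv(2)], [snv(2)], track(), track())
        summary = cohort_concordance([p])
        assert summary["mean_concordance_all_pct"] == p.concordance_all_pct

    def test_empty_cohort_errors(self):
        with pytest.raises(ConfigError):
            cohort_concordance([])


class TestLedgerRecovery:
    def test_pooled_counts_equal_injected(self, small_cohort):
        """Pooled discordance recovered from the call sets matches the
        generator's ledger exactly, pair by pair, stratum by stratum."""
        results = []
        for pair_id, sid_a, sid_b in small_cohort.pair_ids:
            pc = compare_pair(
                small_cohort.calls[sid_a], small_cohort.calls[sid_b],
                small_cohort.depths[sid_a], small_cohort.depths[sid_b],
                pair_id=pair_id,
            )
            results.append(pc)
            ledger_pair = next(
                p for p in small_cohort.ledger.pairs if p["pair_id"] == pair_id
            )
            got = sorted(
                (tuple(e.variant.key), e.direction, e.variant_class, e.stratum)
                for e in pc.events
            )
            expected = sorted(
                (tuple(d["key"]), d["direction"], d["variant_class"], d["stratum"])
                for d in ledger_pair["discordant"]
            )
            assert got == expected
        summary = cohort_concordance(results)
        n_injected = sum(len(p["discordant"]) for p in small_cohort.ledger.pairs)
        assert summary["n_discordant_total"] == n_injected

    def test_high_stratum_clean_when_errors_confined_to_low(self, small_config):
        """With false negatives only in low-coverage regions, high-coverage
        concordance is exactly 100% while all-region concordance drops."""
        import dataclasses

        from nbspanel import build_panel, make_reference, make_truth_and_calls

        cfg = dataclasses.replace(
            small_config, p_fn_high=0.0, p_fp_snv=0.0, p_fp_indel_polyt=0.0,
            p_fn_low=0.6, n_pairs=3,
        )
        synref = make_reference(cfg)
        panel = build_panel(synref.exons, cfg.panel_padding)
        cohort = make_truth_and_calls(cfg, synref, panel)
        any_discordant = False
        for _, sid_a, sid_b in cohort.pair_ids:
            pc = compare_pair(
                cohort.calls[sid_a], cohort.calls[sid_b],
                cohort.depths[sid_a], cohort.depths[sid_b],
            )
            assert pc.concordance_high_cov_pct == 100.0
            any_discordant |= pc.concordance_all_pct < 100.0
        assert any_discordant
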