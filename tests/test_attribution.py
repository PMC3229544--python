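"""Hypergeometric attribution, BH adjustment and derived DE sets."""

from math import comb

import pytest

import probedex as px
from probedex.align import AlignmentHit
from probedex.attribution import AttributionRecord

from conftest import oracle_bh, oracle_hypergeom_tail


def _record(tx, profile, p_adj, x_a=5, a_size=10, x_t=9, t=100, p_raw=None):
    return AttributionRecord(tx, profile, x_a, a_size, x_t, t,
                             p_raw if p_raw is not None else p_adj, p_adj)


class TestHypergeomTail:
    def test_zero_observed_is_whole_support(self):
        assert px.hypergeom_tail(0, 5, 9, 20) == 1.0

    def test_drawing_everything_is_certain(self):
        assert px.hypergeom_tail(7, 20, 7, 20) == pytest.approx(1.0)

    def test_derived_example(self):
        # T=20, X_T=9, A=5, X_A=4: 1512 of the 15504 5-subsets carry >= 4 marked
        expected = (comb(9, 4) * comb(11, 1) + comb(9, 5)) / comb(20, 5)
        assert px.hypergeom_tail(4, 5, 9, 20) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1512 / 15504)

    def test_invalid_counts_rejected(self):
        with pytest.raises(px.InputError):
            px.hypergeom_tail(6, 5, 9, 20)  # X_A > A
        with pytest.raises(px.InputError):
            px.hypergeom_tail(1, 5, 21, 20)  # X_T > T

    def test_matches_enumeration_on_small_universes(self):
        for t in (5, 8):
            for x_t in range(t + 1):
                for a in range(t + 1):
                    for x_a in range(min(a, x_t) + 1):
                        assert px.hypergeom_tail(x_a, a, x_t, t) == pytest.approx(
                            oracle_hypergeom_tail(x_a, a, x_t, t), abs=1e-12
                        )


class TestAttribute:
    def _index(self, hits, probe_ids):
        return px.build_probe_index(hits, probe_ids)

    def test_seven_of_nine_probes_example(self):
        # transcript with 9 probes, 7 sharing a down-regulated profile in a
        # cluster of exactly those 7, among T=100 retained probes
        hits = [AlignmentHit(f"g{i}", "tx1", 1, 25, 25) for i in range(9)]
        hits += [AlignmentHit(f"o{i}", f"other{i}", 1, 25, 25) for i in range(91)]
        index = self._index(hits, [h.probe_id for h in hits])
        clusters = {
            "EEEEELL": {f"g{i}" for i in range(7)},
            "EEEEEEE": {"g7", "g8"} | {f"o{i}" for i in range(91)},
        }
        records = px.attribute(clusters, index)
        rec = next(r for r in records if r.transcript == "tx1")
        assert (rec.x_a, rec.a_size, rec.x_t, rec.t) == (7, 7, 9, 100)
        assert rec.p_raw == pytest.approx(comb(9, 7) / comb(100, 7), rel=1e-12)
        assert rec.p_raw < 0.001

    def test_all_E_profile_not_tested(self):
        hits = [AlignmentHit("p1", "tx1", 1, 25, 25), AlignmentHit("p2", "tx1", 1, 25, 25)]
        index = self._index(hits, ["p1", "p2"])
        records = px.attribute({"EEEEEEE": {"p1", "p2"}}, index)
        assert records == []

    def test_multimapper_contributes_to_both_transcripts(self):
        hits = [
            AlignmentHit("p1", "tx1", 1, 25, 25),
            AlignmentHit("p1", "tx2", 1, 25, 25),
            AlignmentHit("p2", "tx1", 1, 25, 25),
        ]
        index = self._index(hits, ["p1", "p2"])
        records = px.attribute({"HEE": {"p1"}, "EEE": {"p2"}}, index)
        assert {(r.transcript, r.x_a) for r in records} == {("tx1", 1), ("tx2", 1)}

    def test_universe_mismatch_rejected(self):
        hits = [AlignmentHit("p1", "tx1", 1, 25, 25)]
        index = self._index(hits, ["p1"])
        with pytest.raises(px.InputError):
            px.attribute({"HEE": {"p1", "phantom"}}, index)

    def test_partition_conservation(self, noiseless_result):
        """For every transcript the per-profile counts sum to X^T."""
        per_tx: dict[str, int] = {}
        for r in noiseless_result.records:
            per_tx[r.transcript] = per_tx.get(r.transcript, 0) + r.x_a
        # records exclude the all-E cluster; add those members back
        all_e = noiseless_result.clusters.get("E" * 7, set())
        for tx, x_t in noiseless_result.index.targets.items():
            e_probes = sum(1 for p in all_e if tx in noiseless_result.index.hits[p])
            assert per_tx.get(tx, 0) + e_probes == x_t


class TestBH:
    def test_step_up_examples(self):
        assert px.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert px.bh_adjust([0.005, 0.1, 0.2]) == pytest.approx([0.015, 0.15, 0.2])

    def test_single_p_unchanged(self):
        assert px.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_invalid_p_rejected(self):
        with pytest.raises(px.InputError):
            px.bh_adjust([0.5, 0.0])
        with pytest.raises(px.InputError):
            px.bh_adjust([1.5])

    def test_matches_independent_step_up(self):
        import numpy as np

        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
            assert px.bh_adjust(p) == pytest.approx(oracle_bh(p), abs=1e-12)


class TestDECalls:
    def test_inclusion_by_letter_and_position(self):
        records = [_record("tx1", "EEEHEEE", 0.01)]
        calls = px.call_de(records, 0.05, position=4, letter="H")
        assert [c.transcript for c in calls] == ["tx1"]
        assert px.call_de(records, 0.05, position=4, letter="L") == []

    def test_threshold_is_strict(self):
        records = [_record("tx1", "EEEHEEE", 0.05)]
        assert px.call_de(records, 0.05, position=4, letter="H") == []

    def test_empty_when_nothing_significant(self):
        records = [_record("tx1", "EEEHEEE", 0.2)]
        assert px.call_de(records, 0.05, position=4, letter="H") == []

    def test_conflicting_letters_resolve_to_minimal_p(self):
        records = [
            _record("tx1", "EEEHEEE", 0.01),
            _record("tx1", "EEELEEE", 0.03),
        ]
        h_calls = px.call_de(records, 0.05, position=4, letter="H")
        assert len(h_calls) == 1 and h_calls[0].ambiguous
        assert px.call_de(records, 0.05, position=4, letter="L") == []

    def test_position_outside_plan_rejected(self):
        with pytest.raises(px.InputError):
            px.call_de([_record("tx1", "EEEHEEE", 0.01)], 0.05, position=9, letter="H")


class TestEffectSize:
    def test_noiseless_signs_follow_truth(self, noiseless_bundle, noiseless_result):
        b, res = noiseless_bundle, noiseless_result
        for tx, prof in b.truth.true_profile.items():
            for pos, letter in enumerate(prof, start=1):
                if letter == "E":
                    continue
                eff = px.effect_size(tx, prof, pos, res.ranks, b.plan, res.index, res.clusters)
                assert (eff > 0) == (letter == "H")
                assert -1 < eff < 1

    def test_letter_E_position_is_contract_error(self, noiseless_bundle, noiseless_result):
        b, res = noiseless_bundle, noiseless_result
        tx, prof = next(iter(b.truth.true_profile.items()))
        pos = prof.index("E") + 1
        with pytest.raises(px.InputError):
            px.effect_size(tx, prof, pos, res.ranks, b.plan, res.index, res.clusters)


class TestRankingAndContrasts:
    def test_product_ranking_order_and_intersection(self):
        wt = [_record("a", "EEEHEEE", 0.001), _record("b", "EEEHEEE", 0.02),
              _record("c", "EEEHEEE", 0.01)]
        null = [_record("a", "EEEEEHE", 0.01), _record("b", "EEEEEHE", 0.02)]
        ranked = px.p_product_ranking(wt, null, [(4, 6)])[(4, 6)]
        # c is DE only in wt -> excluded; a: 1e-5 < b: 4e-4
        assert [t for t, _ in ranked] == ["a", "b"]
        assert ranked[0][1] == pytest.approx(1e-5)

    def test_equal_products_tie_break_on_id(self):
        wt = [_record("b", "EEEHEEE", 0.01), _record("a", "EEEHEEE", 0.01)]
        null = [_record("b", "EEEEEHE", 0.01), _record("a", "EEEEEHE", 0.01)]
        ranked = px.p_product_ranking(wt, null, [(4, 6)])[(4, 6)]
        assert [t for t, _ in ranked] == ["a", "b"]

    def test_contrast_membership(self):
        records = [
            _record("cons", "EHHEEEE", 0.01),
            _record("only90", "EHEEEEE", 0.01),
            _record("only24", "EELEEEE", 0.01),
            _record("naive", "LEEEEEE", 0.01),
            _record("naive", "EHHEEEE", 0.02),  # naive beats consistent
        ]
        cs = px.contrast_sets(records, 0.05)
        assert set(cs.consistent) == {"cons"} and cs.consistent["cons"] == "H"
        assert set(cs.only_90) == {"only90"}
        assert set(cs.only_24) == {"only24"}
        assert set(cs.naive_diff) == {"naive"}
        assert not set(cs.consistent) & set(cs.naive_diff)
        assert not set(cs.only_90) & set(cs.only_24)

    def test_short_plan_lacks_genotype_positions(self):
        with pytest.raises(px.ConfigError):
            px.contrast_sets([_record("a", "HE", 0.01)], 0.05)
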