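"""Rank normalization, the exact rank test and expression strings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import probedex as px
from probedex.stats import mw_exact_matrix

from conftest import oracle_mw_tails


def _matrix(values, design, probe_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if probe_ids is None:
        probe_ids = [f"p{i}" for i in range(values.shape[0])]
    return px.IntensityMatrix(
        pd.DataFrame(values, index=probe_ids, columns=design.array_ids), design
    )


def _tiny_design(n):
    return px.ExperimentDesign(
        tuple(px.ArrayRecord(f"a{i}", "wt", "0") for i in range(n))
    )


class TestRankNormalize:
    def test_simple_definition(self):
        d = _tiny_design(1)
        m = _matrix([[5.0], [2.0], [9.0]], d)
        r = px.rank_normalize(m)
        assert r.ranks["a0"].tolist() == pytest.approx([2 / 3, 1 / 3, 1.0])

    def test_midranks_on_ties(self):
        d = _tiny_design(1)
        r = px.rank_normalize(_matrix([[4.0], [4.0], [8.0]], d))
        assert r.ranks["a0"].tolist() == pytest.approx([0.5, 0.5, 1.0])

    def test_distinct_values_give_grid(self):
        d = _tiny_design(1)
        vals = [[3.0], [1.0], [7.0], [2.0], [9.0]]
        r = px.rank_normalize(_matrix(vals, d))
        assert sorted(r.ranks["a0"]) == pytest.approx([i / 5 for i in range(1, 6)])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(min_value=1, max_value=5), min_size=3, max_size=3),
            min_size=2,
            max_size=12,
        )
    )
    def test_rank_sum_invariant_under_ties(self, rows):
        """Per-array relative-rank sum is (P+1)/2 exactly, however tied."""
        d = _tiny_design(3)
        r = px.rank_normalize(_matrix(rows, d))
        P = len(rows)
        for col in r.ranks.columns:
            assert r.ranks[col].sum() == pytest.approx((P + 1) / 2, abs=1e-12)

    def test_nonpositive_intensity_rejected(self):
        d = _tiny_design(2)
        with pytest.raises(px.InputError, match="p1"):
            _matrix([[1.0, 2.0], [3.0, 0.0]], d)


class TestExactRankTest:
    def test_complete_separation_5v3(self):
        pu, pl = px.mw_exact([0.4, 0.5, 0.6, 0.7, 0.8], [0.1, 0.2, 0.3])
        assert pu == pytest.approx(1 / 56)
        assert pl == pytest.approx(1.0)

    def test_interleaved_5v3_tail(self):
        # experimental values occupy pooled rank positions {2,4,6,7,8}:
        # 7 of the 56 assignments give the controls a rank sum <= 9
        x = [2.0, 4.0, 6.0, 7.0, 8.0]
        y = [1.0, 3.0, 5.0]
        pu, pl = px.mw_exact(x, y)
        assert pu == pytest.approx(7 / 56)
        assert px.assign_letter(pu, pl) == "E"

    def test_all_tied_degenerate(self):
        pu, pl = px.mw_exact([0.5, 0.5, 0.5], [0.5, 0.5])
        assert pu == 1.0 and pl == 1.0

    def test_group_of_one_rejected(self):
        with pytest.raises(px.InputError):
            px.mw_exact([1.0], [2.0, 3.0])

    @pytest.mark.parametrize("n_exp,n_ctrl", [(5, 3), (5, 5), (4, 5)])
    def test_matches_enumeration_oracle(self, n_exp, n_ctrl):
        rng = np.random.default_rng(17)
        for _ in range(25):
            if rng.random() < 0.4:  # tied inputs from a coarse grid
                x = rng.integers(1, 4, n_exp).astype(float)
                y = rng.integers(1, 4, n_ctrl).astype(float)
            else:
                x = rng.random(n_exp)
                y = rng.random(n_ctrl)
            pu, pl = px.mw_exact(x, y)
            ou, ol = oracle_mw_tails(x, y)
            assert pu == pytest.approx(ou, abs=1e-12)
            assert pl == pytest.approx(ol, abs=1e-12)

    def test_tail_sum_identity_without_ties(self):
        """p_upper + p_lower = 1 + P(rank sum = observed) for untied data."""
        rng = np.random.default_rng(23)
        x, y = rng.random(5), rng.random(4)
        pu, pl = px.mw_exact(x, y)
        from scipy.stats import rankdata
        from itertools import combinations

        ranks = rankdata(np.concatenate([x, y]))
        obs = ranks[:5].sum()
        sums = [sum(ranks[list(c)]) for c in combinations(range(9), 5)]
        p_eq = sum(1 for s in sums if abs(s - obs) < 1e-9) / len(sums)
        assert pu + pl == pytest.approx(1 + p_eq, abs=1e-12)


class TestLetters:
    @pytest.mark.parametrize(
        "pu,pl,expected",
        [(0.0179, 0.996, "H"), (0.996, 0.0179, "L"), (0.125, 0.93, "E"),
         (0.05, 0.999, "H")],  # inclusive threshold
    )
    def test_assignment(self, pu, pl, expected):
        assert px.assign_letter(pu, pl) == expected

    def test_bad_alpha_rejected(self):
        with pytest.raises(px.ConfigError):
            px.assign_letter(0.01, 0.99, alpha=0.7)


class TestExpressionStrings:
    def test_null_probe_is_all_E(self, design, plan):
        cfg = px.SimConfig(n_transcripts=1, noise_sd=0.0, seed=2)
        t = px.simulate_transcriptome(cfg)
        probes, origin = px.design_probes(t, cfg)
        m, _ = px.simulate_intensities(design, probes, origin, cfg)
        strings = px.build_expression_strings(px.rank_normalize(m), plan)
        assert set(strings["expression_string"]) == {"E" * 7}

    def test_strings_have_plan_length(self, noiseless_result):
        assert all(len(s) == 7 for s in noiseless_result.strings["expression_string"])

    def test_planted_profiles_recovered_noiselessly(self, noiseless_bundle, noiseless_result):
        """Nearly all probes of a planted transcript carry the truth string.

        A probe whose baseline already ranks at the very top (or bottom) of
        every array is rank-saturated and cannot display the planted shift,
        so a small deficit from 9/9 is tolerated.
        """
        b = noiseless_bundle
        smap = px.expression_string_map(noiseless_result.strings)
        for tx, prof in b.truth.true_profile.items():
            own = [p for p, o in b.truth.probe_origin.items() if o == tx and p in smap]
            matching = sum(1 for p in own if smap[p] == prof)
            assert matching >= 7, (tx, [smap[p] for p in own])

    def test_letters_invariant_under_monotone_transform(self, design, plan):
        cfg = px.SimConfig(
            n_transcripts=6, noise_sd=0.4, seed=31,
            planted_effects=(px.PlantedEffect("tx1", (4, 5, 6, 7), 1.5),),
        )
        b = px.simulate_bundle(cfg)
        ranks_raw = px.rank_normalize(b.matrix)
        s1 = px.build_expression_strings(ranks_raw, plan)["expression_string"]
        for transform in (np.sqrt, lambda v: v**2, lambda v: 3.0 * v + 1.0):
            transformed = px.IntensityMatrix(transform(b.matrix.values), design)
            s2 = px.build_expression_strings(px.rank_normalize(transformed), plan)[
                "expression_string"
            ]
            assert s1.equals(s2)


class TestClustering:
    def test_exact_string_grouping(self):
        clusters = px.cluster_probes({"p1": "EEE", "p2": "EEE", "p3": "HEE"})
        assert clusters == {"EEE": {"p1", "p2"}, "HEE": {"p3"}}

    def test_degenerate_single_cluster(self):
        clusters = px.cluster_probes({f"p{i}": "HLE" for i in range(5)})
        assert clusters == {"HLE": {f"p{i}" for i in range(5)}}

    def test_clusters_partition_probes(self, noiseless_result):
        sizes = sum(len(v) for v in noiseless_result.clusters.values())
        assert sizes == noiseless_result.index.T
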