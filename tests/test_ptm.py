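import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmquant import (
    DataError,
    ParameterError,
    ThresholdConfig,
    UndefinedResultError,
    annotate_sq_motif,
    call_regulated_sites,
    cluster_site_profiles,
    compare_fc_scatter,
    filter_network_edges,
    integrate_external_ratio_sites,
    map_orthologs,
    responsive_in_wt_stable_in_mutants,
    sq_fraction,
)

from conftest import make_quant_table


def _results(fcs, adj_ps, keys=None):
    keys = keys or [f"S{i}" for i in range(len(fcs))]
    return pd.DataFrame({"log2_fc": fcs, "adj_p": adj_ps},
                        index=pd.Index(keys, name="feature_id"))


class TestRegulatedCalls:
    def test_dataset_defaults_differ(self):
        res = _results([np.log2(1.6)], [0.04])
        # FC 1.6, adj p 0.04: passes the phospho cutoffs (1.5 / 0.05) but not
        # the stricter acetyl cutoffs (2 / 0.01)
        assert call_regulated_sites(res, "phospho")["direction"].iloc[0] == "up"
        assert call_regulated_sites(res, "acetyl")["direction"].iloc[0] == "ns"

    def test_down_direction(self):
        res = _results([-2.0], [0.001])
        assert call_regulated_sites(res, "acetyl")["direction"].iloc[0] == "down"

    def test_empty_input(self):
        assert len(call_regulated_sites(_results([], []), "phospho")) == 0

    def test_unknown_dataset_rejected(self):
        with pytest.raises(ParameterError):
            call_regulated_sites(_results([1.0], [0.01]), "ubiquityl")

    def test_threshold_override(self):
        res = _results([np.log2(1.6)], [0.04])
        strict = ThresholdConfig(3.0, 0.001)
        assert call_regulated_sites(res, "phospho", strict)["direction"].iloc[0] == "ns"


class TestWtResponsiveMutantStable:
    def _calls(self, directions, keys=None):
        keys = keys or [f"S{i}" for i in range(len(directions))]
        return pd.DataFrame(
            {"direction": directions, "log2_fc": [1.0] * len(directions),
             "adj_p": [0.01] * len(directions)},
            index=pd.Index(keys, name="feature_id"))

    def test_definition(self):
        wt = self._calls(["up", "up", "down", "ns"])
        m1 = self._calls(["ns", "up", "ns", "ns"])
        m2 = self._calls(["ns", "ns", "ns", "up"])
        out = responsive_in_wt_stable_in_mutants(wt, [m1, m2])
        # S0: up in WT, ns in both -> in; S1: up in a mutant -> out;
        # S2: down in WT, ns in both -> in; S3: ns in WT -> out
        assert set(out) == {"S0", "S2"}

    def test_no_mutants_returns_wt_regulated(self):
        wt = self._calls(["up", "ns", "down"])
        assert set(responsive_in_wt_stable_in_mutants(wt, [])) == {"S0", "S2"}

    def test_no_wt_regulation_empty(self):
        wt = self._calls(["ns", "ns"])
        m = self._calls(["up", "down"])
        assert len(responsive_in_wt_stable_in_mutants(wt, [m])) == 0

    def test_disjoint_universes_error(self):
        wt = self._calls(["up"], keys=["A"])
        m = self._calls(["ns"], keys=["B"])
        with pytest.raises(DataError):
            responsive_in_wt_stable_in_mutants(wt, [m])

    def test_fc_guard(self):
        wt = self._calls(["up", "up"])
        m = self._calls(["ns", "ns"])
        m["log2_fc"] = [0.1, 0.9]  # S1 is ns but drifting past the guard
        out = responsive_in_wt_stable_in_mutants(wt, [m], max_mutant_abs_log2_fc=0.5)
        assert set(out) == {"S0"}


class TestSQAnnotation:
    def test_sq_window_true(self):
        assert annotate_sq_motif("A" * 15 + "SQ" + "A" * 14) is True

    def test_non_q_follower_false(self):
        assert annotate_sq_motif("A" * 15 + "SA" + "A" * 14) is False

    def test_tq_flag_semantics(self):
        w = "A" * 15 + "TQ" + "A" * 14
        assert annotate_sq_motif(w) is False
        assert annotate_sq_motif(w, include_tq=True) is True

    def test_malformed_window_rejected(self):
        with pytest.raises(DataError):
            annotate_sq_motif("SQAA")  # even length
        with pytest.raises(DataError):
            annotate_sq_motif("ASA", residue="T")  # center mismatch

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_depends_only_on_central_pair(self, seed):
        rng = np.random.default_rng(seed)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        chars = rng.choice(aas, size=31)
        chars[15], chars[16] = "S", "Q"
        base = annotate_sq_motif("".join(chars))
        perm = chars.copy()
        outer = np.r_[0:15, 17:31]
        perm[outer] = rng.permutation(perm[outer])
        assert annotate_sq_motif("".join(perm)) == base is True

    def test_sq_fraction_hand_cases(self):
        ann = pd.Series([True, True, True, False],
                        index=["a", "b", "c", "d"])
        assert sq_fraction(["a", "b", "c", "d"], ann) == 75.0
        assert sq_fraction(["a", "b", "c"], ann) == 100.0
        assert sq_fraction(["d"], ann) == 0.0

    def test_sq_fraction_empty_undefined(self):
        with pytest.raises(UndefinedResultError):
            sq_fraction([], pd.Series(dtype=bool))


class TestFcScatter:
    def test_identical_fcs_r2_one(self):
        fc = pd.Series(np.arange(10, dtype=float), index=[f"S{i}" for i in range(10)])
        r2, paired = compare_fc_scatter(fc, fc)
        assert r2 == pytest.approx(1.0)
        assert len(paired) == 10

    def test_attenuation_model_r2(self):
        """mutant = 0.5*wt + N(0, 0.3): r2 approaches the analytic value
        var(0.5x) / (var(0.5x) + 0.09)."""
        rng = np.random.default_rng(0)
        wt = rng.normal(0, 1.0, size=500)
        mutant = 0.5 * wt + rng.normal(0, 0.3, size=500)
        keys = [f"S{i}" for i in range(500)]
        r2, _ = compare_fc_scatter(pd.Series(wt, index=keys),
                                   pd.Series(mutant, index=keys))
        expected = 0.25 / (0.25 + 0.09)
        assert r2 == pytest.approx(expected, abs=0.05)

    def test_independent_fcs_near_zero(self):
        rng = np.random.default_rng(1)
        keys = [f"S{i}" for i in range(500)]
        r2, _ = compare_fc_scatter(pd.Series(rng.normal(size=500), index=keys),
                                   pd.Series(rng.normal(size=500), index=keys))
        assert r2 <= 0.05

    def test_sq_filter(self):
        keys = [f"S{i}" for i in range(6)]
        wt = pd.Series([1, 2, 3, 1, 2, 3], index=keys, dtype=float)
        mut = pd.Series([1, 2, 3, 3, 2, 1], index=keys, dtype=float)
        sq = pd.Series([True, True, True, False, False, False], index=keys)
        r2, paired = compare_fc_scatter(wt, mut, sq_flags=sq, site_filter="sq")
        assert len(paired) == 3 and r2 == pytest.approx(1.0)

    def test_too_few_common_sites(self):
        wt = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(DataError):
            compare_fc_scatter(wt, wt)


class TestOrthologMapping:
    def test_empty_table_excludes_all(self):
        mapping, excluded = map_orthologs(["A1", "A2"],
                                          pd.DataFrame(columns=["a", "b"]))
        assert len(mapping) == 0 and excluded == ["A1", "A2"]

    def test_one_to_many_flagged_ambiguous(self):
        orth = pd.DataFrame({"a": ["A1", "A1", "A2"], "b": ["B1", "B2", "B3"]})
        mapping, excluded = map_orthologs(["A1", "A2", "A3"], orth)
        a1 = mapping[mapping["source_id"] == "A1"]
        assert set(a1["ortholog_id"]) == {"B1", "B2"}
        assert a1["ambiguous"].all()
        a2 = mapping[mapping["source_id"] == "A2"]
        assert not a2["ambiguous"].any()
        assert excluded == ["A3"]


class TestExternalRatioIntegration:
    def _target(self):
        w1 = "A" * 15 + "SQ" + "A" * 14
        w2 = "C" * 15 + "SD" + "C" * 14
        return make_quant_table(
            np.ones((2, 2)) * 20,
            feature_ids=["P1_10_1", "P2_20_1"],
            protein_id=["P1", "P2"],
            position=[10, 20],
            sequence_window=[w1, w2],
        )

    def test_ratio_normalization_and_mapping(self):
        target = self._target()
        ext_sites = pd.DataFrame({
            "gene": ["G0", "G1"],
            "position": [10, 20],
            "window": [target.meta["sequence_window"].iloc[0],
                       target.meta["sequence_window"].iloc[1]],
            "ratio_hl": [2.0, 8.0],
        })
        ext_prot = pd.DataFrame({"gene": ["G0", "G1"], "ratio_hl": [2.0, 2.0]})
        out = integrate_external_ratio_sites(ext_sites, ext_prot, target)
        assert len(out) == 2
        np.testing.assert_allclose(out["external_log2_ratio"], [0.0, 2.0])

    def test_unquantified_protein_dropped(self):
        target = self._target()
        ext_sites = pd.DataFrame({
            "gene": ["G0"], "position": [10],
            "window": [target.meta["sequence_window"].iloc[0]], "ratio_hl": [2.0]})
        ext_prot = pd.DataFrame({"gene": ["OTHER"], "ratio_hl": [1.0]})
        out = integrate_external_ratio_sites(ext_sites, ext_prot, target)
        assert len(out) == 0

    def test_ambiguous_target_key_dropped(self):
        w = "A" * 15 + "SQ" + "A" * 14
        target = make_quant_table(
            np.ones((2, 2)) * 20,
            feature_ids=["P1_10_1", "P1_10_2"],  # two multiplicity states
            protein_id=["P1", "P1"],
            position=[10, 10],
            sequence_window=[w, w],
        )
        target.meta["gene_name"] = ["G0", "G0"]
        ext_sites = pd.DataFrame({"gene": ["G0"], "position": [10],
                                  "window": [w], "ratio_hl": [2.0]})
        ext_prot = pd.DataFrame({"gene": ["G0"], "ratio_hl": [1.0]})
        out = integrate_external_ratio_sites(ext_sites, ext_prot, target)
        assert len(out) == 0

    def test_output_bounded_by_inputs(self):
        target = self._target()
        ext_sites = pd.DataFrame({
            "gene": ["G0", "G9", "G8"],
            "position": [10, 1, 2],
            "window": [target.meta["sequence_window"].iloc[0],
                       "A" * 15 + "S" + "A" * 15, "A" * 15 + "S" + "A" * 15],
            "ratio_hl": [2.0, 2.0, 2.0]})
        ext_prot = pd.DataFrame({"gene": ["G0", "G9", "G8"], "ratio_hl": [1.0] * 3})
        out = integrate_external_ratio_sites(ext_sites, ext_prot, target)
        assert len(out) <= min(len(ext_sites), target.n_features)


class TestNetworkFilter:
    def _edges(self, scores, pairs=None):
        pairs = pairs or [("n1", "n2"), ("n2", "n3"), ("n3", "n4")]
        return pd.DataFrame({"node1": [p[0] for p in pairs],
                             "node2": [p[1] for p in pairs],
                             "combined_score": scores})

    def test_score_filter(self):
        nodes, kept, degree = filter_network_edges(self._edges([0.9, 0.7, 0.5]),
                                                   min_score=0.7)
        assert len(kept) == 2
        assert degree["n2"] == 2 and "n4" not in degree.index

    def test_min_score_one_empties_graph(self):
        nodes, kept, _ = filter_network_edges(self._edges([0.9, 0.8, 0.7]),
                                              min_score=1.0)
        assert len(kept) == 0 and nodes == []

    def test_disconnected_node_kept_when_flag_off(self):
        nodes, _, degree = filter_network_edges(self._edges([0.9, 0.1, 0.1]),
                                                min_score=0.7,
                                                drop_disconnected=False)
        assert "n4" in nodes and degree["n4"] == 0

    def test_identity_at_zero_threshold(self):
        edges = self._edges([0.3, 0.2, 0.1])
        nodes, kept, _ = filter_network_edges(edges, min_score=0.0,
                                              drop_disconnected=False)
        pd.testing.assert_frame_equal(kept, edges)

    def test_self_loops_removed(self):
        edges = self._edges([0.9, 0.9], pairs=[("n1", "n1"), ("n1", "n2")])
        _, kept, _ = filter_network_edges(edges, min_score=0.5)
        assert len(kept) == 1 and kept["node1"].iloc[0] == "n1"

    def test_bad_min_score_rejected(self):
        with pytest.raises(ParameterError):
            filter_network_edges(self._edges([0.9, 0.9, 0.9]), min_score=1.5)


class TestProfileClustering:
    def test_archetypes_separated(self):
        rng = np.random.default_rng(0)
        up = np.tile([0.0, 0.0, 2.0, 2.0], (50, 1)) + rng.normal(0, 0.1, (50, 4))
        flat = np.tile([1.0, 1.0, 1.0, 1.0], (50, 1)) + rng.normal(0, 0.1, (50, 4))
        t = make_quant_table(np.vstack([up, flat]))
        labels, Z = cluster_site_profiles(t, k=2, seed=0)
        purity = max((labels[:50] == lab).mean() for lab in (0, 1))
        assert purity >= 0.95
        assert Z.shape == (100, 4)
        np.testing.assert_allclose(Z.mean(axis=1), 0, atol=1e-12)

    def test_k_one_single_cluster(self):
        t = make_quant_table(np.random.default_rng(1).normal(size=(10, 4)))
        labels, _ = cluster_site_profiles(t, k=1)
        assert set(labels) == {0}

    def test_seed_determinism(self):
        t = make_quant_table(np.random.default_rng(2).normal(size=(40, 5)))
        l1, _ = cluster_site_profiles(t, k=3, seed=7)
        l2, _ = cluster_site_profiles(t, k=3, seed=7)
        pd.testing.assert_series_equal(l1, l2)


class TestLocalizationFilter:
    def test_default_is_identity(self):
        from ptmquant.ptm import filter_by_localization_prob
        t = make_quant_table(np.ones((3, 2)), localization_prob=[0.2, 0.9, np.nan])
        assert filter_by_localization_prob(t).n_features == 3

    def test_cutoff_drops_low_probability_sites(self):
        from ptmquant.ptm import filter_by_localization_prob
        t = make_quant_table(np.ones((3, 2)), localization_prob=[0.2, 0.9, np.nan])
        out = filter_by_localization_prob(t, min_prob=0.75)
        # sites without a recorded probability are kept
        assert list(out.feature_ids) == ["F1", "F2"]

    def test_bad_cutoff_rejected(self):
        from ptmquant.ptm import filter_by_localization_prob
        t = make_quant_table(np.ones((1, 2)))
        with pytest.raises(ParameterError):
            filter_by_localization_prob(t, min_prob=1.5)
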