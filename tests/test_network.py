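import numpy as np
import pandas as pd
import pytest

import mirprog as mp


def _expr(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T.astype(float)


@pytest.fixture
def toy():
    samples = [f"s{i}" for i in range(6)]
    mirna = _expr({"m1": [1, 2, 3, 4, 5, 6], "m2": [2, 1, 4, 3, 6, 5]})
    mirna.columns = samples
    mrna = _expr(
        {
            "g_neg": [6, 5, 4, 3, 2, 1],   # rho = -1 with m1
            "g_pos": [1, 2, 3, 4, 5, 6],   # rho = +1 with m1
            "g_const": [3, 3, 3, 3, 3, 3],
        }
    )
    mrna.columns = samples
    candidates = pd.DataFrame(
        {
            "mirna": ["m1", "m1", "m1", "m9"],
            "gene": ["g_neg", "g_pos", "g_const", "g_neg"],
        }
    )
    return candidates, mirna, mrna


class TestCorrelationFilter:
    def test_only_negative_rho_retained(self, toy):
        candidates, mirna, mrna = toy
        kept = mp.filter_by_correlation(candidates, mirna, mrna)
        assert set(zip(kept["mirna"], kept["gene"])) == {("m1", "g_neg")}
        assert (kept["rho"] < 0).all()
        assert kept["rho"].iloc[0] == pytest.approx(-1.0)

    def test_zero_and_positive_rho_dropped(self):
        # rho exactly 0 counts as "non-negative" and is filtered out
        samples = [f"s{i}" for i in range(4)]
        mirna = pd.DataFrame([[1, 2, 3, 4]], index=["m1"], columns=samples, dtype=float)
        mrna = pd.DataFrame([[2, 4, 1, 3], [1, 2, 3, 4]], index=["g0", "g1"],
                            columns=samples, dtype=float)
        assert mp.spearman_rho([1, 2, 3, 4], [2, 4, 1, 3]) == pytest.approx(0.0)
        cand = pd.DataFrame({"mirna": ["m1", "m1"], "gene": ["g0", "g1"]})
        assert mp.filter_by_correlation(cand, mirna, mrna).empty

    def test_constant_vector_pair_dropped(self, toy):
        candidates, mirna, mrna = toy
        kept = mp.filter_by_correlation(candidates, mirna, mrna)
        assert "g_const" not in set(kept["gene"])

    def test_unknown_features_skipped_and_counted(self, toy):
        candidates, mirna, mrna = toy
        kept = mp.filter_by_correlation(candidates, mirna, mrna)
        assert kept.attrs["n_unknown"] == 1

    def test_rho_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(24)]
        mirna = pd.DataFrame(rng.normal(size=(5, 24)),
                             index=[f"m{i}" for i in range(5)], columns=samples)
        mrna = pd.DataFrame(rng.normal(size=(5, 24)),
                            index=[f"g{i}" for i in range(5)], columns=samples)
        cand = pd.DataFrame({"mirna": ["m0", "m1", "m2", "m3", "m4"],
                             "gene": ["g0", "g1", "g2", "g3", "g4"]})
        kept = mp.filter_by_correlation(cand, mirna, mrna)
        from scipy.stats import spearmanr

        for _, row in kept.iterrows():
            expected = spearmanr(mirna.loc[row["mirna"]], mrna.loc[row["gene"]]).statistic
            assert row["rho"] == pytest.approx(expected)


def _de(rows):
    return pd.DataFrame(rows, columns=["feature", "timepoint", "direction"])


class TestStageNetwork:
    filtered = pd.DataFrame(
        {"mirna": ["m1", "m2", "m3"], "gene": ["g1", "g2", "g3"],
         "rho": [-0.5, -0.5, -0.5]}
    )

    def test_opposite_directions_make_an_edge(self):
        de_mi = _de([("m1", "w6", "up"), ("m2", "w6", "up"), ("m3", "w6", "up")])
        de_mr = _de([("g1", "w6", "down"), ("g2", "w6", "up"), ("g3", "w6", "ns")])
        edges = mp.stage_network(self.filtered, de_mi, de_mr, "w6")
        assert set(zip(edges["mirna"], edges["gene"])) == {("m1", "g1")}
        assert (edges["admitted_by"] == "stage:w6").all()

    def test_same_direction_is_no_edge(self):
        de_mi = _de([("m1", "w6", "down")])
        de_mr = _de([("g1", "w6", "down")])
        assert mp.stage_network(self.filtered, de_mi, de_mr, "w6").empty

    def test_missing_timepoint_rejected(self):
        de_mi = _de([("m1", "w6", "up")])
        de_mr = _de([("g1", "w6", "down")])
        with pytest.raises(ValueError):
            mp.stage_network(self.filtered, de_mi, de_mr, "w12")

    def test_edge_set_invariant_to_sample_order_and_monotone_rescale(self, sim):
        cfg, mirna, mrna, truth, _, candidates = sim
        norm_mi = mp.quantile_normalize(mirna.values)
        norm_mr = mp.quantile_normalize(mrna.values)
        kept = mp.filter_by_correlation(candidates, norm_mi, norm_mr)
        perm = list(reversed(norm_mi.columns))
        kept_perm = mp.filter_by_correlation(candidates, norm_mi[perm], norm_mr[perm])
        kept_scaled = mp.filter_by_correlation(candidates, norm_mi * 3 + 1, norm_mr ** 3)
        base = set(zip(kept["mirna"], kept["gene"]))
        assert set(zip(kept_perm["mirna"], kept_perm["gene"])) == base
        assert set(zip(kept_scaled["mirna"], kept_scaled["gene"])) == base


class TestTrendNetwork:
    def _profiles(self, patterns, trends=None):
        df = pd.DataFrame({"pattern": patterns})
        df["trend_group"] = trends if trends is not None else [
            mp.trend_group(p) for p in patterns
        ]
        return df

    filtered = pd.DataFrame(
        {"mirna": ["m1", "m1", "m2"], "gene": ["g1", "g2", "g3"],
         "rho": [-0.4, -0.4, -0.4]}
    )

    def test_exact_mirror_match_makes_edge(self):
        mi = self._profiles(["++0"]).set_axis(["m1"])
        mr = self._profiles(["--0", "-00", "000"]).set_axis(["g1", "g2", "g3"])
        edges = mp.trend_network(self.filtered, mi, mr)
        assert set(zip(edges["mirna"], edges["gene"])) == {("m1", "g1")}

    def test_partial_mirror_is_no_edge(self):
        mi = self._profiles(["++0"]).set_axis(["m1"])
        mr = self._profiles(["-00"]).set_axis(["g1"])
        assert mp.trend_network(self.filtered, mi, mr).empty

    def test_flat_mirna_excluded(self):
        mi = self._profiles(["000"]).set_axis(["m1"])
        mr = self._profiles(["000"]).set_axis(["g1"])
        assert mp.trend_network(self.filtered, mi, mr).empty

    def test_mixed_mirna_excluded(self):
        mi = self._profiles(["+-+"]).set_axis(["m1"])
        mr = self._profiles(["-+-"]).set_axis(["g1"])
        assert mp.trend_network(self.filtered, mi, mr).empty

    def test_hamming_tolerance_relaxes_match(self):
        mi = self._profiles(["++0"]).set_axis(["m1"])
        mr = self._profiles(["-00"]).set_axis(["g1"])
        edges = mp.trend_network(self.filtered, mi, mr, hamming_tolerance=1)
        assert len(edges) == 1


class TestDegreeStats:
    def test_shared_example(self):
        edges = pd.DataFrame(
            {"mirna": ["m1", "m1", "m2"], "gene": ["g1", "g2", "g1"],
             "rho": -0.5, "admitted_by": "stage:w6"}
        )
        stats = mp.degree_stats(edges)
        assert stats["mean_targets_per_mirna"] == pytest.approx(1.5)
        assert stats["mean_regulators_per_gene"] == pytest.approx(1.5)

    def test_single_edge(self):
        edges = pd.DataFrame({"mirna": ["m1"], "gene": ["g1"], "rho": -0.1,
                              "admitted_by": "trend"})
        stats = mp.degree_stats(edges)
        assert (stats["mean_targets_per_mirna"], stats["mean_regulators_per_gene"]) == (1, 1)

    def test_star(self):
        edges = pd.DataFrame(
            {"mirna": "m1", "gene": [f"g{i}" for i in range(5)], "rho": -0.1,
             "admitted_by": "trend"}
        )
        stats = mp.degree_stats(edges)
        assert stats["mean_targets_per_mirna"] == 5
        assert stats["mean_regulators_per_gene"] == 1

    def test_empty_network(self):
        stats = mp.degree_stats(pd.DataFrame(columns=["mirna", "gene", "rho", "admitted_by"]))
        assert stats["n_edges"] == 0 and np.isnan(stats["mean_targets_per_mirna"])


class TestSignedConcordance:
    def test_half_agree(self):
        a = {"m1": "up", "m2": "down", "m3": "up"}
        b = {"m1": "up", "m2": "up"}
        assert mp.signed_concordance(a, b) == pytest.approx(50.0)

    def test_identical_maps(self):
        a = {"m1": "up", "m2": "down"}
        assert mp.signed_concordance(a, dict(a)) == pytest.approx(100.0)

    def test_disjoint_ids_na(self):
        assert np.isnan(mp.signed_concordance({"m1": "up"}, {"m2": "up"}))


class TestNetworkInvariants:
    def test_every_edge_negative_rho_and_in_candidates(self, sim, pipeline_result):
        _, _, _, _, _, candidates = sim
        cand = set(zip(candidates["mirna"], candidates["gene"]))
        for edges in [*pipeline_result.stage_edges.values(), pipeline_result.trend_edges]:
            if edges.empty:
                continue
            assert (edges["rho"] < 0).all()
            assert set(zip(edges["mirna"], edges["gene"])) <= cand
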