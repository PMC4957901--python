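import itertools
import math

import numpy as np
import pandas as pd
import pytest

import mirprog as mp
from mirprog.frp import IncidenceMatrix, MaximalBiclique


def brute_force_closed_itemsets(incidence: IncidenceMatrix, min_support: int):
    """Oracle: test every non-empty term subset for closure and support."""
    out = set()
    n_terms = len(incidence.terms)
    cells = incidence.cells
    for r in range(1, n_terms + 1):
        for subset in itertools.combinations(range(n_terms), r):
            genes = cells[:, subset].all(axis=1)
            if genes.sum() < min_support:
                continue
            closure = cells[genes].all(axis=0)
            if set(np.flatnonzero(closure)) != set(subset):
                continue  # not closed
            out.add(
                (
                    frozenset(np.array(incidence.terms)[list(subset)]),
                    frozenset(np.array(incidence.genes)[genes]),
                    int(genes.sum()),
                )
            )
    return out


def as_triples(mbs):
    return {(mb.term_ids, mb.gene_ids, mb.support) for mb in mbs}


def random_incidence(rng, max_genes=12, max_terms=8):
    n_genes = int(rng.integers(1, max_genes + 1))
    n_terms = int(rng.integers(1, max_terms + 1))
    cells = rng.random((n_genes, n_terms)) < rng.uniform(0.2, 0.8)
    return IncidenceMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"t{j}" for j in range(n_terms)],
        cells,
    )


class TestBuildIncidence:
    def test_small_example(self):
        annotations = {"A": {"g1", "g2"}, "B": {"g2"}}
        inc = mp.build_incidence({"g1", "g2"}, annotations)
        frame = inc.to_frame()
        assert frame.loc["g1"].tolist() == [True, False]
        assert frame.loc["g2"].tolist() == [True, True]

    def test_unannotated_gene_excluded(self):
        inc = mp.build_incidence({"g1", "g_lonely"}, {"A": {"g1"}})
        assert inc.genes == ["g1"]

    def test_term_without_network_gene_excluded(self):
        inc = mp.build_incidence({"g1"}, {"A": {"g1"}, "B": {"g_outside"}})
        assert inc.terms == ["A"]


class TestMiner:
    def _four_gene_incidence(self):
        # g1:{A,B} g2:{A,B} g3:{A} g4:{B}
        return IncidenceMatrix(
            ["g1", "g2", "g3", "g4"],
            ["A", "B"],
            np.array([[1, 1], [1, 1], [1, 0], [0, 1]], dtype=bool),
        )

    def test_hand_enumerated_support_two(self):
        mbs = mp.mine_closed_itemsets(self._four_gene_incidence(), 2)
        assert as_triples(mbs) == {
            (frozenset({"A"}), frozenset({"g1", "g2", "g3"}), 3),
            (frozenset({"B"}), frozenset({"g1", "g2", "g4"}), 3),
            (frozenset({"A", "B"}), frozenset({"g1", "g2"}), 2),
        }

    def test_hand_enumerated_support_three(self):
        mbs = mp.mine_closed_itemsets(self._four_gene_incidence(), 3)
        assert as_triples(mbs) == {
            (frozenset({"A"}), frozenset({"g1", "g2", "g3"}), 3),
            (frozenset({"B"}), frozenset({"g1", "g2", "g4"}), 3),
        }

    def test_empty_incidence(self):
        inc = IncidenceMatrix([], [], np.zeros((0, 0), dtype=bool))
        assert mp.mine_closed_itemsets(inc, 1) == []

    def test_matches_brute_force_on_random_incidences(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            inc = random_incidence(rng)
            for support in (1, 2, 3):
                mined = as_triples(mp.mine_closed_itemsets(inc, support))
                assert mined == brute_force_closed_itemsets(inc, support)

    def test_output_bicliques_complete_and_maximal(self):
        rng = np.random.default_rng(23)
        inc = random_incidence(rng)
        frame = inc.to_frame()
        for mb in mp.mine_closed_itemsets(inc, 1):
            sub = frame.loc[sorted(mb.gene_ids), sorted(mb.term_ids)]
            assert sub.to_numpy().all()  # completeness
            other_genes = frame.index.difference(mb.gene_ids)
            if len(other_genes):
                assert not (
                    frame.loc[other_genes, sorted(mb.term_ids)].all(axis=1).any()
                )  # gene-side maximality
            other_terms = frame.columns.difference(mb.term_ids)
            if len(other_terms):
                assert not (
                    frame.loc[sorted(mb.gene_ids), other_terms].all(axis=0).any()
                )  # term-side maximality

    def test_raising_support_never_adds_itemsets(self):
        rng = np.random.default_rng(29)
        inc = random_incidence(rng)
        previous = as_triples(mp.mine_closed_itemsets(inc, 1))
        for support in (2, 3, 4):
            current = as_triples(mp.mine_closed_itemsets(inc, support))
            assert current <= previous
            previous = current

    def test_deterministic_order(self):
        inc = self._four_gene_incidence()
        a = mp.mine_closed_itemsets(inc, 1)
        b = mp.mine_closed_itemsets(inc, 1)
        assert [(m.term_ids, m.support) for m in a] == [(m.term_ids, m.support) for m in b]
        assert [m.support for m in a] == sorted([m.support for m in a], reverse=True)


class TestSignificance:
    def test_single_term_closed_form(self):
        mb = MaximalBiclique(
            gene_ids=frozenset(f"g{i}" for i in range(10)),
            term_ids=frozenset({"T"}),
            support=10,
        )
        background = [f"g{i}" for i in range(100)]
        annotations = {"T": set(f"g{i}" for i in range(10))}
        out = mp.mb_significance([mb], set(background[:10]), annotations, background,
                                 significant_only=False)
        expected = math.comb(10, 10) * math.comb(90, 0) / math.comb(100, 10)
        assert out[0].p_value == pytest.approx(expected)

    def test_null_support_not_significant(self):
        # k equals its null expectation: nothing to report
        background = [f"g{i}" for i in range(100)]
        annotations = {"T": set(background[:40])}
        mb = MaximalBiclique(
            gene_ids=frozenset(background[:8]), term_ids=frozenset({"T"}), support=8
        )
        out = mp.mb_significance([mb], set(background[:20]), annotations, background,
                                 significant_only=False)
        assert out[0].p_value > 0.05

    def test_planted_module_significant(self, sim, pipeline_result):
        cfg, _, _, truth, annotations, _ = sim
        background = [f"gene{i + 1:04d}" for i in range(cfg.n_gene)]
        edges = pipeline_result.stage_edges["w12"]
        genes = set(edges["gene"])
        inc = mp.build_incidence(genes, annotations)
        mbs = mp.mine_closed_itemsets(inc, 6)
        scored = mp.mb_significance(mbs, genes, annotations, background,
                                    significant_only=False)
        planted_terms = [t for _, terms, _ in truth.planted_modules for t in terms]
        full = [mb for mb in scored
                if mb.term_ids in {terms for _, terms, _ in truth.planted_modules}]
        assert full, "planted term sets should be mined"
        assert all(mb.fdr < 0.05 for mb in full)

    def test_missing_background_coannotation_is_error(self):
        mb = MaximalBiclique(frozenset({"g1"}), frozenset({"T"}), 1)
        with pytest.raises(ValueError):
            mp.mb_significance([mb], {"g1"}, {"T": set()}, {"g1", "g2"})


class TestSilhouette:
    def test_disjoint_bicliques_score_one(self):
        inc = IncidenceMatrix(
            ["g1", "g2", "g3", "g4"],
            ["A", "B"],
            np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=bool),
        )
        mbs = [
            MaximalBiclique(frozenset({"g1", "g2"}), frozenset({"A"}), 2),
            MaximalBiclique(frozenset({"g3", "g4"}), frozenset({"B"}), 2),
        ]
        out = mp.silhouette_scores(mbs, inc)
        assert out[0].silhouette == pytest.approx(1.0)
        assert out[1].silhouette == pytest.approx(1.0)

    def test_identical_bicliques_do_not_separate(self):
        inc = IncidenceMatrix(
            ["g1", "g2"], ["A"], np.array([[1], [1]], dtype=bool)
        )
        mb = MaximalBiclique(frozenset({"g1", "g2"}), frozenset({"A"}), 2)
        out = mp.silhouette_scores([mb, mb], inc)
        assert all(m.silhouette is not None and m.silhouette <= 0 for m in out)

    def test_single_biclique_undefined_but_retained(self):
        inc = IncidenceMatrix(["g1"], ["A"], np.array([[1]], dtype=bool))
        out = mp.silhouette_scores(
            [MaximalBiclique(frozenset({"g1"}), frozenset({"A"}), 1)], inc
        )
        assert len(out) == 1 and out[0].silhouette is None


class TestSelectMinSupport:
    def test_single_candidate_returned(self):
        inc = IncidenceMatrix(
            ["g1", "g2"], ["A"], np.array([[1], [1]], dtype=bool)
        )
        assert mp.select_min_support(inc, [2]) == 2

    def test_tie_resolves_to_smaller_support(self):
        inc = IncidenceMatrix(
            ["g1", "g2", "g3", "g4"],
            ["A", "B"],
            np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=bool),
        )
        # supports 1 and 2 mine the same two disjoint bicliques
        assert mp.select_min_support(inc, [2, 1]) == 1

    def test_all_candidates_empty_is_error(self):
        inc = IncidenceMatrix(["g1"], ["A"], np.array([[1]], dtype=bool))
        with pytest.raises(ValueError):
            mp.select_min_support(inc, [5, 6])

    def test_planted_modules_choose_support_at_most_module_size(self, sim, pipeline_result):
        cfg, _, _, truth, annotations, _ = sim
        genes = set(pipeline_result.stage_edges["w12"]["gene"])
        inc = mp.build_incidence(genes, annotations)
        chosen = mp.select_min_support(inc, [4, 6, 8, 10])
        assert chosen <= max(len(g) for g, _, _ in truth.planted_modules)


class TestAssembleFrps:
    def test_attachment(self):
        mb = MaximalBiclique(frozenset({"g1", "g2"}), frozenset({"A"}), 2)
        edges = pd.DataFrame(
            {"mirna": ["m1", "m2"], "gene": ["g1", "g3"], "rho": -0.5,
             "admitted_by": "stage:w6"}
        )
        frps = mp.assemble_frps([mb], edges)
        assert frps[0].mirna_ids == frozenset({"m1"})
        assert not frps[0].flagged_no_regulators

    def test_no_edges_flagged(self):
        mb = MaximalBiclique(frozenset({"g9"}), frozenset({"A"}), 1)
        edges = pd.DataFrame({"mirna": ["m1"], "gene": ["g1"], "rho": -0.5,
                              "admitted_by": "trend"})
        frps = mp.assemble_frps([mb], edges)
        assert frps[0].flagged_no_regulators

    def test_planted_regulators_all_attached(self, sim, pipeline_result):
        _, _, _, truth, _, _ = sim
        recovered = {}
        for frps in pipeline_result.frps.values():
            for frp in frps:
                for genes, terms, regs in truth.planted_modules:
                    j = len(frp.biclique.gene_ids & genes) / len(frp.biclique.gene_ids | genes)
                    if j >= 0.8 and regs <= frp.mirna_ids:
                        recovered[terms] = True
        assert len(recovered) == len(truth.planted_modules)
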