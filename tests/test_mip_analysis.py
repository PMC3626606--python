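"""MIP analysis: timing groups, polymorphism, clustering, segregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from mitescope.mip_analysis import (F2Counts, MipMatrix, TIMING_GROUPS,
                                    UNCLASSIFIED, call_species_presence,
                                    classify_matrix, classify_timing_group,
                                    jaccard_similarity, polymorphism_report,
                                    segregation_chi_square, summarize_groups,
                                    upgma_tree)


def _matrix(cells, species=None, accessions=None):
    cells = np.asarray(cells)
    n_acc, n_loci = cells.shape
    if species is None:
        species = (["B.rapa"] * 2 + ["B.oleracea"] * 3 + ["B.napus"] * 2
                   + ["outgroup"])[:n_acc]
    if accessions is None:
        accessions = [f"acc{i}" for i in range(n_acc)]
    return MipMatrix(accessions=accessions, species=species,
                     loci=[f"L{j}" for j in range(n_loci)], cells=cells)


class TestSpeciesPresence:
    def test_any_rule_with_accession_disagreement(self):
        m = _matrix([[1], [0], [0], [0], [0], [0], [0], [0]])
        out = call_species_presence(m, "L0")
        assert out["presence"]["B.rapa"] is True
        assert out["polymorphic"]["B.rapa"] is True

    def test_all_absent(self):
        m = _matrix(np.zeros((8, 1), dtype=int))
        out = call_species_presence(m, "L0")
        assert not any(out["presence"].values())

    def test_all_present_no_flags(self):
        cells = np.ones((8, 1), dtype=int)
        cells[7, 0] = 0  # outgroup
        m = _matrix(cells)
        out = call_species_presence(m, "L0")
        assert all(out["presence"][s] for s in
                   ("B.rapa", "B.oleracea", "B.napus"))
        assert not any(out["polymorphic"][s] for s in
                       ("B.rapa", "B.oleracea", "B.napus"))

    def test_alternative_rules(self):
        m = _matrix([[1], [0], [0], [0], [0], [0], [0], [0]])
        assert call_species_presence(m, "L0", rule="all")["presence"]["B.rapa"] is False
        assert call_species_presence(m, "L0", rule="majority")["presence"]["B.rapa"] is False


class TestTimingGroups:
    @pytest.mark.parametrize("presence,expected", [
        ((1, 1, 1), "Bs"), ((1, 1, 0), "Bs"),
        ((1, 0, 1), "Br-I"), ((1, 0, 0), "Br-II"),
        ((0, 1, 1), "Bo-I"), ((0, 1, 0), "Bo-II"),
        ((0, 0, 1), UNCLASSIFIED), ((0, 0, 0), UNCLASSIFIED),
    ])
    def test_group_definitions(self, presence, expected):
        r, o, n = presence
        got = classify_timing_group(
            {"B.rapa": r, "B.oleracea": o, "B.napus": n})
        assert got == expected

    def test_genomewide_panel_shared_fraction(self):
        # 9 Bs, 17 Br-I, 5 Br-II, 18 Bo-I, 1 Bo-II over 50 loci
        labels = (["Bs"] * 9 + ["Br-I"] * 17 + ["Br-II"] * 5
                  + ["Bo-I"] * 18 + ["Bo-II"] * 1)
        s = summarize_groups(labels)
        assert s["counts"]["Bs"] == 9
        assert s["shared_pct"] == 18
        assert s["unique_pct"] == 82

    def test_all_shared(self):
        assert summarize_groups(["Bs", "Bs"])["shared_pct"] == 100

    def test_counts_sum_to_classified(self):
        labels = ["Bs", "Br-I", UNCLASSIFIED, "Bo-II"]
        s = summarize_groups(labels)
        assert s["n_classified"] == 3
        assert sum(s["counts"][g] for g in TIMING_GROUPS) == 3


class TestPolymorphismReport:
    def test_monomorphic_column(self):
        cells = np.ones((8, 1), dtype=int)
        cells[7, 0] = 0  # outgroup ignored in the panel-wide call
        rep = polymorphism_report(_matrix(cells))
        assert rep["n_polymorphic"] == 0

    def test_constructed_96_percent(self):
        rng = np.random.default_rng(3)
        cells = np.zeros((8, 50), dtype=int)
        for j in range(48):  # 48 polymorphic loci
            cells[rng.integers(0, 7), j] = 1
        cells[:7, 48] = 1  # two monomorphic (all-present) loci
        cells[:7, 49] = 1
        rep = polymorphism_report(_matrix(cells))
        assert rep["n_polymorphic"] == 48
        assert rep["polymorphic_pct"] == 96

    def test_within_species_rate(self):
        # B. oleracea accessions disagree (1,0,1) at the only locus
        cells = np.array([[0], [0], [1], [0], [1], [0], [0], [0]])
        rep = polymorphism_report(_matrix(cells))
        assert rep["within_species_rates"]["B.oleracea"] == 1.0
        assert rep["within_species_rates"]["B.rapa"] == 0.0


class TestJaccard:
    def test_enumerated_example(self):
        m = _matrix([[1, 1, 0, 1], [1, 0, 0, 1]],
                    species=["B.rapa", "B.rapa"])
        J = jaccard_similarity(m)
        assert J.iloc[0, 1] == pytest.approx(2 / 3)

    def test_identical_and_disjoint(self):
        m = _matrix([[1, 1, 0], [1, 1, 0], [0, 0, 1]],
                    species=["B.rapa", "B.rapa", "B.oleracea"])
        J = jaccard_similarity(m)
        assert J.iloc[0, 1] == 1.0
        assert J.iloc[0, 2] == 0.0

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.integers(0, 2, size=(8, 30)))
        J = jaccard_similarity(m).to_numpy()
        assert np.allclose(J, J.T)
        assert np.allclose(np.diag(J), 1.0)
        assert ((J >= 0) & (J <= 1)).all()

    def test_all_zero_pair_warns(self):
        m = _matrix([[0, 0], [0, 0]], species=["B.rapa", "B.rapa"])
        with pytest.warns(UserWarning):
            J = jaccard_similarity(m)
        assert J.iloc[0, 1] == 1.0


def _cophenetic(tree, names):
    """Pairwise cophenetic distances (2x merge height of the LCA)."""
    n = len(names)
    D = np.zeros((n, n))

    def walk(node):
        if node.is_leaf:
            return [node.name]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        i, j = names.index(a), names.index(b)
                        D[i, j] = D[j, i] = 2 * node.height
        return [x for g in groups for x in g]

    walk(tree)
    return D


class TestUpgma:
    def test_three_taxon_by_hand(self):
        # d(A,B)=2, d(A,C)=d(B,C)=6 -> ((A:1,B:1):2,C:3)
        D = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        sim = pd.DataFrame(1 - D, index=list("ABC"), columns=list("ABC"))
        tree = upgma_tree(sim)
        assert tree.height == pytest.approx(3.0)
        assert tree.newick() == "((A:1,B:1):2,C:3);"

    def test_identical_accessions_join_at_zero(self):
        D = np.array([[0, 0, 4], [0, 0, 4], [4, 4, 0]], dtype=float)
        sim = pd.DataFrame(1 - D, index=list("ABC"), columns=list("ABC"))
        tree = upgma_tree(sim)
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert inner.height == 0.0

    def test_matches_reference_linkage_on_random_matrices(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = 6
            condensed = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
            D = squareform(condensed)
            names = [f"t{i}" for i in range(n)]
            sim = pd.DataFrame(1 - D, index=names, columns=names)
            tree = upgma_tree(sim)
            Z = linkage(condensed, method="average")
            ours = _cophenetic(tree, names)
            ref = squareform(cophenet(Z))
            assert np.allclose(ours, ref)

    def test_ultrametric_output(self):
        rng = np.random.default_rng(11)
        m = _matrix(rng.integers(0, 2, size=(8, 40)))
        tree = upgma_tree(jaccard_similarity(m))

        def depths(node, acc):
            if node.is_leaf:
                return [acc]
            return [d for c in node.children
                    for d in depths(c, acc + (node.height - c.height))]

        ds = depths(tree, 0.0)
        assert np.allclose(ds, ds[0])

    def test_cut_recovers_clusters(self):
        D = np.array([[0, .1, .8, .8], [.1, 0, .8, .8],
                      [.8, .8, 0, .1], [.8, .8, .1, 0]])
        names = list("ABCD")
        tree = upgma_tree(pd.DataFrame(1 - D, index=names, columns=names))
        clusters = {frozenset(c) for c in tree.cut(0.2)}
        assert clusters == {frozenset("AB"), frozenset("CD")}

    def test_asymmetric_rejected(self):
        bad = pd.DataFrame([[1, .2], [.3, 1]], index=list("AB"),
                           columns=list("AB"))
        with pytest.raises(ValueError):
            upgma_tree(bad)


class TestSegregation:
    def test_observed_f2_counts_fit_mendelian(self):
        res = segregation_chi_square(F2Counts(22, 50, 21))
        assert res["chi2"] == pytest.approx(0.548, abs=0.001)
        assert res["df"] == 2
        assert res["p"] == pytest.approx(0.76, abs=0.01)

    def test_perfect_fit(self):
        assert segregation_chi_square(F2Counts(25, 50, 25))["chi2"] == 0.0

    def test_extreme_deviation(self):
        assert segregation_chi_square(F2Counts(0, 0, 100))["p"] < 1e-6

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(a=st.integers(0, 200), h=st.integers(0, 200),
           b=st.integers(0, 200), k=st.integers(1, 9))
    def test_ratio_scale_invariance(self, a, h, b, k):
        if a + h + b == 0:
            return
        c = F2Counts(a, h, b)
        r1 = segregation_chi_square(c, ratio=(1, 2, 1))
        r2 = segregation_chi_square(c, ratio=(k, 2 * k, k))
        assert r1["chi2"] == pytest.approx(r2["chi2"])

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            F2Counts(0, 0, 0)


class TestNoisePropagation:
    def test_within_species_noise_rate_recovered(self):
        from mitescope.synthetic_data import simulate_mip_panel
        eps = 0.1
        rates = []
        for rep in range(20):
            m, _ = simulate_mip_panel(100, within_species_poly_rate=eps,
                                      seed=300 + rep)
            rep_ = polymorphism_report(m)
            rates.append(rep_["within_species_rates"]["B.rapa"])
        # two B. rapa accessions disagree when exactly one of two flips
        expect = 2 * eps * (1 - eps)
        assert np.mean(rates) == pytest.approx(expect, abs=0.03)
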