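"""Generator contracts: structure, composition, determinism, invertibility."""

import numpy as np
import pytest

from mitescope import synthetic_data as syn
from mitescope._seq import at_fraction, revcomp
from mitescope.mip_analysis import TIMING_GROUPS, classify_timing_group


class TestConsensusFixture:
    def test_default_structure(self, model):
        assert len(model.consensus) == 260
        assert model.tir_len == 33
        assert model.internal_len == 194
        arm5 = model.consensus[:33]
        arm3 = model.consensus[-33:]
        assert arm5 == revcomp(arm3)  # exact terminal inverted repeat
        assert at_fraction(arm5) >= 0.69
        assert at_fraction(model.consensus) >= 0.6

    def test_tir_mandatory(self):
        with pytest.raises(syn.ParameterError):
            syn.make_consensus_fixture(tir_len=0)

    def test_infeasible_length(self):
        with pytest.raises(syn.ParameterError):
            syn.make_consensus_fixture(length=60, tir_len=33)

    def test_seed_contract(self):
        a = syn.make_consensus_fixture(seed=1)
        b = syn.make_consensus_fixture(seed=2)
        again = syn.make_consensus_fixture(seed=1)
        assert a.consensus == again.consensus
        assert a.consensus != b.consensus
        assert (a.tir_len, a.internal_len) == (b.tir_len, b.internal_len)


class TestGenome:
    def test_at_fraction_matches_target(self):
        g = syn.generate_genome(1_000_000, 0.6, seed=1)
        assert at_fraction(g.seq) == pytest.approx(0.6, abs=0.005)

    def test_open_interval(self):
        with pytest.raises(syn.ParameterError):
            syn.generate_genome(100, 1.0)

    def test_deterministic(self):
        assert (syn.generate_genome(5000, 0.6, seed=9).seq
                == syn.generate_genome(5000, 0.6, seed=9).seq)


class TestGeneModels:
    def test_composition_targets_recovered(self):
        g = syn.generate_genome(2_000_000, 0.6, seed=5)
        g2, genes = syn.generate_gene_models(g, 100, seed=6)
        from mitescope.insertion_annotation import regional_at_composition
        comp = regional_at_composition(g2, genes)
        assert comp["exonic_at"] == pytest.approx(0.54, abs=0.01)
        assert comp["intronic_at"] == pytest.approx(0.65, abs=0.01)

    def test_no_genes_leaves_genome_unchanged(self):
        g = syn.generate_genome(10_000, 0.6, seed=1)
        g2, genes = syn.generate_gene_models(g, 0, seed=2)
        assert genes == [] and g2.seq == g.seq

    def test_thirteen_exon_gene_has_twelve_introns(self):
        g = syn.generate_genome(50_000, 0.6, seed=3)
        _, genes = syn.generate_gene_models(
            g, 1, exon_profile={"n_exons": (13, 13)}, seed=4)
        assert len(genes[0].exons) == 13
        assert len(genes[0].introns) == 12

    def test_genome_too_small(self):
        g = syn.generate_genome(1000, 0.6, seed=1)
        with pytest.raises(syn.PlacementError):
            syn.generate_gene_models(g, 50, seed=2)

    def test_genes_non_overlapping(self):
        g = syn.generate_genome(500_000, 0.6, seed=7)
        _, genes = syn.generate_gene_models(g, 40, seed=8)
        spans = sorted(g.span for g in genes)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


class TestPlantElements:
    def test_rate_zero_copies_exact_and_ta_flanked(self, model, small_planted):
        _, res = small_planted
        for t in res.truth:
            sub = res.genome.seq[t.start:t.end]
            expect = model.consensus if t.strand == "+" else revcomp(model.consensus)
            assert sub == expect
            assert res.genome.seq[t.start - 2:t.start] == "TA"
            assert res.genome.seq[t.end:t.end + 2] == "TA"

    def test_rate_zero_is_invertible(self, model, small_planted):
        pre, res = small_planted
        seq = res.genome.seq
        # excise each element plus ONE flanking TA, right to left
        for t in sorted(res.truth, key=lambda t: -t.start):
            seq = seq[: t.start - 2] + seq[t.end:]
        assert seq == pre.seq

    def test_truth_spans_disjoint_and_in_bounds(self, small_planted):
        _, res = small_planted
        spans = sorted((t.start, t.end) for t in res.truth)
        assert all(0 <= s < e <= len(res.genome.seq) for s, e in spans)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def test_region_bias_multinomial(self, model):
        # class counts near expectation for the default (gene-rich) bias
        g = syn.generate_genome(6_000_000, 0.6, seed=21)
        g2, genes = syn.generate_gene_models(g, 260, seed=22)
        res = syn.plant_elements(g2, genes, model, 697, mutation_rate=0.0,
                                 seed=23)
        counts = {c: 0 for c in syn.REGION_CLASSES}
        for t in res.truth:
            counts[t.region_class] += 1
        expected = {c: 697 * p for c, p in syn.DEFAULT_REGION_BIAS.items()}
        for c in syn.REGION_CLASSES:
            sd = np.sqrt(697 * syn.DEFAULT_REGION_BIAS[c]
                         * (1 - syn.DEFAULT_REGION_BIAS[c]))
            assert abs(counts[c] - expected[c]) < 4 * sd + 1

    def test_mutation_rate_gives_expected_identity(self, model):
        g = syn.generate_genome(1_000_000, 0.6, seed=31)
        g2, genes = syn.generate_gene_models(g, 50, seed=32)
        res = syn.plant_elements(g2, genes, model, 60, mutation_rate=0.1,
                                 seed=33)
        mean_id = np.mean([1 - t.mutations_applied / len(model)
                           for t in res.truth])
        assert mean_id == pytest.approx(0.90, abs=0.02)

    def test_genic_insertions_only_in_introns(self, small_planted):
        _, res = small_planted
        for t in res.truth:
            if t.region_class != "genic":
                continue
            gene = next(g for g in res.genes
                        if g.start <= t.start and t.end <= g.end)
            assert any(s <= t.start and t.end <= e for s, e in gene.introns)

    def test_insufficient_sites_names_class(self, model):
        g = syn.generate_genome(20_000, 0.6, seed=41)
        with pytest.raises(syn.PlacementError, match="genic"):
            # no genes at all: the genic class cannot be satisfied
            syn.plant_elements(g, [], model, 10, seed=42,
                               region_bias={"genic": 1.0, "near1k": 0,
                                            "near2k": 0, "near3k": 0,
                                            "intergenic": 0})

    def test_invalid_rate(self, model, small_planted):
        pre, _ = small_planted
        with pytest.raises(syn.ParameterError):
            syn.plant_elements(pre, [], model, 1, mutation_rate=0.5)


class TestGss:
    def test_read_count_formula(self):
        g = syn.generate_genome(1_000_000, 0.6, seed=51)
        survey = syn.simulate_gss(g, coverage=1.0, read_len=700, seed=52)
        assert len(survey.reads) == 1429  # round(1e6 / 700)
        assert survey.db_size == pytest.approx(1_000_000, rel=0.01)
        assert survey.coverage == pytest.approx(1.0, rel=0.01)

    def test_zero_coverage_rejected(self):
        g = syn.generate_genome(10_000, 0.6, seed=1)
        with pytest.raises(syn.ParameterError):
            syn.simulate_gss(g, coverage=0.0)

    def test_deterministic(self):
        g = syn.generate_genome(50_000, 0.6, seed=1)
        a = syn.simulate_gss(g, 0.5, read_len=700, seed=2)
        b = syn.simulate_gss(g, 0.5, read_len=700, seed=2)
        assert [r.seq for r in a.reads] == [r.seq for r in b.reads]


class TestMipPanel:
    def test_noiseless_recovery_all_groups(self):
        matrix, truth = syn.simulate_mip_panel(
            50, group_probs={g: 0.2 for g in TIMING_GROUPS}, seed=61)
        from mitescope.mip_analysis import classify_matrix
        labels = classify_matrix(matrix)
        assert list(labels.values()) == truth
        assert set(truth) == set(TIMING_GROUPS)

    def test_outgroup_always_absent(self):
        matrix, _ = syn.simulate_mip_panel(30, seed=62,
                                           within_species_poly_rate=0.2)
        out_rows = [i for i, s in enumerate(matrix.species) if s == "outgroup"]
        assert (matrix.cells[out_rows] == 0).all()

    def test_shared_fraction_matches_probs(self):
        # expected shared fraction is the Bs probability (18% here)
        from mitescope.mip_analysis import classify_matrix, summarize_groups
        fracs = []
        for rep in range(30):
            matrix, _ = syn.simulate_mip_panel(50, seed=100 + rep)
            fracs.append(summarize_groups(classify_matrix(matrix))["shared_fraction"])
        assert np.mean(fracs) == pytest.approx(0.18, abs=0.03)

    def test_empty_panel(self):
        matrix, truth = syn.simulate_mip_panel(0, seed=1)
        assert truth == [] and matrix.cells.shape[1] == 0

    def test_bad_probs_rejected(self):
        with pytest.raises(syn.ParameterError):
            syn.simulate_mip_panel(10, group_probs={g: 0.5 for g in TIMING_GROUPS})


class TestF2:
    def test_het_fraction_expectation(self):
        rng_seeds = range(200)
        fracs = [syn.simulate_f2(94, seed=s).n_het / 94 for s in rng_seeds]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.01)

    def test_single_plant(self):
        c = syn.simulate_f2(1, seed=3)
        assert sorted([c.n_p1hom, c.n_het, c.n_p2hom])[:2] == [0, 0]
        assert c.total == 1

    def test_deterministic(self):
        assert syn.simulate_f2(94, seed=9) == syn.simulate_f2(94, seed=9)
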