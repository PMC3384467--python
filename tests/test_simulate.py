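import numpy as np
import pytest
from scipy.stats import chisquare

from cogevo import (CultureParams, simulate_batch_culture, simulate_cog,
                    simulate_genome, simulate_taxonomy)
from cogevo.simulate import (SUMMARY_CLASS_CODES, SimulationTruth,
                             evolve_states, plan_cog_truths,
                             simulate_species_tree)
from cogevo.taxa import Category

REF = [c for c in Category if c is not Category.FOCAL]


class TestTaxonomy:
    def test_histogram_matches_request(self):
        counts = {c: 2 for c in REF}
        ts = simulate_taxonomy(counts, seed=1)
        assert len(ts) == 10
        assert ts.histogram() == counts

    def test_full_reference_panel_of_59_bacteria_41_archaea(self):
        counts = {Category.PROTEO: 30, Category.OTHER_BACT: 29,
                  Category.THERMO_ARCH: 14, Category.HALO_ARCH: 14,
                  Category.OTHER_ARCH: 13}
        ts = simulate_taxonomy(counts, seed=3)
        assert len(ts) == 100
        assert sum(1 for r in ts if r.domain == "Bacteria") == 59
        assert sum(1 for r in ts if r.domain == "Archaea") == 41

    def test_deterministic_for_fixed_seed(self):
        counts = {c: 3 for c in REF}
        assert simulate_taxonomy(counts, 7) == simulate_taxonomy(counts, 7)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_taxonomy({Category.PROTEO: 0}, seed=1)

    def test_roundtrips_through_tsv(self, small_taxa, tmp_path):
        p = tmp_path / "tax.tsv"
        small_taxa.write_tsv(p)
        from cogevo.taxa import TaxonSet
        back = TaxonSet.read_tsv(p)
        assert back.ids() == small_taxa.ids()
        assert back.histogram() == small_taxa.histogram()


class TestSpeciesTree:
    def test_categories_form_clades(self, small_taxa):
        tree = simulate_species_tree(small_taxa, seed=5)
        splits = {a for a, b, _ in tree.bipartitions()} | \
                 {b for a, b, _ in tree.bipartitions()}
        for cat in REF:
            members = frozenset(small_taxa.ids(cat))
            assert members in splits, f"{cat} not monophyletic"

    def test_all_taxa_present_once(self, small_taxa):
        tree = simulate_species_tree(small_taxa, seed=5)
        assert sorted(tree.leaf_names) == sorted(small_taxa.ids())


class TestSimulateCog:
    def test_zero_branch_lengths_give_identical_sequences(self, small_taxa,
                                                          wag_model):
        truth = SimulationTruth("C1", "C1_A1", "P", seed=1)
        aln, _ = simulate_cog(small_taxa, truth, n_sites=50, model=wag_model,
                              seed=2, branch_scale=0.0, backbone_length=0.0,
                              focal_pendant_range=(0.0, 0.0))
        assert len(set(aln.seqs)) == 1

    def test_planted_proteo_sister_leaves_are_proteo(self, small_taxa,
                                                     wag_model):
        truth = SimulationTruth("C1", "C1_A1", "P", seed=9)
        _, tree = simulate_cog(small_taxa, truth, n_sites=10, model=wag_model,
                               seed=9)
        focal = tree.node_of("C1_A1")
        attach = next(iter(tree.adj[focal]))
        proteo = set(small_taxa.ids(Category.PROTEO))
        sides = [tree.side_leaves(nbr, attach)
                 for nbr in tree.adj[attach] if nbr != focal]
        assert any(side <= proteo for side in sides)

    def test_branch_identity_fraction_matches_matrix_exponential(self,
                                                                 wag_model,
                                                                 rng):
        """Fraction of unchanged sites over t=1 equals sum_i pi_i P_ii(t)."""
        n = 10_000
        t = 1.0
        p = wag_model.transition_matrix(t)
        expected = float(np.dot(wag_model.frequencies, np.diag(p)))
        parent = rng.choice(20, size=n, p=wag_model.frequencies)
        child = evolve_states(parent, p, rng)
        observed = float(np.mean(parent == child))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_leaf_frequencies_converge_to_equilibrium(self, wag_model, rng):
        """A long branch from a point mass relaxes to pi (chi-square GOF)."""
        n = 10_000
        parent = np.zeros(n, dtype=int)  # all alanine
        child = evolve_states(parent, wag_model.transition_matrix(50.0), rng)
        counts = np.bincount(child, minlength=20)
        stat, pval = chisquare(counts, n * wag_model.frequencies)
        assert pval > 0.01

    def test_gap_fraction_masks_expected_columns(self, small_taxa, wag_model):
        truth = SimulationTruth("C1", "C1_A1", "B", seed=4)
        aln, _ = simulate_cog(small_taxa, truth, n_sites=200, model=wag_model,
                              gap_fraction=0.25, seed=4)
        gapped_cols = sum(
            1 for i in range(aln.n_sites)
            if any(s[i] == "-" for s in aln.seqs))
        assert gapped_cols == 50

    def test_nc_allele_hangs_from_long_pendant(self, small_taxa, wag_model):
        truth = SimulationTruth("C1", "C1_A1", "NC", seed=6)
        _, tree = simulate_cog(small_taxa, truth, n_sites=10, model=wag_model,
                               seed=6)
        pend = tree.pendant_lengths()
        others = [v for k, v in pend.items() if k != "C1_A1"]
        assert pend["C1_A1"] >= 5 * float(np.median(others))

    def test_too_few_donor_taxa_rejected(self, wag_model):
        taxa = simulate_taxonomy({Category.PROTEO: 3, Category.OTHER_BACT: 6},
                                 seed=1)
        truth = SimulationTruth("C1", "C1_A1", "P", seed=1)
        with pytest.raises(ValueError, match="4 taxa"):
            simulate_cog(taxa, truth, n_sites=10, model=wag_model, seed=1)

    def test_invalid_gap_fraction_rejected(self, small_taxa, wag_model):
        truth = SimulationTruth("C1", "C1_A1", "P", seed=1)
        with pytest.raises(ValueError):
            simulate_cog(small_taxa, truth, n_sites=10, model=wag_model,
                         gap_fraction=1.0, seed=1)


FRACTIONS = {"other_bacteria_hgt": 0.44, "proteobacteria_vertical": 0.34,
             "archaeal_hgt": 0.13, "no_cluster": 0.09}
CODE_TO_CLASS = {code: cls for cls, codes in SUMMARY_CLASS_CODES.items()
                 for code in codes}


def test_stratified_planting_realises_fractions_exactly():
    n = 160
    truths = plan_cog_truths(n, FRACTIONS, seed=2)
    for cls, p in FRACTIONS.items():
        observed = sum(CODE_TO_CLASS[t.planted_code] == cls
                       for t in truths) / n
        assert abs(observed - p) <= 1.0 / n + 1e-12, cls


def test_multinomial_planting_matches_fractions_within_3_se():
    n = 4000
    truths = plan_cog_truths(n, FRACTIONS, seed=2, stratified=False)
    for cls, p in FRACTIONS.items():
        observed = sum(CODE_TO_CLASS[t.planted_code] == cls
                       for t in truths) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * se, cls


class TestGenome:
    def test_no_genes_means_all_intergenic(self):
        seq, ann = simulate_genome(1000, 0, 0.5, seed=1)
        assert len(seq) == 1000
        assert ann.genes == []

    def test_realised_gc_near_target(self):
        seq, _ = simulate_genome(100_000, 50, 0.5469, seed=2)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.5369 <= gc <= 0.5569

    def test_deterministic_fasta(self, tmp_path):
        from cogevo.simulate import write_genome_fasta
        out = []
        for run in (1, 2):
            seq, _ = simulate_genome(5000, 5, 0.5, seed=9)
            p = tmp_path / f"g{run}.fa"
            write_genome_fasta(seq, "contig1", p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_infeasible_gene_load_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(1000, 100, 0.5, seed=1)

    def test_genes_fit_and_do_not_overlap(self):
        _, ann = simulate_genome(60_000, 40, 0.5, seed=3)
        assert len(ann.genes) == 40
        prev_end = 0
        for g in sorted(ann.genes, key=lambda g: g.start):
            assert g.start > prev_end
            assert g.end <= 60_000
            prev_end = g.end


class TestBatchCulture:
    def test_zero_substrates_flat_series(self):
        params = CultureParams(sucrose_0=0, glucose_0=0, msg_0=0,
                               rcm_0=0.5, phb_0=0.1)
        s = simulate_batch_culture(params, horizon=10, dt=1.0)
        assert np.allclose(s.cdw_gL, 0.6)
        assert np.allclose(s.phb_gL, 0.1)

    def test_growth_monotone_until_glutamate_depletion(self):
        params = CultureParams(sucrose_0=0, glucose_0=20, msg_0=3)
        s = simulate_batch_culture(params, horizon=30, dt=0.5)
        depleted = np.flatnonzero(s.msg_gL <= 1e-9)
        assert depleted.size > 0  # glutamate does run out
        rcm = s.rcm_gL
        assert np.all(np.diff(s.cdw_gL) >= -1e-12)
        # residual cell mass stops growing once glutamate is gone
        after = depleted[0]
        assert rcm[-1] - rcm[after] < 0.05 * rcm[after]

    def test_diauxic_sucrose_plateau_then_decline(self):
        """Sucrose holds steady while glucose is drawn down, then falls."""
        s = simulate_batch_culture(horizon=33, dt=0.5)
        low_glc = np.flatnonzero(s.glucose_gL < 1.0)
        assert low_glc.size > 0
        t_switch = low_glc[0]
        msg_gone = np.flatnonzero(s.msg_gL <= 1e-9)[0]
        plateau = slice(msg_gone, t_switch)
        assert s.glucose_gL[plateau.start] - s.glucose_gL[plateau.stop - 1] \
            > 1.0
        assert abs(s.sucrose_gL[plateau.start]
                   - s.sucrose_gL[plateau.stop - 1]) < 0.2
        assert s.sucrose_gL[-1] < s.sucrose_gL[t_switch] - 1.0

    def test_conservation_cdw_equals_rcm_plus_phb(self):
        s = simulate_batch_culture(CultureParams(noise_sd=0.05), horizon=20,
                                   dt=0.5, seed=11)
        assert np.abs(s.cdw_gL - s.phb_gL - s.rcm_gL).max() == 0.0

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            CultureParams(mu_max=-0.1)

    def test_csv_roundtrip(self, tmp_path):
        s = simulate_batch_culture(horizon=5, dt=1.0)
        p = tmp_path / "series.csv"
        s.to_csv(p)
        from cogevo import CultureSeries
        back = CultureSeries.from_csv(p)
        assert np.allclose(back.cdw_gL, s.cdw_gL)
        assert np.allclose(back.sucrose_gL, s.sucrose_gL)
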