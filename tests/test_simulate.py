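"""Generator contracts: determinism, geometric invariants, ground-truth
statistical structure."""

import numpy as np
import pandas as pd
import pytest

from monosomics.simulate import (BUFFERING_CATEGORIES, BufferingMixture, CohortSpec,
                                 SimGenome, simulate_annotation, simulate_cohort,
                                 simulate_expression, simulate_polysome_trace,
                                 simulate_read_depth)


class TestAnnotation:
    def test_intervals_valid_and_sorted(self, small_annotation):
        ann = small_annotation
        assert (ann["start"] >= 0).all()
        assert (ann["end"] > ann["start"]).all()
        for _, sub in ann.groupby("chromosome"):
            starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
            assert (np.diff(starts) > 0).all()
            assert (ends[:-1] <= starts[1:]).all()  # non-overlapping half-open

    def test_deterministic_under_seed(self):
        spec = SimGenome(chromosomes=(("chr1", 500_000),), genes_per_chromosome=10, seed=5)
        pd.testing.assert_frame_equal(simulate_annotation(spec), simulate_annotation(spec))

    def test_rpg_count_per_chromosome(self):
        spec = SimGenome(
            chromosomes=tuple((f"chr{i}", 500_000) for i in range(1, 6)),
            genes_per_chromosome=20, rpg_per_chromosome=1, seed=1,
        )
        ann = simulate_annotation(spec)
        assert ann["is_rpg"].sum() == 5
        assert (ann.groupby("chromosome")["is_rpg"].sum() == 1).all()

    def test_rpg_free_chromosome_has_none(self):
        spec = SimGenome(chromosomes=(("chr7", 500_000), ("chr8", 500_000)),
                         genes_per_chromosome=20, seed=1)
        ann = simulate_annotation(spec)
        assert ann.loc[ann["chromosome"] == "chr7", "is_rpg"].sum() == 0
        assert ann.loc[ann["chromosome"] == "chr8", "is_rpg"].sum() == 1

    @pytest.mark.parametrize("bad", [
        dict(chromosomes=()),
        dict(genes_per_chromosome=0),
        dict(corum_fraction=1.5),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            SimGenome(**bad).validate()


class TestReadDepth:
    def test_noise_free_expectation(self, small_annotation):
        bins = simulate_read_depth(small_annotation, {"chr1": 2, "chr2": 1},
                                   bin_size=50_000, mean_depth=80.0, dispersion=None)
        assert (bins.loc[bins["chromosome"] == "chr1", "coverage"] == 80.0).all()
        assert (bins.loc[bins["chromosome"] == "chr2", "coverage"] == 40.0).all()

    def test_bins_tile_half_open(self, small_annotation):
        bins = simulate_read_depth(small_annotation, {"chr1": 2}, bin_size=30_000,
                                   dispersion=None,
                                   chrom_lengths={"chr1": 1_000_000})
        sub = bins[bins["chromosome"] == "chr1"]
        assert sub["start"].iloc[0] == 0
        assert (sub["end"].iloc[:-1].to_numpy() == sub["start"].iloc[1:].to_numpy()).all()
        assert sub["end"].iloc[-1] == 1_000_000

    def test_monte_carlo_mean_matches_copy_ratio(self):
        ann = pd.DataFrame({"gene": ["g"], "chromosome": ["chrA"],
                            "start": [0], "end": [10_000_000]})
        bins = simulate_read_depth(ann, {"chrA": 1}, bin_size=1000, mean_depth=100.0,
                                   dispersion=0.05, seed=2)
        cov = bins["coverage"].to_numpy()
        assert len(cov) == 10_000
        m = 50.0
        se = np.sqrt((m + 0.05 * m**2) / len(cov))
        assert abs(cov.mean() - m) < 3 * se

    def test_invalid_copy_number_rejected(self, small_annotation):
        with pytest.raises(ValueError):
            simulate_read_depth(small_annotation, {"chr1": -1})
        with pytest.raises(ValueError):
            simulate_read_depth(small_annotation, {"chr1": 1.5})


class TestExpression:
    def test_degenerate_unbuffered_mixture(self, small_annotation):
        mix = BufferingMixture(p_uu=0, p_du=0, p_dd=1, p_ud=0,
                               sigma_gene=1e-9, sigma_rep=1e-9)
        sim = simulate_expression(small_annotation, {"chr2"}, mix, seed=0)
        mono = sim.truth[sim.truth["monosomic"]]
        assert np.allclose(mono["true_mrna_log2fc"], -1.0, atol=1e-6)
        assert np.allclose(mono["true_protein_log2fc"], -1.0, atol=1e-6)
        assert (mono["category"] == "down;down").all()

    def test_fully_buffered_mixture_centered_at_zero(self, small_annotation):
        mix = BufferingMixture(p_uu=1, p_du=0, p_dd=0, p_ud=0, sigma_gene=0.1)
        sim = simulate_expression(small_annotation, {"chr2"}, mix, seed=1)
        mono = sim.truth[sim.truth["monosomic"]]
        assert abs(mono["true_mrna_log2fc"].mean()) < 0.05
        assert abs(mono["true_protein_log2fc"].mean()) < 0.05

    def test_category_counts_multinomial(self):
        genome = SimGenome(chromosomes=(("chr1", 2_000_000), ("chr2", 2_000_000)),
                           genes_per_chromosome=2000, seed=7)
        ann = simulate_annotation(genome)
        mix = BufferingMixture()
        sim = simulate_expression(ann, {"chr1"}, mix, seed=8)
        counts = sim.truth.loc[sim.truth["monosomic"], "category"].value_counts()
        n = 2000
        for cat, p in zip(BUFFERING_CATEGORIES, mix.probabilities):
            se = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(cat, 0) - n * p) < 3 * se, cat

    def test_pure_dosage_median_true_fc(self):
        # pure-dosage configuration pins the median monosomic log2FC at -1
        genome = SimGenome(chromosomes=(("chr1", 2_000_000), ("chr2", 2_000_000)),
                           genes_per_chromosome=500, seed=3)
        ann = simulate_annotation(genome)
        mix = BufferingMixture(p_uu=0, p_du=0, p_dd=1, p_ud=0, sigma_gene=0.1)
        sim = simulate_expression(ann, {"chr1"}, mix, seed=4)
        med = sim.truth.loc[sim.truth["monosomic"], "true_mrna_log2fc"].median()
        assert abs(med - (-1.0)) < 0.05

    def test_empty_monosome_rejected(self, small_annotation):
        with pytest.raises(ValueError):
            simulate_expression(small_annotation, set(), BufferingMixture())

    def test_deterministic(self, small_annotation):
        a = simulate_expression(small_annotation, {"chr2"}, seed=9)
        b = simulate_expression(small_annotation, {"chr2"}, seed=9)
        pd.testing.assert_frame_equal(a.mrna.data, b.mrna.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestPolysomeTrace:
    def test_single_peak_height_and_position(self):
        profile, truth = simulate_polysome_trace(
            peak_positions=(50.0,), peak_heights=(0.7,), peak_widths=(3.0,),
            baseline=0.1, noise_sd=0.0, n_points=1001)
        i = np.argmax(profile.absorbance)
        assert profile.positions[i] == pytest.approx(50.0, abs=0.1)
        assert profile.absorbance[i] == pytest.approx(0.8, abs=1e-6)

    def test_two_peak_ratio(self):
        profile, _ = simulate_polysome_trace(
            peak_positions=(20.0, 70.0), peak_heights=(0.4, 0.2), peak_widths=(2.0, 2.0),
            baseline=0.0, noise_sd=0.0, n_points=2001)
        x, y = profile.positions, profile.absorbance
        h1 = y[(x > 10) & (x < 30)].max()
        h2 = y[(x > 60) & (x < 80)].max()
        assert h1 / h2 == pytest.approx(2.0, rel=1e-6)

    def test_deterministic_noise(self):
        a, _ = simulate_polysome_trace(noise_sd=0.02, seed=5)
        b, _ = simulate_polysome_trace(noise_sd=0.02, seed=5)
        assert np.array_equal(a.absorbance, b.absorbance)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            simulate_polysome_trace(peak_positions=(10.0,), peak_heights=(1.0,),
                                    peak_widths=(0.0,))


class TestCohort:
    def test_stratum_counts_multinomial(self):
        spec = CohortSpec(n_samples=1000, somy_fractions=(0.1, 0.8, 0.1), seed=0)
        sim = simulate_cohort(spec)
        counts = sim.truth["stratum"].value_counts()
        for name, p in zip(("Monosomy", "Disomy", "Polysomy"), (0.1, 0.8, 0.1)):
            se = np.sqrt(1000 * p * (1 - p))
            assert abs(counts.get(name, 0) - 1000 * p) < 3 * se, name

    def test_equal_alteration_probability_gives_null_odds(self):
        spec = CohortSpec(n_samples=4000, tp53_alt_prob=(0.3, 0.3, 0.3), seed=1)
        sim = simulate_cohort(spec)
        merged = sim.table.merge(sim.truth, on="sample")
        mono = merged[merged["stratum"] == "Monosomy"]["tp53_altered"].mean()
        rest = merged[merged["stratum"] != "Monosomy"]["tp53_altered"].mean()
        odds = (mono / (1 - mono)) / (rest / (1 - rest))
        assert 0.7 < odds < 1.4

    def test_pathway_genes_shifted_in_monosomy(self):
        genes = [f"g{i:05d}" for i in range(20)]
        spec = CohortSpec(n_samples=600, n_genes=100, pathway_effect=-0.5, seed=2)
        sim = simulate_cohort(spec, {"term": genes})
        mono = sim.truth.loc[sim.truth["stratum"] == "Monosomy", "sample"]
        diso = sim.truth.loc[sim.truth["stratum"] == "Disomy", "sample"]
        diff = (sim.expression.loc[genes, mono].values.mean()
                - sim.expression.loc[genes, diso].values.mean())
        assert diff == pytest.approx(-0.5, abs=0.1)

    def test_unknown_pathway_gene_rejected(self):
        spec = CohortSpec(n_samples=10, n_genes=5, seed=0)
        with pytest.raises(ValueError, match="outside the expression universe"):
            simulate_cohort(spec, {"term": ["not_a_gene"]})

    def test_ploidy_positive(self):
        spec = CohortSpec(n_samples=2000, seed=3)
        sim = simulate_cohort(spec)
        assert (sim.table["ploidy"] > 0).all()
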