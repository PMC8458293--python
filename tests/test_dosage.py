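"""Normalization, fold changes, buffering classification and extreme-protein
filters."""

import numpy as np
import pandas as pd
import pytest

from monosomics.dosage import (BufferingParams, classify_buffering,
                               complex_membership_shift, chromosome_median_profile,
                               log2_fold_change, median_shift_normalize,
                               median_shift_normalize_pair, pooled_monosome_medians,
                               shared_extreme_proteins)
from monosomics.simulate import BufferingMixture
from tests.conftest import expression_matrix, make_fold_change_table


class TestMedianShiftNormalize:
    def test_replicate_medians_meet_at_grand_median(self):
        # 3 non-excluded genes per replicate with medians 5 and 7 -> both 6
        m = expression_matrix({"a": [4, 6], "b": [5, 7], "c": [6, 8], "x": [0, 0]})
        out = median_shift_normalize(m, exclude={"x"})
        kept = out.data.loc[["a", "b", "c"]]
        assert kept.median(axis=0).tolist() == [6.0, 6.0]
        # excluded gene shifted by the same per-replicate constants (+1, -1)
        assert out.data.loc["x"].tolist() == [1.0, -1.0]

    def test_equal_medians_identity(self):
        m = expression_matrix({"a": [1.0, 1.0], "b": [2.0, 2.0], "c": [3.0, 3.0]})
        out = median_shift_normalize(m, exclude=set())
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_constant_replicate_offset_undone(self):
        m = expression_matrix({"a": [1, 1], "b": [2, 2], "c": [3, 3]})
        shifted = expression_matrix({"a": [1, 1.7], "b": [2, 2.7], "c": [3, 3.7]})
        out = median_shift_normalize(shifted, exclude=set())
        ref = median_shift_normalize(m, exclude=set())
        # the +0.7 offset on replicate 2 is removed up to the common anchor
        assert np.allclose(out.data.sub(out.data.median(axis=0), axis=1),
                           ref.data.sub(ref.data.median(axis=0), axis=1))

    def test_excluding_all_genes_rejected(self):
        m = expression_matrix({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            median_shift_normalize(m, exclude={"a", "b"})

    def test_monosomic_genes_not_pulled_to_zero(self, small_annotation):
        mix = BufferingMixture(p_uu=0, p_du=0, p_dd=1, p_ud=0)
        fc, _ = make_fold_change_table(small_annotation, {"chr2"}, mix, seed=11)
        mono_median = fc.loc[fc["monosomic"], "mrna_log2fc"].median()
        assert mono_median == pytest.approx(-1.0, abs=0.1)


class TestFoldChange:
    def test_replicate_median_difference(self):
        sample = expression_matrix({"a": [9.0, 9.0, 9.0]})
        parental = expression_matrix({"a": [10.0, 10.0, 10.0]})
        fc = log2_fold_change(sample, parental)
        assert fc["a"] == pytest.approx(-1.0)

    def test_identical_matrices_zero(self):
        m = expression_matrix({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        assert (log2_fold_change(m, m) == 0).all()

    def test_disjoint_universes_rejected(self):
        a = expression_matrix({"a": [1.0]})
        b = expression_matrix({"b": [1.0]})
        with pytest.raises(ValueError):
            log2_fold_change(a, b)

    def test_pair_normalization_pins_disomic_fold_changes_at_zero(self, fc_table):
        diso = fc_table.loc[~fc_table["monosomic"]]
        assert abs(diso["mrna_log2fc"].median()) < 0.07
        assert abs(diso["protein_log2fc"].median()) < 0.07


class TestChromosomeProfile:
    def test_single_chromosome_median(self):
        fc = pd.DataFrame({"gene": list("abc"), "chromosome": ["c"] * 3,
                           "mrna_log2fc": [-1.0, -0.5, 0.0],
                           "protein_log2fc": [0.0, 0.0, 0.0],
                           "monosomic": [True] * 3, "corum": [False] * 3})
        prof = chromosome_median_profile(fc)
        assert prof["mrna_log2fc"].iloc[0] == -0.5

    def test_mixture_medians_ordered(self, small_annotation):
        # protein buffering lifts the monosome protein median above the
        # mRNA median; both sit between -1 and 0
        fc, _ = make_fold_change_table(small_annotation, {"chr2"}, seed=5)
        prof = chromosome_median_profile(fc).set_index("chromosome")
        m = prof.loc["chr2"]
        assert -1.0 < m["mrna_log2fc"] < 0.0
        assert m["protein_log2fc"] > m["mrna_log2fc"]


class TestClassifyBuffering:
    @pytest.mark.parametrize("mrna,protein,expected", [
        (-0.2, -0.1, "up;up"),
        (-0.8, -0.1, "down;up"),
        (-0.8, -0.9, "down;down"),
        (-0.3, -0.7, "up;down"),
        (-0.5, -0.5, "down;down"),  # exact cutoff goes to the down side
    ])
    def test_category_rules(self, mrna, protein, expected):
        fc = pd.DataFrame({"gene": ["g"], "chromosome": ["c"],
                           "mrna_log2fc": [mrna], "protein_log2fc": [protein],
                           "monosomic": [True], "corum": [False]})
        result = classify_buffering(fc, BufferingParams())
        assert result.categories["g"] == expected

    def test_fractions_sum_to_one_and_order_invariant(self, fc_table):
        r1 = classify_buffering(fc_table)
        r2 = classify_buffering(fc_table.sample(frac=1, random_state=0))
        assert sum(r1.fractions.values()) == pytest.approx(1.0)
        assert r1.fractions == r2.fractions

    def test_missing_protein_excluded_from_matched_set(self):
        fc = pd.DataFrame({"gene": ["g1", "g2"], "chromosome": ["c", "c"],
                           "mrna_log2fc": [-0.8, -0.8],
                           "protein_log2fc": [np.nan, -0.1],
                           "monosomic": [True, True], "corum": [False, False]})
        result = classify_buffering(fc)
        assert result.n_matched == 1
        assert list(result.categories.index) == ["g2"]

    def test_no_monosomic_genes_rejected(self):
        fc = pd.DataFrame({"gene": ["g"], "chromosome": ["c"],
                           "mrna_log2fc": [0.0], "protein_log2fc": [0.0],
                           "monosomic": [False], "corum": [False]})
        with pytest.raises(ValueError):
            classify_buffering(fc)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            BufferingParams(cutoff=0.5)


def _fc(genes, chrom, mono, mrna, protein, corum=None):
    return pd.DataFrame({
        "gene": genes, "chromosome": chrom, "mrna_log2fc": mrna,
        "protein_log2fc": protein, "monosomic": mono,
        "corum": corum if corum is not None else [False] * len(genes),
    })


class TestPooledMedians:
    def test_single_line(self):
        fc = _fc(["g"], ["c13"], [True], [-1.0], [-0.2])
        assert pooled_monosome_medians([fc]) == (-1.0, -0.2)

    def test_two_identical_lines_same_medians(self):
        fc = _fc(list("ab"), ["c13"] * 2, [True] * 2, [-1.0, -0.4], [-0.3, -0.1])
        assert pooled_monosome_medians([fc, fc]) == pooled_monosome_medians([fc])

    def test_chrx_excluded(self):
        fc = _fc(["g1", "g2"], ["c13", "chrX"], [True, True], [-1.0, -5.0], [-0.2, -5.0])
        assert pooled_monosome_medians([fc]) == (-1.0, -0.2)

    def test_matches_brute_force_concatenation(self, small_annotation):
        fc1, _ = make_fold_change_table(small_annotation, {"chr2"}, seed=1)
        fc2, _ = make_fold_change_table(small_annotation, {"chr3"}, seed=2)
        got = pooled_monosome_medians([fc1, fc2])
        records = []
        for fc in (fc1, fc2):
            sub = fc.dropna(subset=["mrna_log2fc", "protein_log2fc"])
            records.append(sub[sub["monosomic"]])
        pooled = pd.concat(records)
        assert got[0] == pytest.approx(pooled["mrna_log2fc"].median())
        assert got[1] == pytest.approx(pooled["protein_log2fc"].median())


class TestComplexMembership:
    def test_all_flags_false_rejected(self):
        fc = _fc(list("ab"), ["c"] * 2, [True, False], [0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            complex_membership_shift(fc)

    def test_null_simulation_no_corum_shift(self, small_annotation):
        fc, _ = make_fold_change_table(small_annotation, {"chr2"}, seed=6)
        out = complex_membership_shift(fc)
        diff = out["monosome"]["corum_median"] - out["monosome"]["non_corum_median"]
        assert abs(diff) < 0.25  # flags are independent of the dosage response

    def test_injected_corum_shift_recovered(self, small_annotation):
        fc, _ = make_fold_change_table(small_annotation, {"chr2"}, seed=7)
        delta = 0.4
        fc = fc.copy()
        sel = fc["monosomic"] & fc["corum"]
        fc.loc[sel, "protein_log2fc"] += delta
        out = complex_membership_shift(fc)
        diff = out["monosome"]["corum_median"] - out["monosome"]["non_corum_median"]
        assert diff == pytest.approx(delta, abs=0.2)


class TestSharedExtremes:
    def test_shared_up_protein(self):
        fcs = {"l1": pd.Series({"p": 1.6}), "l2": pd.Series({"p": 1.7}),
               "l3": pd.Series({"p": 0.0})}
        up, down = shared_extreme_proteins(fcs)
        assert up == ["p"] and down == []

    def test_exact_threshold_not_counted(self):
        fcs = {"l1": pd.Series({"p": 1.5}), "l2": pd.Series({"p": 1.5})}
        up, down = shared_extreme_proteins(fcs)
        assert up == [] and down == []

    def test_opposite_directions_excluded(self):
        fcs = {"l1": pd.Series({"p": 1.6}), "l2": pd.Series({"p": -1.6}),
               "l3": pd.Series({"p": 0.0})}
        up, down = shared_extreme_proteins(fcs)
        assert up == [] and down == []

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            shared_extreme_proteins({"l1": pd.Series({"p": 1.0}),
                                     "l2": pd.Series({"p": 1.0})}, threshold=0)
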