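"""Ground-truth generators: determinism, planted structure, noise model."""

import numpy as np
import pytest

from disproteo import (
    PlantSpec,
    PlantedProteomeTruth,
    gen_genome,
    gen_panel,
    gen_psm_study,
)


def small_truth(seed=0, dropout=0.0):
    return PlantedProteomeTruth(
        condition_exclusive={"TD": {"T1"}, "SR": {"S1"}},
        shared={"X1", "X2"},
        fold_change={"X1": 2.0, "X2": 0.5},
        base_abundance={"T1": 1.0, "S1": 1.0, "X1": 1.0, "X2": 1.0},
        length_aa={"T1": 300, "S1": 300, "X1": 300, "X2": 300},
        dropout_prob=dropout,
        seed=seed,
    )


class TestGenPsmStudy:
    def test_same_seed_is_byte_identical(self):
        a = gen_psm_study(small_truth(seed=5))
        b = gen_psm_study(small_truth(seed=5))
        assert a == b

    def test_different_seeds_differ(self):
        a = gen_psm_study(small_truth(seed=5))
        b = gen_psm_study(small_truth(seed=6))
        assert a != b

    def test_no_dropout_means_presence_in_every_replicate(self):
        # lambda = 2 * 1 * 300 = 600 >> 20, so absence would be astronomical
        recs = gen_psm_study(small_truth(), n_reps=3)
        shared = [r for r in recs if r.protein_id in ("X1", "X2")]
        assert all(r.psm_count > 0 for r in shared)

    def test_exclusive_proteins_are_zero_in_the_other_condition(self):
        recs = gen_psm_study(small_truth())
        assert all(
            r.psm_count == 0 for r in recs if r.protein_id == "T1" and r.condition == "SR"
        )
        assert all(
            r.psm_count > 0 for r in recs if r.protein_id == "T1" and r.condition == "TD"
        )

    def test_planted_proteins_carry_passing_q_values(self):
        recs = gen_psm_study(small_truth())
        assert {r.q_value for r in recs} == {0.001}

    def test_fold_change_raises_td_counts(self):
        recs = gen_psm_study(small_truth(), n_reps=20)
        td = np.mean([r.psm_count for r in recs if r.protein_id == "X1" and r.condition == "TD"])
        sr = np.mean([r.psm_count for r in recs if r.protein_id == "X1" and r.condition == "SR"])
        assert td / sr == pytest.approx(2.0, rel=0.15)

    def test_adding_a_protein_does_not_perturb_other_draws(self):
        base = small_truth()
        bigger = small_truth()
        bigger.shared = bigger.shared | {"X9"}
        bigger.fold_change["X9"] = 1.0
        bigger.base_abundance["X9"] = 1.0
        bigger.length_aa["X9"] = 300
        a = {(r.condition, r.replicate, r.protein_id): r.psm_count for r in gen_psm_study(base)}
        b = {(r.condition, r.replicate, r.protein_id): r.psm_count for r in gen_psm_study(bigger)}
        assert all(b[k] == v for k, v in a.items())

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gen_psm_study(small_truth(), n_reps=0)
        with pytest.raises(ValueError):
            PlantedProteomeTruth(
                condition_exclusive={"TD": {"A"}},
                shared={"A"},  # overlaps the exclusive set
                fold_change={"A": 1.0},
                base_abundance={"A": 1.0},
                length_aa={"A": 100},
                dropout_prob=0.0,
                seed=0,
            )

    def test_dropout_zeroes_cells(self):
        recs = gen_psm_study(small_truth(dropout=0.5), n_reps=30)
        shared = [r.psm_count for r in recs if r.protein_id == "X1"]
        zero_frac = np.mean([c == 0 for c in shared])
        assert 0.3 < zero_frac < 0.7


class TestDefaultStudyStructure:
    def test_default_generate_plants_the_study_shape(self):
        truth = PlantedProteomeTruth.generate(seed=1)
        assert len(truth.condition_exclusive["TD"]) == 36
        assert len(truth.condition_exclusive["SR"]) == 476
        assert len(truth.shared) == 660
        assert len(truth.proteins()) == 1172
        assert all(0.25 <= f <= 4.0 for f in truth.fold_change.values())

    def test_expected_fold_changes_account_for_compositionality(self):
        truth = PlantedProteomeTruth.generate(seed=1)
        exp = truth.expected_fold_changes()
        # the compositional correction is a single global factor
        ratios = {p: exp[p] / truth.fold_change[p] for p in exp}
        vals = list(ratios.values())
        assert np.allclose(vals, vals[0])


class TestGenGenome:
    def test_minimal_plant_without_decoys(self):
        genes, seqs, truth = gen_genome(0, [PlantSpec("ttr", "BCA")], seed=0)
        assert len(genes) == 3
        assert len(truth.planted_complexes) == 1
        fam, members, arrangement, distant = truth.planted_complexes[0]
        assert fam == "ttr" and arrangement == "BCA" and not distant
        assert set(members) == {g.locus_tag for g in genes}

    def test_decoys_only_has_empty_truth(self):
        genes, seqs, truth = gen_genome(50, [], seed=0)
        assert len(genes) == 50
        assert truth.planted_complexes == []

    def test_coordinates_do_not_overlap_and_gaps_are_bounded(self):
        genes, _, _ = gen_genome(40, [PlantSpec("ttr")], seed=2, emit_sequences=False)
        for prev, nxt in zip(genes, genes[1:]):
            gap = nxt.start - prev.end - 1
            assert 20 <= gap <= 200

    def test_catalytic_subunits_beat_the_length_veto(self):
        genes, _, _ = gen_genome(0, [PlantSpec("ttr", "BCA")], seed=3)
        a = [g for g in genes if "TtrA" in g.product]
        assert a and all(g.protein_length >= 500 for g in a)

    def test_sequences_match_declared_lengths(self):
        genes, seqs, _ = gen_genome(5, [], seed=4)
        for g in genes:
            assert len(seqs[g.locus_tag]) == g.protein_length

    def test_distance_larger_than_genome_errors(self):
        with pytest.raises(ValueError, match="distance"):
            gen_genome(10, [PlantSpec("ttr", distant_gap=50)], seed=0)

    def test_determinism(self):
        a = gen_genome(20, [PlantSpec("phs")], seed=9)
        b = gen_genome(20, [PlantSpec("phs")], seed=9)
        assert a[0] == b[0] and a[1] == b[1]


class TestGenPanel:
    def test_degenerate_probabilities_give_diagonal_crosstab(self):
        groups, phenos, truth = gen_panel(
            n_species=40, p_feature_given_disprop=1.0, p_feature_given_other=0.0, seed=0
        )
        for feat in ("ttr", "phs", "ytd"):
            assert (truth[feat] == truth["sulfur_disproportionation"]).all()

    def test_panel_shape_defaults(self):
        groups, phenos, truth = gen_panel(seed=0)
        assert len(phenos) == 93
        assert sum(p.sulfur_disproportionation == "yes" for p in phenos) == 33

    def test_conditional_frequencies_within_three_se(self):
        n = 500
        p1, p0 = 0.8, 0.1
        _, _, truth = gen_panel(
            n_species=n, p_feature_given_disprop=p1, p_feature_given_other=p0, seed=11
        )
        disp = truth["sulfur_disproportionation"]
        for feat in ("ttr", "phs", "ytd"):
            f1 = truth.loc[disp, feat].mean()
            f0 = truth.loc[~disp, feat].mean()
            se1 = np.sqrt(p1 * (1 - p1) / disp.sum())
            se0 = np.sqrt(p0 * (1 - p0) / (~disp).sum())
            assert abs(f1 - p1) < 3 * se1
            assert abs(f0 - p0) < 3 * se0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gen_panel(n_species=0)
        with pytest.raises(ValueError):
            gen_panel(n_species=10, p_feature_given_disprop=1.5)
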