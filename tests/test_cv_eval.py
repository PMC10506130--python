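import copy

import numpy as np
import pytest

from conftest import make_as, make_scoreset
from dmsfuse.cv_eval import (
    CVConfig,
    EvaluationError,
    _training_artifacts,
    aggregate_by_amino_acid,
    define_evaluation_variants,
    holm_sidak,
    lopo_splits,
    median_ci,
    merge_replicates,
    paired_t_test,
    run_cv,
    welch_test,
)
from dmsfuse.io_formats import AA_ORDER
from dmsfuse.synthetic_data import GeneratorConfig, simulate_normalized_corpus

import pandas as pd


class TestLopoSplits:
    def test_one_split_per_protein(self, small_corpus):
        splits = lopo_splits(small_corpus.scoresets)
        assert len(splits) == 2
        for train, held in splits:
            assert all(s.protein_id != held for s in train)

    def test_all_datasets_of_protein_withheld_together(self):
        sets = [
            make_scoreset("P1", "d1", {(1, "C", "W"): 0.1}),
            make_scoreset("P1", "d2", {(1, "C", "W"): 0.2}),
            make_scoreset("P2", "d3", {(1, "C", "W"): 0.3}),
        ]
        train, held = [s for s in lopo_splits(sets) if s[1] == "P1"][0]
        assert [s.dataset_id for s in train] == ["d3"]

    def test_single_protein_rejected(self):
        with pytest.raises(EvaluationError):
            lopo_splits([make_scoreset("P1", "d1", {(1, "C", "W"): 0.1})])


class TestEvaluationVariants:
    def test_residue_level_matching(self):
        scores = {(p, "C", v): 0.5 for p in (10, 25) for v in AA_ORDER if v != "C"}
        dms = make_scoreset(scores=scores)
        as_data = make_as(residues={(10, "C"): 0.4, (25, "C"): 0.6})
        V = define_evaluation_variants(dms, as_data)
        assert len(V) == 38

    def test_alanine_only_reading(self):
        scores = {(p, "C", v): 0.5 for p in (10, 25) for v in AA_ORDER if v != "C"}
        dms = make_scoreset(scores=scores)
        as_data = make_as(residues={(10, "C"): 0.4, (25, "C"): 0.6})
        V = define_evaluation_variants(dms, as_data, alanine_only=True)
        assert len(V) == 2 and all(k.var_aa == "A" for k in V)

    def test_no_overlap_empty(self):
        dms = make_scoreset(scores={(1, "C", "W"): 0.5})
        as_data = make_as(residues={(9, "D"): 0.4})
        assert define_evaluation_variants(dms, as_data) == []


class TestMergeReplicates:
    def test_same_study_same_category_merged(self):
        a = make_scoreset("P1", "d1", {(1, "C", "W"): 0.2}, study_id="s1")
        b = make_scoreset("P1", "d2", {(1, "C", "W"): 0.4}, study_id="s1")
        (merged,) = merge_replicates([a, b])
        (value,) = merged.scores.values()
        assert value == pytest.approx(0.3)

    def test_variant_in_one_replicate_retained(self):
        a = make_scoreset("P1", "d1", {(1, "C", "W"): 0.2}, study_id="s1")
        b = make_scoreset("P1", "d2", {(2, "D", "E"): 0.8}, study_id="s1")
        (merged,) = merge_replicates([a, b])
        assert len(merged.scores) == 2

    def test_distinct_categories_not_merged(self):
        a = make_scoreset("P1", "d1", {(1, "C", "W"): 0.2}, study_id="s1",
                          category="binding_affinity")
        b = make_scoreset("P1", "d2", {(1, "C", "W"): 0.4}, study_id="s1",
                          category="cell_survival")
        assert len(merge_replicates([a, b])) == 2

    def test_as_datasets_merged_per_residue(self):
        a = make_as("P1", "a1", {(1, "C"): 0.0}, study_id="s1")
        b = make_as("P1", "a2", {(1, "C"): 1.0}, study_id="s1")
        (merged,) = merge_replicates([a, b])
        assert merged.residues[(1, "C")] == pytest.approx(0.5)


class TestStatistics:
    def test_welch_identical_groups(self):
        t, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_separated_groups(self):
        a = [0.0, 0.001, -0.001, 0.0005]
        b = [1.0, 1.001, 0.999, 1.0005]
        _, p = welch_test(a, b)
        assert p < 1e-6

    def test_welch_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        # Welch-Satterthwaite by hand
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
        from scipy import stats as sps
        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        t, p = welch_test(a, b)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)

    def test_welch_undersized_rejected(self):
        with pytest.raises(EvaluationError):
            welch_test([1.0], [1.0, 2.0])

    def test_paired_t_matches_textbook_formula(self):
        d = np.array([0.3, 0.1, 0.4, 0.2, 0.5])
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats as sps
        p_hand = 2 * sps.t.sf(abs(t_hand), len(d) - 1)
        t, p = paired_t_test(d)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)

    def test_paired_t_near_constant_differences(self):
        _, p = paired_t_test([1.0, 1.0, 1.0, 1.0 + 1e-9])
        assert p < 1e-6

    def test_paired_t_zero_variance_flagged(self):
        with pytest.raises(EvaluationError):
            paired_t_test([0.0, 0.0, 0.0])

    def test_holm_sidak_two_p_hand_computation(self):
        adjusted = holm_sidak([0.01, 0.04])
        assert adjusted[0] == pytest.approx(1 - 0.99**2)  # 0.0199
        assert adjusted[1] == pytest.approx(0.04)

    def test_holm_sidak_single_and_extremes(self):
        assert holm_sidak([0.03])[0] == pytest.approx(0.03)
        assert holm_sidak([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_holm_sidak_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = holm_sidak(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_holm_sidak_rejects_out_of_range(self):
        with pytest.raises(EvaluationError):
            holm_sidak([0.5, 1.5])

    def test_median_ci_constant_vector(self):
        lo, hi = median_ci([2.0, 2.0, 2.0, 2.0])
        assert (lo, hi) == (2.0, 2.0)

    def test_median_ci_n2_clips_to_range(self):
        lo, hi = median_ci([1.0, 5.0])
        assert (lo, hi) == (1.0, 5.0)

    def test_median_ci_coverage_near_95pct(self):
        rng = np.random.default_rng(123)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            lo, hi = median_ci(rng.normal(size=100))
            hits += lo <= 0.0 <= hi
        assert abs(hits / n_sim - 0.95) < 0.02


class TestAggregateByAminoAcid:
    def test_wt_alanine_marked_not_applicable(self):
        rng = np.random.default_rng(1)
        rows = []
        for aa in ("A", "C"):
            for _ in range(5):
                obs = rng.uniform()
                rows.append(dict(wt_aa=aa, var_aa="G", observed=obs,
                                 pred_with=obs, pred_without=obs / 2))
        table = aggregate_by_amino_acid(pd.DataFrame(rows))
        wt_a = table[(table.kind == "wt") & (table.aa == "A")].iloc[0]
        assert not wt_a.applicable and np.isnan(wt_a.rho_with_as)

    def test_perfect_predictions_give_rho_one(self):
        rng = np.random.default_rng(2)
        rows = []
        for _ in range(10):
            obs = rng.uniform()
            rows.append(dict(wt_aa="C", var_aa="W", observed=obs,
                             pred_with=obs, pred_without=obs))
        table = aggregate_by_amino_acid(pd.DataFrame(rows))
        assert np.allclose(table[table.applicable].rho_with_as, 1.0)

    def test_small_groups_excluded(self):
        rows = [dict(wt_aa="C", var_aa="W", observed=0.5, pred_with=0.5,
                     pred_without=0.5)]
        table = aggregate_by_amino_acid(pd.DataFrame(rows))
        assert len(table) == 0


class TestRunCV:
    def test_control_run_has_zero_delta(self):
        cfg = GeneratorConfig(n_proteins=3, length_range=(30, 40), seed=5)
        corpus, _ = simulate_normalized_corpus(cfg)
        evaluations, summary = run_cv(CVConfig(match_mode="none"), corpus)
        assert summary["n_pairs"] > 0
        assert all(e.delta_rho == 0.0 for e in evaluations)

    def test_without_as_arm_invariant_to_as_perturbation(self):
        cfg = GeneratorConfig(n_proteins=3, length_range=(30, 40), seed=6)
        corpus, _ = simulate_normalized_corpus(cfg)
        base, _ = run_cv(CVConfig(match_mode="compat_high"), corpus)
        perturbed = copy.deepcopy(corpus)
        rng = np.random.default_rng(0)
        for ds in perturbed.as_datasets:
            ds.residues = {k: float(rng.uniform()) for k in ds.residues}
        after, _ = run_cv(CVConfig(match_mode="compat_high"), perturbed)
        rho_base = {(e.dms_id, e.as_id): e.rho_without_as for e in base}
        rho_after = {(e.dms_id, e.as_id): e.rho_without_as for e in after}
        assert rho_base == rho_after

    def test_training_artifacts_blind_to_held_out_protein(self):
        cfg = GeneratorConfig(n_proteins=3, length_range=(30, 40), seed=7)
        corpus, _ = simulate_normalized_corpus(cfg)
        config = CVConfig(match_mode="compat_high")
        train_sets, held = lopo_splits(corpus.scoresets)[0]
        train_as = [a for a in corpus.as_datasets if a.protein_id != held]
        matrix1, _, mean1 = _training_artifacts(train_sets, train_as, corpus, config)
        mutated = copy.deepcopy(corpus)
        for ds in mutated.scoresets + mutated.as_datasets:
            if ds.protein_id == held:
                container = ds.scores if hasattr(ds, "scores") else ds.residues
                for k in container:
                    container[k] = 99.0
        train_sets2 = [s for s in mutated.scoresets if s.protein_id != held]
        train_as2 = [a for a in mutated.as_datasets if a.protein_id != held]
        matrix2, _, mean2 = _training_artifacts(
            train_sets2, train_as2, mutated, config
        )
        assert matrix1.entries == matrix2.entries
        assert matrix1.fallback == matrix2.fallback
        assert mean1 == mean2

    def test_determinism(self):
        cfg = GeneratorConfig(n_proteins=3, length_range=(30, 40), seed=8)
        corpus, _ = simulate_normalized_corpus(cfg)
        e1, s1 = run_cv(CVConfig(match_mode="all"), corpus)
        e2, s2 = run_cv(CVConfig(match_mode="all"), corpus)
        assert [vars(a) for a in e1] == [vars(b) for b in e2]
        assert s1["median_delta_rho"] == s2["median_delta_rho"]

    def test_pairs_with_single_residue_dropped(self):
        cfg = GeneratorConfig(n_proteins=3, length_range=(30, 40), seed=9)
        corpus, _ = simulate_normalized_corpus(cfg)
        # shrink one AS dataset to a single residue: its pair must vanish
        victim = corpus.as_datasets[0]
        key = next(iter(victim.residues))
        victim.residues = {key: victim.residues[key]}
        evaluations, summary = run_cv(CVConfig(match_mode="all"), corpus)
        assert all(
            not (e.as_id == victim.dataset_id) for e in evaluations
        )
        assert summary["n_excluded"] >= 1
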