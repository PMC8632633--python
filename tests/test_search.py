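"""Generational combinatorial search: counting, CV evaluation, propagation."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qeegml.core import FEATURE_NAMES, lineage_groups
from qeegml.search import (
    FoldCache,
    SearchConfig,
    count_combinations,
    evaluate_combination,
    fit_linear_svm,
    next_pool,
    run_generation,
    run_heuristic,
)
from qeegml.synthetic import CohortDesign, generate_feature_table, planted_profiles


class TestCountCombinations:
    @pytest.mark.parametrize(
        "p,k,expected",
        [
            (152, 1, 152),
            (152, 2, 11_476),
            (152, 3, 573_800),
            (152, 4, 21_374_050),
            (152, 5, 632_671_880),
            (10, 0, 1),
        ],
    )
    def test_printed_enumeration_sizes(self, p, k, expected):
        assert count_combinations(p, k) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            count_combinations(5, 6)
        with pytest.raises(ValueError):
            count_combinations(-1, 0)

    @given(p=st.integers(0, 160), k=st.integers(0, 6))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_matches_pascal_recurrence(self, p, k):
        if k > p:
            return
        # independent oracle: iterative Pascal-rule row construction
        row = [1]
        for _ in range(p):
            row = [1] + [row[i] + row[i + 1] for i in range(len(row) - 1)] + [1]
        assert count_combinations(p, k) == row[k]


class TestLinearSVM:
    def test_agrees_with_sklearn_linearsvc(self):
        from sklearn.svm import LinearSVC

        rng = np.random.default_rng(3)
        for trial in range(20):
            n, d = int(rng.integers(30, 150)), int(rng.integers(1, 6))
            X = rng.normal(size=(n, d))
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            X[y] += rng.uniform(0.0, 2.5)
            w, b = fit_linear_svm(X, y, C=1.0)
            ref = LinearSVC(C=1.0, dual=False, tol=1e-6, max_iter=50_000).fit(X, y)
            np.testing.assert_allclose(w, ref.coef_.ravel(), atol=2e-4)
            assert abs(b - ref.intercept_[0]) < 2e-4
            assert (((X @ w + b) > 0) == ref.predict(X).astype(bool)).all()


class TestEvaluateCombination:
    def test_separable_feature_reaches_perfect_cv(self, separable_table):
        cfg = SearchConfig(seed=0)
        rec = evaluate_combination(("Fp1.delta",), separable_table, cfg)
        assert rec.cv_accuracy == 1.0
        assert rec.cv_sensitivity == 1.0 and rec.cv_specificity == 1.0

    def test_permuted_labels_score_near_chance(self, null_table):
        accs = []
        cfg = SearchConfig(seed=1)
        for rep in range(30):
            t = null_table.copy()
            rng = np.random.default_rng(rep)
            t["amyloid_label"] = rng.permutation(t["amyloid_label"].to_numpy())
            accs.append(evaluate_combination(("Cz.alpha1",), t, cfg).cv_accuracy)
        assert 0.4 < np.mean(accs) < 0.6

    def test_lineage_halves_share_folds(self, small_table):
        import pandas as pd

        t = small_table.copy()
        pos = t[t["amyloid_label"] == "positive"]
        halves = []
        for tag in ("h1", "h2"):
            h = pos.copy()
            h["lineage"] = h["subject_id"]
            h["subject_id"] = h["subject_id"] + "__" + tag
            halves.append(h)
        aug = pd.concat([t[t["amyloid_label"] == "negative"], *halves], ignore_index=True)
        cache = FoldCache(aug, SearchConfig(seed=2))
        groups = lineage_groups(aug).to_numpy()
        for tr, va in cache.folds:
            assert set(groups[tr]).isdisjoint(set(groups[va]))

    def test_adding_perfect_feature_never_hurts(self, separable_table):
        cfg = SearchConfig(seed=3)
        cache = FoldCache(separable_table, cfg)
        base = evaluate_combination(("T4.beta2", "O1.theta"), cfg=cfg, cache=cache)
        boosted = evaluate_combination(
            ("T4.beta2", "O1.theta", "Fp1.delta"), cfg=cfg, cache=cache
        )
        assert boosted.cv_accuracy >= base.cv_accuracy
        assert boosted.cv_accuracy == 1.0

    def test_single_class_table_rejected(self, small_table):
        t = small_table[small_table["amyloid_label"] == "negative"]
        with pytest.raises(ValueError, match="both amyloid classes"):
            FoldCache(t, SearchConfig())


class TestGenerations:
    def test_exhaustive_generation_counts_and_tally(self, small_table):
        pool = FEATURE_NAMES[:6]
        cfg = SearchConfig(seed=4, top_floor=5)
        gen = run_generation(pool, 2, small_table, cfg)
        assert len(gen.models) == 15  # C(6,2)
        assert len(gen.top_models) == 5
        assert sum(gen.freq.values()) == 2 * len(gen.top_models)

    def test_budget_guard(self, small_table):
        cfg = SearchConfig(seed=0, max_evaluations=10)
        with pytest.raises(RuntimeError, match="reduce the pool"):
            run_generation(FEATURE_NAMES[:10], 3, small_table, cfg)

    def test_next_pool_contracts(self, separable_table):
        pool = FEATURE_NAMES[:8]
        cfg = SearchConfig(seed=5, top_floor=6)
        gen = run_generation(pool, 2, separable_table, cfg)
        # budget >= pool: unchanged as a set
        assert set(next_pool(gen, budget=50)) == set(pool)
        # the separating feature appears in every top model -> ranked first
        reduced = next_pool(gen, budget=1)
        assert reduced == ("Fp1.delta",)
        # deterministic, including tie cases
        assert next_pool(gen, budget=4) == next_pool(gen, budget=4)


class TestHeuristic:
    def test_matches_exhaustive_oracle_on_small_pool(self):
        design = CohortDesign(n_positive=25, n_negative=25, seed=11)
        table = generate_feature_table(design)
        pool = tuple(FEATURE_NAMES[i] for i in range(0, 96, 8))  # 12 features
        cfg = SearchConfig(
            k_max=4, k_exhaustive=3, pool_sizes={}, features=pool,
            top_floor=10, retention_accuracy=0.51, seed=11,
        )
        result = run_heuristic(table, cfg)
        cache = FoldCache(table, cfg)
        oracle_best = max(
            evaluate_combination(c, cfg=cfg, cache=cache).cv_accuracy
            for c in combinations(pool, 4)
        )
        gen4 = [g for g in result.generations if g.k == 4][0]
        assert gen4.max_accuracy == pytest.approx(oracle_best, abs=1e-12)

    def test_recovers_planted_features(self):
        profiles = planted_profiles([("F3", "delta"), ("Cz", "beta1")], shift=0.05)
        design = CohortDesign(n_positive=60, n_negative=60, seed=13, profiles=profiles)
        table = generate_feature_table(design)
        cfg = SearchConfig(
            k_max=2, k_exhaustive=1, pool_sizes={2: 15}, seed=13,
            retention_accuracy=0.6, top_floor=20,
        )
        result = run_heuristic(table, cfg)
        assert {"F3.delta", "Cz.beta1"} <= set(result.best.combo)

    def test_empty_retention_warns(self, null_table):
        cfg = SearchConfig(
            k_max=1, k_exhaustive=1, retention_accuracy=0.99,
            features=FEATURE_NAMES[:5], seed=0,
        )
        with pytest.warns(UserWarning, match="retention"):
            result = run_heuristic(null_table, cfg)
        assert result.candidates == []
        assert result.best is not None

    def test_checkpoints_written(self, tmp_path, small_table):
        cfg = SearchConfig(
            k_max=2, k_exhaustive=2, features=FEATURE_NAMES[:6], seed=1,
            retention_accuracy=0.51, top_floor=3,
        )
        run_heuristic(small_table, cfg, checkpoint_dir=tmp_path)
        assert (tmp_path / "generation_k1.jsonl").exists()
        assert (tmp_path / "generation_k2.jsonl").exists()
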