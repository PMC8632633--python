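"""Voting ensemble: scoring contract, cutoff fitting, metrics, evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qeegml.core import FEATURE_NAMES
from qeegml.ensemble import (
    CutoffConfig,
    EnsembleModel,
    SubModel,
    ensemble_score,
    evaluate_ensemble,
    fit_cutoff,
    metrics_from_confusion,
    out_of_fold_scores,
    score_table,
    select_submodels,
)
from qeegml.prep import holdout_split
from qeegml.search import SearchConfig, run_heuristic

from .conftest import make_separable_table


def _fixed_vote_submodel(vote_positive: bool) -> SubModel:
    """A sub-model that votes the same way for any finite input."""
    return SubModel(
        combo=("Fp1.delta",),
        mean=np.zeros(1),
        scale=np.ones(1),
        weights=np.zeros(1),
        intercept=1.0 if vote_positive else -1.0,
    )


class TestScoringContract:
    @pytest.mark.parametrize("n_pos,expected", [(20, 1.0), (10, 0.5), (0, 0.0)])
    def test_vote_fractions(self, n_pos, expected):
        subs = [_fixed_vote_submodel(i < n_pos) for i in range(20)]
        ens = EnsembleModel(submodels=subs)
        fv = pd.Series({"Fp1.delta": 0.2})
        assert ensemble_score(ens, fv) == expected

    def test_scores_live_on_the_vote_grid(self, small_table):
        rng = np.random.default_rng(0)
        subs = [
            SubModel(
                combo=(FEATURE_NAMES[i],),
                mean=np.array([0.12]),
                scale=np.array([0.05]),
                weights=rng.normal(size=1),
                intercept=rng.normal(),
            )
            for i in range(7)
        ]
        ens = EnsembleModel(submodels=subs)
        scores = score_table(ens, small_table)
        grid = np.arange(8) / 7
        assert np.isin(np.round(scores, 12), np.round(grid, 12)).all()

    def test_missing_feature_errors(self):
        ens = EnsembleModel(submodels=[_fixed_vote_submodel(True)])
        with pytest.raises(ValueError, match="missing feature"):
            ensemble_score(ens, pd.Series({"Fp2.delta": 0.1}))


class TestSelectSubmodels:
    @pytest.fixture
    def trained(self, separable_table):
        table = holdout_split(separable_table, 0.2, seed=1)
        train = table[table["split"] == "train"].reset_index(drop=True)
        cfg = SearchConfig(
            k_max=2, k_exhaustive=2, features=FEATURE_NAMES[:12], seed=1,
            retention_accuracy=0.51, top_floor=30,
        )
        result = run_heuristic(train, cfg)
        return train, table[table["split"] == "test"].reset_index(drop=True), cfg, result

    def test_exactly_n_submodels(self, trained):
        train, _, cfg, result = trained
        ens = select_submodels(result.candidates, train, cfg, n=20)
        assert ens.n == 20
        assert all(set(s.combo) <= set(FEATURE_NAMES) for s in ens.submodels)

    def test_shortage_uses_all_with_warning(self, trained):
        train, _, cfg, result = trained
        few = result.candidates[:5]
        with pytest.warns(UserWarning, match="only 5 candidates"):
            ens = select_submodels(few, train, cfg, n=20)
        assert ens.n == 5

    def test_deterministic(self, trained):
        train, _, cfg, result = trained
        a = select_submodels(result.candidates, train, cfg, n=10)
        b = select_submodels(result.candidates, train, cfg, n=10)
        assert [s.combo for s in a.submodels] == [s.combo for s in b.submodels]

    def test_empty_candidates_rejected(self, trained):
        train, _, cfg, _ = trained
        with pytest.raises(ValueError, match="empty"):
            select_submodels([], train, cfg)


class TestFitCutoff:
    def test_separable_scores_pick_lowest_winning_cutoff(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        cut = fit_cutoff(scores, labels)
        assert cut.cutoff == pytest.approx(0.7)  # smallest grid point with J=1
        assert cut.method == "youden"

    def test_identical_distributions_fall_back_to_half(self):
        scores = np.array([0.2, 0.4, 0.2, 0.4])
        labels = np.array([1, 1, 0, 0], dtype=bool)
        assert fit_cutoff(scores, labels).cutoff == 0.5

    def test_fixed_cutoff_is_echoed(self):
        cut = fit_cutoff(np.array([0.0]), np.array([True]), method="fixed", fixed=0.58)
        assert cut == CutoffConfig(cutoff=0.58, method="fixed")

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_cutoff(np.array([0.1, 0.2]), np.array([True, True]))

    def test_cutoff_range_validated(self):
        with pytest.raises(ValueError):
            CutoffConfig(cutoff=1.2)


class TestMetrics:
    def test_worked_confusion_matrices(self):
        scd = metrics_from_confusion(tp=6, fp=3, fn=1, tn=25)
        assert scd.as_percentages() == {
            "sensitivity": 85.7, "specificity": 89.3,
            "accuracy": 88.6, "balanced_accuracy": 87.5,
        }
        mci = metrics_from_confusion(tp=5, fp=1, fn=1, tn=6)
        assert mci.as_percentages() == {
            "sensitivity": 83.3, "specificity": 85.7,
            "accuracy": 84.6, "balanced_accuracy": 84.5,
        }

    def test_perfect_classifier(self):
        rep = metrics_from_confusion(tp=4, fp=0, fn=0, tn=9)
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0
        assert rep.balanced_accuracy == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(tp=-1, fp=0, fn=0, tn=1)
        with pytest.raises(ValueError):
            metrics_from_confusion(tp=0, fp=0, fn=0, tn=5)

    @given(
        scores=st.lists(st.sampled_from([i / 20 for i in range(21)]), min_size=6, max_size=40),
        flips=st.integers(0, 2**30),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_threshold_monotonicity(self, scores, flips):
        """Raising the cutoff never raises sensitivity, never lowers specificity."""
        scores = np.array(scores)
        rng = np.random.default_rng(flips)
        labels = rng.random(len(scores)) < 0.5
        if labels.all() or not labels.any():
            return
        sens, spec = [], []
        for c in np.linspace(0, 1, 21):
            pred = scores >= c
            sens.append(pred[labels].mean())
            spec.append((~pred[~labels]).mean())
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(spec) >= -1e-12).all()


class TestOutOfFoldScores:
    def test_scores_complete_on_grid_and_not_inflated(self, separable_table):
        split = holdout_split(separable_table, 0.2, seed=2)
        train = split[split["split"] == "train"].reset_index(drop=True)
        cfg = SearchConfig(
            k_max=1, k_exhaustive=1, features=FEATURE_NAMES[:10], seed=2,
            retention_accuracy=0.51, top_floor=10,
        )
        result = run_heuristic(train, cfg)
        ens = select_submodels(result.candidates, train, cfg, n=5)
        oof = out_of_fold_scores(ens, train, train, cfg)
        assert not np.isnan(oof).any()
        assert np.isin(np.round(oof * ens.n, 9) % 1, [0.0]).all()
        # in-sample scores can only look better (or equal) than out-of-fold
        insample = score_table(ens, train)
        truth = (train["amyloid_label"] == "positive").to_numpy()
        def youden(scores):
            return max(
                (scores >= c)[truth].mean() + (~(scores >= c))[~truth].mean() - 1
                for c in np.unique(scores)
            )
        assert youden(insample) >= youden(oof) - 1e-12


class TestEvaluateEnsemble:
    @pytest.fixture
    def fitted(self):
        table = make_separable_table(n_per_class=25, seed=9)
        split = holdout_split(table, 0.2, seed=9)
        train = split[split["split"] == "train"].reset_index(drop=True)
        test = split[split["split"] == "test"].reset_index(drop=True)
        cfg = SearchConfig(
            k_max=1, k_exhaustive=1, features=FEATURE_NAMES[:16], seed=9,
            retention_accuracy=0.51, top_floor=16,
        )
        result = run_heuristic(train, cfg)
        ens = select_submodels(result.candidates, train, cfg, n=5)
        return ens, train, test

    def test_report_consistent_with_per_subject_table(self, fitted):
        ens, train, test = fitted
        cut = CutoffConfig(cutoff=0.5)
        report, detail = evaluate_ensemble(ens, cut, test)
        assert len(detail) == len(test)
        pred_pos = (detail["prediction"] == "positive").to_numpy()
        truth = (detail["truth"] == "positive").to_numpy()
        assert report.tp == int((pred_pos & truth).sum())
        assert report.tn == int((~pred_pos & ~truth).sum())
        recomputed = metrics_from_confusion(report.tp, report.fp, report.fn, report.tn)
        assert recomputed.balanced_accuracy == report.balanced_accuracy

    def test_cutoff_boundary_all_positive(self, fitted):
        ens, _, test = fitted
        subs = [_fixed_vote_submodel(True) for _ in range(20)]
        always = EnsembleModel(submodels=subs, train_subjects=ens.train_subjects)
        report, detail = evaluate_ensemble(always, CutoffConfig(cutoff=0.58), test)
        assert (detail["prediction"] == "positive").all()
        assert report.fn == 0

    def test_strict_mode_catches_leakage(self, fitted):
        ens, train, test = fitted
        with pytest.raises(ValueError, match="non-test rows"):
            evaluate_ensemble(ens, CutoffConfig(0.5), train)
        sneaky = test.copy()
        sneaky["split"] = "test"
        sneaky.loc[sneaky.index[0], "subject_id"] = train["subject_id"].iloc[0]
        with pytest.raises(ValueError, match="seen in training"):
            evaluate_ensemble(ens, CutoffConfig(0.5), sneaky)
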