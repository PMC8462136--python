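import numpy as np
import pandas as pd
import pytest
from scipy import stats

from milfoilsdm import (
    equality_threshold,
    evaluate_discrimination,
    functional_accuracy,
    kappa,
    roc_auc,
    tss,
    wedge_quantiles,
)
from milfoilsdm.evaluation import ConfusionCounts, EvaluationError
from milfoilsdm.models import RFHyper, fit_sdm
from milfoilsdm.pseudoabsence import ResponseDataset
from .oracles import auc_pair_counting, check_loss


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        scores = rng.integers(0, 5, 10) / 4.0  # forces ties
        labels = rng.integers(0, 2, 10)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, 10)
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12
        )

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(5 * scores), labels) == pytest.approx(a, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestEqualityThreshold:
    def test_clean_split(self):
        thr = equality_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == pytest.approx(0.5)

    def test_balances_sensitivity_and_specificity(self, rng):
        n = 1000
        scores = np.concatenate([rng.normal(0.4, 0.15, n), rng.normal(0.6, 0.15, n)])
        labels = np.concatenate([np.zeros(n), np.ones(n)])
        thr = equality_threshold(scores, labels)
        sens = np.mean(scores[labels == 1] > thr)
        spec = np.mean(scores[labels == 0] <= thr)
        assert abs(sens - spec) < 0.05

    def test_deterministic_under_label_reversal(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, 50)
        t1 = equality_threshold(scores, labels)
        t2 = equality_threshold(scores, labels)
        assert t1 == t2
        # reversed labels also resolve deterministically
        r1 = equality_threshold(scores, 1 - labels)
        assert r1 == equality_threshold(scores, 1 - labels)


class TestThresholdMetrics:
    def test_tss_from_sens_spec(self):
        counts = ConfusionCounts(tp=9, fn=1, tn=8, fp=2)  # sens .9 spec .8
        assert tss(counts) == pytest.approx(0.7)

    def test_kappa_contingency(self):
        counts = ConfusionCounts(tp=40, tn=40, fp=10, fn=10)
        assert kappa(counts) == pytest.approx(0.6)

    def test_undefined_margins_fail_loudly(self):
        with pytest.raises(ValueError, match="margin"):
            tss(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        with pytest.raises(ValueError, match="margin"):
            kappa(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))

    def test_null_labels_give_near_zero_skill(self, rng):
        n = 20_000
        labels = rng.integers(0, 2, n)
        preds = rng.integers(0, 2, n)
        counts = ConfusionCounts.from_predictions(labels, preds)
        se = 2.0 / np.sqrt(n)
        assert abs(tss(counts)) < 2 * se
        assert abs(kappa(counts)) < 2 * se


def _dataset_from_arrays(X, labels, coords=None, kind="PA"):
    n = len(labels)
    df = pd.DataFrame(X, columns=[f"c{j}" for j in range(X.shape[1])])
    if coords is None:
        coords = np.random.default_rng(0).uniform(0, 100, (n, 2))
    df.insert(0, "id", [f"l{i}" for i in range(n)])
    df.insert(1, "x", coords[:, 0])
    df.insert(2, "y", coords[:, 1])
    df.insert(3, "role", "presence")
    df.insert(4, "label", np.asarray(labels, dtype=float))
    return ResponseDataset(kind=kind, df=df)


class TestEvaluateDiscrimination:
    def test_separable_dataset_perfect_under_all_schemes(self, rng):
        n = 200
        x = rng.uniform(0, 1, n)
        X = np.column_stack([x, rng.standard_normal(n)])
        ds = _dataset_from_arrays(X, (x > 0.5).astype(float),
                                  coords=rng.uniform(0, 100, (n, 2)))
        for scheme in ("nonindependent", "quasi_independent", "spatially_blocked"):
            m = evaluate_discrimination(ds, scheme, hyper=RFHyper(n_trees=100),
                                        seed=0, n_iterations=2, block_side=20.0,
                                        k_folds=3)
            assert m.auc > 0.99

    def test_reproducible_under_fixed_seed(self, rng):
        n = 150
        X = rng.standard_normal((n, 3))
        y = rng.integers(0, 2, n).astype(float)
        ds = _dataset_from_arrays(X, y)
        a = evaluate_discrimination(ds, "nonindependent", hyper=RFHyper(n_trees=50),
                                    seed=4, n_iterations=2)
        b = evaluate_discrimination(ds, "nonindependent", hyper=RFHyper(n_trees=50),
                                    seed=4, n_iterations=2)
        assert (a.auc, a.tss, a.kappa) == (b.auc, b.tss, b.kappa)

    def test_single_class_dataset_rejected(self, rng):
        ds = _dataset_from_arrays(rng.standard_normal((40, 2)), np.ones(40))
        with pytest.raises(EvaluationError):
            evaluate_discrimination(ds, "quasi_independent", seed=0)


class TestFunctionalAccuracy:
    def _abundance_model(self, table, rng):
        from milfoilsdm.pseudoabsence import build_dataset

        ds = build_dataset(table, "PA")
        return fit_sdm(ds, hyper=RFHyper(n_trees=50), seed=0, train_fraction=None)

    def test_perfect_predictions_give_unit_correlations(self, monkeypatch, default_landscape, rng):
        model = self._abundance_model(default_landscape, rng)
        surveyed = default_landscape[default_landscape["surveyed"].astype(bool)]
        freq = surveyed["freq_occ"].to_numpy()
        monkeypatch.setattr(
            "milfoilsdm.evaluation.suitability_on_table", lambda m, t: freq
        )
        fm = functional_accuracy(model, default_landscape)
        assert fm.r_all == pytest.approx(1.0)
        assert fm.rho_all == pytest.approx(1.0)
        assert fm.r_nonzero == pytest.approx(1.0)
        assert fm.rho_nonzero == pytest.approx(1.0)

    def test_monotone_transform_preserves_spearman_only(self, monkeypatch, default_landscape, rng):
        model = self._abundance_model(default_landscape, rng)
        surveyed = default_landscape[default_landscape["surveyed"].astype(bool)]
        freq = surveyed["freq_occ"].to_numpy()
        monkeypatch.setattr(
            "milfoilsdm.evaluation.suitability_on_table",
            lambda m, t: np.expm1(8 * freq),
        )
        fm = functional_accuracy(model, default_landscape)
        assert fm.rho_all == pytest.approx(1.0)
        assert fm.r_all < 1.0

    def test_unrelated_predictions_give_near_zero_correlation(self, monkeypatch, default_landscape, rng):
        model = self._abundance_model(default_landscape, rng)
        noise = rng.random(468)
        monkeypatch.setattr(
            "milfoilsdm.evaluation.suitability_on_table", lambda m, t: noise
        )
        fm = functional_accuracy(model, default_landscape)
        assert abs(fm.r_all) < 0.1
        assert abs(fm.rho_all) < 0.1


class TestWedgeQuantiles:
    def test_exact_line_gives_equal_slopes(self):
        x = np.linspace(0.01, 1, 100)
        fit = wedge_quantiles(x, 0.5 * x)
        for tau in fit.taus:
            assert fit.slopes[tau] == pytest.approx(0.5, abs=1e-6)
        assert fit.wedge_strength == pytest.approx(0.0, abs=1e-6)

    def test_uniform_wedge_recovers_tau_slopes(self, rng):
        x = rng.uniform(0, 1, 2000)
        y = rng.uniform(0, x)
        fit = wedge_quantiles(x, y)
        for tau in (0.50, 0.75, 0.90):
            assert fit.slopes[tau] == pytest.approx(tau, abs=0.05)
        assert fit.wedge_strength > 0

    def test_check_loss_not_worse_than_ols_line(self, rng):
        x = rng.uniform(0, 1, 500)
        y = rng.uniform(0, x)
        fit = wedge_quantiles(x, y)
        slope_ols, intercept_ols = np.polyfit(x, y, 1)
        for tau in fit.taus:
            q_fit = fit.intercepts[tau] + fit.slopes[tau] * x
            ols = intercept_ols + slope_ols * x
            assert check_loss(y, q_fit, tau) <= check_loss(y, ols, tau) + 1e-9

    def test_degenerate_suitability_rejected(self):
        with pytest.raises(ValueError, match="degenerate|variance"):
            wedge_quantiles(np.full(50, 0.3), np.linspace(0, 1, 50))

    def test_spearman_invariance_mirror(self, rng):
        # rank metrics unaffected by monotone transforms of either variable
        x = rng.random(100)
        y = rng.uniform(0, x)
        rho = stats.spearmanr(x, y).statistic
        assert stats.spearmanr(np.log(x + 1e-9), y).statistic == pytest.approx(rho)
        assert stats.spearmanr(x, y**3).statistic == pytest.approx(rho)
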