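"""Gaussian-mixture subtype classification model."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from bcsubtype.core import Subtype
from bcsubtype.modules import ModuleScoreMatrix
from bcsubtype.scm import SCMClassifier, SCMModel, predict_scm
from bcsubtype.simulate import simulate_module_scores


@pytest.fixture(scope="module")
def fitted():
    scores, truth, means = simulate_module_scores(n=600, separation=3.0, seed=31)
    clf = SCMClassifier(random_state=31).fit(scores)
    return clf, scores, truth, means


class TestComponentLabeling:
    def test_label_rule_on_prescribed_means(self):
        # LUMINAL = max ER mean; HER2 = max HER2 mean of the rest
        rng = np.random.default_rng(32)
        means = {"BASAL": (-1.5, -0.8), "HER2": (-0.2, 1.2), "LUMINAL": (1.4, -0.5)}
        rows = []
        for mu in means.values():
            rows.append(rng.normal(mu, 0.15, size=(80, 2)))
        X = pd.DataFrame(np.vstack(rows), columns=["ER", "HER2"])
        X["PROLIF"] = np.concatenate(
            [rng.normal(1, 0.2, 160), rng.normal(-1, 0.2, 40), rng.normal(1, 0.2, 40)]
        )
        clf = SCMClassifier(random_state=32).fit(X)
        fitted_means = clf.gmm_.means_
        for comp, name in clf.comp_map_.items():
            expected = np.array(means[name])
            assert np.linalg.norm(fitted_means[comp] - expected) < 0.3

    def test_comp_map_is_bijection(self, fitted):
        clf, *_ = fitted
        assert sorted(clf.comp_map_.values()) == ["BASAL", "HER2", "LUMINAL"]


class TestParameterRecovery:
    def test_component_means_within_three_standard_errors(self, fitted):
        clf, scores, truth, means = fitted
        # map true subtype means onto mixture components: LUMA/LUMB share the
        # luminal component, whose ER/HER2 mean is the weighted average
        truth_s = truth.to_series()
        true_mu = {
            "BASAL": means[0, :2],
            "HER2": means[1, :2],
            "LUMINAL": scores.loc[truth_s.isin(["LUMA", "LUMB"]), ["ER", "HER2"]].mean().to_numpy(),
        }
        counts = {
            "BASAL": (truth_s == "BASAL").sum(),
            "HER2": (truth_s == "HER2").sum(),
            "LUMINAL": truth_s.isin(["LUMA", "LUMB"]).sum(),
        }
        sd = 0.5  # generative within-component sd of simulate_module_scores
        for comp, name in clf.comp_map_.items():
            se = sd / np.sqrt(counts[name])
            assert np.all(
                np.abs(clf.gmm_.means_[comp] - true_mu[name]) < 3 * se + 1e-6
            ), name

    def test_luminal_prolif_split_recovers_modes(self, fitted):
        clf, scores, truth, means = fitted
        sp = clf.prolif_split_
        # luminal A and B proliferate at -1.5 / +1.5 at separation 3
        assert sp["mu_low"] == pytest.approx(-1.5, abs=0.2)
        assert sp["mu_high"] == pytest.approx(1.5, abs=0.2)

    def test_held_out_label_recovery(self, fitted):
        clf, *_ = fitted
        scores, truth, _ = simulate_module_scores(n=400, separation=3.0, seed=77)
        from bcsubtype.concordance import cohens_kappa
        from bcsubtype.core import SubtypeAssignment

        pred = SubtypeAssignment(
            sample_ids=tuple(scores.index),
            labels=tuple(clf.predict(scores)),
            predictor_id="scm",
        )
        assert cohens_kappa(truth, pred).kappa > 0.9


class TestPosteriors:
    def test_posterior_matches_bayes_rule_oracle(self, fitted):
        clf, scores, *_ = fitted
        sample = scores.iloc[:50]
        post = clf.component_posterior(sample)
        gmm = clf.gmm_
        for i in range(len(sample)):
            x = sample[["ER", "HER2"]].iloc[i].to_numpy()
            dens = np.array(
                [
                    gmm.weights_[k]
                    * multivariate_normal.pdf(x, gmm.means_[k], gmm.covariances_[k])
                    for k in range(3)
                ]
            )
            expected = dens / dens.sum()
            by_name = {clf.comp_map_[k]: expected[k] for k in range(3)}
            for name, val in by_name.items():
                assert post.iloc[i][name] == pytest.approx(val, abs=1e-10)

    def test_posteriors_sum_to_one(self, fitted):
        clf, scores, *_ = fitted
        post = clf.component_posterior(scores)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_sample_at_component_mean_gets_that_subtype(self):
        clf = SCMClassifier()
        from bcsubtype.scm import _make_gmm_2d

        clf.gmm_ = _make_gmm_2d(
            [1 / 3] * 3,
            [[-1.5, -1.0], [0.0, 1.5], [1.5, -1.0]],
            [np.eye(2) * 0.2] * 3,
        )
        clf.comp_map_ = {0: "BASAL", 1: "HER2", 2: "LUMINAL"}
        clf.prolif_split_ = dict(pi_low=0.5, mu_low=-1, sigma_low=0.3,
                                 mu_high=1, sigma_high=0.3)
        X = pd.DataFrame(
            {"ER": [-1.5, 0.0, 1.5], "HER2": [-1.0, 1.5, -1.0], "PROLIF": [0.0, 0.0, -1.0]}
        )
        pred = clf.predict(X)
        assert list(pred) == [Subtype.BASAL, Subtype.HER2, Subtype.LUMA]

    def test_prolif_equal_posterior_point_breaks_to_luma(self):
        clf = SCMClassifier()
        clf.prolif_split_ = dict(pi_low=0.5, mu_low=-1, sigma_low=0.5,
                                 mu_high=1, sigma_high=0.5)
        # symmetric split: 0 is the exact equal-posterior point
        assert clf.luminal_low_posterior(np.array([0.0]))[0] == pytest.approx(0.5)
        from bcsubtype.scm import _make_gmm_2d

        clf.gmm_ = _make_gmm_2d([1.0 / 3] * 3,
                                [[-2, -2], [0, 2], [2, -2]], [np.eye(2) * 0.1] * 3)
        clf.comp_map_ = {0: "BASAL", 1: "HER2", 2: "LUMINAL"}
        X = pd.DataFrame({"ER": [2.0], "HER2": [-2.0], "PROLIF": [0.0]})
        assert clf.predict(X)[0] == Subtype.LUMA


class TestContracts:
    def test_same_seed_refit_is_identical(self):
        scores, *_ = simulate_module_scores(n=300, separation=3.0, seed=40)
        a = SCMClassifier(random_state=9).fit(scores)
        b = SCMClassifier(random_state=9).fit(scores)
        np.testing.assert_array_equal(a.gmm_.means_, b.gmm_.means_)
        assert a.comp_map_ == b.comp_map_
        assert a.prolif_split_ == b.prolif_split_

    def test_labels_stable_across_seeds_on_separated_data(self):
        scores, *_ = simulate_module_scores(n=300, separation=4.0, seed=41)
        preds = [
            SCMClassifier(random_state=s).fit(scores).predict(scores) for s in (1, 2, 3)
        ]
        assert all(list(p) == list(preds[0]) for p in preds[1:])

    def test_misclassification_vanishes_with_separation(self):
        from bcsubtype.concordance import cohens_kappa
        from bcsubtype.core import SubtypeAssignment

        kappas = []
        for sep in (1.0, 6.0):
            scores, truth, _ = simulate_module_scores(n=400, separation=sep, seed=42)
            clf = SCMClassifier(random_state=42).fit(scores)
            pred = SubtypeAssignment(
                sample_ids=tuple(scores.index),
                labels=tuple(clf.predict(scores)),
                predictor_id="scm",
            )
            kappas.append(cohens_kappa(truth, pred).kappa)
        assert kappas[1] > kappas[0]
        assert kappas[1] > 0.99

    def test_missing_module_column_errors(self):
        scores, *_ = simulate_module_scores(n=100, seed=43)
        with pytest.raises(ValueError, match="PROLIF"):
            SCMClassifier(random_state=0).fit(scores.drop(columns=["PROLIF"]))

    def test_too_few_samples_errors(self):
        scores, *_ = simulate_module_scores(n=20, seed=44)
        with pytest.raises(ValueError, match=">= 30"):
            SCMClassifier(random_state=0).fit(scores)

    def test_json_roundtrip_preserves_predictions(self, fitted, tmp_path):
        clf, scores, *_ = fitted
        model = SCMModel.from_classifier(clf, mgl_id="D", training_set_id="T1")
        path = tmp_path / "scm.json"
        model.to_json(path)
        back = SCMModel.from_json(path)
        sm = ModuleScoreMatrix(scores=scores, mgl_id="D", scaled=True)
        a1, p1 = predict_scm(model, sm)
        a2, p2 = predict_scm(back, sm)
        assert a1.labels == a2.labels
        pd.testing.assert_frame_equal(p1, p2)
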