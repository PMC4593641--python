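"""Split protocols, the two classifiers, metrics, and orchestration."""

import numpy as np
import pytest
from scipy import stats

from _oracles import count_metrics
from cnvprior.annotation import CNVRecord
from cnvprior.classify import (
    CNVFeatureRow,
    balanced_split,
    evaluate,
    permute_labels,
    predict_causative,
    run_experiment,
    train_cnv_classifier,
    train_gene_classifier,
    unbalanced_split,
)
from cnvprior.config import RunConfig


def _cohort(n_harmful, n_benign, phenotype="ph", patient_block=4, start_idx=0):
    out = []
    for i in range(n_harmful + n_benign):
        idx = start_idx + i
        out.append(CNVRecord(
            "chr1", 1000 * idx + 1, 1000 * idx + 500, "DEL",
            frozenset({phenotype}), label=i < n_harmful,
            patient=f"PT{idx // patient_block:03d}",
        ))
    return out


class TestBalancedSplit:
    def test_single_phenotype_sixteen_cnvs(self):
        cnvs = _cohort(8, 8)
        split = balanced_split(cnvs, seed=0)
        sizes = [len(p) for p in split.pools()]
        assert sizes == [8, 4, 4]
        for pool in split.pools():
            labels = [c.label for c in pool]
            assert sum(labels) == len(labels) // 2  # 1:1 in every pool

    def test_deterministic_per_seed(self):
        cnvs = _cohort(8, 8)
        a = balanced_split(cnvs, seed=5)
        b = balanced_split(cnvs, seed=5)
        assert [id(c) for p in a.pools() for c in p] == [
            id(c) for p in b.pools() for c in p
        ]

    def test_is_partition(self):
        cnvs = _cohort(10, 10)
        split = balanced_split(cnvs, seed=1)
        seen = [id(c) for p in split.pools() for c in p]
        assert len(seen) == len(set(seen))
        assert set(seen) <= {id(c) for c in cnvs}

    def test_rejects_when_no_quad_available(self):
        cnvs = _cohort(1, 8)
        with pytest.raises(ValueError, match="two cases and two controls"):
            balanced_split(cnvs, seed=0)

    def test_rejects_unlabeled(self):
        cnvs = _cohort(4, 4)
        object.__setattr__(cnvs[0], "label", None)
        with pytest.raises(ValueError, match="labeled"):
            balanced_split(cnvs, seed=0)

    def test_three_phenotype_cohort_class_balance(self):
        cnvs = (
            _cohort(6, 6, "pa", start_idx=0)
            + _cohort(4, 4, "pb", start_idx=100)
            + _cohort(2, 2, "pc", start_idx=200)
        )
        split = balanced_split(cnvs, seed=3)
        for pool in split.pools():
            n_case = sum(c.label for c in pool)
            assert n_case == len(pool) - n_case
        # counting oracle: selected total is a multiple of 4 per quad
        total = sum(len(p) for p in split.pools())
        assert total % 4 == 0 and total <= len(cnvs)


class TestUnbalancedSplit:
    def test_patients_never_straddle_pools(self):
        cnvs = _cohort(4, 60, patient_block=8)
        split = unbalanced_split(cnvs, seed=0)
        pool_of = {}
        for i, pool in enumerate(split.pools()):
            for c in pool:
                assert pool_of.setdefault(c.patient, i) == i

    def test_preserves_benign_excess(self):
        from cnvprior.simulate import make_bundle

        b = make_bundle(seed=3, benign_ratio=15.0, n_cnvs=160, n_patients=16)
        n_h = sum(c.label for c in b.cnvs)
        assert (n_h, len(b.cnvs) - n_h) == (10, 150)
        split = unbalanced_split(b.cnvs, seed=0)
        test_pool = split.cnv_test
        frac_h = sum(c.label for c in test_pool) / len(test_pool)
        # binomial tolerance around the cohort rate of 1/16
        assert abs(frac_h - 10 / 160) < 3 * np.sqrt((10 / 160) * (150 / 160) / len(test_pool))

    def test_deterministic_and_rejects_few_patients(self):
        cnvs = _cohort(4, 12, patient_block=4)
        a = unbalanced_split(cnvs, seed=9)
        b = unbalanced_split(cnvs, seed=9)
        assert [id(c) for p in a.pools() for c in p] == [
            id(c) for p in b.pools() for c in p
        ]
        with pytest.raises(ValueError, match="4 patients"):
            unbalanced_split(_cohort(2, 4, patient_block=2), seed=0)


class TestGeneClassifier:
    def test_separable_fixture_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        y = X[:, 0] > 0
        model = train_gene_classifier(X, y, RunConfig(rf_trees=30), seed=1)
        assert (model.predict(X) == y).mean() == 1.0

    def test_label_permuted_heldout_accuracy_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for seed in range(20):
            X = rng.normal(size=(200, 10))
            y = rng.random(200) < 0.5
            model = train_gene_classifier(
                X[:100], y[:100], RunConfig(rf_trees=30), seed=seed
            )
            accs.append((model.predict(X[100:]) == y[100:]).mean())
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_rejects_single_class(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_gene_classifier(X, np.ones(10, dtype=bool), RunConfig(), seed=0)

    def test_planted_features_recovered_in_importances(self, planted_bundle):
        from cnvprior.simulate import experiment_config

        cfg = experiment_config(runs=5)
        rep = run_experiment(planted_bundle.cnvs, planted_bundle.resources(), cfg)
        imp = rep.feature_importances
        planted_keys = {f"GO:{t}" for t in planted_bundle.planted_terms}
        background = [v for k, v in imp.items()
                      if k.startswith("GO:") and k not in planted_keys]
        assert np.mean([imp[k] for k in planted_keys]) > np.mean(background)
        ranked = sorted(imp, key=imp.get, reverse=True)
        in_top5 = sum(ranked.index(k) < 5 for k in planted_keys)
        assert in_top5 >= 2  # disease genes' other annotations can correlate


class TestPredictCausative:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = X[:, 0] > 0
        return train_gene_classifier(X, y, RunConfig(rf_trees=20), seed=0)

    def test_or_of_gene_calls(self, model):
        X = np.array([[-2.0, 0, 0], [-3.0, 0, 0], [3.0, 0, 0]])
        calls, flag = predict_causative(model, X)
        assert calls.tolist() == [False, False, True]
        assert flag is True

    def test_all_false_and_empty(self, model):
        X = np.array([[-2.0, 0, 0], [-3.0, 0, 0]])
        _, flag = predict_causative(model, X)
        assert flag is False
        calls, flag = predict_causative(model, np.zeros((0, 3)))
        assert len(calls) == 0 and flag is False

    def test_feature_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="mismatch"):
            predict_causative(model, np.zeros((2, 7)))


class TestCnvNaiveBayes:
    @staticmethod
    def _rows(causative, lengths, dgvs, labels):
        return [CNVFeatureRow(c, l, d, y)
                for c, l, d, y in zip(causative, lengths, dgvs, labels)]

    def test_perfectly_informative_causative_gives_recall_one(self):
        rng = np.random.default_rng(0)
        n = 40
        labels = np.arange(n) % 2 == 0
        rows = self._rows(labels.tolist(),
                          rng.integers(10_000, 1_000_000, n).tolist(),
                          rng.uniform(0, 2, n).tolist(),
                          labels.tolist())
        nb = train_cnv_classifier(rows, features=("gene",))
        test = self._rows([True, False], [50_000, 50_000], [0.5, 0.5], [True, False])
        preds = nb.predict(test)
        assert preds.tolist() == [True, False]

    def test_constant_features_predict_majority_prior(self):
        rows = self._rows([True] * 10, [1000] * 10, [1.0] * 10,
                          [True] * 7 + [False] * 3)
        nb = train_cnv_classifier(rows)
        preds = nb.predict(rows)
        assert preds.all()  # majority class is harmful

    def test_gaussian_posterior_matches_closed_form(self):
        rng = np.random.default_rng(2)
        n = 100
        labels = np.arange(n) < 60
        lengths = np.where(labels, 10 ** rng.normal(5.5, 0.3, n),
                           10 ** rng.normal(4.2, 0.3, n)).astype(int)
        dgvs = np.where(labels, rng.normal(0.2, 0.1, n), rng.normal(1.2, 0.2, n))
        rows = self._rows([False] * n, lengths.tolist(), dgvs.tolist(), labels.tolist())
        nb = train_cnv_classifier(rows, features=("length", "dgv"))

        # independent oracle: per-class Gaussian likelihoods via scipy
        x_len = np.log10(lengths.astype(float))
        logjll = np.zeros((n, 2))
        for j, cls in enumerate((False, True)):
            m = labels == cls
            prior = m.mean()
            mu_l, sd_l = x_len[m].mean(), x_len[m].std()
            mu_d, sd_d = dgvs[m].mean(), dgvs[m].std()
            logjll[:, j] = (
                np.log(prior)
                + stats.norm.logpdf(x_len, mu_l, sd_l)
                + stats.norm.logpdf(dgvs, mu_d, sd_d)
            )
        expected = logjll - np.logaddexp(logjll[:, 0], logjll[:, 1])[:, None]
        got = nb.predict_log_proba(rows)
        assert np.allclose(got, expected, atol=1e-9)

    def test_rejects_single_class(self):
        rows = self._rows([True] * 5, [1000] * 5, [0.0] * 5, [True] * 5)
        with pytest.raises(ValueError, match="single class"):
            train_cnv_classifier(rows)

    def test_adding_causative_never_hurts_conditional_likelihood(self):
        rng = np.random.default_rng(3)
        n = 60
        labels = np.arange(n) % 2 == 0
        causative = [bool(l) if rng.random() < 0.9 else not l for l in labels]
        lengths = rng.integers(10_000, 100_000, n).tolist()
        dgvs = rng.uniform(0, 1, n).tolist()
        rows = self._rows(causative, lengths, dgvs, labels.tolist())
        base = train_cnv_classifier(rows, features=("length", "dgv"))
        full = train_cnv_classifier(rows, features=("gene", "length", "dgv"))
        assert full.conditional_log_likelihood(rows) >= base.conditional_log_likelihood(rows)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([True, False, True], [True, False, True])
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_textbook_confusion_counts(self):
        # TP=3, FP=1, FN=1
        pred = [True, True, True, True, False, False]
        lab = [True, True, True, False, True, False]
        m = evaluate(pred, lab)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_zero_predicted_positives_flagged(self):
        m = evaluate([False, False], [True, False])
        assert m.precision == 0.0 and m.undefined_precision

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([True], [True, False])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random(30) < 0.5).tolist()
        lab = (rng.random(30) < 0.5).tolist()
        m = evaluate(pred, lab)
        p, r, f = count_metrics(pred, lab)
        assert (m.precision, m.recall, m.f1) == pytest.approx((p, r, f))


class TestRunExperiment:
    def test_two_invocations_identical(self, planted_bundle, planted_resources):
        from cnvprior.simulate import experiment_config

        cfg = experiment_config(runs=3)
        a = run_experiment(planted_bundle.cnvs, planted_resources, cfg)
        b = run_experiment(planted_bundle.cnvs, planted_resources, cfg)
        assert a.to_dict() == b.to_dict()
        assert a.feature_importances == b.feature_importances

    def test_feature_ablation_reports_per_subset(self, planted_bundle, planted_resources):
        from cnvprior.simulate import experiment_config

        reports = {}
        for subset in (("gene",), ("length", "dgv"), ("gene", "length", "dgv")):
            cfg = experiment_config(runs=2, cnv_features=subset)
            reports[subset] = run_experiment(planted_bundle.cnvs, planted_resources, cfg)
        for rep in reports.values():
            assert len(rep.runs) == 2
            assert 0.0 <= rep.mean_f1 <= 1.0

    def test_permuted_labels_lose_signal(self, planted_bundle, planted_resources):
        from cnvprior.simulate import experiment_config

        cfg = experiment_config(runs=5)
        null = run_experiment(
            permute_labels(planted_bundle.cnvs, 123), planted_resources, cfg
        )
        real = run_experiment(planted_bundle.cnvs, planted_resources, cfg)
        assert null.mean_f1 < real.mean_f1
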