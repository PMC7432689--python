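import math

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from lncfusion.evaluation import (ConfusionCounts, CVReport, MetricSet,
                                  confusion, cross_validate, mcnemar, metrics,
                                  stratified_folds)
from lncfusion.model import fast_config
from lncfusion.synthetic import GeneratorConfig, generate_benchmark


class TestConfusion:
    def test_all_correct(self):
        y = [1] * 10 + [0] * 10
        c = confusion(y, y)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_all_predicted_positive(self):
        y = [1] * 10 + [0] * 10
        c = confusion([1] * 20, y)
        assert (c.tp, c.fp, c.tn, c.fn) == (10, 10, 0, 0)

    def test_tally_oracle(self, rng):
        yhat = rng.integers(0, 2, 100)
        y = rng.integers(0, 2, 100)
        c = confusion(yhat, y)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for a, b in zip(yhat, y):
            key = ("tp" if b else "fp") if a else ("fn" if b else "tn")
            tally[key] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"])
        assert c.total == 100

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect(self):
        m = metrics(ConfusionCounts(50, 50, 0, 0))
        assert (m.acc, m.sn, m.sp, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_inverted(self):
        m = metrics(ConfusionCounts(0, 0, 50, 50))
        assert m.acc == 0.0 and m.mcc == -1.0

    def test_hand_arithmetic(self):
        m = metrics(ConfusionCounts(tp=40, fn=10, tn=45, fp=5))
        assert m.acc == pytest.approx(0.85, abs=1e-12)
        assert m.sn == pytest.approx(0.80, abs=1e-12)
        assert m.sp == pytest.approx(0.90, abs=1e-12)
        expected_mcc = (40 * 45 - 5 * 10) / math.sqrt(45 * 50 * 50 * 55)
        assert m.mcc == pytest.approx(expected_mcc, abs=1e-12)

    def test_degenerate_mcc_zero(self):
        # all predicted positive: TN+FN factor is 0 -> MCC defined as 0
        m = metrics(ConfusionCounts(tp=10, tn=0, fp=10, fn=0))
        assert m.mcc == 0.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_acc_between_sn_sp(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(1, 50, 4)
            m = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert min(m.sn, m.sp) - 1e-12 <= m.acc <= max(m.sn, m.sp) + 1e-12

    def test_swap_symmetry(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, 4))
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = metrics(ConfusionCounts(tp, tn, fp, fn))
            # swapping labels and predictions 0<->1 maps TP<->TN, FP<->FN
            sw = metrics(ConfusionCounts(tn, tp, fn, fp))
            assert sw.sn == pytest.approx(m.sp)
            assert sw.sp == pytest.approx(m.sn)
            assert sw.acc == pytest.approx(m.acc)
            assert sw.mcc == pytest.approx(m.mcc)

    def test_permutation_invariance(self, rng):
        yhat = rng.integers(0, 2, 60)
        y = rng.integers(0, 2, 60)
        perm = rng.permutation(60)
        assert metrics(confusion(yhat, y)) == metrics(
            confusion(yhat[perm], y[perm]))


class TestMcNemar:
    def test_identical_predictions(self):
        y = [0, 1] * 10
        r = mcnemar(y, y, y)
        assert r.b == r.c == 0 and r.p_value == 1.0 and r.method == "degenerate"

    def test_exact_binomial_b10_c0(self):
        # A correct on 10 where B wrong; agree elsewhere
        labels = [1] * 10 + [0] * 20
        a = [1] * 10 + [0] * 20
        b = [0] * 10 + [0] * 20
        r = mcnemar(a, b, labels)
        assert (r.b, r.c) == (10, 0)
        assert r.method == "exact-binomial"
        assert r.p_value == pytest.approx(2 * 0.5 ** 10)

    def test_chi_square_b30_c10(self):
        labels = [1] * 40 + [0] * 10
        a = [1] * 30 + [0] * 10 + [0] * 10
        b = [0] * 30 + [1] * 10 + [0] * 10
        r = mcnemar(a, b, labels)
        assert (r.b, r.c) == (30, 10)
        assert r.method == "chi-square"
        assert r.statistic == pytest.approx((abs(30 - 10) - 1) ** 2 / 40)
        assert r.statistic == pytest.approx(9.025)

    def test_symmetry_in_b_c(self, rng):
        labels = rng.integers(0, 2, 80)
        a = rng.integers(0, 2, 80)
        b = rng.integers(0, 2, 80)
        r1 = mcnemar(a, b, labels)
        r2 = mcnemar(b, a, labels)
        assert (r1.b, r1.c) == (r2.c, r2.b)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert 0 < r1.p_value <= 1

    def test_against_statsmodels(self, rng):
        for n, exact in ((40, True), (400, False)):
            labels = rng.integers(0, 2, n)
            a = np.where(rng.random(n) < 0.8, labels, 1 - labels)
            b = np.where(rng.random(n) < 0.7, labels, 1 - labels)
            r = mcnemar(a, b, labels)
            n11 = int(((a == labels) & (b == labels)).sum())
            n00 = int(((a != labels) & (b != labels)).sum())
            table = [[n11, r.b], [r.c, n00]]
            ref = sm_mcnemar(table, exact=r.method == "exact-binomial",
                             correction=True)
            assert r.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mcnemar([1, 0], [1], [1, 0])


class TestStratifiedFolds:
    def test_partition_and_stratification(self):
        labels = np.array([1] * 10 + [0] * 10)
        folds = stratified_folds(labels, 2, seed=4)
        assert sorted(np.concatenate(folds).tolist()) == list(range(20))
        for f in folds:
            assert len(f) == 10 and labels[f].sum() == 5

    def test_deterministic(self):
        labels = np.array([0, 1] * 25)
        f1 = stratified_folds(labels, 5, seed=9)
        f2 = stratified_folds(labels, 5, seed=9)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_class_smaller_than_folds(self):
        labels = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="fewer than"):
            stratified_folds(labels, 3, seed=0)


@pytest.fixture(scope="module")
def cv_setup():
    data, _ = generate_benchmark(
        GeneratorConfig(n_per_class=20, length_range=(200, 500), seed=31))
    cfg = fast_config(maxlen=200, modalities=("ofh",), pretrain_epochs=4,
                      fusion_epochs=2, finetune_epochs=1, batch_size=16,
                      seed=2)
    return data, cfg


class TestCrossValidate:
    def test_two_fold_report(self, cv_setup):
        data, cfg = cv_setup
        tables: list = []
        report = cross_validate(data, cfg, folds=2, seed=5,
                                collect_tables=tables)
        assert report.folds == 2
        assert len(tables) == 2 and tables[0] != tables[1]
        summary = report.summary()
        assert set(summary) == {"ACC", "Sn", "Sp", "MCC"}
        for mean, sd in summary.values():
            assert np.isfinite(mean) and sd >= 0

    def test_report_tsv(self, cv_setup, tmp_path):
        data, cfg = cv_setup
        report = cross_validate(data, cfg, folds=2, seed=5)
        report.to_tsv(tmp_path / "cv.tsv")
        lines = (tmp_path / "cv.tsv").read_text().splitlines()
        assert lines[0].startswith("fold") and "±" in lines[-1]
        assert len(lines) == 4
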