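"""Performance measures against independent oracles; matrix bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

from promisig.assembly import PairDataset, SplitTrial, TargetPair
from promisig.evaluation import (
    ConfusionCounts,
    MetricSet,
    OrchestrationError,
    PairData,
    PredictionRecord,
    UndefinedMetricError,
    balanced_accuracy,
    count_cross_predictions,
    count_predictions,
    f1,
    family_subsets,
    mcc,
    precision,
    recall,
    records_to_dataframe,
    run_matrix,
    summarize,
)
from promisig.models import CVConfig, train
from promisig.synthdata import LibraryConfig, Target, generate_bitvector_library


def _labels(c: ConfusionCounts):
    y_true = [1] * (c.tp + c.fn) + [-1] * (c.tn + c.fp)
    y_pred = [1] * c.tp + [-1] * c.fn + [-1] * c.tn + [1] * c.fp
    return y_true, y_pred


class TestMetricFormulas:
    def test_hand_worked_confusion_table(self):
        c = ConfusionCounts(tp=30, fn=20, tn=40, fp=10)
        assert balanced_accuracy(c) == pytest.approx(0.7)           # (0.6+0.8)/2
        assert mcc(c) == pytest.approx(1000 / np.sqrt(40 * 50 * 50 * 60))
        assert f1(c) == pytest.approx(60 / 90)
        assert precision(c) == pytest.approx(0.75)
        assert recall(c) == pytest.approx(0.6)

    def test_perfect_and_chance_classifiers(self):
        perfect = ConfusionCounts(tp=50, fn=0, tn=50, fp=0)
        assert balanced_accuracy(perfect) == 1.0
        assert mcc(perfect) == 1.0
        assert f1(perfect) == precision(perfect) == recall(perfect) == 1.0
        chance = ConfusionCounts(tp=25, fn=25, tn=25, fp=25)
        assert balanced_accuracy(chance) == 0.5
        assert mcc(chance) == 0.0

    def test_undefined_metrics_raise_not_zero(self):
        no_positives = ConfusionCounts(tp=0, fn=0, tn=10, fp=0)
        with pytest.raises(UndefinedMetricError):
            balanced_accuracy(no_positives)
        with pytest.raises(UndefinedMetricError):
            recall(no_positives)
        with pytest.raises(UndefinedMetricError):
            f1(no_positives)
        never_positive = ConfusionCounts(tp=0, fn=5, tn=10, fp=0)
        with pytest.raises(UndefinedMetricError):
            precision(never_positive)
        # tp = 0 with both error kinds present is defined and equals 0
        c = ConfusionCounts(tp=0, fn=5, tn=10, fp=5)
        assert precision(c) == recall(c) == f1(c) == 0.0

    def test_degenerate_mcc_is_flagged_zero(self):
        c = ConfusionCounts(tp=0, fn=5, tn=10, fp=0)  # no positive predictions
        assert mcc(c) == 0.0
        ms = MetricSet.from_counts(c)
        assert ms.mcc == 0.0
        assert ms.mcc_degenerate
        assert ms.precision is None  # undefined stays missing

    @given(
        tp=st.integers(0, 200), fn=st.integers(0, 200),
        tn=st.integers(0, 200), fp=st.integers(0, 200),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_formulas_match_scikit_learn_oracle(self, tp, fn, tn, fp):
        c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        y_true, y_pred = _labels(c)
        if tp + fn > 0 and tn + fp > 0:
            assert balanced_accuracy(c) == pytest.approx(
                skm.balanced_accuracy_score(y_true, y_pred), abs=1e-12
            )
        if not (tp + fn == 0 and tn + fp == 0):
            assert mcc(c) == pytest.approx(
                skm.matthews_corrcoef(y_true, y_pred), abs=1e-12
            )
        if 2 * tp + fp + fn > 0:
            assert f1(c) == pytest.approx(
                skm.f1_score(y_true, y_pred, pos_label=1, zero_division=0),
                abs=1e-12,
            )

    def test_mcc_magnitude_invariant_under_class_swap(self):
        c = ConfusionCounts(tp=30, fn=20, tn=40, fp=10)
        swapped = ConfusionCounts(tp=c.tn, fn=c.fp, tn=c.tp, fp=c.fn)
        assert abs(mcc(c)) == pytest.approx(abs(mcc(swapped)))
        assert balanced_accuracy(c) == pytest.approx(balanced_accuracy(swapped))


class TestCountingFormulas:
    @pytest.mark.parametrize(
        "n_pairs, expected", [(2, 2), (5, 20), (170, 28730)]
    )
    def test_cross_matrix_size(self, n_pairs, expected):
        assert count_cross_predictions(n_pairs) == expected

    @pytest.mark.parametrize(
        "args, expected", [((1, 1, 1), 1), ((5, 10, 3), 750), ((170, 10, 3), 867000)]
    )
    def test_total_prediction_count(self, args, expected):
        assert count_predictions(*args) == expected


def _bitvector_pair_data(n_pairs=3, seed=6):
    cfg = LibraryConfig(n_pairs=n_pairs, n_st_a=10, n_st_b=10, n_dt=20,
                        carrier_rate=1.0, leak_rate=0.0, seed=seed)
    sets = generate_bitvector_library(cfg, n_bits=64, background_rate=0.1)
    pair_data = {}
    for s in sets:
        pid = f"P{s.pair_index}"
        ids = [f"{pid}-{k}-{i}" for i, k in enumerate(s.klass)]
        rng = np.random.default_rng(seed + s.pair_index)
        train_ids, test_ids = set(), set()
        for klass in ("ST_A", "ST_B", "DT"):
            members = [i for i, k in zip(ids, s.klass) if k == klass]
            order = rng.permutation(len(members))
            half = len(members) // 2
            train_ids |= {members[j] for j in order[:half]}
            test_ids |= {members[j] for j in order[half:]}
        pair = TargetPair(Target(f"{pid}a", "kinase"), Target(f"{pid}b", "kinase"), pid)
        pair_data[pid] = PairData(
            pair=pair, compound_ids=ids, X=s.X, y=s.y,
            trials=[SplitTrial(0, 0, frozenset(train_ids), frozenset(test_ids))],
        )
    return pair_data


class TestRunMatrix:
    def test_record_counts_and_kinds_follow_the_formulas(self):
        pair_data = _bitvector_pair_data(n_pairs=3)
        models = {}
        for pid, data in pair_data.items():
            rows = data.train_rows(0)
            models[(pid, "knn", 0)] = train(
                "knn", data.X[rows], data.y[rows],
                CVConfig(grids={"knn": {"n_neighbors": [1]}}, seed=1), pair_id=pid,
            )
        records = run_matrix(pair_data, models, algorithms=("knn",), n_trials=1)
        assert len(records) == count_predictions(3, 1, 1)
        native = [r for r in records if r.kind == "native"]
        cross = [r for r in records if r.kind == "cross"]
        assert len(native) == 3
        assert len(cross) == count_cross_predictions(3)
        for r in records:
            assert r.counts.total == len(pair_data[r.test_pair_id].trials[0].test)

    def test_missing_models_raise_orchestration_error(self):
        pair_data = _bitvector_pair_data(n_pairs=2)
        with pytest.raises(OrchestrationError, match="missing"):
            run_matrix(pair_data, {}, algorithms=("knn",), n_trials=1)


def _record(model_pid, test_pid, ba=0.5, algorithm="svm"):
    c = ConfusionCounts(tp=10, fn=10, tn=10, fp=10)
    ms = MetricSet(ba=ba, mcc=0.0, f1=0.5, precision=0.5, recall=0.5)
    return PredictionRecord(model_pid, test_pid, algorithm, 0, c, ms)


class TestFamilySubsets:
    def _pairs(self, families):
        return {
            f"P{i}": TargetPair(
                Target(f"T{2*i}", fam_a), Target(f"T{2*i+1}", fam_b), f"P{i}"
            )
            for i, (fam_a, fam_b) in enumerate(families)
        }

    def test_single_family_library_is_all_same(self):
        pairs = self._pairs([("kinase", "kinase")] * 3)
        records = [_record(a, b) for a in pairs for b in pairs if a != b]
        buckets = family_subsets(records, pairs)
        assert len(buckets["same"]) == 6
        assert not buckets["different"] and not buckets["mixed"]

    def test_disjoint_families_are_all_different(self):
        pairs = self._pairs([("kinase", "kinase"), ("GPCR", "GPCR")])
        records = [_record("P0", "P1"), _record("P1", "P0")]
        buckets = family_subsets(records, pairs)
        assert len(buckets["different"]) == 2

    def test_three_family_library_matches_brute_force_enumeration(self):
        families = [("kinase", "kinase"), ("GPCR", "GPCR"), ("protease", "kinase"),
                    ("GPCR", "protease"), ("kinase", "kinase")]
        pairs = self._pairs(families)
        records = [_record(a, b) for a in pairs for b in pairs if a != b]
        buckets = family_subsets(records, pairs)
        assert sum(len(b) for b in buckets.values()) == len(records)
        for rec in records:
            fa = pairs[rec.model_pair_id].families
            fb = pairs[rec.test_pair_id].families
            if len(fa | fb) == 1:
                assert rec in buckets["same"]
            elif not fa & fb:
                assert rec in buckets["different"]
            else:
                assert rec in buckets["mixed"]

    def test_native_records_are_ignored(self):
        pairs = self._pairs([("kinase", "kinase"), ("kinase", "kinase")])
        buckets = family_subsets([_record("P0", "P0")], pairs)
        assert all(not b for b in buckets.values())


class TestSummarize:
    def test_single_record_collapses_to_its_value(self):
        stats = summarize([_record("P0", "P1", ba=0.62)])[("cross", "svm", "ba")]
        assert (stats.min, stats.q1, stats.median, stats.q3, stats.max) == (
            0.62, 0.62, 0.62, 0.62, 0.62
        )
        assert stats.outliers == ()

    def test_median_of_three(self):
        records = [_record("P0", "P1", ba=v) for v in (0.4, 0.5, 0.6)]
        assert summarize(records)[("cross", "svm", "ba")].median == 0.5

    def test_quantiles_match_an_independent_routine(self):
        rng = np.random.default_rng(12)
        values = rng.random(1000)
        records = [_record("P0", "P1", ba=float(v)) for v in values]
        stats = summarize(records)[("cross", "svm", "ba")]
        # oracle: manual linear interpolation on the sorted sample
        s = np.sort(values)
        for q, got in ((0.25, stats.q1), (0.5, stats.median), (0.75, stats.q3)):
            pos = q * (len(s) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            expect = s[lo] * (1 - frac) + s[min(lo + 1, len(s) - 1)] * frac
            assert got == pytest.approx(expect, abs=1e-9)
        iqr = stats.q3 - stats.q1
        expect_outliers = values[(values < stats.q1 - 1.5 * iqr)
                                 | (values > stats.q3 + 1.5 * iqr)]
        assert sorted(stats.outliers) == sorted(float(v) for v in expect_outliers)

    def test_missing_metrics_are_excluded_and_counted(self):
        c = ConfusionCounts(tp=0, fn=5, tn=10, fp=0)
        rec_missing = PredictionRecord("P0", "P1", "svm", 0, c,
                                       MetricSet.from_counts(c))
        stats = summarize([rec_missing, _record("P0", "P1", ba=0.5)])
        assert stats[("cross", "svm", "precision")].n_missing == 1
        assert stats[("cross", "svm", "precision")].n == 1

    def test_dataframe_round_trip_carries_all_records(self):
        records = [_record("P0", "P1"), _record("P1", "P0"), _record("P0", "P0")]
        df = records_to_dataframe(records)
        assert len(df) == 3
        assert set(df.kind) == {"native", "cross"}
        assert {"ba", "mcc", "f1", "precision", "recall"} <= set(df.columns)
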