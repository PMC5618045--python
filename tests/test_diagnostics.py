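"""Confusion matrices, performance metrics, agreement, LOD, readout, selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss_kappa

from sicklescreen.diagnostics import (
    AA_VS_REST_SCHEME,
    SS_VS_REST_SCHEME,
    THREE_CLASS_SCHEME,
    BinaryScheme,
    ConfusionMatrix,
    agreement_summary,
    binary_metrics,
    confusion_matrix,
    consistent_binary_counts,
    fleiss_kappa,
    fleiss_kappa_from_counts,
    intra_observer_kappas,
    lod_by_roc,
    one_point_auc,
    readout_time,
    select_formulation,
)
from sicklescreen.errors import ValidationError


def _score_table(rows):
    """rows: (observer, stain, call, true_hbs)"""
    return pd.DataFrame(
        [
            {
                "observer_id": o,
                "stain_id": s,
                "replicate": 1,
                "call": c,
                "true_hbs_percent": h,
            }
            for o, s, c, h in rows
        ]
    )


def _binary_tally_table(tp, fn, tn, fp, pos_hbs=20.0, neg_hbs=0.0):
    """Score table realizing exact binary tally counts."""
    rows = []
    i = itertools.count()
    for n, call, hbs in (
        (tp, "positive", pos_hbs),
        (fn, "negative", pos_hbs),
        (tn, "negative", neg_hbs),
        (fp, "positive", neg_hbs),
    ):
        for _ in range(n):
            rows.append(("observer_1", f"s{next(i):04d}", call, hbs))
    return _score_table(rows)


class TestConfusionMatrix:
    def test_all_correct_gives_diagonal(self):
        rows = [("o1", f"s{i}", label, hbs)
                for i, (label, hbs) in enumerate([("AA", 0), ("AS", 20), ("SS", 80)] * 5)]
        cm = confusion_matrix(_score_table(rows), THREE_CLASS_SCHEME)
        assert cm.total == 15
        assert np.all(cm.counts == np.diag([5, 5, 5]))

    def test_pooling_three_observers_triples_the_total(self):
        rows = [
            (f"observer_{o}", f"s{i}", "AA", 0.0)
            for o in range(1, 4)
            for i in range(185)
        ]
        cm = confusion_matrix(_score_table(rows), THREE_CLASS_SCHEME)
        assert cm.total == 555

    def test_matches_naive_tally_loop(self, rng):
        labels = THREE_CLASS_SCHEME.labels
        hbs_by_label = {"AA": 0.0, "AS": 20.0, "SS": 80.0}
        for _ in range(50):
            n = int(rng.integers(5, 40))
            true_labels = rng.choice(labels, size=n)
            calls = rng.choice(labels, size=n)
            rows = [
                ("o1", f"s{i}", calls[i], hbs_by_label[true_labels[i]])
                for i in range(n)
            ]
            cm = confusion_matrix(_score_table(rows), THREE_CLASS_SCHEME)
            naive = np.zeros((3, 3), dtype=int)
            for t, c in zip(true_labels, calls):
                naive[labels.index(t), labels.index(c)] += 1
            np.testing.assert_array_equal(cm.counts, naive)

    def test_call_outside_label_set_rejected(self):
        with pytest.raises(ValidationError):
            confusion_matrix(_score_table([("o1", "s1", "XX", 0.0)]), THREE_CLASS_SCHEME)

    def test_truth_boundaries_of_the_genotype_scheme(self):
        assert THREE_CLASS_SCHEME.truth_label(0.0) == "AA"
        assert THREE_CLASS_SCHEME.truth_label(10.0) == "AS"
        assert THREE_CLASS_SCHEME.truth_label(40.0) == "AS"
        assert THREE_CLASS_SCHEME.truth_label(41.0) == "SS"
        assert AA_VS_REST_SCHEME.truth_label(10.0) == "positive"
        assert SS_VS_REST_SCHEME.truth_label(79.0) == "negative"
        assert SS_VS_REST_SCHEME.truth_label(80.0) == "positive"


class TestBinaryMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 5]]), ("negative", "positive"))
        m = binary_metrics(cm, {"positive"})
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_matches_direct_formula_on_random_tables(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 200, size=4))
            cm = ConfusionMatrix(
                np.array([[tn, fp], [fn, tp]]), ("negative", "positive")
            )
            m = binary_metrics(cm, {"positive"})
            assert m.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
            assert m.specificity == pytest.approx(tn / (fp + tn), abs=1e-12)
            assert m.ppv == pytest.approx(tp / (tp + fp), abs=1e-12)
            assert m.npv == pytest.approx(tn / (tn + fn), abs=1e-12)
            assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn), abs=1e-12)
            # accuracy is the prevalence-weighted mean of sens and spec
            weight = (tp + fn) / (tp + fp + tn + fn)
            assert m.accuracy == pytest.approx(
                weight * m.sensitivity + (1 - weight) * m.specificity, abs=1e-12
            )

    def test_zero_denominator_reported_as_undefined_not_zero(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 0]]), ("negative", "positive"))
        m = binary_metrics(cm, {"positive"})
        assert m.sensitivity is None
        assert "sensitivity" in m.undefined
        assert m.specificity == 1.0

    def test_collapsing_three_class_matrix(self):
        counts = np.array([[50, 3, 0], [2, 60, 4], [0, 1, 30]])
        cm = ConfusionMatrix(counts, ("AA", "AS", "SS"))
        m = binary_metrics(cm, {"AS", "SS"})
        assert m.tp == 60 + 4 + 1 + 30
        assert m.fn == 2 + 0
        assert m.fp == 3 + 0
        assert m.tn == 50
        assert m.tp + m.fp + m.tn + m.fn == counts.sum()


class TestConsistentCounts:
    def test_recovers_cells_from_printed_aa_vs_rest_metrics(self):
        tp, fp, tn, fn = consistent_binary_counts(92.8, 100.0, 100.0, 77.6, 94.2, 555)
        cm = ConfusionMatrix(np.array([[tn, fp], [fn, tp]]), ("negative", "positive"))
        m = binary_metrics(cm, {"positive"}).as_percents(1)
        assert m == {
            "sensitivity": 92.8,
            "specificity": 100.0,
            "ppv": 100.0,
            "npv": 77.6,
            "accuracy": 94.2,
        }

    def test_impossible_metrics_raise(self):
        with pytest.raises(ValidationError):
            consistent_binary_counts(100.0, 100.0, 100.0, 100.0, 50.0, 10)


class TestFleissKappa:
    def test_unanimous_raters_give_kappa_one(self):
        counts = np.array([[3, 0], [0, 3], [3, 0]])
        assert fleiss_kappa_from_counts(counts) == pytest.approx(1.0)

    def test_hand_worked_two_subject_example(self):
        # counts (2,1) and (2,1): P_i = 1/3, p = (2/3, 1/3), Pe = 5/9,
        # kappa = (1/3 - 5/9)/(1 - 5/9) = -0.5
        counts = np.array([[2, 1], [2, 1]])
        assert fleiss_kappa_from_counts(counts) == pytest.approx(-0.5)

    def test_matches_statsmodels_on_random_tables(self, rng):
        for _ in range(50):
            n_subjects = int(rng.integers(2, 20))
            n_raters = int(rng.integers(2, 6))
            ratings = rng.integers(0, 3, size=(n_subjects, n_raters))
            counts = np.stack([np.bincount(r, minlength=3) for r in ratings])
            if np.all(counts[:, 1:] == 0):
                continue  # single-category table: chance agreement is 1
            ours = fleiss_kappa_from_counts(counts)
            theirs = sm_fleiss_kappa(counts, method="fleiss")
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_invariant_under_category_relabeling(self):
        counts = np.array([[2, 1, 1], [0, 3, 1], [1, 1, 2], [4, 0, 0]])
        base = fleiss_kappa_from_counts(counts)
        for perm in itertools.permutations(range(3)):
            assert fleiss_kappa_from_counts(counts[:, perm]) == pytest.approx(base)

    def test_unequal_rating_counts_rejected(self):
        with pytest.raises(ValidationError):
            fleiss_kappa_from_counts(np.array([[2, 1], [1, 1]]))

    def test_tidy_table_wrapper_and_intra_observer_split(self):
        rows = []
        for obs in ("observer_1", "observer_2"):
            for stain in ("s1", "s2"):
                for rep in (1, 2):
                    call = "AA" if (obs == "observer_1" or stain == "s1") else "SS"
                    rows.append(
                        {
                            "observer_id": obs,
                            "stain_id": stain,
                            "replicate": rep,
                            "call": call,
                            "true_hbs_percent": 0.0,
                        }
                    )
        table = pd.DataFrame(rows)
        per_obs = intra_observer_kappas(table)
        # each observer is internally perfectly self-consistent
        assert per_obs == {"observer_1": 1.0, "observer_2": 1.0}


class TestAgreementSummary:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((0.88, 0.93, 0.97), (0.93, 0.04)),
            ((0.72, 0.88, 0.94), (0.85, 0.09)),
            ((0.5, 0.5, 0.5), (0.5, 0.0)),
        ],
    )
    def test_population_sd_reporting_convention(self, values, expected):
        assert agreement_summary(values).rounded == expected

    def test_unrounded_values_retained(self):
        summary = agreement_summary((0.88, 0.93, 0.97))
        assert summary.mean == pytest.approx(np.mean((0.88, 0.93, 0.97)))
        assert summary.sd == pytest.approx(np.std((0.88, 0.93, 0.97), ddof=0))

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            agreement_summary([0.9])


class TestLodByRoc:
    def test_perfect_separation_at_candidate(self):
        table = _binary_tally_table(tp=20, fn=0, tn=20, fp=0, pos_hbs=10.0)
        result = lod_by_roc(table, (10.0, 20.0))
        assert result.lod_percent == 10.0
        assert result.auc_by_candidate[10.0] == pytest.approx(1.0)

    def test_printed_count_pattern_auc(self):
        table = _binary_tally_table(tp=820, fn=68, tn=220, fp=2, pos_hbs=20.0)
        result = lod_by_roc(table, (10.0,))
        assert result.auc_by_candidate[10.0] == pytest.approx(
            (820 / 888 + 220 / 222) / 2
        )

    def test_uninformative_rater_gives_half_everywhere(self):
        table = _binary_tally_table(tp=10, fn=0, tn=0, fp=10, pos_hbs=20.0)
        result = lod_by_roc(table, (10.0, 15.0))
        assert all(a == pytest.approx(0.5) for a in result.auc_by_candidate.values())

    def test_single_class_candidate_excluded(self):
        table = _binary_tally_table(tp=10, fn=0, tn=10, fp=0, pos_hbs=20.0)
        result = lod_by_roc(table, (10.0, 90.0))
        assert result.excluded == (90.0,)
        assert result.lod_percent == 10.0

    def test_ties_break_toward_lowest_candidate(self):
        table = _binary_tally_table(tp=10, fn=0, tn=10, fp=0, pos_hbs=20.0)
        result = lod_by_roc(table, (20.0, 5.0, 10.0))
        defined = {c: a for c, a in result.auc_by_candidate.items() if a is not None}
        best = max(defined.values())
        assert result.lod_percent == min(c for c, a in defined.items() if a == best)

    def test_one_point_auc_matches_sklearn_on_random_calls(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            truth = rng.random(n) < 0.5
            calls = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            ours = one_point_auc(calls, truth)
            theirs = roc_auc_score(truth, calls.astype(float))
            assert ours == pytest.approx(theirs, abs=1e-12)


def _timed_table(stable_after, window=25):
    """Three observers scoring each class every minute; class becomes
    uniformly correct from its stable_after minute onward."""
    rows = []
    for cls, t_stable in stable_after.items():
        for minute in range(1, window + 1):
            for obs in range(1, 4):
                correct = minute >= t_stable if t_stable is not None else (minute % 2 == 0)
                rows.append(
                    {
                        "minute": minute,
                        "observer_id": f"observer_{obs}",
                        "class_label": cls,
                        "correct": correct,
                    }
                )
    return pd.DataFrame(rows)


class TestReadoutTime:
    def test_paper_pattern_seven_eleven_one(self):
        result = readout_time(_timed_table({"AA": 7, "AS": 11, "SS": 1}))
        assert result.per_class_minutes == {"AA": 7.0, "AS": 11.0, "SS": 1.0}
        assert result.total_minutes == 21.0

    def test_all_correct_from_start_gives_incubation_only(self):
        table = _timed_table({"AA": 0, "AS": 0, "SS": 0})
        table["minute"] -= 1  # recording starts at minute 0
        assert readout_time(table).total_minutes == 10.0

    def test_transient_correct_spell_is_ignored(self):
        # correct at minutes 3-5, wrong at 6, correct from 7: stable time is 7.
        rows = []
        for minute in range(1, 26):
            correct = (3 <= minute <= 5) or minute >= 7
            if minute == 6:
                correct = False
            rows.append(
                {"minute": minute, "observer_id": "o1", "class_label": "AS",
                 "correct": correct}
            )
        table = pd.DataFrame(rows)
        result = readout_time(table)
        # brute-force oracle: scan all minutes for the first all-correct suffix
        minutes = sorted(table["minute"].unique())
        expected = None
        for m in minutes:
            tail = table[table["minute"] >= m]
            if tail["correct"].all():
                expected = m
                break
        assert result.per_class_minutes["AS"] == expected == 7

    def test_never_stable_class_reported_not_crashed(self):
        result = readout_time(_timed_table({"AA": 7, "AS": None}))
        assert result.unstable_classes == ("AS",)
        assert result.total_minutes is None


class TestSelectFormulation:
    def test_dominating_candidate_wins(self):
        curves = {
            "A": {0.0: 1.0, 20.0: 1.8, 40.0: 1.9},
            "B": {0.0: 1.0, 20.0: 1.3, 40.0: 2.2},
        }
        assert select_formulation(curves) == "A"

    def test_tie_broken_by_most_gradual_20_to_40_change(self):
        curves = {
            "steep": {0.0: 1.0, 20.0: 1.5, 40.0: 2.4},
            "gradual": {0.0: 1.0, 20.0: 1.5, 40.0: 1.7},
        }
        assert select_formulation(curves) == "gradual"

    def test_missing_grid_point_rejected(self):
        with pytest.raises(ValidationError):
            select_formulation({"A": {0.0: 1.0, 20.0: 1.5}})

    def test_generator_curves_prefer_15_percent_ms(self):
        from sicklescreen.synthetic import contrast_ratio

        curves = {
            f"{int(pct)}% MS": {
                x: contrast_ratio(x, "MS", pct) for x in (0.0, 20.0, 40.0)
            }
            for pct in (10.0, 15.0, 20.0)
        }
        assert select_formulation(curves) == "15% MS"
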