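"""Tests for annotations, metrics, benchmark filters, subsampling and CV."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from disocrf.crf import LabeledSequence, ObservationSequence
from disocrf.evaluation import (
    AnnotationError,
    ConfusionCounts,
    ProteinRecord,
    apply_benchmark_filters,
    canonicalize_intervals,
    confusion_counts,
    intervals_to_labels,
    kfold_split,
    labels_to_intervals,
    metrics,
    ratio_curve_experiment,
    read_interval_table,
    subsample_ordered_residues,
    write_interval_table,
)

# Published disorder annotations and predictions for three PDB chains
# (crystallographic missing-density regions; 1-based inclusive intervals).
WORKED_EXAMPLES = {
    "3H2YA": {
        "L": 368,
        "actual": [(1, 55), (199, 202)],
        "predictions": {
            "crf": ([(1, 32)], (32, 0, 309, 27)),
            "rf": ([(1, 3), (365, 368)], (3, 4, 305, 56)),
            "svm": ([(1, 3), (16, 21), (28, 29), (31, 31), (170, 172), (185, 185)],
                    (12, 4, 305, 47)),
            "ann": ([(1, 4), (16, 21), (28, 29), (31, 31), (34, 34), (170, 171), (314, 314)],
                    (14, 3, 306, 45)),
        },
    },
    "2ODKA": {
        "L": 85,
        "actual": [(52, 85)],
        "predictions": {
            "crf": ([(1, 4), (49, 85)], (34, 7, 44, 0)),
            "rf": ([(1, 5), (62, 65), (75, 75), (77, 77), (81, 85)], (11, 5, 46, 23)),
            "svm": ([(1, 2), (52, 52), (62, 62), (77, 78), (81, 81), (83, 84)],
                    (7, 2, 49, 27)),
            "ann": ([(1, 4), (48, 49), (52, 52), (62, 62), (77, 78), (83, 84)],
                    (6, 6, 45, 28)),
        },
    },
    "4AD4A": {
        "L": 380,
        "actual": [(1, 30), (380, 380)],
        "predictions": {
            "crf": ([(1, 26), (376, 380)], (27, 4, 345, 4)),
            # the published counts for this combination state FP=22/TN=327, one
            # residue off from what the published intervals themselves give
            "rf": ([(1, 3), (13, 31), (69, 81), (132, 133), (236, 236), (346, 346),
                    (377, 380)], (22, 21, 328, 9)),
            "svm": ([(11, 31), (54, 55), (65, 69), (72, 75), (78, 82), (88, 88),
                     (97, 99), (104, 104), (337, 337), (346, 346), (376, 380)],
                    (21, 28, 321, 10)),
            "ann": ([(10, 31), (33, 33), (53, 54), (65, 66), (68, 68), (72, 76),
                     (78, 82), (86, 86), (88, 88), (97, 99), (129, 129), (201, 201),
                     (207, 207), (260, 260), (337, 338), (342, 342), (344, 344),
                     (346, 347), (376, 380)], (22, 36, 313, 9)),
        },
    },
}


label_chains = st.text(alphabet="OD", min_size=1, max_size=80)


class TestIntervalLabelConversion:
    def test_direct_construction(self):
        assert intervals_to_labels([(1, 4)], 6) == "DDDDOO"

    def test_empty_intervals(self):
        assert intervals_to_labels([], 3) == "OOO"

    def test_published_annotation_count(self):
        # two disordered regions totalling 59 residues on a 368-residue chain
        labels = intervals_to_labels([(1, 55), (199, 202)], 368)
        assert labels.count("D") == 59

    def test_out_of_range_rejected(self):
        with pytest.raises(AnnotationError):
            intervals_to_labels([(0, 3)], 5)
        with pytest.raises(AnnotationError):
            intervals_to_labels([(2, 6)], 5)

    def test_labels_to_intervals_basic(self):
        assert labels_to_intervals("DDDDOO") == [(1, 4)]
        assert labels_to_intervals("OOO") == []
        assert labels_to_intervals("DOD") == [(1, 1), (3, 3)]

    @given(label_chains)
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, chain):
        assert intervals_to_labels(labels_to_intervals(chain), len(chain)) == chain

    def test_canonicalize_merges_overlaps(self):
        # overlapping and touching runs coalesce into maximal intervals
        assert canonicalize_intervals([(5, 9), (1, 3), (8, 12), (4, 4)]) == [(1, 12)]
        assert canonicalize_intervals([(6, 9), (1, 3)]) == [(1, 3), (6, 9)]


class TestConfusionCounts:
    @pytest.mark.parametrize(
        "protein,predictor",
        [(p, m) for p, ex in WORKED_EXAMPLES.items() for m in ex["predictions"]],
    )
    def test_worked_examples(self, protein, predictor):
        ex = WORKED_EXAMPLES[protein]
        truth = intervals_to_labels(ex["actual"], ex["L"])
        pred_intervals, expected = ex["predictions"][predictor]
        pred = intervals_to_labels(pred_intervals, ex["L"])
        c = confusion_counts(truth, pred)
        assert (c.tp, c.fp, c.tn, c.fn) == expected

    def test_identity_has_no_errors(self):
        c = confusion_counts("ODDO", "ODDO")
        assert c.fp == c.fn == 0 and c.tp == 2 and c.tn == 2

    def test_counts_partition_residues(self):
        c = confusion_counts("ODDOO", "DDOOO")
        assert c.total == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(AnnotationError):
            confusion_counts("OD", "ODD")


class TestMetrics:
    def test_published_balanced_accuracy(self):
        # cross-validated Sn/Sp of the CRF predictor reproduce the printed ACC
        sn, sp = 0.637, 0.910
        assert (sn + sp) / 2 == pytest.approx(0.774, abs=5e-4)

    def test_perfect_prediction(self):
        m = metrics(ConfusionCounts(10, 0, 20, 0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_worked_example_mcc(self):
        # independent arithmetic on the published counts (32, 0, 309, 27)
        tp, fp, tn, fn = 32, 0, 309, 27
        expected = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        m = metrics(ConfusionCounts(tp, fp, tn, fn))
        assert m.mcc == pytest.approx(expected)
        assert m.mcc == pytest.approx(0.70625, abs=5e-5)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import balanced_accuracy_score, matthews_corrcoef

        rng = np.random.default_rng(9)
        truth = rng.choice([0, 1], size=500, p=[0.8, 0.2])
        pred = np.where(rng.random(500) < 0.3, 1 - truth, truth)
        c = confusion_counts(
            "".join("OD"[t] for t in truth), "".join("OD"[p] for p in pred)
        )
        m = metrics(c)
        assert m.mcc == pytest.approx(matthews_corrcoef(truth, pred))
        assert m.acc == pytest.approx(balanced_accuracy_score(truth, pred))

    def test_mcc_zero_denominator_convention(self):
        with pytest.warns(UserWarning):
            m = metrics(ConfusionCounts(0, 0, 5, 5))
        assert m.mcc == 0.0

    def test_undefined_sensitivity_warns(self):
        with pytest.warns(UserWarning):
            m = metrics(ConfusionCounts(0, 2, 3, 0))
        assert math.isnan(m.sn)

    def test_mcc_class_swap_symmetry(self):
        c = ConfusionCounts(17, 5, 120, 9)
        swapped = ConfusionCounts(c.tn, c.fn, c.tp, c.fp)
        assert metrics(c).mcc == pytest.approx(metrics(swapped).mcc)


class TestBenchmarkFilters:
    def _rec(self, pid, res, L, idrs):
        return ProteinRecord(pid, "A" * L, idrs, resolution=res)

    def test_boundary_values_kept(self):
        rec = self._rec("x", 2.0, 30, [(1, 5)])
        assert apply_benchmark_filters([rec]) == [rec]

    def test_no_idr_dropped(self):
        log = []
        assert apply_benchmark_filters([self._rec("x", 1.5, 50, [])], log=log) == []
        assert "disordered" in log[0]

    def test_hand_filtered_table(self):
        records = [
            self._rec("a", 1.8, 100, [(1, 10)]),   # keep
            self._rec("b", 2.5, 100, [(1, 10)]),   # resolution too low
            self._rec("c", 1.9, 20, [(1, 5)]),     # too short
            self._rec("d", 2.0, 40, []),           # no disordered region
            self._rec("e", 1.0, 30, [(30, 30)]),   # keep
        ]
        kept = apply_benchmark_filters(records)
        assert [r.id for r in kept] == ["a", "e"]

    def test_missing_resolution_excluded_with_reason(self):
        log = []
        rec = ProteinRecord("x", "A" * 50, [(1, 5)], resolution=None)
        assert apply_benchmark_filters([rec], log=log) == []
        assert "missing resolution" in log[0]


def _toy_dataset(rng, n=6, L=40, disorder_fraction=0.1):
    out = []
    for j in range(n):
        n_d = max(1, int(L * disorder_fraction))
        start = int(rng.integers(1, L - n_d))
        labels = intervals_to_labels([(start, start + n_d - 1)], L)
        X = rng.normal(size=(L, 2))
        out.append(LabeledSequence(ObservationSequence(f"p{j}", X), labels))
    return out


class TestSubsampling:
    def test_reaches_target_ratio(self, rng):
        data = _toy_dataset(rng, n=8, L=60, disorder_fraction=0.08)
        out = subsample_ordered_residues(data, 2.0, seed=1)
        n_d = sum(s.labels.count("D") for s in out)
        n_o = sum(s.labels.count("O") for s in out)
        assert n_d == sum(s.labels.count("D") for s in data)  # no D removed
        assert abs(n_o - 2 * n_d) <= 1

    def test_already_balanced_is_noop(self, rng):
        data = _toy_dataset(rng, n=4, L=30, disorder_fraction=0.4)
        with pytest.warns(UserWarning):
            out = subsample_ordered_residues(data, 10.0, seed=0)
        assert [s.labels for s in out] == [s.labels for s in data]

    def test_label_multiset_conserved(self, rng):
        data = _toy_dataset(rng, n=5, L=50, disorder_fraction=0.1)
        out = subsample_ordered_residues(data, 3.0, seed=2)
        n_d_in = sum(s.labels.count("D") for s in data)
        n_o_in = sum(s.labels.count("O") for s in data)
        n_d_out = sum(s.labels.count("D") for s in out)
        n_o_out = sum(s.labels.count("O") for s in out)
        assert n_d_out == n_d_in
        assert n_o_out == n_o_in - int(round(n_o_in - 3.0 * n_d_in))

    def test_splitting_preserves_feature_rows(self, rng):
        data = _toy_dataset(rng, n=3, L=30, disorder_fraction=0.2)
        out = subsample_ordered_residues(data, 1.0, seed=3)
        for part in out:
            root = part.observation.sequence_id.split("/")[0]
            src = next(s for s in data if s.observation.sequence_id == root)
            # every output row must be a contiguous slice of its source
            X, P = src.observation.features, part.observation.features
            found = any(
                np.array_equal(X[i : i + P.shape[0]], P)
                for i in range(X.shape[0] - P.shape[0] + 1)
            )
            assert found

    def test_deterministic_given_seed(self, rng):
        data = _toy_dataset(rng, n=5, L=50, disorder_fraction=0.1)
        a = subsample_ordered_residues(data, 2.0, seed=7)
        b = subsample_ordered_residues(data, 2.0, seed=7)
        assert [s.labels for s in a] == [s.labels for s in b]


class TestKFold:
    def test_even_fold_sizes(self):
        folds = kfold_split([f"p{i}" for i in range(10)], k=5, seed=0)
        sizes = [len(folds.fold_ids(f)) for f in range(5)]
        assert sizes == [2, 2, 2, 2, 2]

    def test_partition_property(self):
        ids = [f"p{i}" for i in range(13)]
        folds = kfold_split(ids, k=5, seed=3)
        assert sorted(folds.assignment) == sorted(ids)
        sizes = sorted(len(folds.fold_ids(f)) for f in range(5))
        assert max(sizes) - min(sizes) <= 1

    def test_reproducible(self):
        ids = [f"p{i}" for i in range(9)]
        assert kfold_split(ids, seed=4).assignment == kfold_split(ids, seed=4).assignment

    def test_invalid_k(self):
        with pytest.raises(AnnotationError):
            kfold_split(["a", "b", "c"], k=1)
        with pytest.raises(AnnotationError):
            kfold_split(["a", "b"], k=3)


class _ThresholdTrainer:
    """Minimal conforming train/predict pair: mean-difference thresholding."""

    def train(self, data):
        X = np.vstack([s.observation.features for s in data])
        y = np.array([c == "D" for s in data for c in s.labels])
        if y.all() or not y.any():
            return np.zeros(X.shape[1]), 0.0
        w = X[y].mean(axis=0) - X[~y].mean(axis=0)
        thr = (X[y] @ w).mean() / 2 + (X[~y] @ w).mean() / 2
        return w, thr

    def predict(self, model, obs):
        w, thr = model
        return "".join("D" if s > thr else "O" for s in obs.features @ w)


class TestRatioCurveExperiment:
    def _data(self, rng):
        from disocrf.simulate import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(
            n_proteins=10, min_length=30, max_length=60,
            stay_o=0.98, stay_d=0.9, delta=2.0, seed=21,
        )
        return generate_dataset(cfg)[0]

    def test_single_ratio_single_row(self, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = ratio_curve_experiment(self._data(rng), [2.0], _ThresholdTrainer(), seed=0)
        assert list(tab.columns) == ["ratio", "Sn", "Sp", "ACC", "MCC"]
        assert len(tab) == 1
        assert np.isfinite(tab[["Sn", "Sp", "ACC", "MCC"]].to_numpy()).all()

    def test_reproducible_under_fixed_seed(self, rng):
        data = self._data(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ratio_curve_experiment(data, [2.0, 5.0], _ThresholdTrainer(), seed=4)
            b = ratio_curve_experiment(data, [2.0, 5.0], _ThresholdTrainer(), seed=4)
        assert a.equals(b)


class TestIntervalIO:
    def test_round_trip(self, tmp_path):
        table = {"p1": [(1, 5), (10, 12)], "p2": [(3, 3)]}
        path = tmp_path / "iv.tsv"
        write_interval_table(table, path)
        assert read_interval_table(path) == table

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "iv.tsv"
        path.write_text("p1\t3\n")
        with pytest.raises(AnnotationError):
            read_interval_table(path)
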