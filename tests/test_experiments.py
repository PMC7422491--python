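"""Splits, one-vs-rest metrics, and the three evaluation protocols."""

import numpy as np
import pandas as pd
import pytest

from eegemotion import (
    DatasetDesign,
    ExperimentConfig,
    InputError,
    SplitSpec,
    build_feature_matrix,
    channel_wise_experiment,
    emotion_wise_experiment,
    generate_dataset,
    metrics_from_confusion,
    split,
    subband_wise_experiment,
    well_separated_signatures,
)


def _matrix(n_per_class=30, classes=("a", "b", "c", "d"), seed=0):
    r = np.random.default_rng(seed)
    rows = []
    for c in classes:
        for _ in range(n_per_class):
            rows.append({"emotion": c, **{f"f{i}": r.normal() for i in range(1, 11)}})
    return pd.DataFrame(rows)


class TestSplit:
    def test_70_30_arithmetic(self):
        m = _matrix(n_per_class=25)  # 100 rows
        train, test = split(m, SplitSpec(0.7, True, 0))
        assert len(train) == 70 and len(test) == 30

    def test_stratification_preserves_class_proportions(self):
        m = _matrix(n_per_class=30)
        train, test = split(m, SplitSpec(0.7, True, 1))
        assert (train["emotion"].value_counts() == 21).all()
        assert (test["emotion"].value_counts() == 9).all()

    def test_disjoint_and_exhaustive(self):
        m = _matrix(n_per_class=10)
        train, test = split(m, SplitSpec(0.7, True, 2))
        assert len(set(train.index) & set(test.index)) == 0
        assert len(train) + len(test) == len(m)

    def test_same_seed_same_split(self):
        m = _matrix()
        t1, _ = split(m, SplitSpec(0.7, True, 5))
        t2, _ = split(m, SplitSpec(0.7, True, 5))
        assert list(t1.index) == list(t2.index)

    def test_singleton_class_rejected_when_stratified(self):
        m = pd.concat([_matrix(n_per_class=5, classes=("a", "b")),
                       _matrix(n_per_class=1, classes=("c",))])
        with pytest.raises(InputError, match="offending"):
            split(m, SplitSpec(0.7, True, 0))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InputError):
            SplitSpec(train_fraction=1.0)


class TestMetrics:
    def test_perfect_diagonal_gives_unit_metrics(self):
        rep = metrics_from_confusion(np.diag([5, 7, 9]), classes=list("xyz"))
        assert rep.accuracy == 1.0
        assert (rep.per_class.loc["sensitivity"] == 1.0).all()
        assert (rep.per_class.loc["specificity"] == 1.0).all()
        assert rep.macro["f1"] == 1.0

    def test_two_class_hand_example(self):
        rep = metrics_from_confusion(np.array([[8, 2], [1, 9]]), classes=["p", "n"])
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.per_class.loc["sensitivity", "p"] == pytest.approx(0.8)
        assert rep.per_class.loc["precision", "p"] == pytest.approx(8 / 9)
        assert rep.per_class.loc["specificity", "p"] == pytest.approx(0.9)

    def test_empty_predicted_class_zero_precision_with_warning(self):
        rep = metrics_from_confusion(np.array([[0, 5], [0, 5]]), classes=["p", "n"])
        assert rep.per_class.loc["precision", "p"] == 0.0
        assert any("precision" in w and "p" in w for w in rep.warnings)

    def test_non_square_rejected(self):
        with pytest.raises(InputError):
            metrics_from_confusion(np.ones((2, 3)))

    def test_micro_sensitivity_equals_accuracy(self, rng):
        for _ in range(20):
            cm = rng.integers(0, 30, size=(4, 4))
            if cm.sum() == 0:
                continue
            rep = metrics_from_confusion(cm)
            assert rep.micro["sensitivity"] == pytest.approx(rep.accuracy)
            assert rep.accuracy == pytest.approx(np.trace(cm) / cm.sum())


@pytest.fixture(scope="module")
def planted_features():
    """Small dataset with separable signatures planted on FP1-F7 only."""
    design = DatasetDesign(
        n_subjects=3, videos_per_emotion=2, segments_per_video=3,
        channels=("FP2-F4", "FP1-F7"),
    )
    sigs = well_separated_signatures(design, channel="FP1-F7")
    ds = generate_dataset(design, sigs, seed=13)
    return design, build_feature_matrix(ds)


class TestProtocols:
    def test_channel_wise_shapes_and_planted_channel_wins(self, planted_features):
        design, feats = planted_features
        reports, best = channel_wise_experiment(feats, ExperimentConfig(seed=5))
        assert set(reports) == set(design.channels)
        assert best == "FP1-F7"
        assert reports["FP1-F7"].accuracy > reports["FP2-F4"].accuracy
        for rep in reports.values():
            assert rep.confusion.sum() == rep.n_test

    def test_subband_wise_grid_shape_and_gamma_wins_on_planted_channel(self, planted_features):
        design, feats = planted_features
        grid, best = subband_wise_experiment(feats, ExperimentConfig(seed=5))
        assert grid.shape == (2, 5)
        assert list(grid.columns) == ["delta", "theta", "alpha", "beta", "gamma"]
        assert best[0] == "FP1-F7"

    def test_emotion_wise_report_block_shape(self, planted_features):
        design, feats = planted_features
        rep = emotion_wise_experiment(feats, "FP1-F7", "gamma", ExperimentConfig(seed=5))
        assert rep.per_class.shape == (5, 4)
        assert list(rep.per_class.index) == [
            "accuracy", "specificity", "sensitivity", "precision", "f1",
        ]
        assert rep.micro["sensitivity"] == pytest.approx(rep.accuracy)

    def test_unknown_channel_or_band_rejected(self, planted_features):
        _, feats = planted_features
        with pytest.raises(InputError):
            emotion_wise_experiment(feats, "Cz", "gamma", ExperimentConfig())
        with pytest.raises(InputError):
            emotion_wise_experiment(feats, "FP1-F7", "mu", ExperimentConfig())

    def test_accuracy_not_decreasing_with_separation(self):
        """Wider emotion separation never hurts the planted channel.

        Run at a scale where the trend dominates split/classifier noise
        (the generator's aligned noise streams mean only the signature
        weights change between separation levels), with the hidden-layer
        size below the training-row count so the network does not
        interpolate.
        """
        design = DatasetDesign(
            n_subjects=6, videos_per_emotion=3, segments_per_video=3,
            channels=("FP1-F7",),
        )
        accs = []
        for sep in (0.5, 0.75, 1.0):
            sigs = well_separated_signatures(design, channel="FP1-F7", separation=sep)
            ds = generate_dataset(design, sigs, seed=21)
            feats = build_feature_matrix(ds)
            reports, _ = channel_wise_experiment(
                feats, ExperimentConfig(seed=3, hidden_count=200)
            )
            accs.append(reports["FP1-F7"].accuracy)
        assert accs[0] <= accs[1] <= accs[2]
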