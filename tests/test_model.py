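"""Stacked model: peptide statistics, fold assignment, training contracts,
prediction behaviour, cross-validation shape, and archive round-trips."""

import gzip
import io
import json
import tarfile

import numpy as np
import pytest

from acpstack import (
    CLASSES,
    ModelConfig,
    ModelFormatError,
    Peptide,
    TrainingError,
    ValidationError,
    assign_cv_folds,
    compute_peptide_statistics,
    cross_validate,
    cv_summary,
    load_model,
    predict,
    predictions_to_frame,
    save_model,
    train,
)
from acpstack.model import STAT_SCHEMA, _decision, _longest_run


class TestPeptideStatistics:
    def test_constant_one_hot_sequence(self):
        P = np.tile([1.0, 0.0, 0.0], (3, 1))
        stats = dict(zip(STAT_SCHEMA, compute_peptide_statistics(P)))
        for s in ("mean", "median", "min", "max", "frac_gt_half", "longest_run_frac"):
            assert stats[f"ACP_{s}"] == 1.0
        assert stats["ACP_var"] == 0.0
        assert stats["n_mers"] == 3.0

    def test_hand_computed_example(self):
        # ACP probabilities 0.9, 0.2, 0.8 across the three windows
        P = np.array([[0.9, 0.05, 0.05], [0.2, 0.4, 0.4], [0.8, 0.1, 0.1]])
        stats = dict(zip(STAT_SCHEMA, compute_peptide_statistics(P)))
        assert stats["ACP_frac_gt_half"] == pytest.approx(2 / 3)
        assert stats["ACP_longest_run_frac"] == pytest.approx(1 / 3)
        assert stats["ACP_mean"] == pytest.approx(0.6333, abs=1e-4)
        assert stats["ACP_median"] == pytest.approx(0.8)
        assert stats["ACP_min"] == pytest.approx(0.2)
        assert stats["ACP_max"] == pytest.approx(0.9)

    def test_single_mer_fraction_and_run_coincide(self):
        for p_acp in (0.9, 0.1):
            row = np.array([[p_acp, (1 - p_acp) / 2, (1 - p_acp) / 2]])
            stats = dict(zip(STAT_SCHEMA, compute_peptide_statistics(row)))
            assert stats["ACP_frac_gt_half"] == stats["ACP_longest_run_frac"]
            assert stats["ACP_frac_gt_half"] in (0.0, 1.0)

    def test_schema_has_22_entries(self):
        assert len(STAT_SCHEMA) == 22
        P = np.full((4, 3), 1 / 3)
        assert compute_peptide_statistics(P).shape == (22,)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            compute_peptide_statistics(np.empty((0, 3)))

    def test_longest_run(self):
        assert _longest_run(np.array([True, True, False, True])) == 2
        assert _longest_run(np.array([False, False])) == 0


class TestDecisionRule:
    def test_argmax(self):
        assert _decision(np.array([0.7, 0.2, 0.1])) == "ACP"

    def test_ties_break_conservatively(self):
        # exact ties resolve toward NEG, then AMP, never promoting to ACP
        assert _decision(np.array([0.5, 0.0, 0.5])) == "NEG"
        assert _decision(np.array([0.5, 0.5, 0.0])) == "AMP"
        assert _decision(np.array([1 / 3, 1 / 3, 1 / 3])) == "NEG"


class TestFoldAssignment:
    def _single_class(self, lengths):
        return [Peptide(f"p{i}", "A" * L, "ACP") for i, L in enumerate(lengths)]

    def test_balanced_sizes(self):
        peps = self._single_class([10] * 10)
        folds = assign_cv_folds(peps, folds=5, seed=0)
        assert sorted(np.bincount(folds).tolist()) == [2] * 5

    def test_sizes_differ_by_at_most_one_per_class(self):
        peps = self._single_class(range(5, 28))  # 23 peptides
        folds = assign_cv_folds(peps, folds=5, seed=1)
        counts = np.bincount(folds, minlength=5)
        assert counts.max() - counts.min() <= 1

    def test_length_stratification(self):
        peps = self._single_class(range(5, 55))  # lengths 5..54
        folds = assign_cv_folds(peps, folds=5, seed=2)
        lengths = np.array([len(p) for p in peps])
        global_mean = lengths.mean()
        for f in range(5):
            assert abs(lengths[folds == f].mean() - global_mean) <= 3

    def test_deterministic_under_seed(self):
        peps = self._single_class([7] * 20)
        a = assign_cv_folds(peps, folds=4, seed=9)
        b = assign_cv_folds(peps, folds=4, seed=9)
        assert (a == b).all()

    def test_class_smaller_than_folds_rejected(self):
        with pytest.raises(ValidationError):
            assign_cv_folds(self._single_class([8, 8, 8]), folds=5)


class TestTrainingContracts:
    def test_missing_class_rejected(self, tiny_dataset, tiny_config):
        no_neg = [p for p in tiny_dataset if p.label != "NEG"]
        with pytest.raises(TrainingError, match="NEG"):
            train(no_neg, tiny_config)

    def test_short_training_peptide_rejected(self, tiny_dataset, tiny_config):
        bad = list(tiny_dataset) + [Peptide("tiny", "KLAK", "ACP")]
        with pytest.raises(ValidationError, match="tiny"):
            train(bad, tiny_config)

    def test_metadata_records_training_facts(self, tiny_model, tiny_dataset):
        md = tiny_model.metadata
        assert md["class_counts"] == {c: 30 for c in CLASSES}
        assert md["n_mers"] == sum(len(p) - 4 for p in tiny_dataset)
        assert md["n_selected"] == len(tiny_model.selected)
        assert 0 <= md["layer1_oob_accuracy"] <= 1

    def test_config_invariants(self):
        with pytest.raises(ValidationError):
            ModelConfig(trees_layer1=0)
        with pytest.raises(ValidationError):
            ModelConfig(alpha=0.0)
        with pytest.raises(ValidationError):
            ModelConfig(mtry=0)


class TestPredict:
    def test_probability_rows_on_simplex(self, tiny_model, tiny_dataset):
        preds = predict(tiny_model, tiny_dataset[:20])
        for p in preds:
            assert p.probabilities.shape == (3,)
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert (p.probabilities >= 0).all()
            assert p.decision in CLASSES

    def test_prediction_is_repeatable(self, tiny_model, tiny_dataset):
        a = predict(tiny_model, tiny_dataset[:10])
        b = predict(tiny_model, tiny_dataset[:10])
        for x, y in zip(a, b):
            assert np.array_equal(x.probabilities, y.probabilities)
            assert x.decision == y.decision

    def test_short_record_yields_error_entry_not_crash(self, tiny_model):
        peps = [Peptide("ok", "KLAKLAKK"), Peptide("short", "KLAK")]
        preds = predict(tiny_model, peps)
        assert len(preds) == 2
        by_id = {p.id: p for p in preds}
        assert by_id["ok"].error is None
        assert by_id["short"].probabilities is None
        assert "short" in by_id["short"].error

    def test_overlong_peptide_flagged_not_blocked(self, tiny_model):
        pep = Peptide("long", "KLAK" * 15)  # 60 residues
        (pred,) = predict(tiny_model, [pep])
        assert pred.error is None
        assert any("trained range" in w for w in pred.warnings)

    def test_per_mer_report_aligns_with_windows(self, tiny_model):
        pep = Peptide("x", "KLAKLAKK")
        preds, mer_preds = predict(tiny_model, [pep], per_mer=True)
        assert len(mer_preds) == len(pep) - 4
        for mp in mer_preds:
            assert mp.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_prediction_frame_columns(self, tiny_model, tiny_dataset):
        frame = predictions_to_frame(predict(tiny_model, tiny_dataset[:5]))
        assert list(frame.columns) == [
            "id", "prob_ACP", "prob_AMP", "prob_NEG", "decision", "warnings", "error",
        ]


class TestCrossValidation:
    def test_shape_and_ranges(self, tiny_dataset):
        cfg = ModelConfig(trees_layer1=30, trees_layer2=20, seed=17)
        table = cross_validate(tiny_dataset, cfg, folds=3)
        assert len(table) == 3 * 2  # folds x layers
        assert set(table["layer"]) == {"mer", "peptide"}
        assert set(table.columns) == {"fold", "layer", "accuracy", "au1u", "kaps"}
        assert table[["accuracy", "au1u"]].to_numpy().min() >= 0.0
        assert table[["accuracy", "au1u"]].to_numpy().max() <= 1.0
        summary = cv_summary(table)
        assert len(summary) == 2 * 3
        assert {"mean", "sd", "se"} <= set(summary.columns)

    def test_single_class_input_rejected(self):
        peps = [Peptide(f"p{i}", "KLAKLAKK", "ACP") for i in range(20)]
        with pytest.raises(TrainingError):
            cross_validate(peps, ModelConfig(trees_layer1=10, trees_layer2=10), folds=2)


class TestArchive:
    def test_roundtrip_preserves_predictions(self, tiny_model, tiny_dataset, tmp_path):
        path = tmp_path / "model.tar.gz"
        save_model(tiny_model, path)
        loaded = load_model(path)
        a = predict(tiny_model, tiny_dataset[:30])
        b = predict(loaded, tiny_dataset[:30])
        for x, y in zip(a, b):
            assert np.array_equal(x.probabilities, y.probabilities)
            assert x.decision == y.decision

    def test_manifest_lists_selected_descriptors(self, tiny_model, tmp_path):
        path = tmp_path / "model.tar.gz"
        save_model(tiny_model, path)
        with tarfile.open(path) as tar:
            manifest = json.load(tar.extractfile("manifest.json"))
        assert manifest["selected_descriptors"] == [d.text for d in tiny_model.selected]
        assert manifest["schema_version"] == 1
        assert manifest["config"]["seed"] == tiny_model.config.seed

    def test_truncated_archive_raises_format_error(self, tiny_model, tmp_path):
        path = tmp_path / "model.tar.gz"
        save_model(tiny_model, path)
        blob = path.read_bytes()
        bad = tmp_path / "trunc.tar.gz"
        bad.write_bytes(blob[: len(blob) // 3])
        with pytest.raises(ModelFormatError):
            load_model(bad)

    def test_schema_version_mismatch_rejected(self, tiny_model, tmp_path):
        path = tmp_path / "model.tar.gz"
        save_model(tiny_model, path)
        # rewrite the archive with a bumped schema version
        with tarfile.open(path) as tar:
            members = {m.name: tar.extractfile(m).read() for m in tar.getmembers()}
        manifest = json.loads(members["manifest.json"])
        manifest["schema_version"] = 999
        members["manifest.json"] = json.dumps(manifest).encode()
        bad = tmp_path / "future.tar.gz"
        with open(bad, "wb") as fh, gzip.GzipFile(filename="", fileobj=fh, mode="wb") as gz, \
                tarfile.open(fileobj=gz, mode="w") as tar:
            for name, data in members.items():
                info = tarfile.TarInfo(name)
                info.size = len(data)
                tar.addfile(info, io.BytesIO(data))
        with pytest.raises(ModelFormatError, match="schema version"):
            load_model(bad)
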