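"""EMA updates, single training steps, and the fit loop at desk scale."""

import numpy as np
import pytest

from shootcount import nn
from shootcount.annotations_io import select_labeled
from shootcount.network import ShootCountNet
from shootcount.synthetic_data import SceneSpec, generate_dataset
from shootcount.trainer import (ManifestDataset, MeanTeacherTrainer, TrainConfig,
                                _labeled_batch, _unlabeled_batch, ema_update,
                                evaluate_checkpoint, load_checkpoint, train_step)

THIN = dict(width_mult=0.125, stage_depths=(1, 1, 2, 2, 2))


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    """12 synthetic 64x64 images: 8 train (2 labeled), 2 val, 2 test."""
    root = tmp_path_factory.mktemp("tinyds")
    spec = SceneSpec(image_height=64, image_width=64, count_range=(8, 20),
                     blob_sigma_range=(1.0, 2.0))
    manifest = generate_dataset(12, spec, root, seed=0, ratios=(0.7, 0.2, 0.1))
    manifest = select_labeled(manifest, 0.25, seed=0)  # floor(0.25 * 8) = 2 labeled
    return manifest, root


class TestEMA:
    def test_static_student_is_a_fixed_point(self):
        t = {"w": np.array([1.0, 2.0])}
        s = {"w": np.array([1.0, 2.0])}
        for _ in range(5):
            ema_update(t, s, alpha=0.9)
        np.testing.assert_allclose(t["w"], [1.0, 2.0])

    def test_alpha_zero_copies_student(self):
        t = {"w": np.zeros(3)}
        s = {"w": np.arange(3.0)}
        ema_update(t, s, alpha=0.0)
        np.testing.assert_allclose(t["w"], s["w"])

    @pytest.mark.parametrize("n", [1, 5, 20])
    def test_scalar_geometric_closed_form(self, n):
        """teacher_0 = 0, student = 1, alpha = 0.9: teacher_n = 1 - 0.9^n."""
        t = {"w": np.array([0.0])}
        s = {"w": np.array([1.0])}
        for _ in range(n):
            ema_update(t, s, alpha=0.9)
        np.testing.assert_allclose(t["w"], [1.0 - 0.9 ** n], atol=1e-12)

    def test_structure_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ema_update({"a": np.zeros(2)}, {"b": np.zeros(2)}, alpha=0.5)

    def test_module_form_matches_dict_form(self, rng):
        cfg = TrainConfig.reduced()
        student = ShootCountNet(cfg.network_config())
        teacher = ShootCountNet(cfg.network_config())
        expected = teacher.state_dict()
        ema_update(expected, student.state_dict(), alpha=0.7)
        ema_update(teacher, student, alpha=0.7)
        for name, value in teacher.state_dict().items():
            np.testing.assert_allclose(value, expected[name])


def _build(config, manifest, root):
    trainer = MeanTeacherTrainer(config)
    data = ManifestDataset(manifest, root, config)
    return trainer, data


class TestTrainStep:
    def _step(self, trainer, data, config, seed=0):
        drng = np.random.default_rng(seed)
        mrng = np.random.default_rng(seed + 1)
        edges = data.bin_edges()
        labeled = _labeled_batch(data.labeled_train, drng, config, edges)
        unlabeled = (_unlabeled_batch(data.unlabeled_train, drng, config)
                     if config.semi_supervised else None)
        return train_step(trainer.student, trainer.teacher, labeled, unlabeled,
                          config, trainer.optimizer, mrng)

    def test_deterministic_under_fixed_seeds(self, tiny_dataset):
        manifest, root = tiny_dataset
        config = TrainConfig.reduced(batch_size=2, **THIN)
        results = []
        for _ in range(2):
            trainer, data = _build(config, manifest, root)
            results.append(self._step(trainer, data, config))
        assert results[0].total == results[1].total
        assert results[0].l_rl == results[1].l_rl

    def test_supervised_regime_has_zero_unsupervised_loss(self, tiny_dataset):
        manifest, root = tiny_dataset
        config = TrainConfig.reduced(batch_size=2, semi_supervised=False,
                                     eval_model="student", **THIN)
        trainer, data = _build(config, manifest, root)
        bd = self._step(trainer, data, config)
        assert bd.l_ru == 0.0 and bd.l_cu == 0.0 and bd.l_l > 0

    def test_zero_masking_ratio_is_reported_as_misconfiguration(self, tiny_dataset):
        manifest, root = tiny_dataset
        config = TrainConfig.reduced(batch_size=2, masking_ratio=0.0, **THIN)
        trainer, data = _build(config, manifest, root)
        with pytest.raises(ValueError, match="masking_ratio"):
            self._step(trainer, data, config)

    def test_teacher_parameters_never_accumulate_gradients(self, tiny_dataset):
        manifest, root = tiny_dataset
        config = TrainConfig.reduced(batch_size=2, **THIN)
        trainer, data = _build(config, manifest, root)
        self._step(trainer, data, config)
        for name, p in trainer.teacher.named_parameters():
            assert p.grad is None, f"teacher parameter {name} has a gradient"

    def test_unsupervised_loss_breakdown_invariants(self, tiny_dataset):
        manifest, root = tiny_dataset
        config = TrainConfig.reduced(batch_size=2, **THIN)
        trainer, data = _build(config, manifest, root)
        bd = self._step(trainer, data, config)
        assert bd.l_l == pytest.approx(bd.l_rl + bd.l_cl)
        assert bd.l_u == pytest.approx(bd.l_ru + bd.l_cu)
        assert bd.total == pytest.approx(bd.l_l + bd.l_u)
        assert all(np.isfinite(v) and v >= 0
                   for v in (bd.l_rl, bd.l_cl, bd.l_ru, bd.l_cu))


class TestFit:
    def test_loss_decreases_when_overfitting_one_image(self, tiny_dataset):
        """20 supervised steps on a single labeled image shrink the loss."""
        manifest, root = tiny_dataset
        config = TrainConfig.reduced(batch_size=1, semi_supervised=False,
                                     eval_model="student", flip_prob=0.0,
                                     brightness_jitter=0.0, **THIN)
        trainer, data = _build(config, manifest, root)
        data.labeled_train = data.labeled_train[:1]
        edges = data.bin_edges()
        drng = np.random.default_rng(0)
        losses = []
        for _ in range(20):
            labeled = _labeled_batch(data.labeled_train, drng, config, edges)
            bd = train_step(trainer.student, trainer.teacher, labeled, None,
                            config, trainer.optimizer, np.random.default_rng(0))
            losses.append(bd.total)
        assert losses[-1] < 0.5 * losses[0]

    def test_fit_writes_log_and_checkpoint_and_reloads(self, tiny_dataset, tmp_path):
        manifest, root = tiny_dataset
        config = TrainConfig.reduced(batch_size=2, epochs=2, **THIN)
        trainer = MeanTeacherTrainer(config)
        result = trainer.fit(manifest, root, out_dir=tmp_path, steps_per_epoch=2)
        assert (tmp_path / "log.csv").exists()
        assert result.checkpoint_path is not None and result.checkpoint_path.exists()
        assert set(result.log.columns) >= {"epoch", "l_rl", "l_cl", "l_ru", "l_cu",
                                           "val_mae", "val_rmse"}
        # checkpoint reload reproduces the recorded best validation MAE
        val = evaluate_checkpoint(result.checkpoint_path, manifest, root, split="val")
        assert val.mae == pytest.approx(result.best_val_mae, abs=1e-6)

    def test_checkpoint_round_trip_preserves_config(self, tiny_dataset, tmp_path):
        manifest, root = tiny_dataset
        config = TrainConfig.reduced(batch_size=2, epochs=1, **THIN)
        result = MeanTeacherTrainer(config).fit(manifest, root, out_dir=tmp_path,
                                                steps_per_epoch=1)
        _, loaded_cfg, edges = load_checkpoint(result.checkpoint_path)
        assert loaded_cfg.width_mult == config.width_mult
        assert len(edges) == config.n_classes

    def test_empty_labeled_set_rejected(self, tiny_dataset):
        manifest, root = tiny_dataset
        from dataclasses import replace
        from shootcount.annotations_io import DatasetManifest
        stripped = DatasetManifest(
            entries=[replace(e, labeled=False) if e.split == "train" else e
                     for e in manifest.entries])
        config = TrainConfig.reduced(**THIN)
        with pytest.raises(ValueError, match="labeled"):
            MeanTeacherTrainer(config).fit(stripped, root)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        config = TrainConfig.reduced(masking_ratio=0.3, labeled_percentage=0.2)
        path = tmp_path / "c.yaml"
        config.to_yaml(path)
        assert TrainConfig.from_yaml(path) == config

    def test_invalid_labeled_percentage_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(labeled_percentage=0.0)

    def test_full_profile_reference_settings(self):
        config = TrainConfig.full()
        assert (config.crop_size, config.batch_size, config.epochs) == (256, 16, 500)
        assert (config.masked_patch_size, config.masking_ratio) == (16, 0.1)
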