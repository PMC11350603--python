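"""Mean-teacher training loop.

One step: the student does a gradient update on L = L_L + L_U, where the
labeled branch sees augmented labeled crops with ground-truth density maps
and density-class labels, and the unlabeled branch compares the student's
prediction on a *masked* unlabeled crop against the EMA teacher's prediction
on the same crop unmasked (teacher detached).  After every student step the
teacher parameters are updated as

    theta_t <- alpha_t * theta_t + (1 - alpha_t) * theta_s,
    alpha_t = alpha * min(1, step / ramp_iters)

(the usual mean-teacher ramp, so the teacher tracks the student closely at
the start).  Validation runs each epoch on the EMA teacher by default; the
best-validation checkpoint and a per-epoch CSV log are written to the output
directory.

Two built-in profiles: ``TrainConfig.full()`` mirrors the method's reference
settings (256 crops, batch 16, 500 epochs, full-width backbone, Adam 1e-5);
``TrainConfig.reduced()`` is a thin desk-scale profile (64 px images, width
multiplier 1/8, shallow stages, Adam 1e-3) that exercises the identical code
path on a CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .annotations_io import DatasetManifest, read_points
from .augmentation_masking import MaskSpec, apply_mask, random_patch_mask
from .autograd import Tensor
from .density_maps import (DensityMap, density_class_label, downsample_sum_preserving,
                           geometric_adaptive_density, quantile_bin_edges)
from .evaluation import compute_metrics, count_from_density
from .losses import (LossBreakdown, SSIMParams, classification_cross_entropy,
                     labeled_regression_loss, total_loss, unsupervised_losses)
from .network import ModelOutput, NetworkConfig, ShootCountNet, images_to_tensor
from . import nn

__all__ = ["TrainConfig", "TrainingResult", "ema_update", "train_step",
           "MeanTeacherTrainer", "fit", "evaluate_checkpoint"]

HEAD_SCALE = 8


@dataclass(frozen=True)
class TrainConfig:
    # data / augmentation
    crop_size: int = 256
    batch_size: int = 16
    epochs: int = 500
    brightness_jitter: float = 0.2
    flip_prob: float = 0.5
    # masking
    masked_patch_size: int = 16
    masking_ratio: float = 0.1
    mask_fill: float = 0.5
    # semi-supervision
    labeled_percentage: float = 1.0
    semi_supervised: bool = True
    ema_alpha: float = 0.99
    ema_ramp_iters: int = 500
    eval_model: str = "teacher"        # teacher | student
    # optimiser
    lr: float = 1e-5
    weight_decay: float = 1e-4
    # density / loss constants
    epsilon: float = 1e-3
    lambda1: float = 0.01
    ssim_z1: float = 0.01
    ssim_z2: float = 0.03
    ssim_levels: int = 3
    smooth_l1_beta: float = 1.0
    density_k: int = 3
    density_beta: float = 0.3
    n_classes: int = 5
    # architecture
    width_mult: float = 1.0
    stage_depths: tuple = (2, 2, 4, 4, 4)
    # seeds
    data_seed: int = 0
    mask_seed: int = 0
    init_seed: int = 0
    # profile flag
    reduced_scale: bool = False

    def __post_init__(self):
        if not 0 < self.labeled_percentage <= 1:
            raise ValueError("labeled_percentage must lie in (0, 1]")
        if not 0 <= self.ema_alpha < 1:
            raise ValueError("ema_alpha must lie in [0, 1)")
        for name in ("crop_size", "batch_size", "epochs", "masked_patch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eval_model not in ("teacher", "student"):
            raise ValueError("eval_model must be 'teacher' or 'student'")

    @classmethod
    def full(cls, **overrides) -> "TrainConfig":
        return cls(**overrides)

    @classmethod
    def reduced(cls, **overrides) -> "TrainConfig":
        base = dict(crop_size=64, batch_size=4, epochs=10, lr=1e-3,
                    ema_alpha=0.95, ema_ramp_iters=20, width_mult=0.125,
                    stage_depths=(1, 1, 2, 2, 2), reduced_scale=True)
        base.update(overrides)
        return cls(**base)

    def ssim_params(self) -> SSIMParams:
        return SSIMParams(z1=self.ssim_z1, z2=self.ssim_z2, k_levels=self.ssim_levels)

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(width_mult=self.width_mult, stage_depths=tuple(self.stage_depths),
                             n_classes=self.n_classes, init_seed=self.init_seed)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["stage_depths"] = list(self.stage_depths)
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "stage_depths" in payload:
            payload["stage_depths"] = tuple(payload["stage_depths"])
        return cls(**payload)


@dataclass
class TrainingResult:
    log: pd.DataFrame
    best_val_mae: float
    best_val_rmse: float
    best_epoch: int
    checkpoint_path: Path | None
    bin_edges: np.ndarray
    config: TrainConfig


def ema_update(teacher, student, alpha: float):
    """teacher <- alpha * teacher + (1 - alpha) * student, in place.

    Accepts two Modules or two {name: ndarray} state dicts with identical
    structure; the teacher never accumulates gradients.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    if isinstance(teacher, dict):
        if set(teacher) != set(student):
            raise ValueError("parameter structure mismatch")
        for name in teacher:
            if np.shape(teacher[name]) != np.shape(student[name]):
                raise ValueError(f"shape mismatch at {name}")
            teacher[name] = alpha * teacher[name] + (1 - alpha) * student[name]
        return teacher
    t_params = dict(teacher.named_parameters())
    s_params = dict(student.named_parameters())
    if set(t_params) != set(s_params):
        raise ValueError("parameter structure mismatch")
    for name, tp in t_params.items():
        sp = s_params[name]
        if tp.data.shape != sp.data.shape:
            raise ValueError(f"shape mismatch at {name}")
        tp.data[...] = alpha * tp.data + (1 - alpha) * sp.data
    return teacher


# ---------------------------------------------------------------------------
# in-memory dataset
# ---------------------------------------------------------------------------

@dataclass
class _Sample:
    image_id: str
    image: np.ndarray          # (H, W, 3) float on [0, 1]
    density: np.ndarray | None  # full-resolution gt density (labeled only)
    count: float | None


class ManifestDataset:
    """Loads every manifest entry into memory (the datasets this package
    targets are hundreds of modest images) and renders ground-truth density
    maps once with the geometric adaptive kernel."""

    def __init__(self, manifest: DatasetManifest, root, config: TrainConfig,
                 require_labeled: bool = True):
        self.root = Path(root)
        self.config = config
        self.labeled_train: list[_Sample] = []
        self.unlabeled_train: list[_Sample] = []
        self.val: list[_Sample] = []
        self.test: list[_Sample] = []
        for entry in manifest.entries:
            image = np.asarray(Image.open(self.root / entry.image_path),
                               dtype=np.float64) / 255.0
            density = count = None
            if entry.labeled and entry.annotation_path:
                points = read_points(self.root / entry.annotation_path)
                dm = geometric_adaptive_density(points, image.shape[0], image.shape[1],
                                                k=config.density_k, beta=config.density_beta)
                density, count = dm.values, float(points.count)
            sample = _Sample(image_id=entry.image_path, image=image,
                             density=density, count=count)
            if entry.split == "train":
                (self.labeled_train if entry.labeled else self.unlabeled_train).append(sample)
            elif entry.split == "val":
                self.val.append(sample)
            else:
                self.test.append(sample)
        if require_labeled and not self.labeled_train:
            raise ValueError("manifest has no labeled training images")

    def bin_edges(self) -> np.ndarray:
        counts = [s.count for s in self.labeled_train]
        return quantile_bin_edges(counts, n_classes=self.config.n_classes)


def _labeled_batch(samples, rng: np.random.Generator, config: TrainConfig, bin_edges):
    """Sample + augment a labeled batch; returns (images, density/8 targets,
    class indices).  Flip acts on image and density together; brightness only
    on pixels."""
    k = min(config.batch_size, len(samples))
    idx = rng.choice(len(samples), size=k, replace=len(samples) < k)
    images, targets, labels = [], [], []
    for i in idx:
        s = samples[int(i)]
        img, den = s.image, s.density
        if rng.random() < config.flip_prob:
            img, den = img[:, ::-1], den[:, ::-1]
        b = 1.0 + rng.uniform(-config.brightness_jitter, config.brightness_jitter)
        img = np.clip(img * b, 0.0, 1.0)
        images.append(img)
        targets.append(downsample_sum_preserving(DensityMap(den.copy()), HEAD_SCALE).values)
        labels.append(density_class_label(s.count, bin_edges).class_index)
    return np.stack(images), np.stack(targets)[:, None], np.asarray(labels)


def _unlabeled_batch(samples, rng: np.random.Generator, config: TrainConfig):
    k = min(config.batch_size, len(samples))
    idx = rng.choice(len(samples), size=k, replace=len(samples) < k)
    images = []
    for i in idx:
        s = samples[int(i)]
        img = s.image[:, ::-1] if rng.random() < config.flip_prob else s.image
        b = 1.0 + rng.uniform(-config.brightness_jitter, config.brightness_jitter)
        images.append(np.clip(img * b, 0.0, 1.0))
    return np.stack(images)


# ---------------------------------------------------------------------------
# one optimisation step
# ---------------------------------------------------------------------------

def train_step(student: ShootCountNet, teacher: ShootCountNet | None,
               labeled_batch, unlabeled_batch, config: TrainConfig,
               optimizer: nn.Adam, mask_rng: np.random.Generator,
               ema_alpha: float | None = None) -> LossBreakdown:
    """One student gradient step + one EMA teacher update.

    ``labeled_batch`` = (images NHWC, density targets N1hw, class indices);
    ``unlabeled_batch`` = images NHWC or None (supervised-only regime).
    """
    images, targets, labels = labeled_batch
    student_out = student(images_to_tensor(images))
    l_rl_t = labeled_regression_loss(student_out.density, Tensor(targets),
                                     epsilon=config.epsilon, lambda1=config.lambda1,
                                     params=config.ssim_params())
    l_cl_t = classification_cross_entropy(labels, student_out.class_probs)
    loss = l_rl_t + l_cl_t
    l_ru_t = l_cu_t = None

    if unlabeled_batch is not None and config.semi_supervised:
        if teacher is None:
            raise ValueError("semi-supervised step requires a teacher model")
        if config.masking_ratio <= 0:
            raise ValueError(
                "masking_ratio = 0 leaves no masked patches to supervise on; "
                "disable semi_supervised instead")
        n, h, w = unlabeled_batch.shape[:3]
        spec = MaskSpec(patch_size=config.masked_patch_size, ratio=config.masking_ratio,
                        fill_value=config.mask_fill)
        masks, masked_images = [], []
        for i in range(n):
            mask = random_patch_mask(h, w, spec, seed=int(mask_rng.integers(2 ** 31)))
            masks.append(mask)
            masked_images.append(apply_mask(unlabeled_batch[i], mask, config.mask_fill))
        teacher_out = teacher(images_to_tensor(unlabeled_batch))
        student_u_out = student(images_to_tensor(np.stack(masked_images)))
        l_ru_t, l_cu_t = unsupervised_losses(student_u_out, teacher_out, masks,
                                             scale=HEAD_SCALE, beta=config.smooth_l1_beta)
        loss = loss + l_ru_t + l_cu_t

    breakdown = total_loss(l_rl_t, l_cl_t,
                           l_ru_t if l_ru_t is not None else 0.0,
                           l_cu_t if l_cu_t is not None else 0.0)
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    if teacher is not None:
        ema_update(teacher, student, config.ema_alpha if ema_alpha is None else ema_alpha)
    return breakdown


def predict_counts(model: ShootCountNet, samples) -> list:
    out = []
    for s in samples:
        result: ModelOutput = model(images_to_tensor(s.image))
        out.append((s.image_id, count_from_density(result.density.data[0, 0]), s.count))
    return out


# ---------------------------------------------------------------------------
# the full fit loop
# ---------------------------------------------------------------------------

class MeanTeacherTrainer:
    """Owns the student/teacher pair and runs the epoch loop."""

    def __init__(self, config: TrainConfig):
        self.config = config
        self.student = ShootCountNet(config.network_config())
        self.teacher = None
        if config.semi_supervised or config.eval_model == "teacher":
            self.teacher = ShootCountNet(config.network_config())
            self.teacher.load_state_dict(self.student.state_dict())
        self.optimizer = nn.Adam(self.student.parameters(), lr=config.lr,
                                 weight_decay=config.weight_decay)
        self.global_step = 0

    def _current_alpha(self) -> float:
        ramp = max(1, self.config.ema_ramp_iters)
        return self.config.ema_alpha * min(1.0, self.global_step / ramp)

    def eval_model(self) -> ShootCountNet:
        if self.config.eval_model == "teacher" and self.teacher is not None:
            return self.teacher
        return self.student

    def fit(self, manifest: DatasetManifest, root, out_dir=None,
            steps_per_epoch: int | None = None) -> TrainingResult:
        config = self.config
        data = ManifestDataset(manifest, root, config)
        bin_edges = data.bin_edges()
        data_rng = np.random.default_rng(config.data_seed)
        mask_rng = np.random.default_rng(config.mask_seed)
        use_unlabeled = config.semi_supervised and len(data.unlabeled_train) > 0
        if steps_per_epoch is None:
            pool = len(data.unlabeled_train) if use_unlabeled else len(data.labeled_train)
            steps_per_epoch = max(1, int(np.ceil(pool / config.batch_size)))

        out_dir = Path(out_dir) if out_dir is not None else None
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)

        rows, best = [], (np.inf, np.inf, -1)
        best_state = None
        for epoch in range(config.epochs):
            sums = np.zeros(4)
            for _ in range(steps_per_epoch):
                labeled = _labeled_batch(data.labeled_train, data_rng, config, bin_edges)
                unlabeled = (_unlabeled_batch(data.unlabeled_train, data_rng, config)
                             if use_unlabeled else None)
                self.global_step += 1
                bd = train_step(self.student, self.teacher, labeled, unlabeled,
                                config, self.optimizer, mask_rng,
                                ema_alpha=self._current_alpha())
                sums += (bd.l_rl, bd.l_cl, bd.l_ru, bd.l_cu)
            sums /= steps_per_epoch
            val_metrics = compute_metrics(predict_counts(self.eval_model(), data.val)) \
                if data.val else None
            row = {"epoch": epoch, "l_rl": sums[0], "l_cl": sums[1],
                   "l_ru": sums[2], "l_cu": sums[3],
                   "val_mae": val_metrics.mae if val_metrics else np.nan,
                   "val_rmse": val_metrics.rmse if val_metrics else np.nan}
            rows.append(row)
            if val_metrics and val_metrics.mae < best[0]:
                best = (val_metrics.mae, val_metrics.rmse, epoch)
                best_state = {k: v.copy() for k, v in self.eval_model().state_dict().items()}
                if out_dir is not None:
                    save_checkpoint(out_dir / "best.npz", self.eval_model(), config, bin_edges)

        log = pd.DataFrame(rows)
        if out_dir is not None:
            log.to_csv(out_dir / "log.csv", index=False)
        if best_state is not None:
            self.eval_model().load_state_dict(best_state)
        ckpt = (out_dir / "best.npz") if (out_dir is not None and best_state is not None) else None
        return TrainingResult(log=log, best_val_mae=best[0], best_val_rmse=best[1],
                              best_epoch=best[2], checkpoint_path=ckpt,
                              bin_edges=bin_edges, config=config)


def fit(manifest: DatasetManifest, root, config: TrainConfig, out_dir=None,
        steps_per_epoch: int | None = None) -> TrainingResult:
    """Convenience wrapper: build a trainer and run the epoch loop."""
    return MeanTeacherTrainer(config).fit(manifest, root, out_dir=out_dir,
                                          steps_per_epoch=steps_per_epoch)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: ShootCountNet, config: TrainConfig, bin_edges) -> None:
    state = model.state_dict()
    payload = asdict(config)
    payload["stage_depths"] = list(config.stage_depths)
    np.savez(path, __config__=json.dumps(payload),
             __bin_edges__=np.asarray(bin_edges), **state)


def load_checkpoint(path) -> tuple[ShootCountNet, TrainConfig, np.ndarray]:
    with np.load(path, allow_pickle=False) as data:
        payload = json.loads(str(data["__config__"]))
        payload["stage_depths"] = tuple(payload["stage_depths"])
        config = TrainConfig(**payload)
        bin_edges = np.asarray(data["__bin_edges__"])
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    model = ShootCountNet(config.network_config())
    model.load_state_dict(state)
    return model, config, bin_edges


def evaluate_checkpoint(path, manifest: DatasetManifest, root, split: str = "test"):
    """Reload a checkpoint and compute count metrics on a manifest split."""
    model, config, _ = load_checkpoint(path)
    data = ManifestDataset(manifest, root, config, require_labeled=False)
    samples = {"train": data.labeled_train, "val": data.val, "test": data.test}[split]
    if not samples:
        raise ValueError(f"split {split!r} is empty")
    return compute_metrics(predict_counts(model, samples))
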