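"""Desk-scale experiments runnable on one CPU core.

The headline study here is directional: on small synthetic crown scenes with
few labeled and many unlabeled training images, a mean-teacher run should
reach a validation MAE no worse than a supervised-only run given the same
labeled set, seeds and step budget.  This checks that the semi-supervised
machinery helps (or at least does not hurt) — it is a sanity property of the
method at toy scale, not a reproduction of full-scale benchmark numbers.

Study conditions (fixed):  64 x 64 canvases, 8-20 shoots per image (denser
than strict area scaling of a full crown image, so per-image counts are
non-trivial), 5 labeled + 50 unlabeled training images, 10 validation images,
and the thin ``TrainConfig.reduced`` profile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from dataclasses import replace as replace_entry

import numpy as np

from .annotations_io import select_labeled
from .synthetic_data import SceneSpec, generate_dataset
from .trainer import MeanTeacherTrainer, TrainConfig

__all__ = ["SemiVsSupervisedResult", "run_semi_vs_supervised", "DESK_SCENE"]

DESK_SCENE = SceneSpec(image_height=64, image_width=64, count_range=(8, 20),
                       blob_sigma_range=(1.0, 2.0), background_class="grass")

N_TRAIN_LABELED = 5
N_TRAIN_UNLABELED = 50
N_VAL = 10


@dataclass
class SemiVsSupervisedResult:
    seeds: list
    semi_mae: list
    supervised_mae: list

    @property
    def median_semi(self) -> float:
        return float(np.median(self.semi_mae))

    @property
    def median_supervised(self) -> float:
        return float(np.median(self.supervised_mae))


def _desk_config(seed: int, semi: bool, epochs: int) -> TrainConfig:
    return TrainConfig.reduced(
        epochs=epochs, batch_size=5, labeled_percentage=1.0,
        semi_supervised=semi, eval_model="teacher" if semi else "student",
        data_seed=seed, mask_seed=seed + 1, init_seed=seed + 2)


def run_one_seed(root, seed: int, epochs: int = 30,
                 steps_per_epoch: int = 10) -> tuple[float, float]:
    """Train the mean-teacher and the supervised-only model on one dataset
    realisation; returns (semi val MAE, supervised val MAE)."""
    n_train = N_TRAIN_LABELED + N_TRAIN_UNLABELED
    n_total = n_train + N_VAL + 3  # + a minimal test split
    spec = replace(DESK_SCENE, rng_seed=seed)
    manifest = generate_dataset(n_total, spec, root, seed=seed)
    # fixed-size splits: scenes are i.i.d., so assignment by index is unbiased
    entries = sorted(manifest.entries, key=lambda e: e.image_path)
    for i, e in enumerate(entries):
        split = "train" if i < n_train else ("val" if i < n_train + N_VAL else "test")
        entries[i] = replace_entry(e, split=split)
    manifest.entries = entries
    # 5/55 labeled: percentage 0.1 floors to exactly N_TRAIN_LABELED
    manifest = select_labeled(manifest, N_TRAIN_LABELED / 50.0, seed=seed)
    assert manifest.n_labeled_train == N_TRAIN_LABELED

    maes = {}
    for semi in (True, False):
        config = _desk_config(seed, semi=semi, epochs=epochs)
        trainer = MeanTeacherTrainer(config)
        result = trainer.fit(manifest, root, steps_per_epoch=steps_per_epoch)
        maes[semi] = result.best_val_mae
    return maes[True], maes[False]


def run_semi_vs_supervised(out_root, seeds=(1, 2, 3), epochs: int = 30,
                           steps_per_epoch: int = 10) -> SemiVsSupervisedResult:
    """The median-over-seeds comparison; each seed gets its own dataset."""
    from pathlib import Path
    semi, sup = [], []
    for seed in seeds:
        root = Path(out_root) / f"seed_{seed}"
        s, p = run_one_seed(root, int(seed) % (2 ** 31), epochs=epochs,
                            steps_per_epoch=steps_per_epoch)
        semi.append(s)
        sup.append(p)
    return SemiVsSupervisedResult(seeds=list(seeds), semi_mae=semi, supervised_mae=sup)
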