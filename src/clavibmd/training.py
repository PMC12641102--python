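"""Experimental protocol: k-fold cross-validation with a 3:1
train/validation split of the non-test folds, training-set-only
augmentation, Adam optimization of the combined loss, checkpoint selection
at the lowest validation MAE, and λ selection by validation Grad-CAM
overlap.

The default :class:`TrainConfig` carries the full-scale protocol
(learning rate 4e-5, batch 16, 60 multi-task / 30 single-task epochs,
λ = 0.8); phantom-scale runs pass a smaller config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import gradcam, objectives
from .nn import Adam
from .network import MULTI_TASK, SINGLE_TASK, NetworkHandle, NetworkSpec, build_network
from .phantom import PhantomSample, augment_pair, sample_augmentation

DEFAULT_LAMBDA_GRID = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class FoldSplit:
    fold_index: int
    test_ids: list[str]
    train_ids: list[str]
    val_ids: list[str]


@dataclass
class TrainConfig:
    learning_rate: float = 4e-5
    batch_size: int = 16
    epochs_multi: int = 60
    epochs_single: int = 30
    lam: float = 0.8
    max_shift_frac: float = 0.10
    max_rotate_deg: float = 10.0
    flip_prob: float = 0.5
    augment: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.epochs_multi < 1 or self.epochs_single < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")


@dataclass
class TrainingHistory:
    """Per-epoch loss components and validation MAE; ``selected_epoch`` is
    the first epoch attaining the minimum validation MAE (0-based)."""

    l_seg: list[float] = field(default_factory=list)
    l_reg: list[float] = field(default_factory=list)
    l_intg: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)

    @property
    def selected_epoch(self) -> int:
        return int(np.argmin(self.val_mae))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(len(self.val_mae)),
                             "l_seg": self.l_seg, "l_reg": self.l_reg,
                             "l_intg": self.l_intg, "val_mae": self.val_mae})


def make_folds(case_ids: list[str], k: int = 5, val_ratio: float = 0.25,
               seed: int = 0) -> list[FoldSplit]:
    """Shuffle ids, partition into k near-equal test groups, and split the
    remainder of each fold 3:1 into train/validation."""
    ids = list(case_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k = {k} exceeds cohort size {len(ids)}")
    if not 0.0 < val_ratio < 1.0:
        raise ValueError("val_ratio must be in (0, 1)")
    rng = np.random.default_rng([seed, 200])
    order = np.array(ids, dtype=object)
    rng.shuffle(order)
    groups = np.array_split(order, k)
    folds = []
    for i in range(k):
        test = list(groups[i])
        rest = [cid for j, g in enumerate(groups) if j != i for cid in g]
        n_val = round(len(rest) * val_ratio)
        folds.append(FoldSplit(fold_index=i + 1,
                               test_ids=test,
                               train_ids=rest[n_val:],
                               val_ids=rest[:n_val]))
    return folds


def _stack(cohort: dict[str, PhantomSample], ids: list[str]):
    images = np.stack([cohort[c].image for c in ids]).astype(np.float32)
    masks = np.stack([cohort[c].mask for c in ids]).astype(np.float32)
    bmd = np.array([cohort[c].bmd_true for c in ids], dtype=np.float32)
    return images, masks, bmd


def _predict(handle: NetworkHandle, images: np.ndarray, batch: int = 32):
    segs, bmds = [], []
    for i in range(0, len(images), batch):
        seg, bmd = handle.forward(images[i:i + batch], train=False)
        bmds.append(bmd)
        if seg is not None:
            segs.append(seg)
    seg_all = np.concatenate(segs) if segs else None
    return seg_all, np.concatenate(bmds)


def train_model(spec: NetworkSpec, fold: FoldSplit, config: TrainConfig,
                cohort: dict[str, PhantomSample]
                ) -> tuple[NetworkHandle, TrainingHistory]:
    """Train one network on a fold's train split, monitor validation MAE
    each epoch, and return the weights of the best epoch."""
    config.validate()
    spec.validate()
    handle = build_network(spec)
    opt = Adam(handle.params(), lr=config.learning_rate)

    epochs = config.epochs_multi if spec.mode == MULTI_TASK else config.epochs_single
    aug_rng = np.random.default_rng([config.seed, 300, fold.fold_index])
    shuffle_rng = np.random.default_rng([config.seed, 301, fold.fold_index])

    val_images, _vm, val_bmd = _stack(cohort, fold.val_ids)
    history = TrainingHistory()
    best_state, best_mae = None, np.inf

    for _epoch in range(epochs):
        order = list(fold.train_ids)
        shuffle_rng.shuffle(order)
        ep_seg, ep_reg, ep_intg, n_batches = 0.0, 0.0, 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch_ids = order[i:i + config.batch_size]
            imgs, msks = [], []
            for cid in batch_ids:
                s = cohort[cid]
                if config.augment:
                    aug = sample_augmentation(aug_rng, config.max_shift_frac,
                                              config.max_rotate_deg,
                                              config.flip_prob)
                    img, msk = augment_pair(s.image, s.mask, **aug)
                else:
                    img, msk = s.image, s.mask
                imgs.append(img)
                msks.append(msk)
            images = np.stack(imgs).astype(np.float32)
            masks = np.stack(msks).astype(np.float32)
            bmd_gt = np.array([cohort[c].bmd_true for c in batch_ids],
                              dtype=np.float32)

            seg, bmd_pred = handle.forward(images, train=True)
            if not np.all(np.isfinite(bmd_pred)):
                raise RuntimeError(f"training diverged at epoch {_epoch}")
            l_reg = objectives.mse_loss(bmd_pred, bmd_gt)
            dreg = objectives.mse_loss_grad(bmd_pred, bmd_gt)
            if spec.mode == MULTI_TASK:
                l_seg = objectives.dice_loss_batch(seg, masks)
                dseg = objectives.dice_loss_grad(seg, masks) * config.lam
                l_intg = objectives.combined_loss(l_seg, l_reg, config.lam)
                dbmd = dreg * (1.0 - config.lam)
            else:
                l_seg, dseg = 0.0, None
                l_intg = l_reg
                dbmd = dreg
            opt.zero_grad()
            handle.backward(dseg, dbmd)
            opt.step()
            ep_seg += l_seg
            ep_reg += l_reg
            ep_intg += l_intg
            n_batches += 1

        _seg, val_pred = _predict(handle, val_images)
        val_mae = float(np.mean(np.abs(val_pred - val_bmd)))
        history.l_seg.append(ep_seg / n_batches)
        history.l_reg.append(ep_reg / n_batches)
        history.l_intg.append(ep_intg / n_batches)
        history.val_mae.append(val_mae)
        if val_mae < best_mae:   # strict: first epoch at the minimum wins
            best_mae = val_mae
            best_state = handle.state()

    handle.load_state(best_state)
    return handle, history


def argmax_lambda(overlap_by_lambda: dict[float, float]) -> float:
    """λ with the highest overlap rate; ties break toward the larger λ."""
    if not overlap_by_lambda:
        raise ValueError("no candidate λ values")
    best = max(sorted(overlap_by_lambda), key=lambda lam: (overlap_by_lambda[lam], lam))
    return best


def select_lambda(candidates, spec: NetworkSpec, config: TrainConfig,
                  fold: FoldSplit, cohort: dict[str, PhantomSample]
                  ) -> tuple[float, dict[float, float]]:
    """Train one multi-task model per candidate λ on the fold's train split
    and pick the λ whose validation heatmap-overlap rate is highest.

    Uses training/validation data only; the fold's test ids are never
    touched.  Returns (chosen λ, overlap rate per candidate).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate λ values")
    for lam in candidates:
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"candidate λ {lam} outside [0, 1]")
    if len(candidates) == 1:
        return candidates[0], {candidates[0]: np.nan}
    rates = {}
    for lam in candidates:
        handle, _hist = train_model(spec, fold, replace(config, lam=lam), cohort)
        flags = [gradcam.compute_gradcam(handle, cohort[c].image,
                                         mask=cohort[c].mask).overlap
                 for c in fold.val_ids]
        rates[lam] = gradcam.overlap_rate(flags)
    return argmax_lambda(rates), rates


def run_crossval(spec: NetworkSpec, config: TrainConfig,
                 cohort: dict[str, PhantomSample], k: int = 5,
                 return_models: bool = False):
    """Full k-fold protocol: every case is predicted exactly once, by the
    model whose test fold contains it.

    Returns a predictions DataFrame (case_id, fold, sex, bmd_true,
    bmd_pred, dice, overlap) plus histories (and models when requested).
    """
    folds = make_folds(sorted(cohort), k=k, seed=config.seed)
    rows = []
    histories, models = [], []
    for fold in folds:
        handle, history = train_model(spec, fold, config, cohort)
        histories.append(history)
        test_images, test_masks, test_bmd = _stack(cohort, fold.test_ids)
        seg, bmd_pred = _predict(handle, test_images)
        for j, cid in enumerate(fold.test_ids):
            dice = np.nan
            if seg is not None:
                from .evaluation import dice_eval
                dice = dice_eval(seg[j], test_masks[j])
            art = gradcam.compute_gradcam(handle, test_images[j],
                                          mask=cohort[cid].mask)
            rows.append({"case_id": cid, "fold": fold.fold_index,
                         "sex": cohort[cid].sex,
                         "bmd_true": float(test_bmd[j]),
                         "bmd_pred": float(bmd_pred[j]),
                         "dice": float(dice), "overlap": bool(art.overlap)})
        if return_models:
            models.append(handle)
    preds = pd.DataFrame(rows).sort_values("case_id").reset_index(drop=True)
    if len(preds) != len(cohort):
        raise RuntimeError("missing test predictions")
    if return_models:
        return preds, histories, models
    return preds, histories
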