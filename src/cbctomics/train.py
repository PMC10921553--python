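"""Cohort splitting, the Tversky-loss training loop, and cohort evaluation."""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .metrics import assd, dice_coefficient, hausdorff95
from .model import (
    TverskyParams,
    UNet3D,
    predict_mask,
    tversky_loss,
    tversky_loss_grad,
    volume_to_input,
)
from .preprocess import invert_mask_to_original
from .volumes import MaskVolume, Volume

__all__ = ["TrainConfig", "split_cohort", "train", "evaluate_cohort"]


@dataclass
class TrainConfig:
    """Optimisation settings (Adam; scaled profile shortens the schedule)."""

    learning_rate: float = 1e-4
    batch_size: int = 2
    max_epochs: int = 150
    train_fraction: float = 0.7
    #: random axis flips of each training sample (test time is unaugmented);
    #: off by default — at short step budgets augmentation slows convergence
    #: more than it helps generalisation
    augment_flips: bool = False
    #: Adam second-moment decay
    adam_beta2: float = 0.999
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def split_cohort(case_ids, train_fraction: float = 0.7, seed: int = 0):
    """Random disjoint, exhaustive split; test count = floor((1-f)*n)."""
    ids = list(case_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 cases to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = math.floor((1.0 - train_fraction) * n)
    test = [ids[i] for i in order[:n_test]]
    train_ids = [ids[i] for i in order[n_test:]]
    return train_ids, test


def _batch_tensors(pairs, window):
    xs, gs = [], []
    for v, m in pairs:
        xs.append(volume_to_input(v, window))
        gs.append(m.data.astype(np.float64)[None, None])
    return np.concatenate(xs, axis=1), np.concatenate(gs, axis=1)


def train(
    network: UNet3D,
    train_cases: list[tuple[Volume, MaskVolume]],
    cfg: TrainConfig,
    loss_params: TverskyParams = TverskyParams(),
    val_cases: list[tuple[Volume, MaskVolume]] | None = None,
) -> tuple[UNet3D, pd.DataFrame]:
    """Train under the Tversky loss; returns the network and an epoch history.

    History columns: ``epoch``, ``loss`` (mean over batches), ``dsc`` (mean
    training DSC at threshold 0.5) and, when ``val_cases`` is given,
    ``val_dsc``.  The weights of the best epoch (validation DSC when
    available, else training DSC) are restored at the end.  Fully seeded:
    data order comes from ``cfg.seed``, weight initialisation from the
    network's own construction seed.
    """
    if not train_cases:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(network.params(), lr=cfg.learning_rate, betas=(0.9, cfg.adam_beta2))
    window = network.cfg.input_window

    rows = []
    best = (-1.0, None)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_cases))
        losses, dscs = [], []
        for s in range(0, len(order), cfg.batch_size):
            batch = [train_cases[i] for i in order[s: s + cfg.batch_size]]
            x, g = _batch_tensors(batch, window)
            if cfg.augment_flips:
                for i in range(x.shape[1]):
                    axes = tuple(ax for ax in (0, 1, 2) if rng.random() < 0.5)
                    if axes:
                        x[0, i] = np.flip(x[0, i], axes)
                        g[0, i] = np.flip(g[0, i], axes)
            p = network.forward(x)
            nb = x.shape[1]
            grad = np.empty_like(p)
            for i in range(nb):
                losses.append(tversky_loss(p[:, i], g[:, i], loss_params))
                grad[:, i] = tversky_loss_grad(p[:, i], g[:, i], loss_params) / nb
                inter = ((p[:, i] >= 0.5) & (g[:, i] > 0.5)).sum()
                denom = (p[:, i] >= 0.5).sum() + (g[:, i] > 0.5).sum()
                dscs.append(2.0 * inter / denom if denom else 1.0)
            if not np.isfinite(losses[-nb:]).all():
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {losses[-nb:]} — "
                    "check input scaling and learning rate"
                )
            opt.zero_grad()
            network.backward(grad.astype(nn.F32))
            opt.step()

        row = {"epoch": epoch, "loss": float(np.mean(losses)), "dsc": float(np.mean(dscs))}
        if val_cases:
            vds = [
                dice_coefficient(predict_mask(network, v)[1], m) for v, m in val_cases
            ]
            row["val_dsc"] = float(np.mean(vds))
        score = row.get("val_dsc", row["dsc"])
        if score > best[0]:
            best = (score, network.get_weights())
        rows.append(row)

    if best[1] is not None:
        network.set_weights(best[1])
    return network, pd.DataFrame(rows)


def evaluate_cohort(
    network: UNet3D,
    test_cases: list[tuple[Volume, MaskVolume]],
    case_ids: list[str] | None = None,
    records: list[dict] | None = None,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case DSC/HD95/ASSD plus a mean/sd summary.

    ``test_cases`` pairs a preprocessed volume with the reference mask to
    score against.  When ``records`` (from ``preprocess_case(...,
    return_record=True)``) are given, predictions are mapped back to the
    original geometry before scoring, and the reference masks must live on
    that original grid.  Empty predictions against a nonempty reference are
    flagged: DSC 0, distances missing.
    """
    if not test_cases:
        raise ValueError("need at least one test case")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(test_cases))]
    rows = []
    for i, (v, ref) in enumerate(test_cases):
        _, pred = predict_mask(network, v, threshold=threshold)
        if records is not None:
            pred = invert_mask_to_original(pred, records[i])
        row = {"case_id": case_ids[i], "flagged": False}
        row["dsc"] = dice_coefficient(pred, ref)
        if pred.voxel_count == 0 or ref.voxel_count == 0:
            row["hd95"] = np.nan
            row["assd"] = np.nan
            row["flagged"] = pred.voxel_count != ref.voxel_count
        else:
            row["hd95"] = hausdorff95(pred, ref)
            row["assd"] = assd(pred, ref)
        rows.append(row)
    table = pd.DataFrame(rows)
    summary = table[["dsc", "hd95", "assd"]].agg(["mean", "std"])
    return table, summary
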