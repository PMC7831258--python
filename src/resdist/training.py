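"""Multi-task training: masked regression + distogram classification.

Protocol: batch size 1 via a data generator, He-normal initialization,
Adam (lr 0.001) for epochs <= 30 then SGD (lr 0.01, momentum 0.9), masked
MSE on real-value distances (< 16 Å only) plus cross-entropy over all 25
bins, and a per-epoch validation metric: top-L/2 long-range precision of
the average of the contact maps derived from the two heads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import distmaps
from .distmaps import BinScheme, DEFAULT_BINS
from .evaluation import contact_precision
from .features import BranchInput
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.networks import BranchNetwork
from .nn.optim import SGD, Adam

DISTANCE_FILTER = 16.0
CE_EPS = 1e-12  # clip for log of predicted bin probability

logger = logging.getLogger(__name__)


@dataclass
class TrainingTarget:
    """Supervision for one target: true Å distances, <16 Å mask, bin labels."""

    true_distances: np.ndarray
    regression_mask: np.ndarray
    bin_labels: np.ndarray

    @classmethod
    def from_distances(cls, d: np.ndarray,
                       scheme: BinScheme = DEFAULT_BINS) -> "TrainingTarget":
        d = np.asarray(d, dtype=float)
        return cls(true_distances=d,
                   regression_mask=d < DISTANCE_FILTER,
                   bin_labels=np.asarray(scheme.discretize(d)))


@dataclass
class Schedule:
    """Optimizer schedule; defaults follow the published protocol."""

    epochs: int = 40
    adam_epochs: int = 30
    adam_lr: float = 0.001
    sgd_lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("batch size is fixed at 1")
        if min(self.adam_lr, self.sgd_lr) <= 0:
            raise ValueError("learning rates must be positive")


# ---------------------------------------------------------------------------
# losses (public numpy forms + private autograd forms used by the loop)

def masked_mse(pred: np.ndarray, target: TrainingTarget) -> float:
    """Mean squared Å error over pairs with true distance < 16 Å; 0 if the
    mask is empty."""
    pred = np.asarray(pred, dtype=float)
    if pred.shape != target.true_distances.shape:
        raise ValueError("prediction/target shape mismatch")
    m = target.regression_mask
    if not m.any():
        return 0.0
    diff = (pred - target.true_distances)[m]
    return float(np.mean(diff ** 2))


def distogram_cross_entropy(pred: np.ndarray, target: TrainingTarget) -> float:
    """Mean over pairs of -log p(true bin); zero probabilities are clipped
    at 1e-12. All 25 bins (including >= 16 Å) are supervised."""
    pred = np.asarray(pred, dtype=float)
    labels = target.bin_labels
    L = labels.shape[0]
    p_true = pred[np.arange(L)[:, None], np.arange(L)[None, :], labels]
    return float(np.mean(-np.log(np.clip(p_true, CE_EPS, None))))


def _masked_mse_t(reg: Tensor, target: TrainingTarget,
                  distance_scale: float) -> Tensor:
    m = target.regression_mask.astype(float)
    n = m.sum()
    if n == 0:
        return Tensor(0.0)
    truth = Tensor(target.true_distances[None] / distance_scale)
    diff = (reg - truth) * Tensor(m[None])
    return (diff * diff).sum() * (1.0 / n)


def _cross_entropy_t(logits: Tensor, target: TrainingTarget) -> Tensor:
    labels = target.bin_labels
    nb = logits.shape[0]
    onehot = np.zeros((nb,) + labels.shape)
    li, lj = np.meshgrid(np.arange(labels.shape[0]),
                         np.arange(labels.shape[1]), indexing="ij")
    onehot[labels, li, lj] = 1.0
    logp = ag.log_softmax(logits, axis=0)
    n_pairs = labels.size
    return (logp * Tensor(onehot)).sum() * (-1.0 / n_pairs)


def combined_loss(reg: Tensor, logits: Tensor, target: TrainingTarget,
                  w_reg: float = 1.0, w_cls: float = 1.0,
                  distance_scale: float = 1.0) -> Tensor:
    """w_reg * masked MSE + w_cls * distogram cross-entropy (autograd)."""
    loss = None
    if w_reg != 0.0:
        loss = _masked_mse_t(reg, target, distance_scale) * w_reg
    if w_cls != 0.0:
        ce = _cross_entropy_t(logits, target) * w_cls
        loss = ce if loss is None else loss + ce
    return loss if loss is not None else Tensor(0.0)


# ---------------------------------------------------------------------------
# validation metric

def validation_score(real_map: np.ndarray, distogram: np.ndarray,
                     truth: np.ndarray, min_sep: int = 24) -> float:
    """Top-L/2 long-range precision of the averaged contact maps.

    The 1/d map is min-max rescaled to [0, 1] before averaging with the
    distogram-derived contact probabilities. Returns NaN when L is too
    short for any long-range pair.
    """
    L = truth.shape[0]
    inv = distmaps.realdist_to_contact(real_map)
    rng_ = inv.max() - inv.min()
    inv = (inv - inv.min()) / rng_ if rng_ > 0 else np.zeros_like(inv)
    prob = distmaps.distogram_to_contact(distogram)
    avg = 0.5 * (inv + prob)
    return contact_precision(avg, truth, L / 2, min_sep=min_sep)


# ---------------------------------------------------------------------------
# training loop

@dataclass
class EpochRecord:
    epoch: int
    optimizer: str
    train_loss: float
    train_mse: float
    train_ce: float
    validation_precision: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


@dataclass
class TrainResult:
    records: list[EpochRecord]
    best_epoch: int
    best_validation: float
    best_params: list[np.ndarray] = field(repr=False, default_factory=list)


def train(model: BranchNetwork,
          dataset: list[tuple[BranchInput, TrainingTarget]],
          schedule: Schedule,
          loss_weights: tuple[float, float] = (1.0, 1.0),
          validation: list[tuple[BranchInput, TrainingTarget]] | None = None,
          distance_scale: float = 1.0,
          log_path: str | None = None) -> TrainResult:
    """Batch-of-1 multi-task training with the Adam -> SGD schedule.

    Deterministic given ``schedule.seed``. ``loss_weights`` is
    (w_reg, w_cls); (1, 0) reproduces the regression-only ablation design.
    The checkpoint with the best validation precision is retained in
    ``TrainResult.best_params`` (falling back to lowest training loss when
    no validation set is given).
    """
    w_reg, w_cls = loss_weights
    rng = np.random.default_rng(schedule.seed)
    params = model.parameters()
    optimizer = Adam(params, lr=schedule.adam_lr)
    opt_name = "adam"
    records: list[EpochRecord] = []
    best_val, best_epoch, best_params = -np.inf, -1, []
    fh = open(log_path, "w") if log_path else None

    try:
        for epoch in range(1, schedule.epochs + 1):
            if epoch == schedule.adam_epochs + 1:
                # epoch-boundary switch: fresh SGD state
                optimizer = SGD(params, lr=schedule.sgd_lr,
                                momentum=schedule.momentum)
                opt_name = "sgd"
            model.train()
            order = rng.permutation(len(dataset))
            losses, mses, ces = [], [], []
            for idx in order:
                binput, target = dataset[idx]
                x = Tensor(binput.tensor.transpose(2, 0, 1))
                reg, logits = model.forward(x)
                loss = combined_loss(reg, logits, target, w_reg, w_cls,
                                     distance_scale)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: reg range "
                        f"[{reg.data.min():.3g}, {reg.data.max():.3g}]")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(loss.item())
                with ag.no_grad():
                    mses.append(masked_mse(
                        0.5 * (reg.data[0] + reg.data[0].T) * distance_scale,
                        target))
                    probs = np.exp(ag.log_softmax(logits, axis=0).data)
                    ces.append(distogram_cross_entropy(
                        probs.transpose(1, 2, 0), target))

            val = np.nan
            source = validation if validation is not None else dataset
            vscores = []
            for binput, target in source:
                pred = model.predict(binput.tensor)
                vscores.append(validation_score(
                    pred.real_distance * distance_scale, pred.distogram,
                    target.true_distances))
            val = float(np.nanmean(vscores)) if vscores else np.nan

            rec = EpochRecord(epoch=epoch, optimizer=opt_name,
                              train_loss=float(np.mean(losses)),
                              train_mse=float(np.mean(mses)),
                              train_ce=float(np.mean(ces)),
                              validation_precision=val)
            records.append(rec)
            if fh:
                fh.write(rec.to_json() + "\n")
            crit = val if validation is not None else -rec.train_loss
            if np.isnan(crit):
                crit = -rec.train_loss
            if crit > best_val:
                best_val, best_epoch = crit, epoch
                best_params = [p.data.copy() for p in params]
            logger.info("epoch %d [%s] loss %.4f val %.4f",
                        epoch, opt_name, rec.train_loss, val)
    finally:
        if fh:
            fh.close()

    if best_params:
        for p, b in zip(params, best_params):
            p.data = b.copy()
    model.eval()
    return TrainResult(records=records, best_epoch=best_epoch,
                       best_validation=best_val, best_params=best_params)


def compare_multitask(make_model, dataset, validation, schedule_base: Schedule,
                      seeds: list[int], distance_scale: float = 1.0) -> dict:
    """Multi-task vs regression-only comparison (the published ablation
    design at desk scale). Returns per-seed and mean MSE / top-L/5 precision
    for both modes; the direction is reported, not asserted."""
    out = {"multitask": [], "regression_only": []}
    for mode, weights in (("multitask", (1.0, 1.0)),
                          ("regression_only", (1.0, 0.0))):
        for seed in seeds:
            model = make_model(seed)
            sched = Schedule(epochs=schedule_base.epochs,
                             adam_epochs=schedule_base.adam_epochs,
                             adam_lr=schedule_base.adam_lr,
                             sgd_lr=schedule_base.sgd_lr,
                             momentum=schedule_base.momentum, seed=seed)
            train(model, dataset, sched, loss_weights=weights,
                  validation=validation, distance_scale=distance_scale)
            mses, precs = [], []
            for binput, target in validation:
                pred = model.predict(binput.tensor)
                d = pred.real_distance * distance_scale
                mses.append(masked_mse(d, target))
                L = target.true_distances.shape[0]
                inv = distmaps.realdist_to_contact(d)
                precs.append(contact_precision(inv, target.true_distances,
                                               L / 5))
            out[mode].append({"seed": seed,
                              "mse": float(np.mean(mses)),
                              "top_l5_precision": float(np.nanmean(precs))})
    for mode in out:
        rows = out[mode]
        out[mode] = {"runs": rows,
                     "mean_mse": float(np.mean([r["mse"] for r in rows])),
                     "mean_top_l5": float(np.mean([r["top_l5_precision"]
                                                   for r in rows]))}
    out["direction_multitask_better_top_l5"] = bool(
        out["multitask"]["mean_top_l5"] >= out["regression_only"]["mean_top_l5"])
    return out
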