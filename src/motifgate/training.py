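"""AdaDelta training with step-size decay, dual-validation checkpointing,
and the merge-then-retrain protocol.

AdaDelta has no base learning rate; the stated decay ("0.03 per interval")
is applied as a multiplicative scale on the computed update:
scale = (1 - decay) ** floor(instances_seen / interval).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from motifgate.datasets import PackedInstances
from motifgate.evaluation import roc_auc
from motifgate.model import GatedConvModel, ModelConfig, ModelParameters


@dataclass
class TrainingConfig:
    epochs: int = 10
    eval_interval: int = 50_000     # instances between validation passes
    lr_decay: float = 0.03          # fractional decay per interval
    decay_interval: int = 50_000    # instances per decay step
    adadelta_rho: float = 0.95
    adadelta_eps: float = 1e-6
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.lr_decay < 1:
            raise ValueError("lr_decay must be in [0, 1)")
        if self.eval_interval < self.batch_size:
            raise ValueError("eval_interval must be >= batch_size")


@dataclass
class Checkpoint:
    parameters: ModelParameters
    metric_valid1: float
    metric_valid2: float
    instances_seen: int


@dataclass
class TrainResult:
    best_for_within: Checkpoint      # best on validset1 -> testset1/testset2
    best_for_imputation: Checkpoint  # best on validset2 -> testset3
    history: List[dict]


class AdaDeltaState:
    """Accumulated squared gradients and squared updates per parameter."""

    def __init__(self, params: Dict[str, np.ndarray]):
        self.sq_grad = {k: np.zeros_like(v) for k, v in params.items()}
        self.sq_update = {k: np.zeros_like(v) for k, v in params.items()}


def adadelta_step(params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray],
                  state: AdaDeltaState, rho: float, eps: float,
                  scale: float = 1.0) -> None:
    """In-place AdaDelta update, delta = -(RMS[dx]/RMS[g]) * g, times scale."""
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in group {name}")
        p = params[name]
        Eg = state.sq_grad[name]
        Ed = state.sq_update[name]
        Eg *= rho
        Eg += (1.0 - rho) * g * g
        delta = -np.sqrt((Ed + eps) / (Eg + eps)) * g
        Ed *= rho
        Ed += (1.0 - rho) * delta * delta
        p += scale * delta


def lr_schedule(instances_seen: int, decay: float, interval: int) -> float:
    """Multiplicative step-size scale after ``instances_seen`` instances."""
    return (1.0 - decay) ** (instances_seen // interval)


def _pooled_auc(model: GatedConvModel, data: Optional[PackedInstances]) -> float:
    if data is None or len(data) == 0:
        return float("nan")
    scores = model.predict_scores_codes(data.codes, data.tf_ids, data.cell_ids)
    try:
        return roc_auc(scores, data.labels)
    except ValueError:
        return float("nan")


def train(model: GatedConvModel,
          trainset: PackedInstances,
          validset1: Optional[PackedInstances],
          validset2: Optional[PackedInstances],
          config: TrainingConfig,
          verbose: bool = False,
          max_instances: Optional[int] = None) -> TrainResult:
    """Shuffled mini-batch passes with dual running-best checkpoints.

    Every ``eval_interval`` instances (and at the end of training) pooled AUC
    is computed on both validation sets; the best snapshot per metric is kept.
    ``max_instances`` truncates training (used by merge_and_retrain phase 2).
    """
    if len(trainset) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    state = AdaDeltaState(model.params.groups())
    best1: Optional[Checkpoint] = None
    best2: Optional[Checkpoint] = None
    history: List[dict] = []
    instances_seen = 0
    since_eval = 0
    recent_losses: List[float] = []

    def evaluate():
        nonlocal best1, best2
        auc1 = _pooled_auc(model, validset1)
        auc2 = _pooled_auc(model, validset2)
        loss = float(np.mean(recent_losses)) if recent_losses else float("nan")
        recent_losses.clear()
        history.append(dict(instances_seen=instances_seen, loss=loss,
                            auc_valid1=auc1, auc_valid2=auc2))
        if verbose:
            print(f"[train] seen={instances_seen} loss={loss:.4f} "
                  f"auc1={auc1:.4f} auc2={auc2:.4f}", file=sys.stderr)
        snap = None
        if not np.isnan(auc1) and (best1 is None or auc1 > best1.metric_valid1):
            snap = model.params.copy()
            best1 = Checkpoint(snap, auc1, auc2, instances_seen)
        if not np.isnan(auc2) and (best2 is None or auc2 > best2.metric_valid2):
            snap = snap or model.params.copy()
            best2 = Checkpoint(snap, auc1, auc2, instances_seen)

    done = False
    for _ in range(config.epochs):
        order = rng.permutation(len(trainset))
        for s in range(0, len(order), config.batch_size):
            idx = order[s: s + config.batch_size]
            loss, grads = model.loss_and_grads(
                trainset.codes[idx], trainset.tf_ids[idx],
                trainset.cell_ids[idx], trainset.labels[idx])
            scale = lr_schedule(instances_seen, config.lr_decay,
                                config.decay_interval)
            adadelta_step(model.params.groups(), grads, state,
                          config.adadelta_rho, config.adadelta_eps, scale)
            instances_seen += len(idx)
            since_eval += len(idx)
            recent_losses.append(loss)
            if since_eval >= config.eval_interval:
                since_eval = 0
                evaluate()
            if max_instances is not None and instances_seen >= max_instances:
                done = True
                break
        if done:
            break
    if since_eval > 0 or not history:
        evaluate()
    if best1 is None and best2 is None:
        # no usable validation metric; fall back to the final parameters
        final = Checkpoint(model.params.copy(), float("nan"), float("nan"),
                           instances_seen)
        best1 = best1 or final
        best2 = best2 or final
    best1 = best1 or best2
    best2 = best2 or best1
    return TrainResult(best_for_within=best1, best_for_imputation=best2,
                       history=history)


@dataclass
class MergeRetrainResult:
    model: GatedConvModel
    stop_point: int           # instances_seen of the phase-1 best checkpoint
    instances_seen: int       # instances consumed in phase 2 (>= stop_point)
    phase1: TrainResult


def merge_and_retrain(model_config: ModelConfig,
                      merged_sets: Sequence[PackedInstances],
                      validset2: PackedInstances,
                      config: TrainingConfig,
                      verbose: bool = False) -> MergeRetrainResult:
    """Two-phase final-model protocol.

    Phase 1 trains on the merged sets (everything except validset2), using
    validset2 to find the early-stop point (instances seen at its best AUC).
    Phase 2 retrains from scratch on everything *including* validset2 for
    exactly that many instances.
    """
    merged = PackedInstances.concat(list(merged_sets))
    rng_init = np.random.default_rng(config.seed)
    model1 = GatedConvModel(model_config, rng=rng_init)
    res1 = train(model1, merged, None, validset2, config, verbose=verbose)
    stop_point = res1.best_for_imputation.instances_seen

    everything = PackedInstances.concat(list(merged_sets) + [validset2])
    model2 = GatedConvModel(model_config, rng=np.random.default_rng(config.seed))
    train(model2, everything, None, None, config, verbose=verbose,
          max_instances=stop_point)
    seen = min(stop_point + config.batch_size - 1,
               config.epochs * len(everything))
    return MergeRetrainResult(model=model2, stop_point=stop_point,
                              instances_seen=seen, phase1=res1)


def train_multitf(model, trainset: PackedInstances,
                  validset: Optional[PackedInstances],
                  config: TrainingConfig, verbose: bool = False):
    """Training loop for the multi-TF CNN-GRU variant; keeps the best
    parameters by pooled validation AUC (per-instance TF output)."""
    if len(trainset) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    state = AdaDeltaState(model.params)
    best_auc, best_params, instances_seen, since_eval = -np.inf, None, 0, 0

    def val_auc():
        if validset is None or len(validset) == 0:
            return float("nan")
        out = np.empty(len(validset))
        bs = 256
        for s in range(0, len(validset), bs):
            sl = slice(s, s + bs)
            sc, _ = model.forward(validset.codes[sl], validset.cell_ids[sl])
            out[sl] = sc[np.arange(sc.shape[0]), validset.tf_ids[sl]]
        try:
            return roc_auc(out, validset.labels)
        except ValueError:
            return float("nan")

    for _ in range(config.epochs):
        order = rng.permutation(len(trainset))
        for s in range(0, len(order), config.batch_size):
            idx = order[s: s + config.batch_size]
            loss, grads = model.loss_and_grads(
                trainset.codes[idx], trainset.cell_ids[idx],
                trainset.tf_ids[idx], trainset.labels[idx])
            scale = lr_schedule(instances_seen, config.lr_decay,
                                config.decay_interval)
            adadelta_step(model.params, grads, state,
                          config.adadelta_rho, config.adadelta_eps, scale)
            instances_seen += len(idx)
            since_eval += len(idx)
            if since_eval >= config.eval_interval:
                since_eval = 0
                auc = val_auc()
                if verbose:
                    print(f"[multitf] seen={instances_seen} loss={loss:.4f} "
                          f"auc={auc:.4f}", file=sys.stderr)
                if not np.isnan(auc) and auc > best_auc:
                    best_auc = auc
                    best_params = {k: v.copy() for k, v in model.params.items()}
    auc = val_auc()
    if not np.isnan(auc) and auc > best_auc:
        best_auc = auc
        best_params = {k: v.copy() for k, v in model.params.items()}
    if best_params is not None:
        model.params = best_params
    return model, best_auc
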