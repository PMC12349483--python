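"""Weighted cross-entropy training with Adam, early stopping, and the
two-stage hyper-parameter search.

Class imbalance is handled by inverse-frequency class weights
:math:`w_c \\propto 1/N_c` normalized to :math:`\\sum_c w_c = 3`, computed on
the training portion only, so a sample's loss is
:math:`L = -w_c \\log \\hat p_c`.  Optimization is Adam (lr 1e-4,
beta1 0.9, beta2 0.999) for at most 500 epochs with early stopping when the
validation loss fails to improve by at least 1e-6 for 20 consecutive
epochs; the returned parameters are those of the best-validation epoch.
The validation set is a stratified 15% carve-out of the training data.

Hyper-parameters are tuned in two sequential stages of stratified 3-fold
cross-validation maximizing mean weighted F1: first the activation pair
(micro-network, MLP), then capacity (K, micro-net widths, MLP shape) —
choosing the smallest configuration within a 0.005-F1 plateau of the best —
followed by regularization strengths/subsample sizes and the dropout rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autodiff import Tensor, logsumexp
from .containers import FunctionalTrialSet, N_CLASSES
from .model import (
    BasisLayerSpec,
    ClassifierHeadSpec,
    MicroNetworkSpec,
    ModelSpec,
    MultiAdaFNN,
)
from .regularization import (
    RegularizationConfig,
    orthogonality_penalty,
    sparsity_penalty,
)

__all__ = [
    "ClassWeights",
    "TrainingConfig",
    "HyperParamGrid",
    "compute_class_weights",
    "weighted_cross_entropy",
    "train_model",
    "tune_hyperparameters",
]

_PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class ClassWeights:
    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=np.float64)
        if w.shape != (N_CLASSES,) or np.any(w <= 0):
            raise ValueError("need three positive class weights")
        if abs(w.sum() - 3.0) > 1e-9:
            raise ValueError("class weights must sum to 3")
        object.__setattr__(self, "w", w)


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    max_epochs: int = 500
    patience: int = 20
    dropout_rate: float = 0.20
    batch_size: int = 32
    val_fraction: float = 0.15
    seed: int = 0
    reg: RegularizationConfig = field(default_factory=RegularizationConfig)
    improvement_tol: float = 1e-6

    def __post_init__(self):
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def compute_class_weights(labels) -> ClassWeights:
    """Inverse-frequency weights, rescaled to sum to 3."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=N_CLASSES)
    if np.any(counts == 0):
        raise ValueError("every class must appear at least once")
    w = 1.0 / counts
    return ClassWeights(3.0 * w / w.sum())


def weighted_cross_entropy(probs, label: int, weights: ClassWeights) -> float:
    """Single-sample weighted cross-entropy  L = -w_c log p_c."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != (N_CLASSES,) or np.any(probs <= 0):
        raise ValueError("probs must be three positive values")
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("probs must sum to 1")
    p = probs[label]
    if p < _PROB_FLOOR:
        warnings.warn("probability clamped to avoid log underflow")
        p = _PROB_FLOOR
    return float(-weights.w[label] * np.log(p))


class Adam:
    """Plain Adam with bias correction on a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float, beta1: float, beta2: float,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _batch_loss(model: MultiAdaFNN, values, labels, grid, weights: ClassWeights,
                cfg: TrainingConfig, train_mode: bool,
                dropout_rng=None, reg_rng=None) -> Tensor:
    """Weighted CE (mean over the batch) plus the two basis penalties."""
    bases = model.basis_tensor(grid)
    z = model.logits(values, grid, train_mode=train_mode,
                     dropout_rng=dropout_rng, bases=bases)
    n = z.shape[0]
    lse = logsumexp(z, axis=-1)                     # (n,)
    true_logit = z[np.arange(n), labels]            # (n,)
    w = Tensor(weights.w[labels])
    loss = (w * (lse - true_logit)).mean()
    reg = cfg.reg
    if reg.lambda1 > 0:
        loss = loss + reg.lambda1 * sparsity_penalty(bases, grid, reg, reg_rng)
    if reg.lambda2 > 0 and model.spec.basis.K >= 2:
        loss = loss + reg.lambda2 * orthogonality_penalty(bases, grid, reg, reg_rng)
    return loss


def train_model(data: FunctionalTrialSet, model_spec: ModelSpec,
                cfg: TrainingConfig) -> tuple[MultiAdaFNN, dict]:
    """Fit a Multi-AdaFNN on ``data``; returns the model at its
    best-validation epoch and a history dict of per-epoch losses.

    All randomness (parameter init, the validation carve-out, minibatch
    shuffling, dropout masks, penalty subsampling) derives from ``cfg.seed``,
    so identical (data, spec, cfg) yield bitwise-identical parameters.
    """
    from .evaluation import stratified_split  # local import avoids a cycle

    if np.any(data.class_counts() == 0):
        raise ValueError("training data must contain all three classes")
    # seed chain
    root = np.random.SeedSequence(cfg.seed)
    s_init, s_split, s_shuffle, s_drop, s_reg = root.spawn(5)
    init_seed = int(s_init.generate_state(1)[0] % (2**31))
    split_seed = int(s_split.generate_state(1)[0] % (2**31))
    shuffle_rng = np.random.default_rng(s_shuffle)
    dropout_rng = np.random.default_rng(s_drop)
    reg_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.reg.subsample_seed, int(s_reg.generate_state(1)[0] % (2**31))])
    )

    # training-time dropout rate overrides the head default
    spec = replace(model_spec,
                   head=replace(model_spec.head, dropout_rate=cfg.dropout_rate))
    model = MultiAdaFNN(spec, seed=init_seed)

    tr_idx, val_idx = stratified_split(data.labels, 1.0 - cfg.val_fraction,
                                       split_seed)
    train, val = data.subset(tr_idx), data.subset(val_idx)
    weights = compute_class_weights(train.labels)  # training portion only

    opt = Adam(model.parameters(), cfg.learning_rate, cfg.adam_beta1,
               cfg.adam_beta2)
    batch = min(cfg.batch_size, train.n)
    history = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_val, best_state, stall = np.inf, model.state_dict(), 0

    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(train.n)
        epoch_losses = []
        for start in range(0, train.n, batch):
            idx = order[start:start + batch]
            model.zero_grad()
            loss = _batch_loss(model, train.values[idx], train.labels[idx],
                               data.grid, weights, cfg, train_mode=True,
                               dropout_rng=dropout_rng, reg_rng=reg_rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        val_loss = _batch_loss(model, val.values, val.labels, data.grid,
                               weights, cfg, train_mode=False).item()
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - cfg.improvement_tol:
            best_val, best_state, stall = val_loss, model.state_dict(), 0
            history["best_epoch"] = epoch
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return model, history


# -- hyper-parameter search ------------------------------------------------


@dataclass(frozen=True)
class HyperParamGrid:
    activation_pairs: tuple = (("tanh", "relu"),)
    K_options: tuple = (4,)
    micro_width_options: tuple = ((16, 8),)
    mlp_shape_options: tuple = ((32, 16),)
    lambda1_levels: tuple = (0.0,)
    lambda2_levels: tuple = (0.0,)
    kR1_options: tuple = (1,)
    kR2_options: tuple = (2,)
    dropout_options: tuple = (0.20,)

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")


def _cv_weighted_f1(data: FunctionalTrialSet, spec: ModelSpec,
                    cfg: TrainingConfig, n_folds: int = 3) -> list[float]:
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import weighted_f1

    counts = data.class_counts()
    if np.any(counts < n_folds):
        raise ValueError("every class needs at least one trial per fold")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
    scores = []
    for tr, te in skf.split(np.zeros(data.n), data.labels):
        model, _ = train_model(data.subset(tr), spec, cfg)
        pred, _ = model.predict(data.subset(te))
        scores.append(weighted_f1(data.labels[te], pred))
    return scores


def _capacity_size(K: int, micro: tuple, mlp: tuple) -> int:
    return K * (micro[0] + micro[0] * micro[1] + micro[1]) + mlp[0] * mlp[1]


def tune_hyperparameters(train_set: FunctionalTrialSet, grid: HyperParamGrid,
                         cfg: TrainingConfig,
                         plateau_tol: float = 0.005) -> tuple[dict, pd.DataFrame]:
    """Two-stage search; returns the selected configuration and a CV table
    with one row per (stage, configuration, fold)."""
    F = train_set.F
    rows = []

    def evaluate(stage, label, spec, run_cfg):
        scores = _cv_weighted_f1(train_set, spec, run_cfg)
        for fold, s in enumerate(scores):
            rows.append({"stage": stage, "config": label, "fold": fold,
                         "weighted_f1": s})
        return float(np.mean(scores))

    K0 = grid.K_options[0]
    micro0, mlp0 = grid.micro_width_options[0], grid.mlp_shape_options[0]

    def make_spec(K, micro_w, mlp_w, acts, dropout):
        basis_act, mlp_act = acts
        return ModelSpec(
            basis=BasisLayerSpec(K, F, MicroNetworkSpec(tuple(micro_w), basis_act)),
            head=ClassifierHeadSpec(hidden_widths=tuple(mlp_w),
                                    activation=mlp_act, dropout_rate=dropout),
        )

    # stage 1: activation pair at baseline capacity
    best_acts, best_score = None, -np.inf
    for acts in grid.activation_pairs:
        spec = make_spec(K0, micro0, mlp0, acts, cfg.dropout_rate)
        score = evaluate("activations", f"{acts[0]}/{acts[1]}", spec, cfg)
        if score > best_score:
            best_acts, best_score = acts, score

    # stage 2a: capacity, smallest configuration within the plateau
    cap_results = []
    for K in grid.K_options:
        for micro_w in grid.micro_width_options:
            for mlp_w in grid.mlp_shape_options:
                spec = make_spec(K, micro_w, mlp_w, best_acts, cfg.dropout_rate)
                score = evaluate("capacity", f"K{K}-m{micro_w}-h{mlp_w}", spec, cfg)
                cap_results.append((K, micro_w, mlp_w, score))
    top = max(s for *_, s in cap_results)
    in_plateau = [r for r in cap_results if r[3] >= top - plateau_tol]
    K_best, micro_best, mlp_best, _ = min(
        in_plateau, key=lambda r: _capacity_size(r[0], r[1], r[2])
    )

    # stage 2b: regularization strengths and subsample sizes
    best_reg, best_score = cfg.reg, -np.inf
    for l1 in grid.lambda1_levels:
        for l2 in grid.lambda2_levels:
            for kr1 in grid.kR1_options:
                for kr2 in grid.kR2_options:
                    if kr1 > K_best or kr2 > max(K_best, 2):
                        continue
                    reg = replace(cfg.reg, lambda1=l1, lambda2=l2,
                                  kR1=kr1, kR2=min(kr2, max(K_best, 2)))
                    run_cfg = replace(cfg, reg=reg)
                    spec = make_spec(K_best, micro_best, mlp_best, best_acts,
                                     cfg.dropout_rate)
                    score = evaluate("regularization",
                                     f"l1={l1}-l2={l2}-kR1={kr1}-kR2={kr2}",
                                     spec, run_cfg)
                    if score > best_score:
                        best_reg, best_score = reg, score

    # stage 2c: dropout rate
    best_dropout, best_score = cfg.dropout_rate, -np.inf
    for rate in grid.dropout_options:
        run_cfg = replace(cfg, reg=best_reg, dropout_rate=rate)
        spec = make_spec(K_best, micro_best, mlp_best, best_acts, rate)
        score = evaluate("dropout", f"p={rate}", spec, run_cfg)
        if score > best_score:
            best_dropout, best_score = rate, score

    selection = {
        "activation_pair": tuple(best_acts),
        "K": K_best,
        "micro_widths": tuple(micro_best),
        "mlp_widths": tuple(mlp_best),
        "reg": best_reg,
        "dropout_rate": best_dropout,
        "cv_weighted_f1": best_score,
        "model_spec": make_spec(K_best, micro_best, mlp_best, best_acts,
                                best_dropout),
    }
    return selection, pd.DataFrame(rows)
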