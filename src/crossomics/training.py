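"""Fold-safe training: repeated stratified CV, standardization, Adam loop.

Everything that depends on data moments is computed on the training side of a
split only.  All randomness flows from a single root seed through named
substreams so a whole cross-validation run is bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .autodiff import Tensor, no_grad
from .graphs import HeteroGraph, MODALITIES
from .model import CrossOmicsNet, ModelConfig, PatientBatch

_MODALITY_INDEX = {t: i for i, t in enumerate(MODALITIES)}


def substream(seed: int, *names: str) -> np.random.Generator:
    """Named child stream of a root seed (folds / init / masking / ...).

    Names are hashed with blake2s; a plain byte-reinterpretation would make
    long names that differ only in their tail collide modulo 2³¹.
    """
    ints = [seed] + [int.from_bytes(hashlib.blake2s(n.encode()).digest()[:4],
                                    "little") for n in names]
    return np.random.default_rng(np.random.SeedSequence(ints))


# ------------------------------------------------------------------ fold plan
@dataclass
class FoldPlan:
    """Shared outer splits: `n_repeats` × `n_folds` stratified partitions."""

    sample_ids: list[str]
    assignments: np.ndarray  # (n_repeats, n_samples) fold index of each sample
    seed: int

    @property
    def n_repeats(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_folds(self) -> int:
        return int(self.assignments.max()) + 1

    def test_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] == fold)

    def train_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] != fold)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_repeats):
            for i, sid in enumerate(self.sample_ids):
                rows.append((sid, r, int(self.assignments[r, i])))
        return pd.DataFrame(rows, columns=["sample_id", "repeat", "fold"])

    def save(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = 0) -> "FoldPlan":
        sample_ids = frame[frame["repeat"] == 0]["sample_id"].tolist()
        pos = {s: i for i, s in enumerate(sample_ids)}
        n_rep = int(frame["repeat"].max()) + 1
        asg = np.zeros((n_rep, len(sample_ids)), dtype=int)
        for row in frame.itertuples(index=False):
            asg[row.repeat, pos[row.sample_id]] = row.fold
        return cls(sample_ids=sample_ids, assignments=asg, seed=seed)


def make_fold_plan(labels, sample_ids: list[str] | None = None, k: int = 5,
                   r: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan repeated r times, deterministic in the seed."""
    labels = np.asarray(labels)
    n = len(labels)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    rng = substream(seed, "folds")
    assignments = np.zeros((r, n), dtype=int)
    for rep in range(r):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for fold, (_, test_ix) in enumerate(skf.split(np.zeros(n), labels)):
            assignments[rep, test_ix] = fold
    return FoldPlan(sample_ids=list(sample_ids), assignments=assignments, seed=seed)


# -------------------------------------------------------------- standardizer
@dataclass
class StandardizationStats:
    """Per-modality training-fold moments for z-standardization."""

    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    epsilon: float = 1e-8


def fit_standardizer(matrices: dict[str, np.ndarray],
                     epsilon: float = 1e-8) -> StandardizationStats:
    """Column means and population standard deviations of the training split."""
    mean = {t: np.asarray(m, dtype=float).mean(axis=0) for t, m in matrices.items()}
    std = {t: np.asarray(m, dtype=float).std(axis=0) for t, m in matrices.items()}
    return StandardizationStats(mean=mean, std=std, epsilon=epsilon)


def apply_standardizer(stats: StandardizationStats,
                       matrices: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """(x − μ_train) / (σ_train + ε), reusing train statistics verbatim."""
    return {t: (np.asarray(m, dtype=float) - stats.mean[t])
            / (stats.std[t] + stats.epsilon) for t, m in matrices.items()}


def split_inner_validation(train_ids: np.ndarray, labels, frac: float = 0.10,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified, disjoint fit/validation split inside the training fold."""
    train_ids = np.asarray(train_ids)
    labels = np.asarray(labels)
    strata = labels[train_ids]
    # stratification needs >= 2 members per class and a validation split at
    # least as large as the class count; fall back gracefully otherwise
    counts = np.bincount(strata)
    n_classes = int((counts > 0).sum())
    n_val = int(np.ceil(frac * len(train_ids)))
    stratify = strata if ((counts[counts > 0] >= 2).all()
                          and n_val >= n_classes) else None
    fit_ids, val_ids = train_test_split(
        train_ids, test_size=frac, stratify=stratify,
        random_state=int(substream(seed, "inner").integers(2 ** 31)))
    return np.sort(fit_ids), np.sort(val_ids)


# -------------------------------------------------------------------- training
@dataclass
class TrainRun:
    learning_rate: float = 1e-2
    batch_size: int = 48   # minibatch size; 0 = full batch
    max_epochs: int = 150
    patience: int = 25
    clip_norm: float = 5.0     # global gradient-norm clip; 0 disables
    ema_decay: float = 0.0     # weight-averaging decay; 0 disables
    warmup_epochs: int = 10    # linear learning-rate warmup; 0 disables
    class_weighted: bool = False  # inverse-frequency CE weights
    #: when the best inner-validation score stays below this (mean correct-class
    #: probability for the nll monitor, plain fraction otherwise), retrain from
    #: a fresh initialization, up to max_restarts attempts, keeping the best
    restart_below: float = 0.6
    max_restarts: int = 2
    #: keep the k best-scoring validation checkpoints; prediction averages
    #: their probabilities (a free snapshot ensemble within one training)
    snapshot_k: int = 3
    inner_val_frac: float = 0.10
    train_mask_prob: float = 0.0
    mask_modalities: tuple[str, ...] = ("g", "c", "m")
    monitor: str = "nll"
    seed: int = 0
    history: list[dict] = field(default_factory=list)


class Adam:
    """Plain Adam over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def clip_gradients(self, max_norm: float):
        """Scale all gradients down when their global L2 norm exceeds max_norm."""
        total = math.sqrt(sum(float((p.grad ** 2).sum())
                              for p in self.params if p.grad is not None))
        if total > max_norm > 0:
            scale = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad ** 2
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _masked_copy(batch: PatientBatch, masked: set[str]) -> PatientBatch:
    mask = batch.modality_mask.copy()
    for t in masked:
        mask[:, _MODALITY_INDEX[t]] = False
    return PatientBatch(x={t: batch.x[t].copy() for t in MODALITIES},
                        modality_mask=mask, labels=batch.labels,
                        sample_ids=batch.sample_ids)


def _monitor_score(model: CrossOmicsNet, batch: PatientBatch, monitor: str) -> float:
    """Higher-is-better validation score for early stopping."""
    with no_grad():
        probs = model.forward(batch).probs.data
    pred = probs.argmax(axis=1)
    if monitor == "accuracy":
        return float((pred == batch.labels).mean())
    if monitor == "nll":  # smooth; far less noisy than accuracy on tiny splits
        picked = np.clip(probs[np.arange(len(pred)), batch.labels], 1e-12, None)
        return float(np.log(picked).mean())
    return float(f1_score(batch.labels, pred, average="macro", zero_division=0))


def _as_fraction(score: float, monitor: str) -> float:
    """Map a monitor score onto [0, 1] for the restart rule."""
    return float(np.exp(score)) if monitor == "nll" else float(score)


def train_model(model: CrossOmicsNet, fit_batch: PatientBatch,
                val_batch: PatientBatch, run: TrainRun) -> dict:
    """Full-batch Adam with early stopping on the inner-validation metric.

    With ``train_mask_prob > 0``, each epoch's batch independently zero-masks
    one entire modality (drawn uniformly from ``run.mask_modalities``) with the
    stated probability before the forward pass.  When ``ema_decay > 0`` the
    monitored (and returned) weights are an exponential moving average of the
    optimizer trajectory — full-batch training on small cohorts is noisy, and
    averaging stabilizes both the validation signal and the final model.
    A training attempt whose best monitored score stays below
    ``run.restart_below`` is retried from a fresh initialization (at most
    ``run.max_restarts`` attempts); the best attempt wins.  Returns the best
    state dict (by monitored score) plus the history.
    """
    always_masked = set()
    if run.train_mask_prob >= 1.0 and len(run.mask_modalities) == 1:
        always_masked = {run.mask_modalities[0]}
    per_class_weight = None
    if run.class_weighted:
        counts = np.bincount(fit_batch.labels,
                             minlength=model.config.num_classes)
        per_class_weight = len(fit_batch.labels) / np.maximum(counts, 1)

    def fit_once(attempt: int) -> tuple[float, dict, int, list]:
        opt = Adam(model.parameter_list(), lr=run.learning_rate)
        mask_rng = substream(run.seed, "masking", f"a{attempt}")
        best_score, best_state, best_epoch = -np.inf, model.state_dict(), -1
        snaps: list[tuple[float, int, dict]] = []
        ema: dict[str, np.ndarray] | None = None
        n_fit = fit_batch.n_patients
        shuffle_rng = substream(run.seed, "shuffle", f"a{attempt}")
        for epoch in range(run.max_epochs):
            if run.warmup_epochs:
                opt.lr = run.learning_rate * min(1.0, (epoch + 1)
                                                 / run.warmup_epochs)
            if run.batch_size and run.batch_size < n_fit:
                order = shuffle_rng.permutation(n_fit)
                starts = range(0, n_fit, run.batch_size)
                minibatches = [fit_batch.subset(order[s:s + run.batch_size])
                               for s in starts]
            else:
                minibatches = [fit_batch]
            epoch_loss = 0.0
            for batch in minibatches:
                weights = None if per_class_weight is None \
                    else per_class_weight[batch.labels]
                if run.train_mask_prob > 0 and \
                        mask_rng.random() < run.train_mask_prob:
                    choice = run.mask_modalities[
                        mask_rng.integers(len(run.mask_modalities))]
                    batch = _masked_copy(batch, {choice})
                trace = model.forward(batch)
                loss = model.total_loss(trace, batch.labels,
                                        sample_weights=weights)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}: "
                        f"{loss.data!r}")
                opt.zero_grad()
                loss.backward()
                if run.clip_norm:
                    opt.clip_gradients(run.clip_norm)
                opt.step()
                epoch_loss += float(loss.data) * batch.n_patients / n_fit
            loss_value = epoch_loss
            if run.ema_decay > 0:
                current = model.state_dict()
                ema = current if ema is None else {
                    k: run.ema_decay * ema[k]
                    + (1 - run.ema_decay) * current[k] for k in ema}
                model.load_state_dict(ema)
                score = _monitor_score(model, val_batch, run.monitor)
                candidate = {k: v.copy() for k, v in ema.items()}
                model.load_state_dict(current)
            else:
                score = _monitor_score(model, val_batch, run.monitor)
                candidate = model.state_dict()
            run.history.append({"attempt": attempt, "epoch": epoch,
                                "loss": loss_value, "val": score})
            if run.snapshot_k > 1:
                if len(snaps) < run.snapshot_k or score > snaps[-1][0]:
                    snaps.append((score, epoch, candidate))
                    snaps.sort(key=lambda t: (-t[0], t[1]))
                    del snaps[run.snapshot_k:]
            if score > best_score:
                best_score, best_state, best_epoch = score, candidate, epoch
            elif epoch - best_epoch >= run.patience:
                break
        return best_score, best_state, best_epoch, snaps

    best_score, best_state, best_epoch, snaps = fit_once(0)
    attempt = 0
    while (_as_fraction(best_score, run.monitor) < run.restart_below
           and attempt < run.max_restarts):
        attempt += 1
        model.reinitialize(substream(run.seed, "restart", f"a{attempt}"))
        score, state, epoch, snaps_i = fit_once(attempt)
        if score > best_score:
            best_score, best_state, best_epoch, snaps = score, state, epoch, snaps_i
    model.load_state_dict(best_state)
    return {"state": best_state, "best_val": best_score, "best_epoch": best_epoch,
            "epochs_run": len(run.history), "attempts": attempt + 1,
            "snapshots": [st for _, _, st in snaps] or [best_state],
            "always_masked": sorted(always_masked)}


def predict_probs(model: CrossOmicsNet, batch: PatientBatch,
                  always_masked: set[str] | None = None,
                  snapshots: list[dict] | None = None) -> np.ndarray:
    """Inference probabilities; modalities the model never saw stay masked.

    With ``snapshots`` the prediction is the mean probability over the stored
    checkpoint states (the model's current state is restored afterwards).
    """
    if always_masked:
        batch = _masked_copy(batch, set(always_masked))
    if not snapshots or len(snapshots) == 1:
        with no_grad():
            return model.forward(batch).probs.data.copy()
    current = model.state_dict()
    probs = []
    with no_grad():
        for state in snapshots:
            model.load_state_dict(state)
            probs.append(model.forward(batch).probs.data.copy())
    model.load_state_dict(current)
    return np.mean(probs, axis=0)


# ----------------------------------------------------------- cross-validation
def _standardized_fold_batches(raw: dict[str, np.ndarray], labels: np.ndarray,
                               sample_ids: list[str], train_ix, test_ix,
                               epsilon: float = 1e-8):
    stats = fit_standardizer({t: raw[t][train_ix] for t in MODALITIES}, epsilon)

    def batch_for(ix):
        x = apply_standardizer(stats, {t: raw[t][ix] for t in MODALITIES})
        return PatientBatch(x=x, modality_mask=np.ones((len(ix), 3), dtype=bool),
                            labels=labels[ix],
                            sample_ids=[sample_ids[i] for i in ix])
    return batch_for(train_ix), batch_for(test_ix), stats


def cross_validate(graph: HeteroGraph, raw: dict[str, np.ndarray],
                   labels: np.ndarray, config: ModelConfig,
                   plan: FoldPlan, run_template: TrainRun | None = None,
                   sample_ids: list[str] | None = None,
                   keep_models: bool = False, n_ensemble: int = 1) -> dict:
    """Repeated stratified CV; returns out-of-fold predictions and fold summaries.

    Every sample appears exactly `n_repeats` times in the OOF table (once per
    repeat).  Standardization, inner validation and early stopping all live
    strictly inside each outer training fold.  With ``n_ensemble > 1`` each
    fold's prediction is the mean probability of independently initialized
    models (a small deep ensemble; tames init-to-init training variance).
    """
    labels = np.asarray(labels)
    sample_ids = sample_ids or plan.sample_ids
    run_template = run_template or TrainRun()
    oof_rows, fold_records, models = [], [], []
    for rep in range(plan.n_repeats):
        for fold in range(plan.n_folds):
            train_ix = plan.train_indices(rep, fold)
            test_ix = plan.test_indices(rep, fold)
            fold_seed = int(substream(plan.seed, f"rep{rep}", f"fold{fold}")
                            .integers(2 ** 31))
            train_batch, test_batch, _ = _standardized_fold_batches(
                raw, labels, sample_ids, train_ix, test_ix)
            fit_loc, val_loc = split_inner_validation(
                np.arange(len(train_ix)), train_batch.labels,
                frac=run_template.inner_val_frac, seed=fold_seed)
            fit_batch = train_batch.subset(fit_loc)
            val_batch = train_batch.subset(val_loc)
            member_probs = []
            for member in range(max(1, n_ensemble)):
                mseed = fold_seed if member == 0 else int(
                    substream(fold_seed, f"member{member}").integers(2 ** 31))
                cfg = ModelConfig(**{**config.to_dict(), "seed": mseed})
                model = CrossOmicsNet(graph, cfg, rng=substream(mseed, "init"))
                run = TrainRun(**{**run_template.__dict__, "seed": mseed,
                                  "history": []})
                result = train_model(model, fit_batch, val_batch, run)
                member_probs.append(predict_probs(
                    model, test_batch, set(result["always_masked"]),
                    snapshots=result["snapshots"]))
            probs = np.mean(member_probs, axis=0)
            for j, ix in enumerate(test_ix):
                oof_rows.append({"sample_id": sample_ids[ix], "repeat": rep,
                                 "fold": fold, "label": int(labels[ix]),
                                 **{f"p{k}": probs[j, k]
                                    for k in range(probs.shape[1])}})
            pred = probs.argmax(axis=1)
            fold_records.append({"repeat": rep, "fold": fold,
                                 "accuracy": float((pred == labels[test_ix]).mean()),
                                 "best_val": result["best_val"],
                                 "epochs": result["epochs_run"]})
            if keep_models:
                models.append(((rep, fold), model, result))
    oof = pd.DataFrame(oof_rows)
    out = {"oof": oof, "folds": pd.DataFrame(fold_records),
           "accuracy": oof_accuracy(oof)}
    if keep_models:
        out["models"] = models
    return out


def oof_accuracy(oof: pd.DataFrame) -> float:
    prob_cols = sorted(c for c in oof.columns if c.startswith("p")
                       and c[1:].isdigit())
    pred = oof[prob_cols].to_numpy().argmax(axis=1)
    return float((pred == oof["label"].to_numpy()).mean())
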