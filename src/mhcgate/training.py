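"""Joint training of the presentation and binding-affinity tasks.

The two tasks have losses of different character (binary cross-entropy on
mass-spectrometry hit labels vs mean squared error on model-scale affinities),
so naive summation lets one task dominate. Two mechanisms counter this:

* *Uncertainty weighting*: each task loss L_i is scaled by a learned
  precision, total = exp(-s_i) L_i + s_i with s_i = log sigma_i^2 a trainable
  scalar, so the optimizer itself balances the tasks.
* *Conflict-averse gradient combination (CAGrad)*: on parameters shared by
  both tasks, the update direction is not the mean of the two task gradients
  but the direction inside a ball of radius c*||g0|| around the mean g0 that
  maximizes the worst-case task improvement. Task-specific branches receive
  their own task's gradient unchanged.

Class imbalance is handled by synthesizing decoy negatives every epoch:
random peptides (length 8-15, residues drawn from the positive pool's
empirical composition) paired with random training alleles, labelled as
non-presented. After `negative_recycle_epochs` epochs the previously
generated decoy sets are recycled in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ._nn import AdamW
from .encoders import (AMINO_ACIDS, MAX_PEPTIDE_LEN, MIN_PEPTIDE_LEN,
                       PseudoSequenceTable, encode_allele, encode_peptide)
from .model import GatedMultiTaskModel, nM_to_model_output

MS = "MS"
BA = "BA"

_EPS = 1e-7


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainingExample:
    """One training record: an MS presentation hit/decoy or a BA measurement."""

    peptide: str
    allele: str
    task: str  # MS | BA
    label: int | None = None            # 0/1, MS only
    measurement_nM: float | None = None  # positive nM, BA only

    def __post_init__(self):
        if self.task == MS:
            if self.label not in (0, 1) or self.measurement_nM is not None:
                raise ValueError(
                    f"MS example needs label in {{0,1}} and no nM: {self}")
        elif self.task == BA:
            if self.measurement_nM is None or self.measurement_nM <= 0 \
                    or self.label is not None:
                raise ValueError(
                    f"BA example needs positive measurement_nM and no label: {self}")
        else:
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class LossState:
    """Learned log-variances of the two task losses."""

    s_np: float = 0.0
    s_ba: float = 0.0


@dataclass
class TrainingConfig:
    batch_size: int = 1024
    lr: float = 1e-3
    weight_decay: float = 1e-2
    epochs: int = 80
    val_fraction: float = 0.10
    cagrad_c: float = 0.5
    negative_recycle_epochs: int = 40
    n_synthetic_negatives: int | None = None  # None: balance classes
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.cagrad_c < 0:
            raise ValueError("cagrad_c must be nonnegative")


def desk_scale_config(seed: int = 0) -> TrainingConfig:
    """Training configuration for desk-scale (~5k example) synthetic runs.

    The full-data defaults (batch 1024, lr 1e-3) are tuned to corpora of
    hundreds of thousands of examples; at a few thousand examples they give
    too few optimizer steps per epoch. This uses batch 128 and lr 5e-3,
    selected by validation loss, with the 30-epoch cap of a quick run.
    """
    return TrainingConfig(batch_size=128, lr=5e-3, epochs=30, patience=8,
                          seed=seed)


@dataclass
class TrainingHistory:
    train_np: list[float] = field(default_factory=list)
    train_ba: list[float] = field(default_factory=list)
    val_np: list[float] = field(default_factory=list)
    val_ba: list[float] = field(default_factory=list)
    val_total: list[float] = field(default_factory=list)
    converged: bool = False
    best_epoch: int = -1

    def __len__(self):
        return len(self.val_total)


# ---------------------------------------------------------------------------
# Loss balancing and gradient combination


def uncertainty_weighted_loss(loss_np: float, loss_ba: float,
                              state: LossState) -> float:
    """exp(-s_np) L_np + s_np + exp(-s_ba) L_ba + s_ba."""
    for loss in (loss_np, loss_ba):
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite task loss: {loss}")
    return (np.exp(-state.s_np) * loss_np + state.s_np
            + np.exp(-state.s_ba) * loss_ba + state.s_ba)


def cagrad_direction(g_np: np.ndarray, g_ba: np.ndarray,
                     c: float) -> np.ndarray:
    """Two-task conflict-averse update direction.

    With g0 = (g_np + g_ba)/2, finds the mixture weight w in [0, 1]
    minimizing <g_w, g0> + c ||g0|| ||g_w|| for g_w = w g_np + (1-w) g_ba,
    then returns d = g0 + c ||g0|| g_w / ||g_w||. Guarantees
    ||d - g0|| <= c ||g0||; c = 0 reduces to the mean gradient.
    """
    g_np = np.asarray(g_np, dtype=float)
    g_ba = np.asarray(g_ba, dtype=float)
    if g_np.shape != g_ba.shape:
        raise ValueError("task gradients must have equal shapes")
    g0 = 0.5 * (g_np + g_ba)
    norm_g0 = np.linalg.norm(g0)
    if c == 0.0 or norm_g0 == 0.0:
        return g0

    def g_w(w: float) -> np.ndarray:
        return w * g_np + (1.0 - w) * g_ba

    def objective(w: float) -> float:
        gw = g_w(w)
        return float(gw @ g0) + c * norm_g0 * float(np.linalg.norm(gw))

    res = minimize_scalar(objective, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-12})
    # the dual objective can be flat near endpoints; check them explicitly
    w_star = min([0.0, 1.0, float(res.x)], key=objective)
    gw = g_w(w_star)
    norm_gw = np.linalg.norm(gw)
    if norm_gw == 0.0:
        return g0
    return g0 + c * norm_g0 * gw / norm_gw


# ---------------------------------------------------------------------------
# Data handling


def sample_synthetic_negatives(positive_ms: list[TrainingExample], n: int,
                               rng: np.random.Generator) -> list[TrainingExample]:
    """Decoy MS negatives: random peptides from the positive pool's residue
    composition (lengths uniform on 8-15), paired with uniformly drawn
    training alleles."""
    if n <= 0:
        return []
    if not positive_ms:
        raise ValueError("positive_ms must be nonempty")
    pool = "".join(ex.peptide for ex in positive_ms)
    residues = np.array(list(AMINO_ACIDS))
    counts = np.array([pool.count(aa) for aa in AMINO_ACIDS], dtype=float)
    freqs = counts / counts.sum()
    alleles = sorted({ex.allele for ex in positive_ms})
    lengths = rng.integers(MIN_PEPTIDE_LEN, MAX_PEPTIDE_LEN + 1, size=n)
    allele_idx = rng.integers(0, len(alleles), size=n)
    out = []
    for length, ai in zip(lengths, allele_idx):
        pep = "".join(rng.choice(residues, size=length, p=freqs))
        out.append(TrainingExample(peptide=pep, allele=alleles[ai], task=MS,
                                   label=0))
    return out


def split_train_val(data: list[TrainingExample], fraction: float,
                    rng: np.random.Generator):
    """Disjoint task-stratified split; `fraction` is the training share."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    train: list[TrainingExample] = []
    val: list[TrainingExample] = []
    for task in (MS, BA):
        idx = [i for i, ex in enumerate(data) if ex.task == task]
        if not idx:
            continue
        if len(idx) < 2:
            raise TrainingError(
                f"cannot stratify: task {task} has fewer than 2 examples")
        idx = np.array(idx)
        rng.shuffle(idx)
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(data[i] for i in idx[:n_train])
        val.extend(data[i] for i in idx[n_train:])
    return train, val


class _EncodedSet:
    """Pre-encoded examples as dense batch arrays."""

    def __init__(self, examples: list[TrainingExample],
                 table: PseudoSequenceTable):
        self.examples = examples
        allele_mats: dict[str, np.ndarray] = {}
        pep = np.empty((len(examples), 45, 21), dtype=np.float32)
        alle = np.empty((len(examples), 37, 21), dtype=np.float32)
        is_ms = np.zeros(len(examples), dtype=bool)
        target = np.zeros(len(examples), dtype=np.float64)
        for i, ex in enumerate(examples):
            pep[i] = encode_peptide(ex.peptide)
            if ex.allele not in allele_mats:
                allele_mats[ex.allele] = encode_allele(ex.allele, table)
            alle[i] = allele_mats[ex.allele]
            if ex.task == MS:
                is_ms[i] = True
                target[i] = ex.label
            else:
                target[i] = nM_to_model_output(ex.measurement_nM)
        self.pep = pep
        self.allele = alle
        self.is_ms = is_ms
        self.target = target

    def __len__(self):
        return len(self.examples)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _task_losses(model: GatedMultiTaskModel, enc: _EncodedSet,
                 batch_size: int = 1024) -> tuple[float, float]:
    """Unweighted validation losses (BCE on MS rows, MSE on BA rows)."""
    np_prob, ba_out = model.predict_batch(enc.pep, enc.allele,
                                          batch_size=batch_size)
    ms = enc.is_ms
    loss_np = _bce(np_prob[ms], enc.target[ms]) if ms.any() else 0.0
    loss_ba = float(np.mean((ba_out[~ms] - enc.target[~ms]) ** 2)) \
        if (~ms).any() else 0.0
    return loss_np, loss_ba


def freeze_ba_branch(model: GatedMultiTaskModel) -> GatedMultiTaskModel:
    """Mark the BA expert and BA tower non-trainable (the Drop-BA ablation)."""
    model.frozen_parameters = frozenset(model.ba_branch_parameter_names())
    return model


def fit(data: list[TrainingExample], model: GatedMultiTaskModel,
        config: TrainingConfig, table: PseudoSequenceTable,
        ) -> tuple[GatedMultiTaskModel, TrainingHistory]:
    """Train the joint model; returns the model at its best validation epoch."""
    rng = np.random.default_rng(config.seed)
    frozen = frozenset(getattr(model, "frozen_parameters", frozenset()))
    has_ba = any(ex.task == BA for ex in data)
    if not has_ba and not frozen:
        raise TrainingError("no BA examples; freeze the BA branch or add data")
    if not any(ex.task == MS for ex in data):
        raise TrainingError("no MS examples in training data")

    train, val = split_train_val(data, 1.0 - config.val_fraction, rng)
    positives = [ex for ex in train if ex.task == MS and ex.label == 1]
    n_existing_neg = sum(1 for ex in train if ex.task == MS and ex.label == 0)
    n_neg = config.n_synthetic_negatives
    if n_neg is None:
        n_neg = max(0, len(positives) - n_existing_neg)

    enc_train = _EncodedSet(train, table)
    enc_val = _EncodedSet(val, table)

    params = model.parameters()
    shared_names = model.shared_parameter_names()
    state = LossState()
    aux = {"s_np": np.array(state.s_np), "s_ba": np.array(state.s_ba)}
    optimizer = AdamW(lr=config.lr, weight_decay=config.weight_decay)
    history = TrainingHistory()
    neg_sets: list[_EncodedSet] = []
    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    patience_left = config.patience

    for epoch in range(config.epochs):
        # per-epoch decoy negatives, recycled after the configured horizon
        if n_neg > 0 and positives:
            if epoch < config.negative_recycle_epochs:
                negs = sample_synthetic_negatives(positives, n_neg, rng)
                neg_sets.append(_EncodedSet(negs, table))
            enc_neg = neg_sets[epoch % len(neg_sets)]
            pep = np.concatenate([enc_train.pep, enc_neg.pep])
            alle = np.concatenate([enc_train.allele, enc_neg.allele])
            is_ms = np.concatenate([enc_train.is_ms, enc_neg.is_ms])
            target = np.concatenate([enc_train.target, enc_neg.target])
        else:
            pep, alle = enc_train.pep, enc_train.allele
            is_ms, target = enc_train.is_ms, enc_train.target

        order = rng.permutation(len(target))
        ep_np, ep_ba, n_np_batches, n_ba_batches = 0.0, 0.0, 0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            b_ms = is_ms[idx]
            np_prob, ba_out, _, _, cache = model.forward_batch(pep[idx],
                                                               alle[idx])
            w_np = np.exp(-float(aux["s_np"]))
            w_ba = np.exp(-float(aux["s_ba"]))

            d_np = np.zeros_like(np_prob)
            loss_np = 0.0
            if b_ms.any():
                y = target[idx][b_ms]
                p = np.clip(np_prob[b_ms], _EPS, 1.0 - _EPS)
                loss_np = _bce(np_prob[b_ms], y)
                d_np[b_ms] = w_np * (p - y) / (p * (1.0 - p)) / b_ms.sum()
            d_ba = np.zeros_like(ba_out)
            loss_ba = 0.0
            if (~b_ms).any():
                t = target[idx][~b_ms]
                loss_ba = float(np.mean((ba_out[~b_ms] - t) ** 2))
                d_ba[~b_ms] = w_ba * 2.0 * (ba_out[~b_ms] - t) / (~b_ms).sum()
            if not np.isfinite(loss_np) or not np.isfinite(loss_ba):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: NP={loss_np}, BA={loss_ba}")

            # per-task gradients on shared parameters, then CAGrad surgery
            model.zero_grad()
            model.backward_batch(cache, d_np_prob=d_np)
            grads_np = {k: v.copy() for k, v in model.gradients().items()}
            model.zero_grad()
            model.backward_batch(cache, d_ba_out=d_ba)
            grads_ba = model.gradients()

            combined: dict[str, np.ndarray] = {}
            flat_np = np.concatenate([grads_np[k].ravel()
                                      for k in shared_names])
            flat_ba = np.concatenate([grads_ba[k].ravel()
                                      for k in shared_names])
            # the task losses enter shared params as a sum, so the per-task
            # shared gradients are combined directly (mean + conflict-averse
            # correction), while branch params keep their own task gradient
            flat = cagrad_direction(2.0 * flat_np, 2.0 * flat_ba,
                                    config.cagrad_c)
            offset = 0
            for k in shared_names:
                size = params[k].size
                combined[k] = flat[offset:offset + size].reshape(params[k].shape)
                offset += size
            for k in params:
                if k not in combined:
                    combined[k] = grads_np[k] + grads_ba[k]

            combined["s_np"] = np.array(
                (1.0 - w_np * loss_np) if b_ms.any() else 0.0)
            combined["s_ba"] = np.array(
                (1.0 - w_ba * loss_ba) if (~b_ms).any() else 0.0)
            all_params = dict(params)
            all_params.update(aux)
            optimizer.step(all_params, combined, frozen=frozen,
                           no_decay=frozenset(aux))
            if b_ms.any():
                ep_np += loss_np
                n_np_batches += 1
            if (~b_ms).any():
                ep_ba += loss_ba
                n_ba_batches += 1

        history.train_np.append(ep_np / max(n_np_batches, 1))
        history.train_ba.append(ep_ba / max(n_ba_batches, 1))
        val_np, val_ba = _task_losses(model, enc_val,
                                      batch_size=config.batch_size)
        val_total = val_np + val_ba
        history.val_np.append(val_np)
        history.val_ba.append(val_ba)
        history.val_total.append(val_total)

        if val_total < best_val - 1e-6:
            best_val = val_total
            history.best_epoch = epoch
            best_params = {k: v.copy() for k, v in params.items()}
            patience_left = config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                history.converged = True
                break

    state.s_np = float(aux["s_np"])
    state.s_ba = float(aux["s_ba"])
    if best_params is not None:
        for k, p in params.items():
            p[...] = best_params[k]
    model.loss_state = state
    return model, history
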