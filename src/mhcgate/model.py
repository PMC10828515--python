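"""The multi-task gated-expert presentation model.

Three stages:

1. *Embedding*: the 45x21 peptide matrix and 37x21 allele pseudo-sequence
   matrix each pass through a separate 2-layer bidirectional LSTM (hidden 32).
   Each stream is summarized by the last layer's final forward and backward
   hidden states (64 dims), and the two summaries are concatenated into a
   128-dim pair feature.
2. *Experts*: three MLP experts (hidden 128 -> output 64) — one for the
   presentation task, one for the binding-affinity task, one shared. A
   per-task gate (dense + softmax over {task expert, shared expert}) mixes
   the task expert with the shared expert by a convex combination.
3. *Prediction towers*: two MLP heads (hidden 32 -> 1, sigmoid) produce the
   presentation probability and the model-scale binding affinity.

Model-scale affinity y relates to nanomolar affinity by y = 1 - log_50000(nM),
so y = 1 means 1 nM (strong binder) and y = 0 means 50,000 nM (non-binder).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from .encoders import EncodedPair, N_CHANNELS, PEPTIDE_ROWS, PSEUDO_LENGTH

AFFINITY_BASE = 50000.0

FEATURE_DIM = 128


class DomainError(ValueError):
    pass


def model_output_to_nM(y) -> np.ndarray | float:
    """Invert the model-scale affinity to nanomolar: nM = 50000^(1 - y).

    y must lie in [0, 1]; the boundaries (unreachable through a sigmoid but
    meaningful analytically) give 50000 nM at y=0 and 1 nM at y=1.
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DomainError(f"model-scale affinity must be in [0, 1], got {y}")
    out = AFFINITY_BASE ** (1.0 - arr)
    return float(out) if np.isscalar(y) else out


def nM_to_model_output(nM) -> np.ndarray | float:
    """Map nanomolar affinity to model scale: clamp(1 - log_50000(nM), 0, 1)."""
    arr = np.asarray(nM, dtype=float)
    if np.any(arr <= 0):
        raise DomainError(f"nM affinity must be positive, got {nM}")
    out = np.clip(1.0 - np.log(arr) / np.log(AFFINITY_BASE), 0.0, 1.0)
    return float(out) if np.isscalar(nM) else out


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; the defaults are the base model."""

    lstm_hidden: int = 32
    lstm_layers: int = 2
    expert_hidden: int = 128
    expert_out: int = 64
    expert_depth: int = 1
    tower_hidden: int = 32
    seed: int = 0

    def __post_init__(self):
        for name in ("lstm_hidden", "lstm_layers", "expert_hidden",
                     "expert_out", "expert_depth", "tower_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GateWeights:
    np_gate: tuple[float, float]  # (w_task, w_shared), sums to 1
    ba_gate: tuple[float, float]


@dataclass
class ForwardOutput:
    np_prob: float
    ba_out: float
    gates: GateWeights


class _MLP(_nn.Layer):
    """ReLU-hidden MLP with a linear output layer."""

    def __init__(self, d_in: int, hidden: int, d_out: int, depth: int,
                 rng: np.random.Generator):
        super().__init__()
        self.layers: list[_nn.Linear] = []
        d = d_in
        for _ in range(depth):
            self.layers.append(_nn.Linear(d, hidden, rng))
            d = hidden
        self.layers.append(_nn.Linear(d, d_out, rng))
        self._register()

    def _register(self):
        for i, lin in enumerate(self.layers):
            for name, p in lin.params.items():
                self.params[f"{i}.{name}"] = p
        self.zero_grad()

    def zero_grad(self):
        super().zero_grad()
        for lin in getattr(self, "layers", []):
            lin.zero_grad()

    def forward(self, x):
        caches = []
        out = x
        for lin in self.layers[:-1]:
            out, c_lin = lin.forward(out)
            out, mask = _nn.relu(out)
            caches.append((c_lin, mask))
        out, c_last = self.layers[-1].forward(out if caches else x)
        caches.append((c_last, None))
        return out, caches

    def backward(self, dout, caches):
        d = self.layers[-1].backward(dout, caches[-1][0])
        for lin, (c_lin, mask) in zip(reversed(self.layers[:-1]),
                                      reversed(caches[:-1])):
            d = _nn.relu_backward(d, mask)
            d = lin.backward(d, c_lin)
        for i, lin in enumerate(self.layers):
            for name, g in lin.grads.items():
                self.grads[f"{i}.{name}"] = g
        return d


class _Tower(_nn.Layer):
    """Prediction head: hidden (ReLU) -> scalar sigmoid output."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = _nn.Linear(d_in, hidden, rng)
        self.fc2 = _nn.Linear(hidden, 1, rng)
        for prefix, lin in (("fc1", self.fc1), ("fc2", self.fc2)):
            for name, p in lin.params.items():
                self.params[f"{prefix}.{name}"] = p
        self.zero_grad()

    def zero_grad(self):
        super().zero_grad()
        if hasattr(self, "fc1"):
            self.fc1.zero_grad()
            self.fc2.zero_grad()

    def forward(self, x):
        h, c1 = self.fc1.forward(x)
        h, mask = _nn.relu(h)
        logit, c2 = self.fc2.forward(h)
        prob = _nn.sigmoid(logit[:, 0])
        return prob, (c1, mask, c2, prob)

    def backward(self, dprob, cache):
        c1, mask, c2, prob = cache
        dlogit = (dprob * prob * (1.0 - prob))[:, None]
        d = self.fc2.backward(dlogit, c2)
        d = _nn.relu_backward(d, mask)
        d = self.fc1.backward(d, c1)
        for prefix, lin in (("fc1", self.fc1), ("fc2", self.fc2)):
            for name, g in lin.grads.items():
                self.grads[f"{prefix}.{name}"] = g
        return d


class GatedMultiTaskModel:
    """Joint presentation (classification) + binding affinity (regression) model."""

    # parameter-name prefixes owned exclusively by the BA branch
    BA_BRANCH_PREFIXES = ("ba_expert.", "ba_tower.")
    # prefixes shared between the two tasks (embedding + shared expert);
    # the per-task gates receive gradient only from their own task
    SHARED_PREFIXES = ("pep_encoder.", "allele_encoder.", "shared_expert.",
                      "np_gate.", "ba_gate.")

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        summary_dim = 2 * cfg.lstm_hidden
        feature_dim = 2 * summary_dim
        self.pep_encoder = _nn.BiLSTMStack(N_CHANNELS, cfg.lstm_hidden,
                                           cfg.lstm_layers, rng)
        self.allele_encoder = _nn.BiLSTMStack(N_CHANNELS, cfg.lstm_hidden,
                                              cfg.lstm_layers, rng)
        self.np_expert = _MLP(feature_dim, cfg.expert_hidden, cfg.expert_out,
                              cfg.expert_depth, rng)
        self.ba_expert = _MLP(feature_dim, cfg.expert_hidden, cfg.expert_out,
                              cfg.expert_depth, rng)
        self.shared_expert = _MLP(feature_dim, cfg.expert_hidden,
                                  cfg.expert_out, cfg.expert_depth, rng)
        self.np_gate = _nn.Linear(feature_dim, 2, rng)
        self.ba_gate = _nn.Linear(feature_dim, 2, rng)
        self.np_tower = _Tower(cfg.expert_out, cfg.tower_hidden, rng)
        self.ba_tower = _Tower(cfg.expert_out, cfg.tower_hidden, rng)
        self._modules = {
            "pep_encoder": self.pep_encoder,
            "allele_encoder": self.allele_encoder,
            "np_expert": self.np_expert,
            "ba_expert": self.ba_expert,
            "shared_expert": self.shared_expert,
            "np_gate": self.np_gate,
            "ba_gate": self.ba_gate,
            "np_tower": self.np_tower,
            "ba_tower": self.ba_tower,
        }

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for mod_name, mod in self._modules.items():
            for name, p in mod.params.items():
                out[f"{mod_name}.{name}"] = p
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for mod_name, mod in self._modules.items():
            for name, g in mod.grads.items():
                out[f"{mod_name}.{name}"] = g
        return out

    def zero_grad(self) -> None:
        for mod in self._modules.values():
            mod.zero_grad()

    def shared_parameter_names(self) -> list[str]:
        return [k for k in self.parameters()
                if k.startswith(self.SHARED_PREFIXES)]

    def ba_branch_parameter_names(self) -> list[str]:
        return [k for k in self.parameters()
                if k.startswith(self.BA_BRANCH_PREFIXES)]

    # -- forward / backward -------------------------------------------------

    def embed_batch(self, pep: np.ndarray, allele: np.ndarray):
        if pep.shape[1:] != (PEPTIDE_ROWS, N_CHANNELS):
            raise ValueError(f"peptide batch must be (B, {PEPTIDE_ROWS}, "
                             f"{N_CHANNELS}), got {pep.shape}")
        if allele.shape[1:] != (PSEUDO_LENGTH, N_CHANNELS):
            raise ValueError(f"allele batch must be (B, {PSEUDO_LENGTH}, "
                             f"{N_CHANNELS}), got {allele.shape}")
        pep = np.ascontiguousarray(pep, dtype=_nn.DTYPE)
        allele = np.ascontiguousarray(allele, dtype=_nn.DTYPE)
        pep_sum, c_pep = self.pep_encoder.forward(pep)
        all_sum, c_all = self.allele_encoder.forward(allele)
        feature = np.concatenate([pep_sum, all_sum], axis=1)
        return feature, (c_pep, c_all)

    def _gate_combine(self, feature, expert: _MLP, gate: _nn.Linear):
        e_task, c_task = expert.forward(feature)
        e_shared, c_shared = self.shared_expert.forward(feature)
        logits, c_gate = gate.forward(feature)
        w = _nn.softmax(logits)  # (B, 2): [w_task, w_shared]
        combined = w[:, :1] * e_task + w[:, 1:] * e_shared
        return combined, w, (c_task, c_shared, c_gate, e_task, e_shared, w)

    def forward_batch(self, pep: np.ndarray, allele: np.ndarray):
        """Run a batch; returns (np_prob, ba_out, gates_np, gates_ba, cache)."""
        feature, c_embed = self.embed_batch(pep, allele)
        np_comb, w_np, c_np = self._gate_combine(feature, self.np_expert,
                                                 self.np_gate)
        ba_comb, w_ba, c_ba = self._gate_combine(feature, self.ba_expert,
                                                 self.ba_gate)
        np_prob, c_np_tower = self.np_tower.forward(np_comb)
        ba_out, c_ba_tower = self.ba_tower.forward(ba_comb)
        cache = (c_embed, c_np, c_ba, c_np_tower, c_ba_tower, feature.shape)
        return np_prob, ba_out, w_np, w_ba, cache

    def _gate_backward(self, dcomb, cache, expert: _MLP, gate: _nn.Linear):
        c_task, c_shared, c_gate, e_task, e_shared, w = cache
        d_e_task = dcomb * w[:, :1]
        d_e_shared = dcomb * w[:, 1:]
        dw = np.stack([(dcomb * e_task).sum(axis=1),
                       (dcomb * e_shared).sum(axis=1)], axis=1)
        dlogits = w * (dw - (dw * w).sum(axis=1, keepdims=True))
        dfeature = gate.backward(dlogits, c_gate)
        dfeature += expert.backward(d_e_task, c_task)
        dfeature += self.shared_expert.backward(d_e_shared, c_shared)
        return dfeature

    def backward_batch(self, cache, d_np_prob=None, d_ba_out=None) -> None:
        """Accumulate parameter gradients for the given output gradients.

        Pass only one of d_np_prob / d_ba_out to obtain that task's gradient
        in isolation (as needed for per-task gradient combination).
        """
        c_embed, c_np, c_ba, c_np_tower, c_ba_tower, feat_shape = cache
        dfeature = np.zeros(feat_shape, dtype=_nn.DTYPE)
        if d_np_prob is not None:
            dcomb = self.np_tower.backward(
                np.asarray(d_np_prob, dtype=_nn.DTYPE), c_np_tower)
            dfeature += self._gate_backward(dcomb, c_np, self.np_expert,
                                            self.np_gate)
        if d_ba_out is not None:
            dcomb = self.ba_tower.backward(
                np.asarray(d_ba_out, dtype=_nn.DTYPE), c_ba_tower)
            dfeature += self._gate_backward(dcomb, c_ba, self.ba_expert,
                                            self.ba_gate)
        half = feat_shape[1] // 2
        c_pep, c_all = c_embed
        self.pep_encoder.backward(np.ascontiguousarray(dfeature[:, :half]),
                                  c_pep)
        self.allele_encoder.backward(np.ascontiguousarray(dfeature[:, half:]),
                                     c_all)

    # -- single-pair convenience -------------------------------------------

    def forward_pair(self, pair: EncodedPair) -> ForwardOutput:
        np_prob, ba_out, w_np, w_ba, _ = self.forward_batch(
            pair.peptide_matrix[None], pair.allele_matrix[None])
        return ForwardOutput(
            np_prob=float(np_prob[0]),
            ba_out=float(ba_out[0]),
            gates=GateWeights(np_gate=(float(w_np[0, 0]), float(w_np[0, 1])),
                              ba_gate=(float(w_ba[0, 0]), float(w_ba[0, 1]))),
        )

    def predict_batch(self, pep: np.ndarray, allele: np.ndarray,
                      batch_size: int = 512):
        """Memory-bounded inference; returns (np_prob, ba_out) arrays.

        Allele matrices are deduplicated before encoding: scoring many
        peptides against few alleles (the common prediction workload) runs
        the allele encoder once per distinct allele.
        """
        allele = np.ascontiguousarray(allele, dtype=_nn.DTYPE)
        keys = [a.tobytes() for a in allele]
        unique: dict[bytes, int] = {}
        for k in keys:
            unique.setdefault(k, len(unique))
        uniq_mats = np.empty((len(unique),) + allele.shape[1:], dtype=_nn.DTYPE)
        for k, i in unique.items():
            uniq_mats[i] = np.frombuffer(k, dtype=_nn.DTYPE).reshape(
                allele.shape[1:])
        uniq_sum, _ = self.allele_encoder.forward(uniq_mats)
        allele_idx = np.array([unique[k] for k in keys])

        probs, bas = [], []
        pep = np.ascontiguousarray(pep, dtype=_nn.DTYPE)
        for start in range(0, pep.shape[0], batch_size):
            stop = start + batch_size
            pep_sum, _ = self.pep_encoder.forward(pep[start:stop])
            feature = np.concatenate(
                [pep_sum, uniq_sum[allele_idx[start:stop]]], axis=1)
            np_comb, _, _ = self._gate_combine(feature, self.np_expert,
                                               self.np_gate)
            ba_comb, _, _ = self._gate_combine(feature, self.ba_expert,
                                               self.ba_gate)
            probs.append(self.np_tower.forward(np_comb)[0])
            bas.append(self.ba_tower.forward(ba_comb)[0])
        return np.concatenate(probs), np.concatenate(bas)

    # -- checkpointing -------------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, path) -> None:
        meta = {"version": self.CHECKPOINT_VERSION, "config": asdict(self.config)}
        arrays = {k.replace(".", "__"): v for k, v in self.parameters().items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "GatedMultiTaskModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(ModelConfig(**meta["config"]))
            params = model.parameters()
            for key, p in params.items():
                p[...] = data[key.replace(".", "__")]
        return model

    def weights_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for key in sorted(self.parameters()):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.parameters()[key]).tobytes())
        return h.hexdigest()[:16]
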