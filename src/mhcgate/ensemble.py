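"""Ensembling over architecture variants.

Ten configurations (the base model plus nine variants over expert width,
expert depth and tower width) are trained independently; a greedy stepwise
pass then selects up to five members, at each step adding the model whose
inclusion most reduces the validation presentation loss of the averaged
prediction, stopping early if no candidate improves it. The ensemble
prediction is the arithmetic mean of member presentation probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import GatedMultiTaskModel, ModelConfig

_EPS = 1e-7


@dataclass
class EnsembleSpec:
    variant_configs: list[ModelConfig]
    selected: list[int] = field(default_factory=list)
    combine: str = "mean"

    def __post_init__(self):
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected member indices must be unique")
        for i in self.selected:
            if not 0 <= i < len(self.variant_configs):
                raise ValueError(f"selected index {i} out of range")


def make_variant_configs(base: ModelConfig) -> list[ModelConfig]:
    """The base configuration plus nine variants of the expert and
    prediction layers (width and depth); 10 distinct configs, base first."""
    configs = [base]
    grid = [(eh, ed, th)
            for eh in (64, 128, 256)
            for ed in (1, 2)
            for th in (32, 64)]
    for i, (eh, ed, th) in enumerate(grid):
        cfg = replace(base, expert_hidden=eh, expert_depth=ed,
                      tower_hidden=th, seed=base.seed + i + 1)
        if all(cfg != existing for existing in configs):
            configs.append(cfg)
        if len(configs) == 10:
            break
    return configs


def _mean_bce(prob_rows: list[np.ndarray], hits: np.ndarray) -> float:
    p = np.clip(np.mean(prob_rows, axis=0), _EPS, 1.0 - _EPS)
    return float(-np.mean(hits * np.log(p) + (1.0 - hits) * np.log(1.0 - p)))


def stepwise_select(members: list[GatedMultiTaskModel], val_pep: np.ndarray,
                    val_allele: np.ndarray, val_hits: np.ndarray,
                    k: int = 5) -> EnsembleSpec:
    """Greedy forward selection of up to k members by validation NP loss of
    the averaged prediction; stops early when no candidate reduces the loss."""
    if len(val_hits) == 0:
        raise ValueError("validation set must be nonempty")
    if len(members) < k:
        raise ValueError(f"need at least k={k} members, got {len(members)}")
    member_probs = [m.predict_batch(val_pep, val_allele)[0] for m in members]
    hits = np.asarray(val_hits, dtype=float)
    selected: list[int] = []
    best_loss = np.inf
    while len(selected) < k:
        candidates = [i for i in range(len(members)) if i not in selected]
        losses = [(_mean_bce([member_probs[j] for j in selected + [i]], hits), i)
                  for i in candidates]
        loss, pick = min(losses)
        if loss >= best_loss - 1e-12:
            break
        best_loss = loss
        selected.append(pick)
    return EnsembleSpec(variant_configs=[m.config for m in members],
                        selected=selected)


def ensemble_predict(models: list[GatedMultiTaskModel], pep: np.ndarray,
                     allele: np.ndarray) -> np.ndarray:
    """Arithmetic mean of member presentation probabilities."""
    if not models:
        raise RuntimeError("empty ensemble")
    return np.mean([m.predict_batch(pep, allele)[0] for m in models], axis=0)


class Ensemble:
    """A selected set of trained members acting as one presentation scorer."""

    def __init__(self, spec: EnsembleSpec, members: list[GatedMultiTaskModel]):
        if not spec.selected:
            raise RuntimeError("ensemble has no selected members")
        self.spec = spec
        self.members = [members[i] for i in spec.selected]

    def predict_batch(self, pep: np.ndarray, allele: np.ndarray):
        probs = ensemble_predict(self.members, pep, allele)
        bas = np.mean([m.predict_batch(pep, allele)[1] for m in self.members],
                      axis=0)
        return probs, bas

    def weights_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for m in self.members:
            h.update(m.weights_hash().encode())
        return h.hexdigest()[:16]
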