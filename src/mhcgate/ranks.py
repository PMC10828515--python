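"""Percentile-rank calibration of presentation scores.

Raw presentation probabilities are not comparable across alleles: an easy
allele may give every peptide a high score. Scores are therefore converted
to percentile ranks against the score distribution of random natural
peptides for the same allele — by default 50,000 peptides of each length
8-12, residues drawn i.i.d. from human-proteome-like amino-acid background
frequencies, pooled across lengths. A rank of r% means r% of random
background peptides score at least as high; lower rank = stronger predicted
presentation.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import numpy as np

from .encoders import AMINO_ACIDS, PseudoSequenceTable, encode_allele, encode_peptide
from .model import GatedMultiTaskModel

DEFAULT_LENGTHS = (8, 9, 10, 11, 12)
DEFAULT_N_PER_LENGTH = 50_000

# Human proteome amino-acid frequencies (UniProt-style composition, percent),
# ordered as AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY".
HUMAN_PROTEOME_FREQS = np.array([
    7.0, 2.3, 4.7, 7.1, 3.7, 6.6, 2.6, 4.3, 5.7, 10.0,
    2.1, 3.6, 6.3, 4.8, 5.6, 8.3, 5.4, 6.0, 1.2, 2.7,
]) / 100.0


class RankError(RuntimeError):
    pass


def generate_random_peptides(n_per_length: int, lengths=DEFAULT_LENGTHS,
                             background_freqs: np.ndarray | None = None,
                             rng: np.random.Generator | None = None) -> list[str]:
    """Random natural peptides: n_per_length per length, residues i.i.d.
    from the background frequency table."""
    if n_per_length <= 0:
        raise ValueError("n_per_length must be positive")
    freqs = HUMAN_PROTEOME_FREQS if background_freqs is None \
        else np.asarray(background_freqs, dtype=float)
    if freqs.shape != (20,) or not np.isclose(freqs.sum(), 1.0, atol=1e-6) \
            or np.any(freqs < 0):
        raise ValueError("background_freqs must be 20 nonnegative values "
                         "summing to 1")
    rng = rng or np.random.default_rng()
    residues = np.array(list(AMINO_ACIDS))
    peptides = []
    for length in lengths:
        draws = rng.choice(residues, size=(n_per_length, length), p=freqs)
        peptides.extend("".join(row) for row in draws)
    return peptides


@dataclass
class RankDatabase:
    """Descending-sorted presentation scores of random peptides for one allele."""

    allele: str
    scores: np.ndarray  # sorted descending
    n_per_length: int
    lengths: tuple[int, ...]
    seed: int | None = None
    model_hash: str | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size == 0:
            raise RankError("rank database must be nonempty")
        if np.any(np.diff(self.scores) > 0):
            raise RankError("rank database scores must be sorted descending")

    def __len__(self):
        return self.scores.size

    def save(self, path) -> None:
        np.savez(path, scores=self.scores, allele=np.str_(self.allele),
                 n_per_length=self.n_per_length,
                 lengths=np.array(self.lengths),
                 seed=-1 if self.seed is None else self.seed,
                 model_hash=np.str_(self.model_hash or ""))

    @classmethod
    def load(cls, path) -> "RankDatabase":
        with np.load(path) as data:
            seed = int(data["seed"])
            return cls(allele=str(data["allele"]),
                       scores=data["scores"],
                       n_per_length=int(data["n_per_length"]),
                       lengths=tuple(int(x) for x in data["lengths"]),
                       seed=None if seed < 0 else seed,
                       model_hash=str(data["model_hash"]) or None)


def _cache_path(cache_dir, model_hash: str, allele: str) -> str:
    safe = re.sub(r"[^A-Za-z0-9]+", "_", allele)
    return os.path.join(cache_dir, f"ranks_{model_hash}_{safe}.npz")


def build_rank_database(model: GatedMultiTaskModel, allele: str,
                        table: PseudoSequenceTable,
                        n_per_length: int = DEFAULT_N_PER_LENGTH,
                        lengths=DEFAULT_LENGTHS,
                        background_freqs: np.ndarray | None = None,
                        seed: int = 0,
                        cache_dir: str | None = None) -> RankDatabase:
    """Score random background peptides against one allele and sort them.

    With `cache_dir`, databases are reused across calls keyed by
    (model weights hash, allele).
    """
    model_hash = model.weights_hash()
    if cache_dir is not None:
        path = _cache_path(cache_dir, model_hash, allele)
        if os.path.exists(path):
            return RankDatabase.load(path)
    rng = np.random.default_rng(seed)
    peptides = generate_random_peptides(n_per_length, lengths,
                                        background_freqs, rng)
    allele_mat = encode_allele(allele, table)
    pep = np.stack([encode_peptide(p) for p in peptides])
    alle = np.broadcast_to(allele_mat, (len(peptides),) + allele_mat.shape)
    probs, _ = model.predict_batch(pep, np.ascontiguousarray(alle))
    db = RankDatabase(allele=allele, scores=np.sort(probs)[::-1],
                      n_per_length=n_per_length, lengths=tuple(lengths),
                      seed=seed, model_hash=model_hash)
    if cache_dir is not None:
        os.makedirs(cache_dir, exist_ok=True)
        db.save(_cache_path(cache_dir, model_hash, allele))
    return db


def percentile_rank(score, db: RankDatabase):
    """Percentile rank in (0, 100]: 100 (1 + #{db >= score}) / (N + 1)."""
    if len(db) == 0:
        raise RankError("empty rank database")
    ascending = db.scores[::-1]
    arr = np.asarray(score, dtype=float)
    n_ge = db.scores.size - np.searchsorted(ascending, arr, side="left")
    rank = 100.0 * (1.0 + n_ge) / (db.scores.size + 1.0)
    return float(rank) if np.isscalar(score) else rank
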