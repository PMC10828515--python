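"""Seeded generator of motif-planted peptide-MHC datasets.

Real training data for presentation models mix mass-spectrometry eluted
ligands (hits against a cell's alleles, heavily negative-skewed) with
quantitative binding-affinity measurements. This module emulates that
structure at desk scale so the whole pipeline is testable without downloads:

* each synthetic allele gets a random 37-residue pseudo-sequence and a
  binding motif concentrated on 2-3 preferred residues at the canonical
  MHC-I anchor positions (peptide position 2 and the C-terminus);
* MS positives are drawn from the motif-weighted peptide distribution,
  negatives are uniform random peptides;
* BA measurements are a noisy sigmoidal function of the motif log-score,
  mapped to nanomolar units;
* multi-allelic benchmark samples carry up to six alleles with a configured
  positive prevalence (default 1%), mirroring clinical immunopeptidomics.

Everything is driven by one integer seed through a numpy Generator, so a
fixed seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoders import AMINO_ACIDS, PSEUDO_LENGTH, PseudoSequenceTable
from .evaluation import BenchmarkRecord, BenchmarkSample
from .model import model_output_to_nM
from .training import BA, MS, TrainingExample
from ._nn import sigmoid

_RESIDUES = np.array(list(AMINO_ACIDS))
_UNIFORM = np.full(20, 1.0 / 20)

MOTIF_LENGTH_RANGE = (8, 12)  # lengths of generated MS/BA/benchmark peptides


@dataclass
class SyntheticAllele:
    """An invented allele: pseudo-sequence plus a planted anchor motif."""

    name: str
    pseudo_sequence: str
    anchor_weights: np.ndarray  # (n_anchors, 20), rows normalized; anchors
    # are peptide position 2 (index 1) and the C-terminal residue
    affinity_slope: float = 0.2

    def __post_init__(self):
        if len(self.pseudo_sequence) != PSEUDO_LENGTH:
            raise ValueError("pseudo-sequence must have 37 residues")
        w = np.asarray(self.anchor_weights, dtype=float)
        if np.any(w <= 0) or not np.allclose(w.sum(axis=1), 1.0):
            raise ValueError("anchor weights must be positive and normalized")
        self.anchor_weights = w

    @property
    def n_anchors(self) -> int:
        return self.anchor_weights.shape[0]

    @property
    def affinity_center(self) -> float:
        # midpoint between the expected motif score of a uniform-background
        # peptide and the best achievable score, so the affinity sigmoid is
        # centered on the binder/non-binder transition
        logw = np.log(self.anchor_weights)
        return 0.5 * (logw.mean(axis=1).sum() + logw.max(axis=1).sum())


@dataclass
class SyntheticDatasetSpec:
    n_alleles: int = 4
    n_pos_per_allele: int = 500
    negatives_ratio: float = 1.0     # MS negatives per positive
    ba_fraction: float = 0.2         # BA share of the full training set
    noise_sd: float = 0.05           # model-scale affinity noise
    prevalence: float = 0.01         # benchmark positive fraction
    alleles_per_sample: int = 4      # up to 6
    n_benchmark_samples: int = 4
    records_per_sample: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 1 <= self.alleles_per_sample <= 6:
            raise ValueError("alleles_per_sample must be in [1, 6]")


MIN_PREFERRED_WEIGHT = 0.05  # anchor residues at/above this count as preferred
_AFFINITY_TEMPER = 0.2      # anchor tempering exponent for BA peptides


def make_synthetic_allele(index: int, rng: np.random.Generator,
                          affinity_slope: float = 0.2) -> SyntheticAllele:
    """Random pseudo-sequence plus a motif with 2-3 strongly preferred
    residues at each anchor.

    Anchor weights are Dirichlet-distributed with concentration mass on the
    preferred residues, so log-weights vary continuously across alleles
    (real position-weight matrices are never two-valued)."""
    name = f"HLA-A*{90 + index % 10:02d}:{1 + index // 10:02d}"
    pseudo = "".join(rng.choice(_RESIDUES, size=PSEUDO_LENGTH))
    weights = np.empty((2, 20))
    for a in range(2):
        n_top = int(rng.integers(2, 4))
        top = rng.choice(20, size=n_top, replace=False)
        alpha = np.full(20, 0.03)
        alpha[top] = 3.0
        w = np.maximum(rng.dirichlet(alpha), 1e-6)
        weights[a] = w / w.sum()
    return SyntheticAllele(name=name, pseudo_sequence=pseudo,
                           anchor_weights=weights,
                           affinity_slope=affinity_slope)


def _anchor_indices(length: int) -> tuple[int, int]:
    return 1, length - 1  # position 2 and C-terminus


def motif_score(peptide: str, allele: SyntheticAllele) -> float:
    """Sum over anchor positions of the log motif weight of the residue there."""
    score = 0.0
    for anchor, pos in enumerate(_anchor_indices(len(peptide))):
        aa_index = AMINO_ACIDS.index(peptide[pos])
        score += float(np.log(allele.anchor_weights[anchor, aa_index]))
    return score


def _random_peptide(rng: np.random.Generator, length: int,
                    freqs: np.ndarray = _UNIFORM) -> str:
    return "".join(rng.choice(_RESIDUES, size=length, p=freqs))


def _motif_peptide(rng: np.random.Generator, allele: SyntheticAllele,
                   length: int, max_tries: int = 100) -> str:
    """A presented (eluted-ligand-like) peptide: anchors drawn from the motif,
    accepted only when every anchor carries a genuinely preferred residue —
    mass spectrometry observes peptides that actually bound."""
    pep = None
    for _ in range(max_tries):
        pep = list(rng.choice(_RESIDUES, size=length))
        ok = True
        for anchor, pos in enumerate(_anchor_indices(length)):
            w = allele.anchor_weights[anchor]
            pep[pos] = rng.choice(_RESIDUES, p=w)
            if w[AMINO_ACIDS.index(pep[pos])] < MIN_PREFERRED_WEIGHT:
                ok = False
        if ok:
            break
    return "".join(pep)


def _affinity_peptide(rng: np.random.Generator, allele: SyntheticAllele,
                      length: int) -> str:
    """A peptide for the affinity task: anchors drawn from a tempered motif
    (weights^tau, renormalized), spreading measurements across the whole
    binding range instead of clustering at the strong-binder extreme."""
    pep = list(rng.choice(_RESIDUES, size=length))
    for anchor, pos in enumerate(_anchor_indices(length)):
        w = allele.anchor_weights[anchor] ** _AFFINITY_TEMPER
        pep[pos] = rng.choice(_RESIDUES, p=w / w.sum())
    return "".join(pep)


def _random_length(rng: np.random.Generator) -> int:
    lo, hi = MOTIF_LENGTH_RANGE
    return int(rng.integers(lo, hi + 1))


def sample_presentation_dataset(spec: SyntheticDatasetSpec,
                                alleles: list[SyntheticAllele],
                                rng: np.random.Generator
                                ) -> list[TrainingExample]:
    """MS examples: motif-drawn positives and uniform-random negatives."""
    out: list[TrainingExample] = []
    n_neg = int(round(spec.negatives_ratio * spec.n_pos_per_allele))
    for allele in alleles:
        for _ in range(spec.n_pos_per_allele):
            pep = _motif_peptide(rng, allele, _random_length(rng))
            out.append(TrainingExample(pep, allele.name, MS, label=1))
        for _ in range(n_neg):
            pep = _random_peptide(rng, _random_length(rng))
            out.append(TrainingExample(pep, allele.name, MS, label=0))
    return out


def model_scale_affinity(peptide: str, allele: SyntheticAllele,
                         noise_sd: float,
                         rng: np.random.Generator | None = None) -> float:
    """Planted affinity on the model's 0-1 scale: a sigmoid of the centered
    motif score plus optional Gaussian noise, clamped to [0, 1]."""
    y = sigmoid(np.array(
        allele.affinity_slope * (motif_score(peptide, allele)
                                 - allele.affinity_center)))
    if noise_sd > 0 and rng is not None:
        y = y + rng.normal(0.0, noise_sd)
    return float(np.clip(y, 0.0, 1.0))


def sample_affinity_dataset(spec: SyntheticDatasetSpec,
                            alleles: list[SyntheticAllele],
                            rng: np.random.Generator) -> list[TrainingExample]:
    """BA examples with tempered-motif peptides spanning the affinity range,
    labelled with noisy planted affinities."""
    n_ms = spec.n_alleles * spec.n_pos_per_allele * (1 + spec.negatives_ratio)
    n_ba_total = int(round(n_ms * spec.ba_fraction / (1.0 - spec.ba_fraction)))
    per_allele = max(1, n_ba_total // max(len(alleles), 1))
    out: list[TrainingExample] = []
    for allele in alleles:
        for _ in range(per_allele):
            pep = _affinity_peptide(rng, allele, _random_length(rng))
            y = model_scale_affinity(pep, allele, spec.noise_sd, rng)
            nM = model_output_to_nM(y)
            out.append(TrainingExample(pep, allele.name, BA,
                                       measurement_nM=float(nM)))
    return out


def make_multiallelic_benchmark(spec: SyntheticDatasetSpec,
                                alleles: list[SyntheticAllele],
                                rng: np.random.Generator
                                ) -> list[BenchmarkSample]:
    """Benchmark samples carrying several alleles each, positives drawn from
    one of the sample's allele motifs, prevalence as configured."""
    samples = []
    k = min(spec.alleles_per_sample, len(alleles))
    for s in range(spec.n_benchmark_samples):
        chosen = list(rng.choice(len(alleles), size=k, replace=False))
        sample_alleles = [alleles[i] for i in chosen]
        names = tuple(a.name for a in sample_alleles)
        n_pos = max(1, int(round(spec.prevalence * spec.records_per_sample)))
        records = []
        for _ in range(n_pos):
            source = sample_alleles[int(rng.integers(0, k))]
            pep = _motif_peptide(rng, source, _random_length(rng))
            records.append(BenchmarkRecord(pep, names, hit=1))
        for _ in range(spec.records_per_sample - n_pos):
            pep = _random_peptide(rng, _random_length(rng))
            records.append(BenchmarkRecord(pep, names, hit=0))
        samples.append(BenchmarkSample(sample_id=f"synthetic-{s + 1}",
                                       records=records))
    return samples


@dataclass
class SyntheticDataset:
    alleles: list[SyntheticAllele]
    table: PseudoSequenceTable
    training: list[TrainingExample]
    benchmark: list[BenchmarkSample] = field(default_factory=list)


def make_pseudo_table(alleles: list[SyntheticAllele]) -> PseudoSequenceTable:
    table = PseudoSequenceTable()
    for allele in alleles:
        table.add(allele.name, allele.pseudo_sequence)
    return table


def generate_dataset(spec: SyntheticDatasetSpec,
                     with_benchmark: bool = True) -> SyntheticDataset:
    """One-call generation of alleles, training examples and benchmark."""
    rng = np.random.default_rng(spec.seed)
    alleles = [make_synthetic_allele(i, rng) for i in range(spec.n_alleles)]
    training = sample_presentation_dataset(spec, alleles, rng)
    training += sample_affinity_dataset(spec, alleles, rng)
    benchmark = make_multiallelic_benchmark(spec, alleles, rng) \
        if with_benchmark else []
    return SyntheticDataset(alleles=alleles, table=make_pseudo_table(alleles),
                            training=training, benchmark=benchmark)
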