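"""Benchmark machinery for immunopeptidomics test sets.

Multi-allelic mass-spectrometry samples carry up to six HLA class-I alleles
per individual; a record's score is deconvolved as the maximum per-allele
prediction. Per-sample metrics follow the conventions of eluted-ligand
benchmarks: AUC-ROC, AUC-PR and PPV 1% (fraction of true positives among the
top ceil(1% n) scores), with paired Wilcoxon signed-rank tests across samples
to compare predictors. Binding-affinity predictions are assessed by Spearman
rank correlation. A leakage filter removes positive records present in a
training set and then drops samples left with under 0.1% positives.

For immunogenicity, a two-step procedure ranks neoantigens by presentation
score and removes candidates with agretopicity (mutant nM / wild-type nM)
above a threshold before computing PPV5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

MAX_ALLELES_PER_SAMPLE = 6


class MetricError(ValueError):
    pass


class DegenerateTestError(MetricError):
    pass


@dataclass
class BenchmarkRecord:
    peptide: str
    alleles: tuple[str, ...]  # 1-6 alleles; hit shared across them
    hit: int
    score: float | None = None

    def __post_init__(self):
        if not 1 <= len(self.alleles) <= MAX_ALLELES_PER_SAMPLE:
            raise ValueError(
                f"record must carry 1-{MAX_ALLELES_PER_SAMPLE} alleles")
        if self.hit not in (0, 1):
            raise ValueError("hit must be 0 or 1")


@dataclass
class BenchmarkSample:
    sample_id: str
    records: list[BenchmarkRecord] = field(default_factory=list)

    @property
    def n_positive(self) -> int:
        return sum(r.hit for r in self.records)

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / len(self.records) if self.records else 0.0


def deconvolve_multi_allelic(record: BenchmarkRecord, scorer) -> float:
    """Deconvolved record score: the highest score among the record's alleles."""
    try:
        return max(scorer(record.peptide, allele) for allele in record.alleles)
    except Exception as exc:
        raise MetricError(
            f"failed to score record {record.peptide!r} / "
            f"{record.alleles}: {exc}") from exc


def score_benchmark(samples: list[BenchmarkSample], scorer) -> None:
    """Fill every record's score in place via multi-allelic deconvolution."""
    for sample in samples:
        for record in sample.records:
            record.score = deconvolve_multi_allelic(record, scorer)


def ppv_top_1pct(scores: np.ndarray, hits: np.ndarray) -> float:
    """True positives among the top ceil(0.01 n) scores, over that count.
    Ties are broken by stable input order."""
    n = len(scores)
    k = math.ceil(0.01 * n)
    order = np.argsort(-np.asarray(scores), kind="stable")
    return float(np.asarray(hits)[order[:k]].sum() / k)


def compute_sample_metrics(scores, hits) -> tuple[float, float, float]:
    """(AUC-ROC, AUC-PR, PPV 1%) for one sample."""
    scores = np.asarray(scores, dtype=float)
    hits = np.asarray(hits, dtype=int)
    if hits.min() == hits.max():
        raise MetricError("metrics undefined: sample has a single class")
    auc_roc = float(roc_auc_score(hits, scores))
    auc_pr = float(average_precision_score(hits, scores))
    return auc_roc, auc_pr, ppv_top_1pct(scores, hits)


def ppv_top_k(scores, hits, k: int = 5) -> float:
    """True positives among the k highest scores, divided by k."""
    scores = np.asarray(scores, dtype=float)
    hits = np.asarray(hits, dtype=int)
    if len(scores) < k:
        warnings.warn(f"only {len(scores)} records for top-{k} PPV; using all",
                      stacklevel=2)
        k = len(scores)
    order = np.argsort(-scores, kind="stable")
    return float(hits[order[:k]].sum() / k)


def spearman_corr(pred, truth) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if len(pred) != len(truth) or len(pred) < 3:
        raise MetricError("need equal-length vectors of at least 3 values")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise MetricError("Spearman correlation undefined for constant input")
    rho, _ = stats.spearmanr(pred, truth)
    return float(rho)


def paired_wilcoxon(metric_a, metric_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value; zero differences dropped."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise MetricError("paired vectors must have equal length")
    diffs = a - b
    if np.all(diffs == 0):
        raise DegenerateTestError("all paired differences are zero")
    _, p = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(p)


def filter_leakage(samples: list[BenchmarkSample],
                   train_peptide_allele_set: set[tuple[str, str]],
                   min_pos_frac: float = 0.001) -> list[BenchmarkSample]:
    """Remove positive records seen in training (exact peptide-allele match
    on any of the record's alleles), then drop samples whose surviving
    positive fraction falls below `min_pos_frac`."""
    filtered: list[BenchmarkSample] = []
    for sample in samples:
        kept = [
            r for r in sample.records
            if not (r.hit == 1 and any((r.peptide, a) in train_peptide_allele_set
                                       for a in r.alleles))
        ]
        if not kept:
            continue
        survivor = BenchmarkSample(sample_id=sample.sample_id, records=kept)
        if survivor.positive_fraction >= min_pos_frac:
            filtered.append(survivor)
    return filtered


@dataclass
class Neoantigen:
    name: str
    presentation_score: float
    mutant_nM: float
    wildtype_nM: float
    immunogenic: int  # experimentally determined label

    @property
    def agretopicity(self) -> float:
        if self.wildtype_nM <= 0:
            raise MetricError(f"wild-type nM must be positive for {self.name}")
        return self.mutant_nM / self.wildtype_nM


def immunogenicity_two_step(neoantigens: list[Neoantigen],
                            threshold: float = 0.1,
                            k: int = 5) -> tuple[list[Neoantigen], float]:
    """Rank by presentation score, drop agretopicity > threshold, report PPV5."""
    survivors = [n for n in neoantigens if n.agretopicity <= threshold]
    ranked = sorted(survivors, key=lambda n: -n.presentation_score)
    if not ranked:
        return [], float("nan")
    ppv5 = ppv_top_k([n.presentation_score for n in ranked],
                     [n.immunogenic for n in ranked], k=k)
    return ranked, ppv5


@dataclass
class MetricsReport:
    """Per-sample benchmark metrics with medians and optional paired tests."""

    per_sample: pd.DataFrame  # columns: sample_id, auc_roc, auc_pr, ppv_top1pct
    paired_tests: dict[str, float] = field(default_factory=dict)

    @property
    def medians(self) -> dict[str, float]:
        return {col: float(self.per_sample[col].median())
                for col in ("auc_roc", "auc_pr", "ppv_top1pct")}

    def to_csv(self, path) -> None:
        self.per_sample.to_csv(path, index=False)

    def to_json(self) -> dict:
        return {"per_sample": self.per_sample.to_dict(orient="records"),
                "medians": self.medians,
                "paired_tests": self.paired_tests}


def benchmark_report(samples: list[BenchmarkSample]) -> MetricsReport:
    """Metrics for every scored sample (records must have scores filled)."""
    rows = []
    for sample in samples:
        scores = np.array([r.score for r in sample.records], dtype=float)
        if np.any(np.isnan(scores)):
            raise MetricError(f"sample {sample.sample_id} has unscored records")
        hits = np.array([r.hit for r in sample.records])
        auc_roc, auc_pr, ppv = compute_sample_metrics(scores, hits)
        rows.append({"sample_id": sample.sample_id, "auc_roc": auc_roc,
                     "auc_pr": auc_pr, "ppv_top1pct": ppv})
    return MetricsReport(per_sample=pd.DataFrame(rows))
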