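"""CSV input/output for pairs, training data, benchmarks and predictions.

All tabular files are UTF-8 comma-separated with a header row. Prediction
output preserves input row order and uses fixed 6-decimal formatting so
files are byte-stable across runs with the same seed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

from .encoders import (AMINO_ACIDS, MAX_PEPTIDE_LEN, MIN_PEPTIDE_LEN)
from .evaluation import BenchmarkRecord, BenchmarkSample
from .training import BA, MS, TrainingExample


class InputError(ValueError):
    pass


@dataclass
class PredictionRecord:
    peptide: str
    allele: str
    np_prob: float
    ba_nM: float
    percentile_rank: float | None = None
    gate_np_task: float | None = None
    gate_ba_task: float | None = None


def _check_peptide(peptide: str, row: int) -> str | None:
    if not MIN_PEPTIDE_LEN <= len(peptide) <= MAX_PEPTIDE_LEN:
        return (f"row {row}: peptide {peptide!r} has length {len(peptide)}, "
                f"expected {MIN_PEPTIDE_LEN}-{MAX_PEPTIDE_LEN}")
    bad = [aa for aa in peptide if aa not in AMINO_ACIDS]
    if bad:
        return f"row {row}: invalid residue(s) {bad} in peptide {peptide!r}"
    return None


def read_pairs_csv(path, strict: bool = True) -> list[tuple[str, str]]:
    """Read a `peptide,allele` CSV. In strict mode any invalid row aborts;
    in lenient mode invalid rows are skipped with a warning."""
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                {"peptide", "allele"} - set(reader.fieldnames):
            raise InputError(f"{path}: expected header with peptide,allele")
        for rownum, row in enumerate(reader, start=2):
            peptide = (row["peptide"] or "").strip().upper()
            allele = (row["allele"] or "").strip()
            problem = _check_peptide(peptide, rownum)
            if problem is None and not allele:
                problem = f"row {rownum}: missing allele"
            if problem:
                if strict:
                    raise InputError(f"{path}: {problem}")
                warnings.warn(f"{path}: {problem}; row skipped", stacklevel=2)
                continue
            pairs.append((peptide, allele))
    if not pairs:
        raise InputError(f"{path}: no valid peptide-allele rows")
    return pairs


def write_predictions(records: list[PredictionRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["peptide", "allele", "presentation_score",
                         "presentation_percentile", "affinity_nM"])
        for rec in records:
            rank = "" if rec.percentile_rank is None \
                else f"{rec.percentile_rank:.6f}"
            writer.writerow([rec.peptide, rec.allele, f"{rec.np_prob:.6f}",
                             rank, f"{rec.ba_nM:.6f}"])


def read_predictions(path) -> list[PredictionRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rank = row.get("presentation_percentile") or None
            records.append(PredictionRecord(
                peptide=row["peptide"], allele=row["allele"],
                np_prob=float(row["presentation_score"]),
                ba_nM=float(row["affinity_nM"]),
                percentile_rank=None if rank is None else float(rank)))
    return records


def write_training_csv(examples: list[TrainingExample], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["peptide", "allele", "task", "label_or_nM"])
        for ex in examples:
            value = ex.label if ex.task == MS else ex.measurement_nM
            writer.writerow([ex.peptide, ex.allele, ex.task, value])


def read_training_csv(path) -> list[TrainingExample]:
    """Read `peptide,allele,task,label_or_nM`. Censored BA measurements
    (">" / "<" prefixes) are rejected: the model treats affinities as
    quantitative equalities."""
    examples = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"peptide", "allele", "task", "label_or_nM"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise InputError(f"{path}: expected header {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            peptide = row["peptide"].strip().upper()
            problem = _check_peptide(peptide, rownum)
            if problem:
                raise InputError(f"{path}: {problem}")
            task = row["task"].strip().upper()
            raw = row["label_or_nM"].strip()
            if raw.startswith((">", "<")):
                raise InputError(
                    f"{path}: row {rownum}: censored measurement {raw!r} "
                    "not supported")
            try:
                if task == MS:
                    ex = TrainingExample(peptide, row["allele"].strip(), MS,
                                         label=int(float(raw)))
                elif task == BA:
                    ex = TrainingExample(peptide, row["allele"].strip(), BA,
                                         measurement_nM=float(raw))
                else:
                    raise ValueError(f"unknown task {task!r}")
            except ValueError as exc:
                raise InputError(f"{path}: row {rownum}: {exc}") from exc
            examples.append(ex)
    if not examples:
        raise InputError(f"{path}: no training rows")
    return examples


def write_benchmark_csv(samples: list[BenchmarkSample], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "peptide", "alleles", "hit"])
        for sample in samples:
            for rec in sample.records:
                writer.writerow([sample.sample_id, rec.peptide,
                                 ";".join(rec.alleles), rec.hit])


def read_benchmark_csv(path) -> list[BenchmarkSample]:
    by_id: dict[str, BenchmarkSample] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "peptide", "alleles", "hit"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise InputError(f"{path}: expected header {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            peptide = row["peptide"].strip().upper()
            problem = _check_peptide(peptide, rownum)
            if problem:
                raise InputError(f"{path}: {problem}")
            sid = row["sample_id"].strip()
            alleles = tuple(a.strip() for a in row["alleles"].split(";")
                            if a.strip())
            rec = BenchmarkRecord(peptide, alleles, hit=int(row["hit"]))
            by_id.setdefault(sid, BenchmarkSample(sample_id=sid)) \
                .records.append(rec)
    if not by_id:
        raise InputError(f"{path}: no benchmark rows")
    return list(by_id.values())
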