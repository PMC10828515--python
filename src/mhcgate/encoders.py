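"""Peptide and MHC-I allele encoding.

Peptides (8-15 residues) are turned into a fixed 45x21 matrix: three
15-position alignment blocks (left-aligned, centered, right-aligned), each
position carrying the residue's BLOSUM62 substitution row scaled to O(1),
with a dedicated 21st channel marking padding. MHC-I alleles are represented
by their 37-residue pseudo-sequence (the peptide-contacting positions), each
residue encoded the same way, giving a 37x21 matrix. The pseudo-sequence
representation makes the downstream model pan-allele: any allele with a
known pseudo-sequence can be scored, trained on or not.
"""

from __future__ import annotations

import csv
import difflib
import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "X"
PEPTIDE_WINDOW = 15
PEPTIDE_ROWS = 3 * PEPTIDE_WINDOW  # left + centered + right alignment blocks
PSEUDO_LENGTH = 37
N_CHANNELS = 21  # 20 amino-acid channels + 1 pad channel
BLOSUM_SCALE = 0.1  # divide raw integer BLOSUM62 rows by 10

MIN_PEPTIDE_LEN = 8
MAX_PEPTIDE_LEN = 15


class EncodingError(ValueError):
    """Base class for encoding failures."""


class InvalidResidueError(EncodingError):
    def __init__(self, char: str, position: int | None = None):
        self.char = char
        self.position = position
        where = f" at position {position}" if position is not None else ""
        super().__init__(f"invalid residue {char!r}{where}; expected one of "
                         f"{AMINO_ACIDS} or pad symbol {PAD!r}")


class PeptideLengthError(EncodingError):
    def __init__(self, seq: str):
        super().__init__(
            f"peptide {seq!r} has length {len(seq)}; must be in "
            f"[{MIN_PEPTIDE_LEN}, {MAX_PEPTIDE_LEN}]")


class AlleleNameError(EncodingError):
    """Raised for allele names that look like malformed HLA class-I names."""


class MissingAlleleError(EncodingError, KeyError):
    def __init__(self, allele: str, suggestions: list[str]):
        hint = f"; nearest matches: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(f"allele {allele!r} not in pseudo-sequence table{hint}")


def _build_encoding_table() -> dict[str, np.ndarray]:
    blosum = substitution_matrices.load("BLOSUM62")
    table: dict[str, np.ndarray] = {}
    for aa in AMINO_ACIDS:
        row = np.zeros(N_CHANNELS)
        row[:20] = [blosum[aa, other] for other in AMINO_ACIDS]
        table[aa] = row * BLOSUM_SCALE
    pad = np.zeros(N_CHANNELS)
    pad[20] = 1.0
    table[PAD] = pad
    return table


_ENCODING = _build_encoding_table()


def encode_residue(aa: str, position: int | None = None) -> np.ndarray:
    """21-vector for one residue: scaled BLOSUM62 row, or the pad row for 'X'."""
    try:
        return _ENCODING[aa].copy()
    except KeyError:
        raise InvalidResidueError(aa, position) from None


def _validate_peptide(seq: str) -> None:
    if not MIN_PEPTIDE_LEN <= len(seq) <= MAX_PEPTIDE_LEN:
        raise PeptideLengthError(seq)
    for i, aa in enumerate(seq):
        if aa not in AMINO_ACIDS:
            raise InvalidResidueError(aa, i)


def _align_blocks(seq: str) -> str:
    """Left-, center-, and right-aligned copies in a 15-wide window, concatenated."""
    n_pad = PEPTIDE_WINDOW - len(seq)
    left = seq + PAD * n_pad
    lpad = n_pad // 2  # odd remainder: extra pad on the right
    center = PAD * lpad + seq + PAD * (n_pad - lpad)
    right = PAD * n_pad + seq
    return left + center + right


def encode_peptide(seq: str) -> np.ndarray:
    """Encode an 8-15mer peptide as a 45x21 matrix (three alignment blocks)."""
    _validate_peptide(seq)
    aligned = _align_blocks(seq)
    return np.stack([_ENCODING[aa] for aa in aligned])


# ---------------------------------------------------------------------------
# Allele names and pseudo-sequences

_HLA_RE = re.compile(
    r"^(?:HLA[-*]?)?([ABCEFG])\s*\*?\s*(\d{2,3}):?(\d{2,3})$", re.IGNORECASE)
_HLA_LIKE_RE = re.compile(r"^HLA", re.IGNORECASE)


def normalize_allele(name: str) -> str:
    """Canonicalize an MHC-I allele name.

    "A0201", "A*02:01", "HLA-A02:01" all map to "HLA-A*02:01". Tokens that do
    not look like HLA names (e.g. synthetic allele ids) are passed through
    uppercased; strings that start with "HLA" but fail to parse are rejected
    rather than guessed.
    """
    token = name.strip()
    if not token:
        raise AlleleNameError("empty allele name")
    m = _HLA_RE.match(token.replace(" ", ""))
    if m:
        gene, group, protein = m.groups()
        return f"HLA-{gene.upper()}*{int(group):02d}:{int(protein):02d}"
    if _HLA_LIKE_RE.match(token):
        raise AlleleNameError(f"cannot parse HLA allele name {name!r}")
    return token.upper()


@dataclass
class PseudoSequenceTable:
    """Map from normalized allele name to a 37-residue pseudo-sequence."""

    entries: dict[str, str] = field(default_factory=dict)

    def add(self, allele: str, pseudo_sequence: str, line: int | None = None) -> None:
        where = f" (line {line})" if line is not None else ""
        if len(pseudo_sequence) != PSEUDO_LENGTH:
            raise EncodingError(
                f"pseudo-sequence for {allele!r} has length "
                f"{len(pseudo_sequence)}, expected {PSEUDO_LENGTH}{where}")
        for i, aa in enumerate(pseudo_sequence):
            if aa not in AMINO_ACIDS:
                raise InvalidResidueError(aa, i)
        key = normalize_allele(allele)
        if key in self.entries and self.entries[key] != pseudo_sequence:
            raise EncodingError(
                f"conflicting pseudo-sequences for allele {key!r}{where}")
        self.entries[key] = pseudo_sequence

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, allele: str) -> bool:
        return normalize_allele(allele) in self.entries

    def get(self, allele: str) -> str:
        key = normalize_allele(allele)
        try:
            return self.entries[key]
        except KeyError:
            suggestions = difflib.get_close_matches(key, self.entries, n=3)
            raise MissingAlleleError(allele, suggestions) from None

    def alleles(self) -> list[str]:
        return list(self.entries)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["allele", "pseudo_sequence"])
            for allele, seq in self.entries.items():
                writer.writerow([allele, seq])


def example_table_path() -> str:
    """Path to the bundled example pseudo-sequence table.

    The table carries common HLA allele names with SYNTHETIC random
    pseudo-sequences (it is a format/plumbing fixture, not real contact-site
    biology); real analyses should load a curated table."""
    import os
    return os.path.join(os.path.dirname(__file__), "data",
                        "synthetic_example_alleles.csv")


def load_pseudo_table(path) -> PseudoSequenceTable:
    """Load a two-column CSV/TSV (allele, pseudo_sequence) into a table."""
    table = PseudoSequenceTable()
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if "\t" in sample.split("\n", 1)[0] else ","
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() == "allele":
                continue
            if len(row) < 2:
                raise EncodingError(f"malformed row at line {lineno}: {row!r}")
            try:
                table.add(row[0].strip(), row[1].strip(), line=lineno)
            except EncodingError:
                raise
    if not table.entries:
        raise EncodingError(f"no pseudo-sequence entries found in {path}")
    return table


def encode_allele(allele: str, table: PseudoSequenceTable) -> np.ndarray:
    """Encode an allele's 37-residue pseudo-sequence as a 37x21 matrix."""
    seq = table.get(allele)
    return np.stack([_ENCODING[aa] for aa in seq])


@dataclass
class EncodedPair:
    """A peptide-allele pair in the numeric form the network consumes."""

    peptide: str
    allele: str
    peptide_matrix: np.ndarray  # (45, 21)
    allele_matrix: np.ndarray   # (37, 21)


def encode_pair(peptide: str, allele: str, table: PseudoSequenceTable) -> EncodedPair:
    return EncodedPair(
        peptide=peptide,
        allele=allele,
        peptide_matrix=encode_peptide(peptide),
        allele_matrix=encode_allele(allele, table),
    )
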