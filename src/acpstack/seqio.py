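"""FASTA I/O, peptide validation, and physicochemical profiling.

Peptides are short sequences (typically 5-50 residues) over the 20 canonical
amino-acid letters. This module reads and writes them as FASTA, filters them
by length, and computes the simple physicochemical descriptors used to
characterise anticancer (ACP) and antimicrobial (AMP) peptides: net charge,
mean Kyte-Doolittle hydropathy, and amino-acid composition.

Nonstandard residues (B, J, O, U, X, Z, gaps) are rejected at validation
rather than silently skipped: the downstream n-gram vocabulary is defined
over exactly 20 letters and dropping residues would corrupt 5-mer offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FastaParseError, ValidationError

#: The 20 canonical amino acids, in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Fixed class order used throughout the package.
CLASSES = ("ACP", "AMP", "NEG")

#: Kyte-Doolittle hydropathy index per residue (dimensionless, 1 decimal).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Default pKa table for the optional Henderson-Hasselbalch charge mode
#: (EMBOSS values). Keys: side chains plus the two termini.
DEFAULT_PKA = {
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    "Nterm": 8.6, "Cterm": 3.6,
}

#: Sequences longer than this are accepted at prediction time with a warning:
#: models are trained on peptides, not proteins.
MAX_TRAINED_LENGTH = 50


def validate_sequence(sequence: str, record: str | None = None) -> None:
    """Raise :class:`ValidationError` unless *sequence* is a non-empty
    uppercase string over the 20 canonical amino-acid letters."""
    where = f" in record {record!r}" if record else ""
    if not sequence:
        raise ValidationError(f"empty sequence{where}")
    for ch in sequence:
        if ch not in _AA_SET:
            raise ValidationError(
                f"invalid residue {ch!r}{where}: only the 20 canonical "
                f"amino acids ({AMINO_ACIDS}) are accepted; nonstandard "
                "residues (B, J, O, U, X, Z) and gaps must be removed first"
            )


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with an optional class label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, record=self.id)
        if self.label is not None and self.label not in CLASSES:
            raise ValidationError(
                f"unknown class label {self.label!r} for {self.id!r}; "
                f"expected one of {CLASSES}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(
    path: str | Path,
    labels: Mapping[str, str] | None = None,
) -> list[Peptide]:
    """Read a FASTA file into a list of validated :class:`Peptide`.

    Sequences are uppercased; record order is preserved; duplicate ids and
    alphabet violations raise :class:`ValidationError`. If *labels* maps
    peptide ids to class names, those labels are attached.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: expected a '>' header before "
                "sequence data"
            )
        break
    peptides: list[Peptide] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            pid = header.split()[0] if header.split() else header
            if pid in seen:
                raise ValidationError(f"{path}: duplicate record id {pid!r}")
            seen.add(pid)
            label = labels.get(pid) if labels is not None else None
            peptides.append(Peptide(id=pid, sequence=seq.upper(), label=label))
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path, width: int = 60) -> None:
    """Write peptides as wrapped FASTA (one record per peptide, order kept)."""
    with open(path, "w") as handle:
        for pep in peptides:
            handle.write(f">{pep.id}\n")
            for i in range(0, len(pep.sequence), width):
                handle.write(pep.sequence[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id, class) into a dict. A header row with
    'id' in the first column is skipped."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}: line {lineno}: expected 2 columns")
        if lineno == 1 and parts[0].lower() in ("id", "#id"):
            continue
        out[parts[0]] = parts[1]
    return out


def filter_by_length(
    peptides: Sequence[Peptide],
    min_len: int = 5,
    max_len: int | None = None,
) -> tuple[list[Peptide], list[Peptide]]:
    """Partition peptides into (kept, removed) by inclusive length bounds.

    The default ``min_len=5`` reflects the shortest peptides the classifier
    can window into 5-mers. The partition is exhaustive and order-preserving.
    """
    if min_len < 1:
        raise ValidationError("min_len must be >= 1")
    kept, removed = [], []
    for pep in peptides:
        n = len(pep)
        if n >= min_len and (max_len is None or n <= max_len):
            kept.append(pep)
        else:
            removed.append(pep)
    return kept, removed


def net_charge(
    sequence: str,
    mode: str = "simple",
    ph: float = 7.0,
    pka: Mapping[str, float] | None = None,
) -> float:
    """Net charge of a peptide.

    ``mode="simple"`` (default): count(K) + count(R) - count(D) - count(E).
    Histidine is excluded from the positive count because its side chain is
    mostly neutral at pH 7.

    ``mode="hh"``: fractional charge at *ph* from the Henderson-Hasselbalch
    equation using *pka* (default :data:`DEFAULT_PKA`), including both
    termini and the H, C, Y side chains.
    """
    validate_sequence(sequence)
    if mode == "simple":
        return float(
            sequence.count("K") + sequence.count("R")
            - sequence.count("D") - sequence.count("E")
        )
    if mode == "hh":
        table = dict(DEFAULT_PKA)
        if pka:
            table.update(pka)
        pos = 10 ** -(ph - table["Nterm"])
        charge = pos / (1.0 + pos)
        for res in "KRH":
            frac = 10 ** (table[res] - ph)
            charge += sequence.count(res) * frac / (1.0 + frac)
        frac = 10 ** (ph - table["Cterm"])
        charge -= frac / (1.0 + frac)
        for res in "DECY":
            frac = 10 ** (ph - table[res])
            charge -= sequence.count(res) * frac / (1.0 + frac)
        return charge
    raise ValidationError(f"unknown charge mode {mode!r}; use 'simple' or 'hh'")


def hydropathy_index(sequence: str) -> float:
    """Arithmetic mean of per-residue Kyte-Doolittle values."""
    validate_sequence(sequence)
    return float(np.mean([KYTE_DOOLITTLE[ch] for ch in sequence]))


def aa_composition(
    peptides: Sequence[Peptide],
    by: str = "pooled",
) -> pd.DataFrame:
    """Amino-acid composition table(s): residue counts / total residues.

    ``by="pooled"``: one row over all peptides. ``by="label"``: one row per
    class (pooled residues within class). ``by="peptide"``: one row per
    peptide. Columns are the 20 residues in alphabetical order; every row
    sums to 1.
    """
    if len(peptides) == 0:
        raise ValidationError("aa_composition requires a non-empty peptide list")

    def _freqs(seqs: Iterable[str]) -> np.ndarray:
        counts = np.zeros(20)
        for s in seqs:
            for ch in s:
                counts[AMINO_ACIDS.index(ch)] += 1
        total = counts.sum()
        return counts / total

    cols = list(AMINO_ACIDS)
    if by == "pooled":
        return pd.DataFrame([_freqs(p.sequence for p in peptides)],
                            index=["all"], columns=cols)
    if by == "label":
        groups: dict[str, list[str]] = {}
        for p in peptides:
            groups.setdefault(p.label or "unlabeled", []).append(p.sequence)
        return pd.DataFrame(
            {g: _freqs(seqs) for g, seqs in groups.items()}, index=cols
        ).T[cols]
    if by == "peptide":
        return pd.DataFrame(
            [_freqs([p.sequence]) for p in peptides],
            index=[p.id for p in peptides], columns=cols,
        )
    raise ValidationError(f"unknown grouping {by!r}")


def property_table(peptides: Sequence[Peptide]) -> pd.DataFrame:
    """Per-peptide property table: id, length, net_charge, hydropathy,
    then the 20 composition columns in alphabetical residue order."""
    if len(peptides) == 0:
        raise ValidationError("property_table requires a non-empty peptide list")
    comp = aa_composition(peptides, by="peptide").reset_index(drop=True)
    base = pd.DataFrame(
        {
            "id": [p.id for p in peptides],
            "length": [len(p) for p in peptides],
            "net_charge": [net_charge(p.sequence) for p in peptides],
            "hydropathy": [hydropathy_index(p.sequence) for p in peptides],
        }
    )
    return pd.concat([base, comp], axis=1)


def warn_if_long(peptides: Iterable[Peptide]) -> list[str]:
    """Return (and emit) warnings for peptides longer than the trained range."""
    msgs = []
    for pep in peptides:
        if len(pep) > MAX_TRAINED_LENGTH:
            msg = (
                f"{pep.id}: length {len(pep)} exceeds the trained range "
                f"(<= {MAX_TRAINED_LENGTH} residues); prediction may be unreliable"
            )
            warnings.warn(msg)
            msgs.append(msg)
    return msgs
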