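"""Overlapping 5-mer decomposition and gapped n-gram featurisation.

Each peptide is cut into overlapping windows of ``k=5`` residues (5-mers),
the unit classified by the first model layer. Each 5-mer is encoded as a
binary vector over a fixed vocabulary of short motifs (n-grams):

* unigrams: single residues, 20 of them;
* bigrams: two residues separated by a gap of 0-3 positions (a gap matches
  any residue), 4 x 20^2 = 1600;
* trigrams: three residues where each of the two inter-residue gaps is 0 or
  1, 4 x 20^3 = 32,000.

Total vocabulary: 33,620 descriptors, every one spanning at most 5
positions. Occurrence is *binarised*: a motif present anywhere in the 5-mer
(at least once, at any offset) scores 1, otherwise 0 -- multiplicity and
position within the window are deliberately discarded.

The canonical text form writes one underscore per skipped position:
``"KL"`` (contiguous), ``"K__A"`` (K, any two residues, A), ``"K_A_L"``
(gaps 1 and 1). Vocabulary order is (size, gap pattern, residues), which is
deterministic and stable across runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ConfigError, ValidationError
from .seqio import AMINO_ACIDS, Peptide, validate_sequence

DEFAULT_K = 5

#: Gap patterns per n-gram size: () for unigrams; a single gap of 0-3 for
#: bigrams; each inter-residue gap 0 or 1 for trigrams.
DEFAULT_GAP_PATTERNS: dict[int, tuple[tuple[int, ...], ...]] = {
    1: ((),),
    2: ((0,), (1,), (2,), (3,)),
    3: ((0, 0), (0, 1), (1, 0), (1, 1)),
}


@dataclass(frozen=True)
class NGramDescriptor:
    """A continuous or gapped motif of 1-3 residues; the feature identity."""

    residues: str
    gaps: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError("descriptor needs at least one residue")
        validate_sequence(self.residues)
        if len(self.gaps) != len(self.residues) - 1:
            raise ValidationError(
                f"descriptor {self.residues!r} needs {len(self.residues) - 1} "
                f"gap entries, got {len(self.gaps)}"
            )
        if any(g < 0 for g in self.gaps):
            raise ValidationError("gap lengths must be non-negative")

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def span(self) -> int:
        """Number of window positions the motif covers, gaps included."""
        return len(self.residues) + sum(self.gaps)

    @property
    def text(self) -> str:
        """Canonical text form: one underscore per skipped position."""
        parts = [self.residues[0]]
        for gap, res in zip(self.gaps, self.residues[1:]):
            parts.append("_" * gap)
            parts.append(res)
        return "".join(parts)

    @classmethod
    def from_text(cls, text: str) -> "NGramDescriptor":
        """Parse the canonical text form back into a descriptor."""
        residues: list[str] = []
        gaps: list[int] = []
        run = 0
        for ch in text:
            if ch == "_":
                if not residues:
                    raise ValidationError(f"{text!r}: cannot start with a gap")
                run += 1
            else:
                if residues:
                    gaps.append(run)
                run = 0
                residues.append(ch)
        if run:
            raise ValidationError(f"{text!r}: cannot end with a gap")
        return cls("".join(residues), tuple(gaps))

    def __str__(self) -> str:
        return self.text


def descriptor_sort_key(d: NGramDescriptor) -> tuple:
    """Canonical vocabulary order: by size, then gap pattern, then residues."""
    return (d.n, d.gaps, d.residues)


@dataclass(frozen=True)
class Mer:
    """An overlapping k-residue window of a peptide.

    Carries its parent peptide id, 0-based start offset, and (during
    training) the class label inherited from the parent.
    """

    parent_id: str
    offset: int
    sequence: str
    label: str | None = None


def decompose_to_mers(peptide: Peptide, k: int = DEFAULT_K) -> list[Mer]:
    """Cut a peptide into its ``len - k + 1`` overlapping k-mers (stride 1).

    Raises :class:`ValidationError` for peptides shorter than *k*: such
    sequences cannot be windowed and are not predictable.
    """
    L = len(peptide)
    if L < k:
        raise ValidationError(
            f"peptide {peptide.id!r} has length {L} < {k}: too short to "
            f"decompose into {k}-mers"
        )
    return [
        Mer(peptide.id, off, peptide.sequence[off : off + k], peptide.label)
        for off in range(L - k + 1)
    ]


def decompose_all(peptides: Iterable[Peptide], k: int = DEFAULT_K) -> list[Mer]:
    """Decompose every peptide; mers appear in peptide order, offsets ascending."""
    mers: list[Mer] = []
    for pep in peptides:
        mers.extend(decompose_to_mers(pep, k))
    return mers


def _check_gap_patterns(
    k: int, gap_patterns: dict[int, tuple[tuple[int, ...], ...]]
) -> None:
    for n, patterns in gap_patterns.items():
        for gaps in patterns:
            if len(gaps) != n - 1:
                raise ConfigError(
                    f"size-{n} pattern {gaps} must have {n - 1} gap entries"
                )
            if n + sum(gaps) > k:
                raise ConfigError(
                    f"size-{n} pattern {gaps} spans {n + sum(gaps)} > k={k}"
                )


def enumerate_vocabulary(
    k: int = DEFAULT_K,
    gap_patterns: dict[int, tuple[tuple[int, ...], ...]] | None = None,
    alphabet: str = AMINO_ACIDS,
) -> list[NGramDescriptor]:
    """Enumerate the complete, duplicate-free, canonically ordered vocabulary.

    With the default gap rules and 20-letter alphabet this yields
    20 + 4*400 + 4*8000 = 33,620 descriptors.
    """
    if gap_patterns is None:
        gap_patterns = DEFAULT_GAP_PATTERNS
    _check_gap_patterns(k, gap_patterns)
    vocab: list[NGramDescriptor] = []
    for n in sorted(gap_patterns):
        for gaps in sorted(gap_patterns[n]):
            for combo in product(alphabet, repeat=n):
                vocab.append(NGramDescriptor("".join(combo), gaps))
    return vocab


def vocabulary_hash(vocabulary: Sequence[NGramDescriptor]) -> str:
    """SHA-256 of the newline-joined canonical texts; pins vocabulary order."""
    joined = "\n".join(d.text for d in vocabulary)
    return hashlib.sha256(joined.encode()).hexdigest()


@lru_cache(maxsize=8)
def _placements(
    k: int, gap_patterns_items: tuple
) -> tuple[tuple[tuple[int, ...], tuple[tuple[int, ...], ...]], ...]:
    """All (gap pattern, admissible index tuples) placements inside a k-window."""
    out = []
    for n, patterns in gap_patterns_items:
        for gaps in patterns:
            span = n + sum(gaps)
            positions = []
            for start in range(k - span + 1):
                idx = [start]
                for g in gaps:
                    idx.append(idx[-1] + g + 1)
                positions.append(tuple(idx))
            out.append((gaps, tuple(positions)))
    return tuple(out)


def extract_ngrams(
    mer: Mer | str,
    k: int = DEFAULT_K,
    gap_patterns: dict[int, tuple[tuple[int, ...], ...]] | None = None,
) -> set[NGramDescriptor]:
    """The exact set of vocabulary n-grams occurring anywhere in a k-mer.

    Gapped positions match any residue; presence at one or more offsets
    yields the descriptor once (binarisation).
    """
    seq = mer.sequence if isinstance(mer, Mer) else mer
    if len(seq) != k:
        raise ValidationError(f"expected a {k}-residue mer, got length {len(seq)}")
    validate_sequence(seq)
    if gap_patterns is None:
        gap_patterns = DEFAULT_GAP_PATTERNS
    _check_gap_patterns(k, gap_patterns)
    items = tuple(sorted((n, tuple(p)) for n, p in gap_patterns.items()))
    found: set[NGramDescriptor] = set()
    for gaps, positions in _placements(k, items):
        for idx in positions:
            found.add(NGramDescriptor("".join(seq[i] for i in idx), gaps))
    return found


@dataclass
class FeatureMatrix:
    """Binary mers x n-grams occurrence matrix, stored sparse.

    ``values`` is a CSR matrix of 0/1 (uint8); ``descriptors`` gives the
    column identities in canonical order; ``mers`` the row identities.
    """

    mers: list[Mer]
    descriptors: list[NGramDescriptor]
    values: sp.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        return self.values.toarray()

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def labels(self) -> np.ndarray:
        return np.array([m.label for m in self.mers], dtype=object)

    def subset_columns(self, descriptors: Sequence[NGramDescriptor]) -> "FeatureMatrix":
        """Restrict to the given columns, in the given order. Columns absent
        from this matrix come back all-zero."""
        index = {d: j for j, d in enumerate(self.descriptors)}
        cols = []
        n_rows = self.values.shape[0]
        for d in descriptors:
            j = index.get(d)
            if j is None:
                cols.append(sp.csr_matrix((n_rows, 1), dtype=np.uint8))
            else:
                cols.append(self.values[:, [j]])
        values = sp.hstack(cols, format="csr") if cols else sp.csr_matrix(
            (n_rows, 0), dtype=np.uint8
        )
        return FeatureMatrix(self.mers, list(descriptors), values)

    def to_tsv(self, path: str | Path) -> None:
        """Dense TSV export: mer id, offset, then one column per descriptor."""
        dense = self.to_dense()
        with open(path, "w") as fh:
            fh.write("mer_id\toffset\t" + "\t".join(d.text for d in self.descriptors) + "\n")
            for mer, row in zip(self.mers, dense):
                fh.write(
                    f"{mer.parent_id}\t{mer.offset}\t"
                    + "\t".join(str(int(v)) for v in row) + "\n"
                )

    def to_triplets(self, path: str | Path) -> None:
        """Sparse triplet text export: mer-index, descriptor text, 1."""
        coo = self.values.tocoo()
        with open(path, "w") as fh:
            fh.write("mer_index\tdescriptor\tvalue\n")
            for i, j in zip(coo.row, coo.col):
                fh.write(f"{i}\t{self.descriptors[j].text}\t1\n")


def build_feature_matrix(
    mers: Sequence[Mer],
    vocabulary: Sequence[NGramDescriptor] | None = None,
    k: int = DEFAULT_K,
    gap_patterns: dict[int, tuple[tuple[int, ...], ...]] | None = None,
) -> FeatureMatrix:
    """Build the binary occurrence matrix for a list of mers.

    With ``vocabulary=None`` the columns are the n-grams actually observed
    in *mers*, in canonical order (the full 33,620-descriptor space is the
    universe; all-zero columns carry no information and are dropped, the
    mapping being the descriptor list itself).
    """
    per_mer: list[set[NGramDescriptor]] = [
        extract_ngrams(m, k=k, gap_patterns=gap_patterns) for m in mers
    ]
    if vocabulary is None:
        observed: set[NGramDescriptor] = set()
        for s in per_mer:
            observed |= s
        vocabulary = sorted(observed, key=descriptor_sort_key)
    else:
        vocabulary = list(vocabulary)
    col = {d: j for j, d in enumerate(vocabulary)}
    indptr = [0]
    indices: list[int] = []
    for s in per_mer:
        js = sorted(col[d] for d in s if d in col)
        indices.extend(js)
        indptr.append(len(indices))
    values = sp.csr_matrix(
        (np.ones(len(indices), dtype=np.uint8), indices, indptr),
        shape=(len(mers), len(vocabulary)),
    )
    return FeatureMatrix(list(mers), vocabulary, values)
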