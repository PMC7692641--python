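"""Synthetic labelled peptide sets with controllable class separation.

The generator emulates the qualitative statistical structure of real
anticancer/antimicrobial peptide collections: ACP-like sequences are
enriched in lysine, leucine, alanine and phenylalanine; AMP-like sequences
in glycine, cysteine and lysine; the negative class draws from a flat
background. Residues are drawn i.i.d. from a per-class frequency profile,
optionally with a short class motif implanted at a random admissible offset
-- enough structure to exercise n-gram selection (motifs create informative
bigrams/trigrams) while staying fully auditable.

The ``separation`` knob linearly interpolates each class profile toward the
shared background: at 0 all three classes are statistically identical (a
null data set by construction); at 1 (default) the profiles are fully
distinct. Lengths are uniform over the configured range. Everything is
deterministic under the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .seqio import AMINO_ACIDS, CLASSES, Peptide, write_fasta


def default_profiles() -> dict[str, np.ndarray]:
    """Per-class residue frequency profiles plus the shared background.

    Repository constants chosen to mirror the qualitative enrichment pattern
    of real data (ACP: K/L/A/F-rich; AMP: G/C/K-rich; NEG = background),
    not measured values. Each vector indexes :data:`AMINO_ACIDS`
    alphabetically and sums to 1.
    """
    def profile(boosts: Mapping[str, float]) -> np.ndarray:
        p = np.zeros(20)
        rest = 1.0 - sum(boosts.values())
        others = [aa for aa in AMINO_ACIDS if aa not in boosts]
        for aa, w in boosts.items():
            p[AMINO_ACIDS.index(aa)] = w
        for aa in others:
            p[AMINO_ACIDS.index(aa)] = rest / len(others)
        return p / p.sum()

    background = np.full(20, 1.0 / 20.0)
    return {
        "ACP": profile({"K": 0.18, "L": 0.12, "A": 0.12, "F": 0.08}),
        "AMP": profile({"G": 0.15, "C": 0.12, "K": 0.10}),
        "NEG": background.copy(),
        "background": background,
    }


#: Default class motifs implanted with the given probability. The ACP motif
#: is a lysine/leucine repeat typical of amphipathic helical anticancer
#: peptides; the AMP motif is glycine/cysteine-flavoured.
DEFAULT_MOTIFS: dict[str, tuple[str, float]] = {
    "ACP": ("KLAK", 0.5),
    "AMP": ("GCGC", 0.5),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic peptide generator."""

    n_per_class: int = 300
    length_range: tuple[int, int] = (5, 50)
    profiles: dict[str, np.ndarray] | None = None
    motifs: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIFS)
    )
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (5 <= lo <= hi <= 200):
            raise ConfigError("length_range must satisfy 5 <= lo <= hi <= 200")
        if not (0.0 <= self.separation <= 1.0):
            raise ConfigError("separation must lie in [0, 1]")
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")
        if self.profiles is None:
            self.profiles = default_profiles()
        for name in (*CLASSES, "background"):
            if name not in self.profiles:
                raise ConfigError(f"missing profile for {name!r}")
            p = np.asarray(self.profiles[name], dtype=float)
            if p.shape != (20,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(f"profile {name!r} is not on the 20-simplex")
            self.profiles[name] = p
        for cls, (motif, prob) in self.motifs.items():
            if cls not in CLASSES:
                raise ConfigError(f"motif class {cls!r} unknown")
            if not motif or any(ch not in AMINO_ACIDS for ch in motif):
                raise ConfigError(f"motif {motif!r} must use canonical residues")
            if not (0.0 <= prob <= 1.0):
                raise ConfigError("implant probability must lie in [0, 1]")


def effective_profiles(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Class profiles after interpolation toward the background."""
    bg = config.profiles["background"]
    s = config.separation
    return {
        cls: s * config.profiles[cls] + (1.0 - s) * bg for cls in CLASSES
    }


def generate_peptides(config: SyntheticConfig) -> tuple[list[Peptide], dict]:
    """Draw a labelled synthetic peptide set.

    Returns the peptides (n_per_class per class, ids ``<CLS>_<i>``) plus a
    provenance record of every parameter used, suitable for JSON export.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    lo, hi = config.length_range
    profiles = effective_profiles(config)
    peptides: list[Peptide] = []
    for cls in CLASSES:
        p = profiles[cls]
        motif, prob = config.motifs.get(cls, ("", 0.0))
        for i in range(config.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = rng.choice(alphabet, size=length, p=p)
            if motif and len(motif) <= length and rng.random() < prob:
                off = int(rng.integers(0, length - len(motif) + 1))
                seq[off : off + len(motif)] = list(motif)
            peptides.append(
                Peptide(id=f"{cls}_{i:04d}", sequence="".join(seq), label=cls)
            )
    provenance = {
        "generator": "acpstack.synthetic",
        "n_per_class": config.n_per_class,
        "length_range": list(config.length_range),
        "separation": config.separation,
        "seed": config.seed,
        "motifs": {c: list(m) for c, m in config.motifs.items()},
        "profiles": {k: np.asarray(v).tolist() for k, v in config.profiles.items()},
        "class_order": list(CLASSES),
    }
    return peptides, provenance


def write_dataset(
    peptides: list[Peptide],
    provenance: dict,
    fasta_path: str | Path,
    labels_path: str | Path | None = None,
    provenance_path: str | Path | None = None,
) -> None:
    """Emit FASTA + labels TSV + JSON provenance for a generated set."""
    write_fasta(peptides, fasta_path)
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            fh.write("id\tclass\n")
            for pep in peptides:
                fh.write(f"{pep.id}\t{pep.label}\n")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
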