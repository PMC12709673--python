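"""CDR3 variant alphabet, positions, and amino-acid embedding schemes.

The library randomizes six CDR3 positions of the A6 TCR framework — three on
the alpha chain (a99, a100, a101) and three on the beta chain (b98, b99, b100)
— over a 19-letter amino-acid alphabet, giving 19**6 (~47 million) variants.

Three per-residue embeddings are provided for the downstream classifiers:

* ``BLOSUM50`` — each residue mapped to its row of the BLOSUM50 substitution
  matrix over the 20 canonical columns (20 dims/residue);
* ``VHSE8`` — the eight published VHSE principal-component physicochemical
  descriptors (hydrophobic, steric, electronic; 8 dims/residue);
* ``ONEHOT`` — indicator over the 20 canonical residues (20 dims/residue).

A full 6-mer therefore embeds to 120, 48 or 120 dimensions respectively;
masked (residue-deleted) sequences embed to ``(6 - d) * per_residue_dim``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 canonical amino acids in the fixed column order used throughout.
CANONICAL_AA = "ARNDCQEGHILKMFPSTWYV"

#: Randomized CDR3 positions, alpha chain before beta chain.
POSITIONS: Tuple[str, ...] = ("a99", "a100", "a101", "b98", "b99", "b100")

#: Canonical residue/chain mask labels (six single positions + two chains).
MASK_LABELS: Tuple[str, ...] = POSITIONS + ("alpha", "beta")

# VHSE descriptors (8 principal components per amino acid) from Mei et al.,
# Biopolymers 2005, the scale conventionally used for physicochemical
# embeddings of peptide sequences.
VHSE8_TABLE: Dict[str, Tuple[float, ...]] = {
    "A": (0.15, -1.11, -1.35, -0.92, 0.02, -0.91, 0.36, -0.48),
    "R": (-1.47, 1.45, 1.24, 1.27, 1.55, 1.47, 1.30, 0.83),
    "N": (-0.99, 0.00, -0.37, 0.69, -0.55, 0.85, 0.73, -0.80),
    "D": (-1.15, 0.67, -0.41, -0.01, -2.68, 1.31, 0.03, 0.56),
    "C": (0.18, -1.67, -0.46, -0.21, 0.00, 1.20, -1.61, -0.19),
    "Q": (-0.96, 0.12, 0.18, 0.16, 0.09, 0.42, -0.20, -0.41),
    "E": (-1.18, 0.40, 0.10, 0.36, -2.16, -0.17, 0.91, 0.02),
    "G": (-0.20, -1.53, -2.63, 2.28, -0.53, -1.18, 2.01, -1.34),
    "H": (-0.43, -0.25, 0.37, 0.19, 0.51, 1.28, 0.93, 0.65),
    "I": (1.27, -0.14, 0.30, -1.80, 0.30, -1.61, -0.16, -0.13),
    "L": (1.36, 0.07, 0.26, -0.80, 0.22, -1.37, 0.08, -0.62),
    "K": (-1.17, 0.70, 0.70, 0.80, 1.64, 0.67, 1.63, 0.13),
    "M": (1.01, -0.53, 0.43, 0.00, 0.23, 0.10, -0.86, -0.68),
    "F": (1.52, 0.61, 0.96, -0.16, 0.25, 0.28, -1.33, -0.20),
    "P": (0.22, -0.17, -0.50, 0.05, -0.01, -1.34, -0.19, 3.56),
    "S": (-0.67, -0.86, -1.07, -0.41, -0.32, 0.27, -0.64, 0.11),
    "T": (-0.34, -0.51, -0.55, -1.06, -0.06, -0.01, -0.79, 0.39),
    "W": (1.50, 2.06, 1.79, 0.75, 0.75, -0.13, -1.01, -0.85),
    "Y": (0.61, 1.60, 1.17, 0.73, 0.53, 0.25, -0.96, -0.52),
    "V": (0.76, -0.92, -0.17, -1.91, 0.22, -1.40, -0.24, -0.03),
}


@dataclass(frozen=True)
class Alphabet:
    """Ordered amino-acid alphabet of the randomized library."""

    letters: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be unique")
        bad = [aa for aa in self.letters if aa not in CANONICAL_AA]
        if bad:
            raise ValueError(f"non-canonical letters in alphabet: {bad}")

    @property
    def size(self) -> int:
        return len(self.letters)

    @property
    def diversity(self) -> int:
        """Number of distinct 6-mer variants expressible over this alphabet."""
        return self.size ** len(POSITIONS)

    def __contains__(self, letter: str) -> bool:
        return letter in self.letters

    def index(self, letter: str) -> int:
        return self.letters.index(letter)


def make_alphabet(excluded_residue: str = "C") -> Alphabet:
    """Build the randomized-library alphabet by excluding one canonical residue.

    The library spans 19 of the 20 canonical amino acids.  Cysteine is excluded
    by default — the usual choice in display libraries, avoiding unpaired
    disulfides — but the excluded residue is configurable.
    """
    if excluded_residue not in CANONICAL_AA:
        raise ValueError(
            f"excluded residue {excluded_residue!r} is not one of the 20 "
            f"canonical amino acids {CANONICAL_AA}"
        )
    return Alphabet(tuple(aa for aa in CANONICAL_AA if aa != excluded_residue))


@dataclass(frozen=True)
class TCRVariant:
    """A library variant: 3 alpha-chain + 3 beta-chain randomized residues."""

    alpha: str
    beta: str

    def __post_init__(self) -> None:
        if len(self.alpha) != 3 or len(self.beta) != 3:
            raise ValueError("alpha and beta must each be 3 residues")

    @property
    def sequence(self) -> str:
        """Residues in position order a99, a100, a101, b98, b99, b100."""
        return self.alpha + self.beta

    def __getitem__(self, position: str) -> str:
        return self.sequence[POSITIONS.index(position)]

    @classmethod
    def from_sequence(cls, seq: str) -> "TCRVariant":
        if len(seq) != 6:
            raise ValueError(f"variant sequence must have 6 residues, got {seq!r}")
        return cls(seq[:3], seq[3:])


@dataclass(frozen=True)
class EmbeddingScheme:
    """Named per-residue embedding: letter -> fixed-length real vector."""

    name: str
    per_residue_dim: int
    lookup: Mapping[str, np.ndarray] = field(repr=False)

    def vector(self, letter: str) -> np.ndarray:
        try:
            return self.lookup[letter]
        except KeyError:
            raise KeyError(
                f"residue {letter!r} has no {self.name} embedding"
            ) from None


def _blosum50_lookup() -> Dict[str, np.ndarray]:
    mat = substitution_matrices.load("BLOSUM50")
    return {
        aa: np.array([mat[aa, bb] for bb in CANONICAL_AA], dtype=np.float64)
        for aa in CANONICAL_AA
    }


def blosum50_scheme() -> EmbeddingScheme:
    """Residue -> its BLOSUM50 row over the 20 canonical columns (raw scores)."""
    return EmbeddingScheme("BLOSUM50", 20, _blosum50_lookup())


def vhse8_scheme() -> EmbeddingScheme:
    return EmbeddingScheme(
        "VHSE8",
        8,
        {aa: np.asarray(v, dtype=np.float64) for aa, v in VHSE8_TABLE.items()},
    )


def onehot_scheme() -> EmbeddingScheme:
    eye = np.eye(len(CANONICAL_AA))
    return EmbeddingScheme(
        "ONEHOT", 20, {aa: eye[i].copy() for i, aa in enumerate(CANONICAL_AA)}
    )


_SCHEME_FACTORIES = {
    "BLOSUM50": blosum50_scheme,
    "VHSE8": vhse8_scheme,
    "ONEHOT": onehot_scheme,
}

SCHEME_NAMES: Tuple[str, ...] = tuple(_SCHEME_FACTORIES)


def get_scheme(name: str) -> EmbeddingScheme:
    try:
        return _SCHEME_FACTORIES[name.upper()]()
    except KeyError:
        raise ValueError(
            f"unknown embedding scheme {name!r}; choose from {SCHEME_NAMES}"
        ) from None


def embed_sequence(variant: TCRVariant | str, scheme: EmbeddingScheme) -> np.ndarray:
    """Embed a full 6-mer variant, positions concatenated alpha-then-beta.

    The result has exactly ``6 * scheme.per_residue_dim`` entries (120 for
    BLOSUM50/one-hot, 48 for VHSE8).
    """
    seq = variant.sequence if isinstance(variant, TCRVariant) else variant
    if len(seq) != 6:
        raise ValueError(f"expected a 6-residue variant, got {seq!r}")
    return embed_masked_sequence(seq, scheme)


def embed_masked_sequence(seq: str, scheme: EmbeddingScheme) -> np.ndarray:
    """Embed a (possibly residue-deleted) sequence of 1-6 residues.

    Masked sequences carry no indicator of which positions were deleted: the
    embedding is simply the concatenation of the surviving residues' vectors,
    of length ``len(seq) * per_residue_dim``.
    """
    if not 1 <= len(seq) <= 6:
        raise ValueError(
            f"sequence must retain between 1 and 6 residues, got {len(seq)}"
        )
    return np.concatenate([scheme.vector(aa) for aa in seq])


def embed_many(seqs: Iterable[str], scheme: EmbeddingScheme) -> np.ndarray:
    """Vectorized embedding of equal-length sequences into an (n, L*d) matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0))
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("all sequences must have equal length")
    table = np.stack([scheme.vector(aa) for aa in CANONICAL_AA])
    codes = np.array(
        [[CANONICAL_AA.index(aa) for aa in s] for s in seqs], dtype=np.intp
    )
    return table[codes].reshape(len(seqs), length * scheme.per_residue_dim)


def scheme_to_tsv(scheme: EmbeddingScheme, path) -> None:
    """Write the per-residue embedding table as TSV (rows=letters)."""
    import pandas as pd

    rows = {aa: scheme.lookup[aa] for aa in sorted(scheme.lookup)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "letter"
    df.to_csv(path, sep="\t")


def scheme_from_tsv(path, name: str = "CUSTOM") -> EmbeddingScheme:
    """Read a per-residue embedding table written by :func:`scheme_to_tsv`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col="letter")
    lookup = {aa: row.to_numpy(dtype=np.float64) for aa, row in df.iterrows()}
    dims = {v.size for v in lookup.values()}
    if len(dims) != 1:
        raise ValueError("inconsistent embedding dimensions in table")
    return EmbeddingScheme(name, dims.pop(), lookup)
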