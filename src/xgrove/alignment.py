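"""Gapped nucleotide alignments with codon structure.

The central container is :class:`Alignment`, an ordered taxon -> sequence
matrix over the alphabet ``A C G T`` plus gap ``-`` and missing ``N``.
Codon-aware operations (third-position exclusion, per-position GC content)
require ``codon_frame=True``, i.e. a length divisible by three with column
``i`` belonging to codon position ``i % 3 + 1``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

VALID_CHARS = set("ACGTN-")
#: integer codes used by the likelihood engine: A,C,G,T = 0..3, missing = 4
MISSING_CODE = 4
_CODE = {c: i for i, c in enumerate("ACGT")}


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate taxa...)."""


class Alignment:
    """Immutable multiple sequence alignment of nucleotides.

    Parameters
    ----------
    taxa:
        Ordered unique taxon identifiers.
    sequences:
        One upper-case string per taxon, all of equal length. ``U`` is
        accepted and mapped to ``T``; any other non-ACGT symbol is read as
        missing ``N``.
    codon_frame:
        Declare that columns follow reading frame 1 (length % 3 == 0).
    """

    def __init__(self, taxa: Sequence[str], sequences: Sequence[str],
                 codon_frame: bool = False):
        taxa = list(taxa)
        if len(set(taxa)) != len(taxa):
            raise AlignmentError("duplicate taxon identifiers")
        if len(taxa) != len(sequences):
            raise AlignmentError("taxa/sequence count mismatch")
        if not taxa:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}")
        cleaned = []
        for s in sequences:
            s = s.upper().replace("U", "T")
            if set(s) - VALID_CHARS:
                s = "".join(c if c in VALID_CHARS else "N" for c in s)
            cleaned.append(s)
        self._taxa = taxa
        self._index = {t: i for i, t in enumerate(taxa)}
        self._mat = np.array([list(s) for s in cleaned], dtype="<U1")
        if codon_frame and self.length % 3 != 0:
            raise AlignmentError(
                f"codon_frame requires length % 3 == 0, got {self.length}")
        self.codon_frame = bool(codon_frame)

    # -- basic accessors -------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self._taxa)

    @property
    def n_taxa(self) -> int:
        return len(self._taxa)

    @property
    def length(self) -> int:
        return self._mat.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """Character matrix of shape (n_taxa, length), dtype '<U1'."""
        return self._mat

    def sequence(self, taxon: str) -> str:
        return "".join(self._mat[self._index[taxon]])

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def __eq__(self, other) -> bool:
        return (isinstance(other, Alignment) and self._taxa == other._taxa
                and bool(np.all(self._mat == other._mat)))

    def __repr__(self) -> str:
        return f"Alignment({self.n_taxa} taxa x {self.length} bp)"

    def codes(self) -> np.ndarray:
        """uint8 matrix with A,C,G,T = 0..3 and gap/N = 4 (missing)."""
        out = np.full(self._mat.shape, MISSING_CODE, dtype=np.uint8)
        for c, i in _CODE.items():
            out[self._mat == c] = i
        return out

    # -- derived alignments ----------------------------------------------
    def select_taxa(self, taxa: Iterable[str]) -> "Alignment":
        """Restrict to ``taxa`` (kept in the given order)."""
        taxa = list(taxa)
        missing = [t for t in taxa if t not in self._index]
        if missing:
            raise AlignmentError(f"unknown taxa: {missing}")
        rows = [self._index[t] for t in taxa]
        return Alignment(taxa, ["".join(r) for r in self._mat[rows]],
                         codon_frame=self.codon_frame)

    def drop_taxon(self, taxon: str) -> "Alignment":
        if taxon not in self._index:
            raise AlignmentError(f"unknown taxon: {taxon}")
        return self.select_taxa([t for t in self._taxa if t != taxon])

    def codon_subset(self, keep: Iterable[int]) -> "Alignment":
        """Keep only columns at the given codon positions (subset of {1,2,3})."""
        keep = sorted(set(keep))
        if not keep or any(k not in (1, 2, 3) for k in keep):
            raise AlignmentError(f"codon positions must be within {{1,2,3}}: {keep}")
        if self.length % 3 != 0:
            raise AlignmentError("codon_subset requires length divisible by 3")
        pos = np.arange(self.length) % 3 + 1
        cols = np.isin(pos, keep)
        sub = self._mat[:, cols]
        # only the full frame keeps its reading-frame interpretation
        return Alignment(self._taxa, ["".join(r) for r in sub],
                         codon_frame=(keep == [1, 2, 3]))

    def missing_proportion(self) -> float:
        return float(np.mean((self._mat == "-") | (self._mat == "N")))


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered (name, 1-based inclusive column range) over a supermatrix."""

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        pos = 1
        for name, a, b in self.entries:
            if a != pos or b < a:
                raise AlignmentError(
                    f"partition {name!r}: range {a}-{b} not contiguous at {pos}")
            pos = b + 1

    @property
    def total_length(self) -> int:
        return self.entries[-1][2] if self.entries else 0

    def __len__(self) -> int:
        return len(self.entries)

    def to_raxml(self) -> str:
        return "\n".join(f"DNA, {n} = {a}-{b}" for n, a, b in self.entries) + "\n"

    @classmethod
    def from_raxml(cls, text: str) -> "PartitionScheme":
        entries = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            left, rng = line.split("=")
            name = left.split(",", 1)[1].strip()
            a, b = (int(x) for x in rng.strip().split("-"))
            entries.append((name, a, b))
        return cls(tuple(entries))


def concatenate(loci: Sequence[tuple[str, Alignment]]
                ) -> tuple[Alignment, PartitionScheme]:
    """Concatenate named loci into a supermatrix, padding absent taxa with N.

    Returns the supermatrix and the partition scheme with 1-based inclusive
    per-locus column ranges in input order.
    """
    all_taxa: list[str] = []
    for _, aln in loci:
        for t in aln.taxa:
            if t not in all_taxa:
                all_taxa.append(t)
    chunks = {t: [] for t in all_taxa}
    entries = []
    pos = 1
    codon = all(aln.codon_frame for _, aln in loci) and bool(loci)
    for name, aln in loci:
        L = aln.length
        entries.append((name, pos, pos + L - 1))
        pos += L
        for t in all_taxa:
            chunks[t].append(aln.sequence(t) if t in aln else "N" * L)
    sup = Alignment(all_taxa, ["".join(chunks[t]) for t in all_taxa],
                    codon_frame=codon)
    return sup, PartitionScheme(tuple(entries))


# -- FASTA I/O -----------------------------------------------------------

def read_fasta(path: str | Path, codon_frame: bool = False) -> Alignment:
    """Read an aligned FASTA file (equal-length sequences required)."""
    taxa, seqs = [], []
    name, buf = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    taxa.append(name)
                    seqs.append("".join(buf))
                name = line[1:].split()[0]
                buf = []
            elif line:
                buf.append(line)
    if name is not None:
        taxa.append(name)
        seqs.append("".join(buf))
    if not taxa:
        raise AlignmentError(f"no sequences in {path}")
    return Alignment(taxa, seqs, codon_frame=codon_frame)


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for t in aln.taxa:
            fh.write(f">{t}\n")
            s = aln.sequence(t)
            for i in range(0, len(s), wrap):
                fh.write(s[i:i + wrap] + "\n")
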