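"""Foundational DNA/protein sequence handling.

Sequence container, reverse complement, affine-gap global alignment,
percent identity, ORF finding, translation, and FASTA/GenBank IO. All
coordinates in this package are 0-based half-open on the forward strand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# 20 amino acids + stop/ambiguity markers; used only to tell the two
# alphabets apart, not to validate proteins rigorously.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

STANDARD_STOPS = frozenset({"TAA", "TAG", "TGA"})


class AlphabetError(ValueError):
    """Raised when an operation receives a sequence of the wrong alphabet."""


@dataclass(frozen=True)
class Sequence:
    """A named DNA or protein sequence.

    Parameters
    ----------
    id : str
        Record label.
    residues : str
        Upper-case residues. DNA is restricted to A/C/G/T/N.
    topology : str
        ``"linear"`` or ``"circular"``; circular only makes sense for DNA
        replicons (plasmids, chromosomes).
    """

    id: str
    residues: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id!r}: empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear|circular, got {self.topology!r}")
        if self.topology == "circular" and not self.is_dna():
            raise AlphabetError("circular topology is only valid for DNA")

    def __len__(self) -> int:
        return len(self.residues)

    def is_dna(self) -> bool:
        return set(self.residues) <= DNA_ALPHABET

    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass(frozen=True)
class AlignParams:
    """Scoring settings for :func:`global_align`.

    Defaults mirror a ClustalW-style protein setup: BLOSUM62 with gap open
    cost 10 and gap extension cost 0.1. For DNA the default substitution
    scheme is match +1 / mismatch 0 with the same gap costs (configurable).
    """

    matrix: str | None = "BLOSUM62"  # None => match/mismatch scoring
    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = 10.0
    gap_extend: float = 0.1

    @classmethod
    def dna(cls, match: float = 1.0, mismatch: float = 0.0,
            gap_open: float = 10.0, gap_extend: float = 0.1) -> "AlignParams":
        return cls(matrix=None, match=match, mismatch=mismatch,
                   gap_open=gap_open, gap_extend=gap_extend)

    @classmethod
    def protein(cls, matrix: str = "BLOSUM62",
                gap_open: float = 10.0, gap_extend: float = 0.1) -> "AlignParams":
        return cls(matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)


@dataclass(frozen=True)
class Alignment:
    """A pairwise global alignment: two gapped strings of equal length."""

    seq_a: str
    seq_b: str
    score: float
    params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("gapped rows differ in length")

    def ungapped(self) -> tuple[str, str]:
        return self.seq_a.replace("-", ""), self.seq_b.replace("-", "")


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a DNA sequence.

    ``start``/``end`` are 0-based half-open forward-strand coordinates of
    the full ATG..stop span (stop codon included), so ``end - start`` is
    divisible by 3 and the protein has ``(end - start) // 3 - 1`` residues.
    """

    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF span not divisible by 3")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.protein) != (self.end - self.start) // 3 - 1:
            raise ValueError("protein length inconsistent with span")

    @property
    def aa_length(self) -> int:
        return len(self.protein)


def _require_dna(residues: str) -> None:
    bad = set(residues.upper()) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-DNA characters: {sorted(bad)}")


def revcomp(s: Sequence | str) -> Sequence | str:
    """Reverse complement of a DNA sequence (N maps to N).

    Accepts and returns either a bare string or a :class:`Sequence` (the
    latter keeps id and topology).
    """
    if isinstance(s, Sequence):
        if not s.is_dna():
            raise AlphabetError(f"{s.id!r} is not DNA")
        return dataclasses.replace(s, residues=revcomp(s.residues))
    _require_dna(s)
    return s.upper().translate(_COMPLEMENT)[::-1]


def _residues(s: Sequence | str) -> str:
    return s.residues if isinstance(s, Sequence) else s.upper()


def _build_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if params.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    else:
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(a: Sequence | str, b: Sequence | str,
                 params: AlignParams | None = None) -> Alignment:
    """Optimal global (Needleman-Wunsch, affine-gap) pairwise alignment.

    Both inputs must be of the same alphabet. With no ``params``, DNA pairs
    get match +1 / mismatch 0 scoring and protein pairs get BLOSUM62, both
    with gap open 10 / extend 0.1. The first optimal alignment in the
    aligner's fixed traversal order is returned, so output is deterministic.
    """
    ra, rb = _residues(a), _residues(b)
    a_dna = set(ra) <= DNA_ALPHABET
    b_dna = set(rb) <= DNA_ALPHABET
    if a_dna != b_dna:
        raise AlphabetError("cannot align DNA against protein")
    if params is None:
        params = AlignParams.dna() if a_dna else AlignParams.protein()
    aligner = _build_aligner(params)
    aln = aligner.align(ra, rb)[0]
    return Alignment(seq_a=aln[0], seq_b=aln[1], score=float(aln.score), params=params)


def percent_identity(aln: Alignment) -> float:
    """Percent identity of an alignment, over columns where neither row gaps.

    ``100 * identical / (columns with no gap in either row)``. N is counted
    as a mismatch against everything (including N): conservative for DNA.
    """
    ident = 0
    ungapped = 0
    for x, y in zip(aln.seq_a, aln.seq_b):
        if x == "-" or y == "-":
            continue
        ungapped += 1
        if x == y and x != "N":
            ident += 1
    if ungapped == 0:
        raise ValueError("alignment has no ungapped columns")
    return 100.0 * ident / ungapped


def pairwise_identity(a: Sequence | str, b: Sequence | str,
                      params: AlignParams | None = None) -> float:
    """Convenience: align then compute :func:`percent_identity`."""
    return percent_identity(global_align(a, b, params))


def translate(s: Sequence | str) -> str:
    """Standard-code translation; stop codons render as ``*``.

    The input length must be divisible by 3.
    """
    r = _residues(s)
    _require_dna(r)
    if len(r) % 3:
        raise ValueError(f"length {len(r)} not divisible by 3")
    return str(Seq(r).translate(table=1))


def find_orfs(s: Sequence | str, min_aa: int = 1) -> list[Orf]:
    """All ATG..stop ORFs of >= ``min_aa`` residues on both strands.

    Every in-frame ATG opens its own ORF ending at the first downstream stop
    codon (standard code). Coordinates are forward-strand 0-based half-open
    spans including the stop. Sorted by protein length descending, then by
    start (determinism for equal lengths).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    fwd = _residues(s)
    _require_dna(fwd)
    n = len(fwd)
    orfs: list[Orf] = []
    for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
        # first in-frame stop at/after each codon position, per frame
        for frame in range(3):
            starts: list[int] = []
            for i in range(frame, n - 2, 3):
                codon = seq[i:i + 3]
                if codon == "ATG":
                    starts.append(i)
                elif codon in STANDARD_STOPS:
                    for st in starts:
                        aa = (i - st) // 3
                        if aa >= min_aa:
                            if strand == "+":
                                span = (st, i + 3)
                            else:
                                span = (n - (i + 3), n - st)
                            orfs.append(Orf(start=span[0], end=span[1],
                                            strand=strand,
                                            protein=translate(seq[st:i])))
                    starts = []
    orfs.sort(key=lambda o: (-o.aa_length, o.start, o.strand))
    return orfs


# --- IO -------------------------------------------------------------------

def read_fasta(path: str | Path, topology: str = "linear") -> list[Sequence]:
    """Read a (multi-)FASTA file into :class:`Sequence` records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not len(rec.seq):
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        records.append(Sequence(id=rec.id, residues=str(rec.seq).upper(),
                                topology=topology))
    return records


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    """Write records wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


def read_genbank(path: str | Path) -> list[Sequence]:
    """Read GenBank flat files (sequence + topology only)."""
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        topo = rec.annotations.get("topology", "linear")
        records.append(Sequence(id=rec.id, residues=str(rec.seq).upper(),
                                topology="circular" if topo == "circular" else "linear"))
    return records


def read_sequences(path: str | Path, topology: str | None = None) -> list[Sequence]:
    """Dispatch on extension: ``.gb``/``.gbk``/``.genbank`` else FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gb", ".gbk", ".genbank"):
        recs = read_genbank(path)
        if topology is not None:
            recs = [dataclasses.replace(r, topology=topology) for r in recs]
        return recs
    return read_fasta(path, topology=topology or "linear")
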