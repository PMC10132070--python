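"""Characterize an IS element: TIRs, internal repeats, transposase.

Members of this IS family are ~1.3-2.5 kb, bounded by 24-26 bp imperfect
terminal inverted repeats (TIRs) whose outermost bases are 5'-TGT ... ACA-3',
carry a second copy of the inner 19 bp of each TIR 7-10 bp inside the
element (additional transposase binding sites, as in Tn7/TnsB), and encode
a single large DDE transposase (394-507 aa in the curated set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .seqcore import Orf, Sequence, find_orfs, revcomp

# transposase lengths observed across the curated family
TNP_AA_RANGE = (394, 507)
IS_LENGTH_RANGE = (1327, 2528)


@dataclass(frozen=True)
class TirPair:
    """A detected terminal inverted repeat pair.

    ``left_seq`` is the first ``length`` bases of the element; ``right_seq``
    is the reverse complement of the last ``length`` bases, so both read
    outside->in and can be compared position by position.
    """

    left_seq: str
    right_seq: str
    length: int
    n_identical: int
    ends_TGT_ACA: bool

    def __post_init__(self) -> None:
        if len(self.left_seq) != self.length or len(self.right_seq) != self.length:
            raise ValueError("TIR strings inconsistent with length")
        if not 0 <= self.n_identical <= self.length:
            raise ValueError("n_identical out of range")

    @property
    def found(self) -> bool:
        return self.length > 0


NO_TIR = TirPair(left_seq="", right_seq="", length=0, n_identical=0,
                 ends_TGT_ACA=False)


@dataclass(frozen=True)
class InternalRepeat:
    """An interior copy of the inner segment of a TIR.

    ``offset`` is the gap in bp between the TIR's inner edge and the start
    of the repeat copy (expected 7-10); ``identity`` is the match fraction
    to the TIR-derived probe.
    """

    end: str  # "left" | "right"
    offset: int
    length: int
    identity: float

    def __post_init__(self) -> None:
        if self.end not in ("left", "right"):
            raise ValueError(f"end must be left|right, got {self.end!r}")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


@dataclass
class ISElement:
    """An IS sequence with its detected anatomy."""

    seq: Sequence
    tir: TirPair = NO_TIR
    internal: list[InternalRepeat] = field(default_factory=list)
    tnp: Orf | None = None

    @property
    def name(self) -> str:
        return self.seq.id

    def __len__(self) -> int:
        return len(self.seq)


def detect_tirs(is_seq: Sequence | str, min_len: int = 20, max_len: int = 30,
                min_identical_frac: float = 0.7) -> TirPair:
    """Best imperfect terminal inverted repeat over lengths [min_len, max_len].

    For each candidate length L the first L bases are compared with the
    reverse complement of the last L bases; the L maximizing n_identical/L
    wins, ties broken toward longer L. If no L reaches
    ``min_identical_frac`` the distinguishable :data:`NO_TIR` result is
    returned (``found`` is False).
    """
    residues = is_seq.residues if isinstance(is_seq, Sequence) else is_seq.upper()
    if len(residues) < 2 * max_len:
        raise ValueError(f"sequence shorter than 2*max_len ({2 * max_len})")
    best: tuple[float, int, int] | None = None  # (frac, L, n_identical)
    for L in range(min_len, max_len + 1):
        left = residues[:L]
        right = revcomp(residues[-L:])
        n_id = sum(a == b for a, b in zip(left, right))
        frac = n_id / L
        if best is None or (frac, L) > (best[0], best[1]):
            best = (frac, L, n_id)
    frac, L, n_id = best
    if frac < min_identical_frac:
        return NO_TIR
    left = residues[:L]
    right = revcomp(residues[-L:])
    ends = residues[:3] == "TGT" and residues[-3:] == "ACA"
    return TirPair(left_seq=left, right_seq=right, length=L,
                   n_identical=n_id, ends_TGT_ACA=ends)


def tir_string(t: TirPair) -> str:
    """``"n/len"`` label, e.g. ``"19/24"``; ``"-"`` when no TIR was found."""
    if not t.found:
        return "-"
    return f"{t.n_identical}/{t.length}"


def _best_probe_hit(interior: str, probe: str, search_window: int) -> tuple[int, float] | None:
    """Best (offset, identity) of ``probe`` within the first
    ``search_window`` start offsets of ``interior``; ties to smallest offset."""
    plen = len(probe)
    best: tuple[float, int] | None = None
    for off in range(0, min(search_window, len(interior) - plen) + 1):
        seg = interior[off:off + plen]
        if len(seg) < plen:
            break
        ident = sum(a == b for a, b in zip(seg, probe)) / plen
        if best is None or ident > best[0]:
            best = (ident, off)
    if best is None:
        return None
    return best[1], best[0]


def find_internal_repeats(e: ISElement, probe_len: int = 19,
                          search_window: int = 40,
                          min_identity: float = 0.8) -> list[InternalRepeat]:
    """Interior copies of the inner ``probe_len`` bases of each TIR.

    For each end, the inner ``probe_len`` bases of that end's TIR (the
    segment adjacent to the IS interior) are slid across the adjacent
    interior window; the best hit at or above ``min_identity`` is reported
    with its offset from the TIR's inner edge. The right end is handled by
    running the same search on the reverse complement of the element, so
    both offsets read outside->in.
    """
    if not e.tir.found:
        return []
    L = e.tir.length
    out: list[InternalRepeat] = []
    forward = e.seq.residues
    for end, residues, tir_seq in (("left", forward, e.tir.left_seq),
                                   ("right", revcomp(forward), e.tir.right_seq)):
        probe = tir_seq[L - probe_len:]
        interior = residues[L:L + probe_len + search_window]
        hit = _best_probe_hit(interior, probe, search_window)
        if hit is not None and hit[1] >= min_identity:
            out.append(InternalRepeat(end=end, offset=hit[0],
                                      length=probe_len, identity=hit[1]))
    return out


def extract_transposase(e: ISElement | Sequence, min_aa: int = 300) -> Orf:
    """The transposase ORF: the longest ORF of >= ``min_aa`` residues.

    Ties on length break to the leftmost start. Warns when the protein
    length falls outside the family range (the shortest family member lacks
    the C-terminal domain). Raises ``ValueError`` when no ORF qualifies.
    """
    seq = e.seq if isinstance(e, ISElement) else e
    orfs = find_orfs(seq, min_aa=min_aa)
    if not orfs:
        raise ValueError(f"{seq.id!r}: no ORF of >= {min_aa} aa")
    tnp = orfs[0]
    lo, hi = TNP_AA_RANGE
    if not lo <= tnp.aa_length <= hi:
        warnings.warn(
            f"{seq.id!r}: transposase length {tnp.aa_length} aa outside "
            f"the family range [{lo}, {hi}]", stacklevel=2)
    return tnp


def characterize(seq: Sequence, **kwargs) -> ISElement:
    """Run the full anatomy: TIRs, internal repeats, transposase."""
    e = ISElement(seq=seq)
    e.tir = detect_tirs(seq,
                        min_len=kwargs.get("min_len", 20),
                        max_len=kwargs.get("max_len", 30),
                        min_identical_frac=kwargs.get("min_identical_frac", 0.7))
    e.internal = find_internal_repeats(
        e, probe_len=kwargs.get("probe_len", 19),
        search_window=kwargs.get("search_window", 40),
        min_identity=kwargs.get("min_identity", 0.8))
    try:
        e.tnp = extract_transposase(e, min_aa=kwargs.get("min_aa", 300))
    except ValueError:
        e.tnp = None
    return e


def summarize_element(e: ISElement) -> dict:
    """One summary row: name, length, TIR label, tnp length, end triplets."""
    return {
        "name": e.name,
        "length_bp": len(e),
        "tir": tir_string(e.tir),
        "tnp_aa": e.tnp.aa_length if e.tnp is not None else 0,
        "ends_TGT_ACA": e.tir.ends_TGT_ACA,
    }
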