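"""Model and locate dif/pdif sites.

A dif site is an 11 bp XerC binding box and an 11 bp XerD binding box in
inverse orientation separated by a 6 bp spacer (28 bp total). Sites are
scored by Hamming mismatches against consensus boxes: the XerD box against
the pdif consensus variants (the better-conserved half of the site) and the
XerC box against the chromosomal reference. Sites whose XerC box has
diverged beyond a small budget are flagged "dif-like".
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import Sequence, revcomp

XERD_CONSENSUS_VARIANTS = ("TTATGTTAATT", "TTATGTTAAAT")
XERC_REFERENCE = "TGTTCGTATAA"

BOX_LEN = 11
SPACER_LEN = 6
SITE_LEN = 2 * BOX_LEN + SPACER_LEN  # 28

# mm_C above this is reported but flagged as only dif-like
DIF_LIKE_MM_C = 2


@dataclass(frozen=True)
class BindingSiteModel:
    """Consensus boxes and mismatch budgets for site acceptance.

    ``strict()`` (exact XerD box) reproduces a consensus survey;
    ``dif_like()`` (up to 3 XerD mismatches) admits the degenerate sites
    seen outside *Acinetobacter*.
    """

    xerD_variants: tuple[str, ...] = XERD_CONSENSUS_VARIANTS
    xerC_reference: str = XERC_REFERENCE
    spacer_len: int = SPACER_LEN
    max_mm_D: int = 0
    max_mm_C: int = 4

    def __post_init__(self) -> None:
        for box in (*self.xerD_variants, self.xerC_reference):
            if len(box) != BOX_LEN:
                raise ValueError(f"box {box!r} is not {BOX_LEN} bp")
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")

    @property
    def site_len(self) -> int:
        return 2 * BOX_LEN + self.spacer_len

    @classmethod
    def strict(cls) -> "BindingSiteModel":
        return cls(max_mm_D=0)

    @classmethod
    def dif_like(cls) -> "BindingSiteModel":
        return cls(max_mm_D=3)


@dataclass(frozen=True)
class DifSite:
    """A located XerC-box/spacer/XerD-box triple.

    ``start``/``end`` span the whole site on the forward strand (0-based
    half-open). ``xerC``/``spacer``/``xerD`` are given in C->spacer->D
    reading order regardless of genomic strand; for a ``-`` strand site the
    C box therefore occupies the *end* of the forward-strand span.
    """

    replicon_id: str
    start: int
    end: int
    strand: str
    xerC: str
    spacer: str
    xerD: str
    mm_C: int
    mm_D: int

    def __post_init__(self) -> None:
        if self.end - self.start != 2 * BOX_LEN + len(self.spacer):
            raise ValueError("span inconsistent with box/spacer lengths")
        if len(self.xerC) != BOX_LEN or len(self.xerD) != BOX_LEN:
            raise ValueError("boxes must be 11 bp")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def dif_like(self) -> bool:
        """True when the XerC box only loosely resembles the reference."""
        return self.mm_C > DIF_LIKE_MM_C

    def xerC_span(self) -> tuple[int, int]:
        """Forward-strand span of the XerC box."""
        if self.strand == "+":
            return self.start, self.start + BOX_LEN
        return self.end - BOX_LEN, self.end

    def xerD_span(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.end - BOX_LEN, self.end
        return self.start, self.start + BOX_LEN


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def score_box(box11: str, variants: tuple[str, ...] | list[str] | str) -> int:
    """Minimum Hamming distance of an 11 bp box over consensus variants."""
    if len(box11) != BOX_LEN:
        raise ValueError(f"box must be {BOX_LEN} bp, got {len(box11)}")
    if isinstance(variants, str):
        variants = (variants,)
    return min(hamming(box11.upper(), v.upper()) for v in variants)


def parse_site(s28: str, model: BindingSiteModel | None = None,
               replicon_id: str = "site", start: int = 0,
               strand: str = "+") -> DifSite:
    """Split a site string into XerC box | spacer | XerD box and score it.

    The string is interpreted in C->spacer->D reading direction.
    """
    model = model or BindingSiteModel()
    s28 = s28.upper()
    if len(s28) != model.site_len:
        raise ValueError(f"site must be {model.site_len} characters, got {len(s28)}")
    c = s28[:BOX_LEN]
    spacer = s28[BOX_LEN:BOX_LEN + model.spacer_len]
    d = s28[BOX_LEN + model.spacer_len:]
    return DifSite(replicon_id=replicon_id, start=start, end=start + model.site_len,
                   strand=strand, xerC=c, spacer=spacer, xerD=d,
                   mm_C=score_box(c, model.xerC_reference),
                   mm_D=score_box(d, model.xerD_variants))


def _scan_linear(seq: str, rep_id: str, model: BindingSiteModel) -> list[DifSite]:
    w = model.site_len
    out = []
    n = len(seq)
    for i in range(n - w + 1):
        window = seq[i:i + w]
        if "N" in window:
            continue
        for strand, reading in (("+", window), ("-", revcomp(window))):
            d = reading[w - BOX_LEN:]
            if score_box(d, model.xerD_variants) > model.max_mm_D:
                continue
            c = reading[:BOX_LEN]
            if score_box(c, model.xerC_reference) > model.max_mm_C:
                continue
            out.append(parse_site(reading, model, replicon_id=rep_id,
                                  start=i, strand=strand))
    return out


def scan_replicon(rep: Sequence, model: BindingSiteModel | None = None) -> list[DifSite]:
    """Every position (both strands) carrying an acceptable site.

    A hit requires an XerD box within ``max_mm_D`` of a consensus variant
    with an XerC box ``spacer_len`` bp upstream in C->D reading, and
    ``mm_C <= max_mm_C``. Circular replicons are scanned on an extended
    copy so sites may wrap the origin; wrapped hits are reported at their
    (mod L) start. Overlapping hits on opposite strands are both reported.
    Sorted by (start, strand).
    """
    model = model or BindingSiteModel()
    seq = rep.residues
    n = len(seq)
    w = model.site_len
    if rep.is_circular() and n >= w:
        hits = _scan_linear(seq + seq[:w - 1], rep.id, model)
        uniq = {}
        for h in hits:
            key = (h.start % n, h.strand)
            if key not in uniq:
                start = h.start % n
                uniq[key] = DifSite(replicon_id=h.replicon_id, start=start,
                                    end=start + w, strand=h.strand, xerC=h.xerC,
                                    spacer=h.spacer, xerD=h.xerD,
                                    mm_C=h.mm_C, mm_D=h.mm_D)
        hits = list(uniq.values())
    else:
        hits = _scan_linear(seq, rep.id, model)
    hits.sort(key=lambda s: (s.start, s.strand))
    return hits


def classify_orientation(site: DifSite, reference: int) -> str:
    """``"C/D"`` if the XerC box is proximal to ``reference``, else ``"D/C"``.

    ``reference`` is a forward-strand coordinate (e.g. an IS boundary) that
    must lie outside the site span.
    """
    if site.start <= reference < site.end:
        raise ValueError("reference point lies inside the site span")
    c_lo, c_hi = site.xerC_span()
    d_lo, d_hi = site.xerD_span()
    if reference < site.start:
        c_dist, d_dist = c_lo - reference, d_lo - reference
    else:
        c_dist, d_dist = reference - c_hi, reference - d_hi
    return "C/D" if c_dist < d_dist else "D/C"
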