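"""Generate replicons, IS elements and insertion loci with known truth.

The generator emulates the structures this family of elements shows in
real sequence data: elements with imperfect TIRs whose outermost bases are
5'-TGT ... ACA-3', an interior copy of the inner 19 bp of each TIR a few
bp inside the element, a single large transposase ORF, and insertion loci
with the canonical display geometry

    pad - TSD - IS - TSD - XerC box - spacer - XerD box - pad

(the element sits on the XerC side of the site, the second TSD copy being
the gap between them). Backgrounds are uniform A/C/G/T and are
rejection-sampled so no accidental consensus XerD motif occurs; TSDs are
rejection-sampled so the maximal-duplication caller recovers exactly the
planted length. Every draw comes from a seeded generator, so a fixed seed
reproduces the corpus byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dif_scanner import BindingSiteModel, SITE_LEN, XERD_CONSENSUS_VARIANTS
from .insertion_analysis import call_tsd
from .registry import registry_entry
from .seqcore import STANDARD_STOPS, Sequence, find_orfs, revcomp

BASES = "ACGT"
_OTHER = {b: [x for x in BASES if x != b] for b in BASES}

# pads around planted features; keeps 50 bp flank windows collision-free
MIN_PAD = 60


@dataclass(frozen=True)
class ISProfile:
    """Blueprint for one synthetic element.

    ``internal_offset`` may be a fixed int or an inclusive (lo, hi) range
    sampled per end, matching the 7-10 bp spacings seen in the family.
    """

    name: str
    length: int
    tir_len: int
    tir_identical: int
    tnp_aa: int
    tsd_len: int
    internal_offset: int | tuple[int, int] = (7, 10)

    def __post_init__(self) -> None:
        if not 20 <= self.tir_len <= 30:
            raise ValueError("tir_len outside the detectable window 20-30")
        if not 0 < self.tir_identical <= self.tir_len:
            raise ValueError("tir_identical out of range")
        n_mm = self.tir_len - self.tir_identical
        if n_mm > 17:
            raise ValueError("too many TIR mismatches to place in positions 3-19")
        off_hi = self.internal_offset if isinstance(self.internal_offset, int) \
            else self.internal_offset[1]
        fixed = 2 * (self.tir_len + off_hi + 19) + 3 * (self.tnp_aa + 1) + 3
        if fixed > self.length:
            raise ValueError(
                f"{self.name}: anatomy ({fixed} bp) exceeds element length "
                f"{self.length}")

    @classmethod
    def preset(cls, name: str, internal_offset: int | tuple[int, int] = (7, 10)
               ) -> "ISProfile":
        """Build a profile from the curated family registry by IS name."""
        row = registry_entry(name)
        return cls(name=name, length=int(row["length_bp"]),
                   tir_len=int(row["tir_len"]),
                   tir_identical=int(row["tir_identical"]),
                   tnp_aa=int(row["tnp_aa"]), tsd_len=int(row["tsd_len"]),
                   internal_offset=internal_offset)


@dataclass
class ISElementTruth:
    """Planted ground truth for one generated element."""

    name: str
    length: int
    tir_len: int
    tir_n_identical: int
    internal_offsets: dict[str, int]
    orf_start: int
    orf_end: int
    orf_strand: str
    protein: str


@dataclass
class InsertionTruth:
    """Planted ground truth for one insertion locus in a replicon."""

    replicon_id: str
    is_name: str
    start: int
    end: int
    strand: str
    tsd_seq: str
    site_start: int | None
    site_strand: str | None
    distance: int | None

    @property
    def tsd_len(self) -> int:
        return len(self.tsd_seq)


@dataclass
class ModuleTruth:
    """Planted ground truth for one dif module."""

    replicon_id: str
    left_site_start: int
    right_site_start: int
    cargo_start: int
    cargo_end: int
    module_type: str


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n)) if n else ""


def _motif_hits(seq: str, motifs: tuple[str, ...]) -> list[int]:
    hits = []
    rc = revcomp(seq)
    n = len(seq)
    for motif in motifs:
        start = 0
        for hay, flip in ((seq, False), (rc, True)):
            i = hay.find(motif)
            while i >= 0:
                hits.append(n - i - len(motif) if flip else i)
                i = hay.find(motif, i + 1)
    return hits


def scrub_motifs(seq: str, rng: np.random.Generator,
                 motifs: tuple[str, ...] = XERD_CONSENSUS_VARIANTS,
                 protected: list[tuple[int, int]] | None = None) -> str:
    """Mutate accidental motif occurrences (both strands) away.

    One base inside each hit is replaced until no exact occurrence of any
    motif remains; positions inside ``protected`` intervals are never
    touched (a hit fully inside a protected interval is left alone).
    """
    protected = protected or []
    chars = list(seq)
    for _ in range(100):
        hits = _motif_hits("".join(chars), motifs)
        free = []
        for h in hits:
            span = range(h, h + 11)
            editable = [p for p in span
                        if not any(lo <= p < hi for lo, hi in protected)]
            if editable:
                free.append(editable)
        if not free:
            return "".join(chars)
        for editable in free:
            p = editable[len(editable) // 2]
            chars[p] = rng.choice(_OTHER[chars[p]])
    raise RuntimeError("motif scrub failed to converge")


def _random_codons(rng: np.random.Generator, n: int) -> str:
    out = []
    while len(out) < n:
        codon = _random_dna(rng, 3)
        if codon not in STANDARD_STOPS:
            out.append(codon)
    return "".join(out)


def make_is_element(profile: ISProfile, seed: int) -> tuple[Sequence, ISElementTruth]:
    """Generate one element with planted TIRs, internal repeats and ORF.

    TIR mismatches between the two ends are placed at positions 3..19 of
    the repeat (never in the outer TGT/ACA triplets), and the three bases
    just inside each TIR are forced not to extend the inverted repeat, so
    the length-maximizing TIR detector provably recovers the planted
    length and mismatch count. The transposase ORF is preceded by an
    in-frame stop so it cannot be extended upstream.
    """
    rng = np.random.default_rng(seed)
    L = profile.tir_len
    n_mm = L - profile.tir_identical
    for _attempt in range(50):
        left_tir = "TGT" + _random_dna(rng, L - 3)
        mm_pos = rng.choice(np.arange(3, 20), size=n_mm, replace=False)
        right_out = list(left_tir)
        for p in mm_pos:
            right_out[p] = rng.choice(_OTHER[right_out[p]])
        right_out = "".join(right_out)

        if isinstance(profile.internal_offset, int):
            off_l = off_r = profile.internal_offset
        else:
            lo, hi = profile.internal_offset
            off_l = int(rng.integers(lo, hi + 1))
            off_r = int(rng.integers(lo, hi + 1))
        probe_l = left_tir[L - 19:]
        probe_r = right_out[L - 19:]
        left_ext = left_tir + _random_dna(rng, off_l) + probe_l
        right_ext_out = right_out + _random_dna(rng, off_r) + probe_r

        orf_block = "TAA" + "ATG" + _random_codons(rng, profile.tnp_aa - 1) + "TAA"
        middle = profile.length - len(left_ext) - len(right_ext_out) - len(orf_block)
        if middle < 0:
            raise ValueError(f"{profile.name}: inconsistent profile")
        pad_a = middle // 2
        seq = (left_ext + _random_dna(rng, pad_a) + orf_block
               + _random_dna(rng, middle - pad_a) + revcomp(right_ext_out))

        # keep the inverted repeat from extending past the planted length
        chars = list(seq)
        n = len(chars)
        for j in range(3):
            inner = chars[L + j]
            mirror = revcomp(chars[n - L - 1 - j])
            if inner == mirror:
                choices = [b for b in _OTHER[inner] if b != mirror]
                chars[L + j] = rng.choice(choices)
        seq = "".join(chars)

        protected = [(0, len(left_ext)), (n - len(right_ext_out), n)]
        seq = scrub_motifs(seq, rng, protected=protected)
        if _motif_hits(seq, XERD_CONSENSUS_VARIANTS):
            continue  # hit inside a protected interval: redraw

        orf_start = len(left_ext) + pad_a + 3
        orf_end = orf_start + 3 * (profile.tnp_aa + 1)
        orfs = find_orfs(seq, min_aa=profile.tnp_aa)
        if not orfs or (orfs[0].start, orfs[0].end) != (orf_start, orf_end):
            continue  # an accidental ORF outgrew the planted one: redraw
        truth = ISElementTruth(
            name=profile.name, length=len(seq), tir_len=L,
            tir_n_identical=profile.tir_identical,
            internal_offsets={"left": off_l, "right": off_r},
            orf_start=orf_start, orf_end=orf_end, orf_strand="+",
            protein=orfs[0].protein)
        return Sequence(id=profile.name, residues=seq), truth
    raise RuntimeError(f"{profile.name}: element generation did not converge")


def make_dif_site(seed: int | np.random.Generator,
                  model: BindingSiteModel | None = None,
                  mm_C: int = 0, mm_D: int = 0) -> str:
    """A 28 bp site string in C->spacer->D reading order.

    XerC box at ``mm_C`` mismatches from the chromosomal reference, random
    6 bp spacer, XerD box at ``mm_D`` mismatches from one consensus
    variant chosen at random.
    """
    model = model or BindingSiteModel()
    if not 0 <= mm_C <= 11 or not 0 <= mm_D <= 11:
        raise ValueError("mismatch budgets must be within 0..11")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    def mutate(box: str, k: int) -> str:
        chars = list(box)
        for p in rng.choice(len(box), size=k, replace=False):
            chars[p] = rng.choice(_OTHER[chars[p]])
        return "".join(chars)

    c = mutate(model.xerC_reference, mm_C)
    d = mutate(str(rng.choice(list(model.xerD_variants))), mm_D)
    spacer = _random_dna(rng, model.spacer_len)
    return c + spacer + d


def plant_insertion(rep: Sequence, pos: int, element: Sequence, tsd_len: int,
                    seed: int | np.random.Generator,
                    site28: str | None = "auto", strand: str = "+",
                    occupied: list[tuple[int, int]] | None = None
                    ) -> tuple[Sequence, InsertionTruth]:
    """Insert a TSD-flanked element (plus its target site) at ``pos``.

    The cassette follows the canonical locus geometry
    ``TSD - IS - TSD - site`` (distance from element to XerC box equals
    the TSD length); ``site28=None`` plants no site (an untargeted
    insertion), ``"auto"`` draws a consensus site. ``strand="-"`` inserts
    the reverse complement of the whole cassette. The TSD is redrawn until
    the maximal-duplication caller recovers exactly the planted length.
    ``occupied`` intervals (on the pre-insertion replicon) must not
    contain ``pos``.
    """
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    for lo, hi in occupied or []:
        if lo <= pos < hi:
            raise ValueError(f"position {pos} overlaps planted feature [{lo},{hi})")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if site28 == "auto":
        site28 = make_dif_site(rng)
    background = rep.residues
    for _ in range(200):
        tsd = _random_dna(rng, tsd_len)
        if tsd_len == 0 and _ > 0 and pos > 0:
            # nothing to redraw: break the accidental duplication by
            # mutating the background base abutting the cassette
            background = (background[:pos - 1]
                          + rng.choice(_OTHER[background[pos - 1]])
                          + background[pos:])
        cassette = tsd + element.residues + tsd + (site28 or "")
        if strand == "-":
            cassette = revcomp(cassette)
        new_seq = background[:pos] + cassette + background[pos:]
        if strand == "+":
            is_start = pos + tsd_len
        else:
            is_start = pos + (len(site28) if site28 else 0) + tsd_len
        is_end = is_start + len(element)
        # verify the caller sees exactly the planted duplication
        lf = new_seq[max(0, is_start - 50):is_start]
        rf = new_seq[is_end:is_end + 50]
        if strand == "-":
            lf, rf = revcomp(rf), revcomp(lf)
        if call_tsd(lf, rf)[1] == tsd_len:
            break
    else:
        raise RuntimeError("TSD rejection sampling did not converge")
    if site28 is None:
        site_start = site_strand = distance = None
    else:
        site_strand = strand
        distance = tsd_len
        if strand == "+":
            site_start = is_end + tsd_len
        else:
            site_start = pos
    truth = InsertionTruth(replicon_id=rep.id, is_name=element.id,
                           start=is_start, end=is_end, strand=strand,
                           tsd_seq=tsd, site_start=site_start,
                           site_strand=site_strand, distance=distance)
    return Sequence(id=rep.id, residues=new_seq, topology=rep.topology), truth


def plant_module(rep: Sequence, pos: int, cargo_len: int,
                 seed: int | np.random.Generator,
                 module_type: str = "C-type"
                 ) -> tuple[Sequence, ModuleTruth]:
    """Insert a dif module: cargo bounded by two inversely oriented sites.

    A C-type module has both XerC boxes facing the cargo (left boundary on
    the reverse strand, right boundary forward); D-type is the mirror.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if module_type not in ("C-type", "D-type"):
        raise ValueError(f"bad module_type {module_type!r}")
    left = make_dif_site(rng)
    right = make_dif_site(rng)
    cargo = scrub_motifs(_random_dna(rng, cargo_len), rng)
    if module_type == "C-type":
        cassette = revcomp(left) + cargo + right
    else:
        cassette = left + cargo + revcomp(right)
    new_seq = rep.residues[:pos] + cassette + rep.residues[pos:]
    truth = ModuleTruth(replicon_id=rep.id, left_site_start=pos,
                        right_site_start=pos + SITE_LEN + cargo_len,
                        cargo_start=pos + SITE_LEN,
                        cargo_end=pos + SITE_LEN + cargo_len,
                        module_type=module_type)
    return Sequence(id=rep.id, residues=new_seq, topology=rep.topology), truth


def make_background(rng: np.random.Generator, rep_id: str, length: int,
                    topology: str = "circular") -> Sequence:
    """Uniform-composition replicon with no accidental XerD consensus."""
    return Sequence(id=rep_id, residues=scrub_motifs(_random_dna(rng, length), rng),
                    topology=topology)


@dataclass
class DatasetParams:
    """Study conditions for a generated corpus.

    Defaults: 10 circular ~8 kb replicons with 3 targeted insertions each,
    elements drawn from the two *Acinetobacter* clusters plus the
    long-TSD founder profile, all TSDs per preset.
    """

    n_replicons: int = 10
    replicon_length: int = 8000
    insertions_per_replicon: int = 3
    profiles: tuple[str, ...] = ("ISAjo2", "ISAba32", "IS1202")
    with_sites: bool = True
    modules_per_replicon: int = 0
    module_cargo_len: int = 600
    topology: str = "circular"


@dataclass
class Dataset:
    replicons: list[Sequence]
    elements: dict[str, Sequence]
    element_truth: dict[str, ISElementTruth]
    insertions: list[InsertionTruth]
    modules: list[ModuleTruth] = field(default_factory=list)

    def truth_table(self) -> pd.DataFrame:
        rows = [{
            "replicon": t.replicon_id, "is_name": t.is_name,
            "start": t.start, "end": t.end, "strand": t.strand,
            "tsd": t.tsd_seq, "tsd_len": t.tsd_len,
            "site_start": t.site_start if t.site_start is not None else "",
            "site_strand": t.site_strand or "",
            "distance": t.distance if t.distance is not None else "",
        } for t in self.insertions]
        return pd.DataFrame(rows)


def make_dataset(params: DatasetParams | None = None, seed: int = 0) -> Dataset:
    """Generate a reproducible corpus with machine-readable ground truth.

    Elements are generated once per profile; each replicon receives
    ``insertions_per_replicon`` insertions at evenly spaced positions
    (pads >= 60 bp apart by construction) and optionally planted modules.
    """
    params = params or DatasetParams()
    rng = np.random.default_rng(seed)
    elements: dict[str, Sequence] = {}
    element_truth: dict[str, ISElementTruth] = {}
    for name in params.profiles:
        profile = ISProfile.preset(name)
        elements[name], element_truth[name] = make_is_element(
            profile, seed=int(rng.integers(0, 2**31 - 1)))

    n_ins = params.insertions_per_replicon
    n_mod = params.modules_per_replicon
    n_slots = n_ins + n_mod
    if n_slots and params.replicon_length < (n_slots + 1) * 2 * MIN_PAD:
        raise ValueError("replicon too short for the requested feature packing")

    insertions: list[InsertionTruth] = []
    modules: list[ModuleTruth] = []
    replicons: list[Sequence] = []
    for r in range(params.n_replicons):
        rep = make_background(rng, f"rep{r:02d}", params.replicon_length,
                              params.topology)
        gap = params.replicon_length // (n_slots + 1) if n_slots else 0
        # plant right-to-left: inserting at a lower position shifts the
        # features already planted to its right by the cassette length
        slots = [gap * (k + 1) for k in range(n_slots)][::-1]
        local_ins: list[InsertionTruth] = []
        local_mod: list[ModuleTruth] = []
        for k, pos in enumerate(slots):
            before = len(rep)
            if k < n_mod:
                rep, mtruth = plant_module(rep, pos, params.module_cargo_len,
                                           rng)
                local_mod.append(mtruth)
            else:
                name = params.profiles[len(local_ins) % len(params.profiles)]
                profile = ISProfile.preset(name)
                # on module-bearing replicons all insertion sites face the
                # same way as the module's left boundary, so adjacent-pair
                # module discovery cannot pair an IS target site with a
                # module boundary
                strand = "-" if n_mod else ("+" if rng.random() < 0.5 else "-")
                # only the short-TSD subgroup targets dif sites; long/no-TSD
                # members show no associated site in real data
                targeted = params.with_sites and 1 <= profile.tsd_len <= 5
                rep, truth = plant_insertion(
                    rep, pos, elements[name], profile.tsd_len, rng,
                    site28="auto" if targeted else None, strand=strand)
                local_ins.append(truth)
            shift = len(rep) - before
            for t in local_ins[:-1] if k >= n_mod else local_ins:
                if t.start >= pos:
                    t.start += shift
                    t.end += shift
                    if t.site_start is not None:
                        t.site_start += shift
            for m in local_mod[:-1] if k < n_mod else local_mod:
                if m.cargo_start >= pos:
                    m.left_site_start += shift
                    m.right_site_start += shift
                    m.cargo_start += shift
                    m.cargo_end += shift
        insertions.extend(sorted(local_ins, key=lambda t: t.start))
        modules.extend(local_mod)
        replicons.append(rep)
    return Dataset(replicons=replicons, elements=elements,
                   element_truth=element_truth, insertions=insertions,
                   modules=modules)
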