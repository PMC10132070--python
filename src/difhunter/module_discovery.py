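"""Discover dif modules and match them against a catalog.

A dif module is a cargo interval bounded by two inversely oriented pdif
sites. By which boxes face the cargo, modules are C-type (XerC boxes
inward) or D-type (XerD boxes inward); the mobile modules documented
around these IS are C-type. Discovered cargo is compared against a
user-supplied catalog of named modules; below-threshold matches are
reported as novel.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dif_scanner import DifSite
from .seqcore import AlignParams, Sequence, global_align, percent_identity


@dataclass(frozen=True)
class DifModule:
    """A cargo interval bounded by two inversely oriented pdif sites."""

    replicon_id: str
    left_site: DifSite
    right_site: DifSite
    cargo_start: int
    cargo_end: int
    module_type: str  # "C-type" | "D-type"
    cargo_seq: str

    def __post_init__(self) -> None:
        if not (self.left_site.end <= self.cargo_start
                <= self.cargo_end <= self.right_site.start):
            raise ValueError("cargo interval not between the two sites")
        if self.left_site.strand == self.right_site.strand:
            raise ValueError("bounding sites must be inversely oriented")
        if self.module_type not in ("C-type", "D-type"):
            raise ValueError(f"bad module_type {self.module_type!r}")


@dataclass(frozen=True)
class CatalogMatch:
    """Best catalog hit for a module's cargo, or ``"novel"``."""

    module_name: str
    identity: float
    coverage: float


def _inward_box(site: DifSite, side: str) -> str:
    """Which box faces the cargo when ``site`` bounds it on ``side``.

    A ``+`` site reads C->spacer->D left to right on the forward strand, so
    as a left boundary its D box faces the cargo; a ``-`` site has its C
    box at the right of the span.
    """
    if side == "left":
        return "D" if site.strand == "+" else "C"
    return "C" if site.strand == "+" else "D"


def find_modules(rep: Sequence, sites: list[DifSite],
                 max_cargo: int = 20000) -> list[DifModule]:
    """Pair inversely oriented sites into modules, greedily left to right.

    A module's cargo contains no further site, so each site is considered
    only with the next non-overlapping site along the replicon: when that
    neighbour is oppositely oriented and the cargo span is <= ``max_cargo``
    the pair forms a module and both sites are consumed. Pairing is
    non-nested and deterministic. Sites left unpaired (e.g. a lone pdif
    site next to an IS in a plasmid backbone) are simply not part of any
    module.
    """
    ordered = sorted(sites, key=lambda s: (s.start, s.strand))
    modules: list[DifModule] = []
    i = 0
    while i < len(ordered):
        left = ordered[i]
        j = i + 1
        while j < len(ordered) and ordered[j].start < left.end:
            j += 1  # overlapping opposite-strand hits of one locus
        if j < len(ordered):
            right = ordered[j]
            if (right.strand != left.strand
                    and right.start - left.end <= max_cargo):
                mtype = ("C-type" if _inward_box(left, "left") == "C"
                         else "D-type")
                modules.append(DifModule(
                    replicon_id=rep.id, left_site=left, right_site=right,
                    cargo_start=left.end, cargo_end=right.start,
                    module_type=mtype,
                    cargo_seq=rep.residues[left.end:right.start]))
                i = j + 1
                continue
        i += 1
    return modules


def unpaired_sites(sites: list[DifSite], modules: list[DifModule]) -> list[DifSite]:
    """Sites not bounding any module (plasmid-backbone contexts)."""
    bound = {id(m.left_site) for m in modules} | {id(m.right_site) for m in modules}
    taken = {(m.left_site.start, m.left_site.strand) for m in modules}
    taken |= {(m.right_site.start, m.right_site.strand) for m in modules}
    return [s for s in sites
            if id(s) not in bound and (s.start, s.strand) not in taken]


def match_catalog(m: DifModule, catalog: list[Sequence],
                  min_identity: float = 95.0,
                  min_coverage: float = 80.0) -> CatalogMatch:
    """Best global-alignment identity of the cargo over catalog entries.

    Both orientations of the cargo are tried (module orientation on the
    replicon is arbitrary). Below either threshold the module is reported
    as ``"novel"``; an empty catalog makes every module novel.
    """
    from .seqcore import revcomp

    if not m.cargo_seq:
        return CatalogMatch(module_name="novel", identity=0.0, coverage=0.0)
    best: CatalogMatch | None = None
    params = AlignParams.dna()
    for entry in catalog:
        for cargo in (m.cargo_seq, revcomp(m.cargo_seq)):
            aln = global_align(cargo, entry.residues, params)
            ident = percent_identity(aln)
            coverage = 100.0 * min(len(cargo), len(entry.residues)) \
                / max(len(cargo), len(entry.residues))
            if best is None or (ident, coverage) > (best.identity, best.coverage):
                best = CatalogMatch(module_name=entry.id, identity=ident,
                                    coverage=coverage)
    if best is None or best.identity < min_identity or best.coverage < min_coverage:
        return CatalogMatch(module_name="novel",
                            identity=best.identity if best else 0.0,
                            coverage=best.coverage if best else 0.0)
    return best
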