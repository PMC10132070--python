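"""Family-definition machinery: identity matrices, clusters, phylogeny.

Pairwise percent-identity matrices (ClustalW-style settings: BLOSUM62,
gap open 10 / extend 0.1 for proteins), the isoform rule (>98 % aa or
>95 % nt identity), single-linkage identity clustering, neighbour-joining
trees on d = 100 - identity with column-bootstrap majority-rule consensus
support, and the DDE catalytic-motif check (the diagnostic Q at the
seventh position after the catalytic E).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .seqcore import AlignParams, Sequence, global_align, percent_identity

ISOFORM_AA_THRESHOLD = 98.0
ISOFORM_NT_THRESHOLD = 95.0
CLUSTER_AA_THRESHOLD = 90.0


@dataclass
class IdentityMatrix:
    """Symmetric all-pairs percent-identity matrix (diagonal 100)."""

    labels: list[str]
    values: np.ndarray
    kind: str  # "nt" | "aa"

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("diagonal must be 100")
        if self.values.min() < 0 or self.values.max() > 100.0 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")
        if self.kind not in ("nt", "aa"):
            raise ValueError(f"kind must be nt|aa, got {self.kind!r}")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def distances(self) -> np.ndarray:
        """Distance transform d = 100 - percent identity."""
        return 100.0 - self.values


@dataclass
class Tree:
    """An unrooted tree with branch lengths and per-split support (%).

    Thin wrapper over a dendropy tree; ``newick()`` writes support values
    as internal node labels.
    """

    dtree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)

    def leaf_names(self) -> set[str]:
        return {lf.taxon.label for lf in self.dtree.leaf_node_iter()}

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the smaller leaf-name side."""
        return _splits(self.dtree)

    def newick(self) -> str:
        for node in self.dtree.preorder_internal_node_iter():
            sup = getattr(node, "support", None)
            if sup is not None and node.parent_node is not None:
                node.label = f"{sup:g}"
        return self.dtree.as_string(
            schema="newick", suppress_rooting=True).strip()


def _splits(dtree: dendropy.Tree) -> set[frozenset]:
    taxa = frozenset(lf.taxon.label for lf in dtree.leaf_node_iter())
    out: set[frozenset] = set()
    for node in dtree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(taxa) - 1:
            other = taxa - side
            out.add(side if (len(side), sorted(side)) <= (len(other), sorted(other))
                    else other)
    return out


def identity_matrix(seqs: list[Sequence], kind: str,
                    params: AlignParams | None = None) -> IdentityMatrix:
    """All-pairs percent identity via global alignment.

    ``kind`` selects default scoring: BLOSUM62 for ``"aa"``, match/mismatch
    for ``"nt"``, both with gap open 10 / extend 0.1.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    labels = [s.id for s in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if params is None:
        params = AlignParams.dna() if kind == "nt" else AlignParams.protein()
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = percent_identity(global_align(seqs[i], seqs[j], params))
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(labels=labels, values=values, kind=kind)


def isoform_check(id_nt: float, id_aa: float) -> bool:
    """ISFinder isoform rule: >98 % aa identity and/or >95 % nt identity."""
    return id_aa > ISOFORM_AA_THRESHOLD or id_nt > ISOFORM_NT_THRESHOLD


def cluster_by_identity(m: IdentityMatrix,
                        threshold: float = CLUSTER_AA_THRESHOLD) -> list[set[str]]:
    """Single-linkage components over identity edges strictly above threshold.

    Returns a partition of the labels, components sorted by their smallest
    member for determinism.
    """
    n = len(m.labels)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if m.values[i, j] > threshold:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(m.labels[i])
    return sorted(comps.values(), key=lambda s: min(s))


def _nj_newick(labels: list[str], dist: np.ndarray) -> str:
    """Saitou-Nei neighbour joining, deterministic.

    Q-matrix ties are broken toward the pair whose representative leaf
    labels (the lexicographically smallest leaf in each cluster) sort
    lowest, so runs are reproducible regardless of input order or object
    identity. The final three clusters are resolved in closed form around
    the central node.
    """
    n = len(labels)
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n)}
    newick = {i: lab for i, lab in enumerate(labels)}
    rep = {i: lab for i, lab in enumerate(labels)}
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((rep[i], rep[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        newick[nxt] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        rep[nxt] = min(rep[i], rep[j])
        for k in active:
            if k in (i, j):
                continue
            dk = (d[i, k] + d[j, k] - d[i, j]) / 2
            d[nxt, k] = d[k, nxt] = dk
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = d[a, b] - la
    lc = d[a, c] - la
    return (f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},"
            f"{newick[c]}:{lc:.10g});")


def _nj_dendropy(labels: list[str], dist: np.ndarray,
                 tns: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(data=_nj_newick(labels, dist), schema="newick",
                             taxon_namespace=tns, preserve_underscores=True)


def nj_tree(m: IdentityMatrix) -> Tree:
    """Unrooted neighbour-joining tree on d = 100 - identity."""
    if len(m.labels) < 3:
        raise ValueError("need at least three labels for a tree")
    return Tree(dtree=_nj_dendropy(m.labels, m.distances()))


# --- multiple alignment + bootstrap --------------------------------------

def multiple_align(seqs: list[Sequence]) -> list[Sequence]:
    """Multiple sequence alignment of protein or DNA sequences via MAFFT."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    mafft = shutil.which("mafft")
    if mafft is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        with open(fin, "w") as fh:
            for s in seqs:
                fh.write(f">{s.id}\n{s.residues}\n")
        proc = subprocess.run([mafft, "--quiet", "--retree", "2", str(fin)],
                              capture_output=True, text=True, check=True)
    out: list[Sequence] = []
    label, chunks = None, []
    for line in proc.stdout.splitlines() + [">"]:
        if line.startswith(">"):
            if label is not None:
                out.append(Sequence(id=label, residues="".join(chunks).upper()))
            label, chunks = line[1:].split()[0] if len(line) > 1 else None, []
        else:
            chunks.append(line.strip())
    order = {s.id: s for s in out}
    return [order[s.id] for s in seqs]


def _alignment_identity_matrix(labels: list[str], cols: np.ndarray) -> np.ndarray:
    """Pairwise identity (%) from alignment columns (rows x columns array)."""
    n = cols.shape[0]
    values = np.full((n, n), 100.0)
    gap = cols == "-"
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(gap[i] | gap[j])
            tot = int(both.sum())
            ident = 100.0 * float((cols[i][both] == cols[j][both]).sum()) / tot \
                if tot else 0.0
            values[i, j] = values[j, i] = ident
    return values


def bootstrap_consensus(aligned: list[Sequence], n_resamples: int = 10000,
                        seed: int = 0) -> Tree:
    """Majority-rule consensus of NJ trees over column bootstrap replicates.

    Columns of the multiple alignment are resampled with replacement; for
    each replicate an identity matrix and an NJ tree are rebuilt; splits
    occurring in >50 % of replicates form the consensus, with support =
    split frequency x 100. Deterministic for a fixed seed.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    labels = [s.id for s in aligned]
    ncol = len(aligned[0].residues)
    if any(len(s.residues) != ncol for s in aligned):
        raise ValueError("sequences are not aligned (unequal lengths)")
    cols = np.array([list(s.residues) for s in aligned])
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=tns)
    for _ in range(n_resamples):
        idx = rng.integers(0, ncol, size=ncol)
        values = _alignment_identity_matrix(labels, cols[:, idx])
        trees.append(_nj_dendropy(labels, 100.0 - values, tns))
    cons = trees.consensus(min_freq=0.5, support_as_percentages=True)
    tree = Tree(dtree=cons)
    for node in cons.preorder_internal_node_iter():
        sup = getattr(node, "support", None)
        if sup is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        tree.supports[side] = float(sup)
    return tree


# --- DDE motif ------------------------------------------------------------

@dataclass(frozen=True)
class DdeReport:
    """Catalytic-triad check for a DDE transposase.

    Positions are 1-based residue numbers. ``residue_at_E_plus_7`` is the
    amino acid seven positions downstream of the catalytic E - Q in this
    family, where other DDE transposases carry R or K - and ``motif_ok``
    requires D/D/E at the stated positions plus that Q.
    """

    d1: int
    d2: int
    e: int
    residues: tuple[str, str, str]
    residue_at_E_plus_7: str
    motif_ok: bool


def dde_motif_check(protein: Sequence | str,
                    positions: tuple[int, int, int] = (142, 203, 247)
                    ) -> DdeReport:
    """Verify the D, D, E catalytic residues and the E+7 signature.

    ``positions`` are 1-based. Raises when any position (or E+7) exceeds
    the protein length.
    """
    seq = protein.residues if isinstance(protein, Sequence) else protein.upper()
    d1, d2, e = positions
    if not 1 <= d1 < d2 < e:
        raise ValueError("positions must be strictly increasing and >= 1")
    if e + 7 > len(seq):
        raise ValueError(f"position {e}+7 beyond protein length {len(seq)}")
    found = (seq[d1 - 1], seq[d2 - 1], seq[e - 1])
    at7 = seq[e + 7 - 1]
    ok = found == ("D", "D", "E") and at7 == "Q"
    return DdeReport(d1=d1, d2=d2, e=e, residues=found,
                     residue_at_E_plus_7=at7, motif_ok=ok)
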