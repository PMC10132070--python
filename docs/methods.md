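# Methods

## The site model

A dif site is modelled as XerC box (11 bp) + spacer (6 bp) + XerD box
(11 bp), 28 bp in all, read in C→spacer→D order. Boxes are scored by
plain Hamming distance; no position-weight or log-odds scoring is
attempted because the published surveys operate on literal consensus
matching. The XerD box is scored as the minimum distance over the two
consensus variants `TTATGTTAATT` and `TTATGTTAAAT`; the XerC box against
the chromosomal reference `TGTTCGTATAA`. Two acceptance modes are
exposed: *strict* (`max_mm_D = 0`, the default for surveys of intact
sites) and *dif-like* (`max_mm_D = 3`), which admits the degenerate
sites observed outside *Acinetobacter*. Either mode also requires
`mm_C ≤ 4`; sites with `mm_C > 2` are flagged `dif_like` in reports,
since the XerC half is known to diverge much faster than the XerD half.
`N` never matches anything (conservative). Scanning a circular replicon
extends the sequence by one window so sites may wrap the origin;
duplicated wrapped hits are collapsed.

Coordinates are 0-based half-open on the forward strand throughout the
library; GFF3 output converts to 1-based inclusive. A site on the `-`
strand stores its boxes in C→spacer→D reading order (the display
convention of the published tables), so its XerC box occupies the *end*
of the forward-strand span — orientation logic (`classify_orientation`,
C/D when the XerC box is proximal to a reference point) accounts for
this.

## Element anatomy

TIR detection compares, for each candidate length L in 20–30 bp, the
first L bases with the reverse complement of the last L bases and keeps
the L maximizing the identical fraction, ties resolved toward longer L.
The window brackets the 23–29 bp repeats recorded across the family. A
result below `min_identical_frac` (default 0.7, matching the 19/24–20/26
identity of the *Acinetobacter* cluster elements; the most diverged
family repeats, e.g. 17/28, need a relaxed threshold) is returned as a
distinguishable no-TIR value rather than an exception. The internal
binding-site search slides the inner 19 bp of each TIR across the
adjacent 40 bp of interior sequence and reports the best hit at ≥0.8
identity with its offset from the TIR inner edge; the right end is
handled on the reverse complement of the element so both ends read
outside→in. The transposase is the longest ORF ≥300 aa (ties to the
leftmost start, for determinism), with a warning outside the family
range of 394–507 aa.

## Copy location and TSD calling

`locate_is_copies` seeds candidate loci with shared 15-mers binned by
diagonal (±30 bp to absorb indels), then aligns the whole query against
the candidate window with a glocal (free target ends) edit-distance
alignment via edlib. Identity is `100·(1 − edits/|query|)`; overlapping
candidates resolve best-identity-first, then leftmost. Flanks are
reported in the element's own orientation, so "left" always abuts the
left TIR; circular replicons wrap and truncation at linear ends is
flagged rather than padded.

The TSD is the longest exact match (up to 40 bp, above the longest
duplication recorded for the family, 28 bp) between the end of the left
flank and the start of the right flank. Matching is exact because the
documented duplications are identical copies; a mismatch-tolerant caller
would blur the subgroup boundaries the TSD length defines. Subgroups:
0 → none, 1–15 → short (with the observed 3–5 bp band flagged), >15 →
long. The target-site association scans both flanks in both readings and
reports the site whose XerC box lies nearest the element;
`orientation_consistent` is true when that box is the element-proximal
box, the arrangement every documented targeting event shows. Distance
and TSD length are computed independently — they coincide in all
published loci, but the pipeline never assumes it.

## Module discovery

Modules pair a site with the next non-overlapping site along the
replicon when the two are inversely oriented and the cargo is ≤20 kb;
the pairing is adjacent-only because a module's cargo contains no
further boundary site, and greedy left-to-right for determinism. C-type
means both XerC boxes face the cargo. Cargo is matched against a
user-supplied catalog by global alignment in both orientations; below
95 % identity or 80 % coverage the module is reported novel. The 95 %
novelty threshold reflects the treatment of ~94 %-identical
toxin–antitoxin module variants as new modules in the published survey.

## Comparative machinery

Pairwise identity uses global affine-gap alignment — BLOSUM62 with gap
open 10 / extend 0.1 for proteins (ClustalW-style settings), match +1 /
mismatch 0 with the same gap costs for DNA (a documented, configurable
choice; the published analysis states only the protein matrix). Identity
is counted over columns where neither row gaps; the alignment engine is
Biopython's `PairwiseAligner`. Distances for trees are d = 100 −
identity: simple, monotone, and sufficient for topology at the identity
ranges involved.

Neighbour joining is implemented directly (Saitou–Nei), with Q-matrix
ties broken toward the pair whose representative leaf labels sort
lowest; an earlier delegation to a library NJ was dropped because its
tie handling depended on object identity and broke run-to-run
reproducibility. The final three clusters are resolved in closed form.
Correctness is checked in the tests against exhaustive topology
enumeration with least-squares branch fitting on additive matrices.
Bootstrap support resamples alignment columns with replacement, rebuilds
the identity matrix and NJ tree per replicate, and takes the
majority-rule (>50 %) consensus with support = split frequency × 100;
the multiple alignment underneath comes from MAFFT. 10 000 resamples are
practical at family scale; tests use 25–200. Single-linkage clustering
at >90 % aa identity reproduces the two-cluster structure of the
*Acinetobacter* elements; the isoform rule is >98 % aa or >95 % nt
identity, strict inequalities.

The DDE check verifies D/D/E at stated 1-based positions and reports the
residue seven positions after the catalytic E; the family signature is Q
there, where most DDE transposases carry R or K.

## The synthetic generator

The generator emulates what the family's elements look like in real
sequence data: uniform-composition backgrounds (GC content is not
modelled), elements with imperfect TIRs whose outermost bases are
TGT…ACA, interior copies of the inner 19 bp of each TIR at 7–10 bp
offsets, a single transposase ORF of the registry length made of random
codons (no homology to real transposases — anatomy tests need geometry,
not phylogeny; the DDE fixture is a separately constructed protein), and
targeted insertion loci in the canonical geometry with the site on the
XerC side. Three constructions guarantee recoverability rather than
leaving it to chance:

- TIR mismatches are confined to positions 3–19 of the repeat and the
  three bases just inside each TIR are forced not to extend the inverted
  repeat. Under the length-selection rule this makes the planted (L,
  n_identical) the unique maximizer: for shorter candidates the identity
  fraction (L − m)/L increases toward the planted L, and for longer ones
  the three forced mismatches cap the fraction below the planted value
  across the whole 20–30 window.
- Backgrounds and element interiors are scrubbed of exact XerD-consensus
  occurrences on both strands, so strict scans find planted sites and
  nothing else.
- TSDs (and the bases abutting zero-TSD insertions) are rejection-sampled
  until the maximal-duplication caller returns exactly the planted
  length.

The transposase ORF is preceded by an in-frame stop so it cannot extend
upstream, and generation is retried if an accidental ORF outgrows it.
Long-TSD and no-TSD elements are planted without an associated site,
matching the observation that only the short-TSD subgroup targets
dif-like sites. On module-bearing replicons all insertions are planted
on the reverse strand so an IS target site can never pair with a module
boundary under adjacent-pair discovery. A fixed seed reproduces every
byte of output.

What the generator does not emulate: realistic base composition or codon
usage, sequence homology between elements of one family, nested or
truncated elements, decayed TSDs, or module cargo with real genes.
Passing tests therefore demonstrate the correctness of the detection
logic under the documented geometry, not recall on diverged real-world
loci — for those, the printed-survey reconstruction tests (real site
strings and TSDs around synthetic element bodies) are the closer proxy.

## Problem sizes and defaults

The default corpus is 10 circular 8 kb replicons × 3 insertions, the
scale of the plasmid loci the method addresses; the bulk property check
runs 100 seeds of a 6 kb/2-insertion corpus, which exercises the same
code paths at one-third the cost. Registry profiles whose real anatomy
overlaps the transposase ORF with the end repeats (e.g. the most compact
no-TSD member) cannot be expressed by the non-overlapping generator
layout and are rejected with an explanatory error rather than silently
adjusted.

## Known limitations

- Identity values depend mildly on the (documented) DNA scoring scheme
  and on the gap-column-free denominator; a ±0.5-point band should be
  allowed when comparing to values produced by other aligners.
- The site scanner is consensus-based; genuinely novel dif-like sites
  with a different XerD consensus (as hypothesized for some hosts) will
  be missed by design.
- `locate_is_copies` is built for near-identity copies (≥95 %); it is
  not a general homology search and has no E-value model.
- Bootstrap consensus requires an external MAFFT binary.
- The full-length nucleotide identity check between the two closest
  named elements requires their sequences from the public IS database,
  which are not redistributable with the package; the corresponding test
  reports failure until the user supplies them.
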