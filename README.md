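# difhunter

Tools for annotating a family of bacterial insertion sequences (IS) that
target *dif* and *pdif* recombination sites — "*dif*-site hunters". These
~1.3–2.5 kb elements, typified by ISAjo2 and its relatives in
*Acinetobacter* plasmids, are found a fixed short distance (typically
5 bp) from the XerC binding box of a dif/pdif site, always in the same
orientation, flanked by a short target-site duplication (TSD). The
package is aimed at mobile-genetic-element and plasmid researchers who
want to reproduce or extend this style of analysis on their own replicons.

## What it computes

A *dif* site is an 11 bp XerC box and an 11 bp XerD box in inverse
orientation separated by a 6 bp spacer:

```
XerC(11) — spacer(6) — XerD(11)        e.g.  TGTTCGTATAA TGTATA TTATGTTAAAT
```

Sites are scored by Hamming mismatches: the XerD box (the conserved half)
against the pdif consensus variants `TTATGTTAATT` / `TTATGTTAAAT`, the
XerC box against the chromosomal reference `TGTTCGTATAA`. The canonical
targeted locus reads

```
flank — TSD — IS — TSD — XerC — spacer — XerD — flank
```

so the distance from the element to the XerC box equals the TSD length.
The pipeline stages are:

- **seqcore** — sequences, affine-gap global alignment (Needleman–Wunsch;
  BLOSUM62 for proteins, gap open 10 / extend 0.1), percent identity over
  ungapped columns, ORF finding, FASTA/GenBank IO.
- **dif_scanner** — locate sites on both strands (strict or
  mismatch-tolerant "dif-like" mode), classify C/D vs D/C orientation.
- **is_anatomy** — detect the 24–26 bp imperfect terminal inverted
  repeats (TIRs, outermost bases 5′-TGT…ACA-3′), the interior copy of the
  inner 19 bp of each TIR (an additional transposase binding site 7–10 bp
  inside the element), and the 394–507 aa DDE transposase.
- **insertion_analysis** — find IS copies in replicons (k-mer seeding +
  glocal alignment), extract 50 bp flanks, call the TSD as the longest
  exact duplication bridging the element, measure the distance to the
  XerC box, and classify the TSD subgroup (short 3–5 bp / long >15 bp /
  none).
- **module_discovery** — pair inversely oriented pdif sites into *dif*
  modules (C-type or D-type by the inward-facing boxes) and match cargo
  against a user-supplied catalog (<95 % identity ⇒ novel).
- **comparative** — identity matrices, the isoform rule (>98 % aa or
  >95 % nt), single-linkage clustering at 90 % aa identity, neighbour
  joining on d = 100 − identity with column-bootstrap majority-rule
  consensus support, and the DDE catalytic-motif check (D, D, E plus the
  diagnostic Q seven residues after the E).
- **synthetic_data** — a ground-truthed generator of replicons, elements
  and insertion loci matching the documented anatomy, for testing without
  any database downloads.

The curated family registry (element lengths, TIR identity labels, TSD
lengths, transposase lengths) and the published site surveys ship as
small TSV tables under `difhunter/data/`.

## Worked example

Generate a two-replicon synthetic corpus and survey it:

```bash
difhunter simulate --seed 4 --n-replicons 2 --out demo
difhunter target demo/replicons.fasta --is demo/elements.fasta
```

selected columns of the output:

```
replicon  start  end    strand  identity  tsd                          tsd_len  subgroup  distance_to_xerC  orientation_consistent
rep00     9326   10808  +       100.0     TCCCC                        5        short     5                 True
rep00     5806   7288   +       100.0     TATGA                        5        short     5                 True
rep00     2027   3774   -       100.0     TAGAAGGCACGCTGGACGCAAGGATTG  27       long                        False
```

Each row is one located IS copy. The two short-TSD elements sit exactly
5 bp from the XerC box of a consensus pdif site in the canonical
orientation (`orientation_consistent=True`); the long-TSD element carries
a 27 bp duplication and, as in real data for that subgroup, has no
associated site. `difhunter scan` lists the sites themselves,
`difhunter anatomy` prints per-element TIR/transposase summaries,
`difhunter modules` reports cargo intervals between inversely oriented
sites, and `difhunter compare --kind nt --tree` writes an identity matrix
and an NJ tree.

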