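# quicklama

Design and in-silico simulation of PCR/ligation synthesis of DNA
minicircles that mimic extrachromosomal circular DNA (eccDNA).

## The problem

eccDNAs are circular DNA molecules derived from genomic segments of
eukaryotic chromosomes. Studying the function of an *individual* eccDNA
requires synthesizing a covalently closed circle with exactly that
sequence, at lengths (≈0.3–3 kb) where chemical oligo synthesis is
impractical. A purely enzymatic route solves this with two linear PCR
products that are *circular permutations* of each other:

* **Fragment A** — the target region itself, length *N*.
* **Fragment E** — the same sequence rotated by the split point
  *m = ⌊N/2⌋*: `E = A[m+1..N] + A[1..m]`.

Denaturing an equimolar A + E mix and reannealing lets one strand of A
pair with one strand of E. Because the two sequences are half a turn
apart, the heteroduplex closes into a circle of length *N* carrying two
single-strand nicks — one per strand, separated by exactly *m* — which a
thermostable ligase seals into the minicircle. Cycling
denature/anneal/ligate accumulates closed circles: with per-cycle
circularization probability *p*, the closed fraction after *c* cycles is
**1 − (1 − p)^c** (sealed circles leave the reactive pool).

The trick is making fragment E without long synthetic oligos. Six primers
suffice:

| product | pair | top strand |
|---|---|---|
| fragA | P1F, P1R | `A[1..N]` |
| C-long | P1F, P3R | `A[1..m]` |
| C-short | P2F, P3R | `A[4..m]` |
| D-short | P3F, P1R | `A[m+1..N]` |
| D-long | P3F, P2R | `A[m+1..N] + A[1..3]` |
| fragE | P3F, P3R | `A[m+1..N] + A[1..m]` |

P2R carries a 3-base 5′ extension equal to the reverse complement of
`A[1..3]`, so the D-long amplicon ends with a copy of the target's start.
Reannealing each long/short pair leaves 50 % of the strands in
heteroduplexes with one 3-nucleotide cohesive end and one blunt end; a
cohesive-end-only ligase (T7 DNA ligase) joins the complementary C and D
overhangs — and nothing else — reconstructing fragment E, which is then
amplified with P3F/P3R. T4 polynucleotide kinase supplies the 5′
phosphates every ligation needs.

Validation is predicted three ways: an ATP-dependent plasmid-safe DNase
spares only covalently closed circles (surviving mass / input mass = the
circularization ratio); double restriction digestion gives *k* + 1
fragments on the linear molecule but *k* on the circle (3-vs-2 with two
single-cutters); and an inward PCR across the junction yields a product
whose sequence contains the rotated-order junction context.

## Worked example

```bash
quicklama fixtures --length 1000 --seed 1 \
    --plant GAATTC@200 --plant AAGCTT@600 --out fx
quicklama design   --target fx/synthetic_target.fa --out plan
quicklama simulate --plan plan --cycles 3
printf 'name\tmotif\tcut_offset\nEcoRI\tGAATTC\t1\nHindIII\tAAGCTT\t1\n' > enzymes.tsv
quicklama validate --plan plan --enzymes enzymes.tsv
```

prints

```
fixture written: fx/synthetic_target.fa fx/synthetic_target.bed
plan bundle written to plan
minicircle fraction after 3 cycles: 0.8750
circularization ratio 96.9% ; junction matched
```

`plan/primers.tsv` holds the six primers, e.g. for this seed:

```
name  sequence                          anchor  orientation  extension  tm     pcr_pairings
P1F   GTGGCCGAGCGTACCAGGTGC             1       forward      .          62.32  fragA,C-long
P2R   CACGACGGCCAGGTAACTAGCACTTTAAGTCC  1000    reverse      CAC        60.7   D-long
...
```

P2R's `CAC` extension is the reverse complement of the target's first
three bases (`GTG`). The simulate step reports the closed-circle fraction
1 − 0.5³ = 0.875 after three cycles; validate reports the ratio for the
plan's default five cycles (1 − 0.5⁵ = 96.9 %), a digest signature of
3 fragments (200/400/400 bp, the two 400 bp fragments co-migrating as one
double-intensity band) versus 2 (400/600 bp) on the circle, and a
junction read that matches the expected rotated context with zero
mismatches. `plan/plan.gb` is a GenBank record of fragment A annotated
with all six primer binding sites, parts C/D, the junction and both nick
positions.

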