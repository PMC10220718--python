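# Methods

## Model of the synthesis route

The package treats the bench protocol as a chain of deterministic species
transformations over an explicit strand-level representation:

* **Duplexes** store both strands 5′→3′ plus end descriptors (blunt, or an
  overhang on one strand with its bases). Overhang polarity (3′ vs 5′) is
  implied by which strand protrudes at which end. Every constructor checks
  that the paired region is an exact Watson–Crick complement, so malformed
  intermediates fail fast rather than propagating.
* **PCR** is exact-match priming: the templated portion of each primer
  must occur exactly once on the appropriate strand, primers must face
  inward, and non-templated 5′ extensions are copied into the product.
  There is no mismatch or partial-annealing model — the designer emits
  primers taken from the template itself, so mismatch tolerance would add
  parameters without adding testable behaviour. Circular templates are
  supported; binding sites and amplicons may span the origin (this is what
  makes inward junction PCR a circularity assay).
* **Reannealing** of an equimolar long/short duplex pair follows the
  random-reassortment model: the four top/bottom strand pairings are
  equiprobable, so each parent re-forms with probability ¼ and the two
  heteroduplexes — each with one cohesive and one blunt end — together
  make up exactly ½ of the pool. No temperature-dependent annealing
  thermodynamics are modelled; protocol temperatures are carried as
  operator metadata only.
* **Ligation** (T7 DNA ligase step) joins two duplexes only when each has
  exactly one overhang end, the overhangs sit on opposite strands (equal
  3′/5′ polarity), their bases are exact reverse complements, and both
  junction nicks carry a 5′ phosphate. Blunt–blunt joining never occurs,
  which is the selectivity the protocol exploits to suppress
  intermolecular concatemers.
* **Circle assembly** anneals fragment A's top strand with fragment E's
  bottom strand. The rotation offset is recovered by locating E's top
  strand in A's doubled top strand; for a periodic sequence the smallest
  admissible offset is used. The result is a circle with a top-strand
  nick at the junction (position 0) and a bottom-strand nick at the split
  (position m).

## Accumulation kinetics

The bench protocol gives no rate model for circularization, so the
package uses an explicit geometric model: each denature/anneal/ligate
cycle converts the remaining linear pool to closed circles with
probability `p_circ`, and sealed circles leave the reactive pool, giving
closed fraction `1 − (1 − p_circ)^c` after `c` cycles. `p_circ` defaults
to 0.5, the analytic heteroduplex fraction of random reassortment. This
accumulation law is a documented model choice of this package, not a
measured rate. A stochastic mode draws per-cycle binomial outcomes over
`n_molecules` (default 10⁵) with a single integer seed (default 42) and
converges to the closed form; it exists so sampling-noise behaviour can
be tested, not because the deterministic answer is in doubt. Unligated
nicked circles are not explicitly re-denatured between cycles; they are
subsumed in the linear (reactive) remainder.

## Primer design

The protocol fixes the six primer *anchors* but not their lengths, and
does not state which primer pairs produce the long vs short part
fragments. The layout implemented here — C-long = (P1F, P3R), C-short =
(P2F, P3R) with P2F starting `overhang_len` bases in, D-short =
(P3F, P1R), D-long = (P3F, P2R) — is the unique six-primer assignment
consistent with (a) P2R's extension complementing P1F's 5′ end, (b) the
ligase requiring a cohesive end on both parts, and (c) fragment E
amplifying with P3F/P3R alone. Generated outputs label the layout as
reconstructed.

Primer lengths grow from a forced anchor, 3′-ward one base at a time,
until the nearest-neighbor melting temperature reaches the target.
Defaults: target Tm 60 °C, length bounds 18–32 nt, 50 mM monovalent salt,
25 nM strand concentration, unified SantaLucia nearest-neighbor
parameters (Biopython's `DNA_NN3` table, salt correction
0.368·(N−1)·ln[Na⁺] on ΔS). P2R's Tm is computed on its templated portion
only, since the extension is unpaired at the first annealing. If the
target Tm is unreachable within the length bounds (AT-rich anchors), the
longest admissible primer is returned and a `PrimerQualityWarning` is
attached rather than failing the design — anchors are forced by the
geometry, so there is nothing else to vary. The split point defaults to
⌊N/2⌋ (ties broken low, fixed and documented); an optional window search
shifts it by up to ±w to minimise the midpoint primers' Tm deviation,
with both cohesive arms kept ≥ 50 nt so the A/E heteroduplex arms anneal
stably. The minimum target length is 200 bp (two ≥ 50 nt arms plus room
for four distinct anchor regions); the supported range exercised in tests
is 300–3000 bp, bracketing the lengths the wet protocol produced.
`overhang_len` defaults to 3 nt (the protocol's value), configurable 2–6.

## Coordinates and conventions

Genomic and fragment coordinates are 1-based fully closed; BED input
(0-based half-open) is converted on ingest. The bundled reference locus
records include one whose printed length disagrees by one with its
coordinate span (2668 vs 2669) — published tables sometimes mix
conventions — and constructing that record emits a
`LengthDiscrepancyWarning` rather than silently adopting either number.
Motif search supports IUPAC ambiguity codes in enzyme motifs only;
targets are strict ACGT (primers and ligation junctions are meaningless
over ambiguous bases, so N-containing targets are rejected loudly).
Circular motif search scans the sequence extended by `len(motif) − 1`
bases and reports positions modulo N, making it rotation-invariant.

## Validation predictors

* **DNase filter**: only covalently closed circles survive; nicked
  circles and all linear species are removed. The circularization ratio
  weighs species by molar fraction × length (a mass proxy, matching a
  spectrophotometric ng-based measurement) and refers surviving species
  back to their pre-filter fractions, so renormalisation cannot distort
  it. Applying the filter twice equals applying it once.
* **Digestion** pools cut positions from all enzymes over
  `find_sites` with the molecule's topology. Cut offsets default to the
  motif midpoint when unspecified, since only fragment lengths (not cut
  maps) are compared downstream; for matches found only on the bottom
  strand the top-strand offset of a non-palindromic enzyme is
  approximated by the same offset, an error of at most a few bases that
  never changes fragment counts. Fragment lengths always sum to the
  molecule length; a cut set that is empty yields a single uncut fragment
  flagged "enzymes do not cut". Band prediction sorts fragments
  descending and merges sizes within a relative resolution (default 5 %)
  into one band with summed multiplicity — true fragment sizes are used;
  electrophoretic artifacts such as protein-bound mobility shifts are
  deliberately not modelled.
* **Junction check** slides the expected 2k-base junction context
  (default k = 50) along the read and reports the best Hamming window;
  a window within the mismatch budget (default 5) is a match with
  located mismatch positions, anything else — including a read from the
  unrotated linear molecule — is junction-absent. IUPAC ambiguity calls
  in reads match any compatible base.

## Synthetic data

`random_target` draws i.i.d. bases at a requested GC content, writes
planted motifs at exact positions, and redraws (bounded retries) until
forbidden motifs are absent outside their planted positions on both
strands. It emulates a PCR-amplifiable genomic target for the designer
and simulator; it does not emulate repeat structure, homopolymer runs,
low-complexity junction neighbourhoods, or chromatin context, so passing
tests demonstrate the correctness of the design arithmetic and species
bookkeeping, not primer performance on hard genomic loci. The three
bundled locus records carry coordinates only; resolving their sequences
requires a user-supplied reference FASTA and is never needed by tests.

## Problem sizes

The test suite and acceptance script run on synthetic targets of
300–3000 bp (100-target rotation sweeps, 200-case digest fuzzing,
10⁵-molecule stochastic draws), sizes chosen to bracket the supported
design range while keeping every check a string-arithmetic exercise that
completes in seconds.

## Known limitations

No genome-scale primer specificity screening or dimer/hairpin scoring
(warning hooks only); no polymerase error model; no intermolecular
concatemer formation; no gel-mobility modelling of topological isomers;
no chromatogram parsing (reads are accepted as plain FASTA). Multi-locus
targets would need an extra upstream ligation step and are out of scope.
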