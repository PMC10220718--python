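"""Synthetic targets and the bundled published locus records.

Random targets stand in for genomic PCR products so the whole design ->
simulate -> validate pipeline runs with zero downloads.  The generator is
deterministic for a fixed seed and supports planting restriction-site
motifs at exact positions (for digest demos) and forbidding motifs
elsewhere (so planted sites are the *only* sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CoordinateError, GenerationError
from .seqcore import TargetLocus, Topology, clean_seq, find_sites

#: Coordinates (hg38, 1-based inclusive) and published lengths of the three
#: reference eccDNA loci.  eccLIMD1's printed length (2668) disagrees by one
#: with its coordinate span (2669); constructing the record emits a
#: LengthDiscrepancyWarning rather than silently adopting either number.
REFERENCE_LOCI: tuple[tuple[str, str, int, int, int, str], ...] = (
    ("eccBRCA1", "chr17", 43_129_109, 43_129_839, 731, "upstream of BRCA1"),
    ("eccLIMD1", "chr3", 45_597_836, 45_600_504, 2668, "first intron of LIMD1"),
    ("eccMir2392", "chr14", 100_814_436, 100_815_570, 1135, "contains mir2392"),
)


@dataclass
class FixtureSpec:
    """Recipe for one synthetic target sequence.

    ``planted_sites`` are (motif, 1-based position) pairs written verbatim
    into the sequence; ``forbid_motifs`` must not occur anywhere except at
    their own planted positions (both strands are checked).
    """

    length: int
    gc: float = 0.5
    seed: int = 0
    planted_sites: list[tuple[str, int]] = field(default_factory=list)
    forbid_motifs: list[str] = field(default_factory=list)
    name: str = "synthetic_target"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise CoordinateError(f"length must be positive, got {self.length}")
        if not 0.0 < self.gc < 1.0:
            raise CoordinateError(f"gc must be in (0, 1), got {self.gc}")
        occupied: list[tuple[int, int]] = []
        for motif, pos in self.planted_sites:
            motif = clean_seq(motif)
            lo, hi = pos, pos + len(motif) - 1
            if not (1 <= lo and hi <= self.length):
                raise CoordinateError(
                    f"planted motif {motif} at {pos} exceeds length {self.length}"
                )
            for a, b in occupied:
                if lo <= b and a <= hi:
                    raise CoordinateError("planted sites overlap")
            occupied.append((lo, hi))


def random_target(spec: FixtureSpec, max_retries: int = 100) -> TargetLocus:
    """Generate a reproducible target satisfying the fixture constraints."""
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    planted_positions: dict[str, set[int]] = {}
    for motif, pos in spec.planted_sites:
        planted_positions.setdefault(clean_seq(motif), set()).add(pos)

    for _ in range(max_retries):
        seq = list(rng.choice(bases, size=spec.length, p=p))
        for motif, pos in spec.planted_sites:
            seq[pos - 1: pos - 1 + len(motif)] = list(clean_seq(motif))
        seq_str = "".join(seq)
        ok = True
        for motif in spec.forbid_motifs:
            motif = clean_seq(motif, allow_iupac=True)
            allowed = planted_positions.get(motif, set())
            stray = set(find_sites(seq_str, motif, Topology.LINEAR)) - allowed
            if stray:
                ok = False
                break
        if ok:
            return TargetLocus(
                name=spec.name, chrom=spec.name, start=1, end=spec.length,
                sequence=seq_str,
            )
    raise GenerationError(
        f"could not satisfy forbid constraints within {max_retries} attempts"
    )


def paper_loci() -> list[TargetLocus]:
    """The three bundled reference eccDNA locus records (coordinates only).

    Sequences are not bundled; resolve them against a user-supplied
    reference FASTA if needed.  Length discrepancies between coordinates
    and the published length column surface as warnings.
    """
    return [
        TargetLocus(name=name, chrom=chrom, start=start, end=end,
                    expected_length=length, description=desc)
        for name, chrom, start, end, length, desc in REFERENCE_LOCI
    ]


def write_fixture(locus: TargetLocus, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a fixture target as FASTA + BED (0-based half-open)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{locus.name}.fa"
    bed = out_dir / f"{locus.name}.bed"
    with open(fasta, "w") as fh:
        fh.write(f">{locus.name}\n")
        seq = locus.sequence or ""
        for i in range(0, len(seq), 70):
            fh.write(seq[i: i + 70] + "\n")
    with open(bed, "w") as fh:
        fh.write(f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t{locus.name}\n")
    return fasta, bed
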