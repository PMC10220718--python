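"""Sequence primitives and topology-aware motif search.

Conventions used throughout the toolkit:

* Genomic and fragment coordinates are **1-based, fully closed** (a locus
  ``start..end`` has length ``end - start + 1``). Internal Python string
  indices are 0-based half-open; the conversion happens at function
  boundaries, never mid-algorithm.
* Target sequences are strict ``{A,C,G,T}``; IUPAC ambiguity codes are
  accepted only in enzyme recognition motifs. Input case is normalised to
  uppercase.
* Circular molecules are represented by their top strand read once; motif
  search on circular topology detects matches that span the origin.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AlphabetError, CoordinateError, InputError

DNA_BASES = frozenset("ACGT")

#: IUPAC nucleotide ambiguity codes -> set of matching bases.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class LengthDiscrepancyWarning(UserWarning):
    """A locus' computed length disagrees with its stated expected length."""


class Topology(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


def clean_seq(s: str, allow_iupac: bool = False) -> str:
    """Validate and canonicalise a DNA string (uppercase).

    Targets must be strict ACGT; set ``allow_iupac`` for enzyme motifs.
    """
    if not isinstance(s, str) or not s:
        raise AlphabetError("sequence must be a nonempty string")
    up = s.upper()
    allowed = IUPAC_CODES.keys() if allow_iupac else DNA_BASES
    bad = set(up) - set(allowed)
    if bad:
        raise AlphabetError(
            f"invalid character(s) {sorted(bad)} in sequence "
            f"(alphabet: {'IUPAC' if allow_iupac else 'ACGT'})"
        )
    return up


def reverse_complement(s: str, allow_iupac: bool = False) -> str:
    """Watson–Crick reverse complement. Involution: rc(rc(x)) == x."""
    up = clean_seq(s, allow_iupac=allow_iupac)
    return str(Seq(up).reverse_complement())


def circular_permute(s: str, split: int) -> str:
    """Rotate ``s`` about ``split`` (1-based): s[split+1..N] + s[1..split].

    This is the fragment-A -> fragment-E transformation: the two sequences
    are identical when read around a circle but start half a turn apart.
    """
    up = clean_seq(s)
    if not 1 <= split < len(up):
        raise CoordinateError(
            f"split must be in [1, {len(up) - 1}], got {split}"
        )
    return up[split:] + up[:split]


@dataclass
class TargetLocus:
    """A genomic interval destined to become a minicircle.

    ``start``/``end`` are 1-based fully closed. ``expected_length`` is an
    externally stated length (e.g. from a published table); if it disagrees
    with the coordinate arithmetic a :class:`LengthDiscrepancyWarning` is
    emitted — published coordinates sometimes mix inclusive and half-open
    conventions and the discrepancy should be surfaced, not silently fixed.
    """

    name: str
    chrom: str
    start: int
    end: int
    sequence: Optional[str] = None
    expected_length: Optional[int] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise CoordinateError("locus name must be nonempty")
        if self.end < self.start:
            raise CoordinateError(
                f"{self.name}: end ({self.end}) < start ({self.start})"
            )
        if self.sequence is not None:
            self.sequence = clean_seq(self.sequence)
            if len(self.sequence) != self.length:
                raise CoordinateError(
                    f"{self.name}: sequence length {len(self.sequence)} != "
                    f"coordinate span {self.length}"
                )
        if self.expected_length is not None and self.expected_length != self.length:
            warnings.warn(
                f"{self.name}: computed length {self.length} "
                f"(1-based inclusive {self.chrom}:{self.start}-{self.end}) "
                f"differs from stated length {self.expected_length}; "
                "the source may use a half-open convention for this record",
                LengthDiscrepancyWarning,
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def locus_length(locus: TargetLocus) -> int:
    """Length of a locus under the 1-based fully-closed convention."""
    return locus.length


def iupac_regex(motif: str) -> re.Pattern[str]:
    """Compile an IUPAC motif to an overlap-aware lookahead regex."""
    motif = clean_seq(motif, allow_iupac=True)
    parts = []
    for ch in motif:
        opts = IUPAC_CODES[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile(f"(?={''.join(parts)})")


def find_sites(s: str, motif: str, topology: Topology = Topology.LINEAR) -> list[int]:
    """Find motif matches on both strands; positions are 1-based starts.

    A match on the bottom strand is reported at the top-strand start of the
    reverse-complemented motif, so palindromic motifs deduplicate naturally.
    On circular topology the search wraps: ``s`` is extended by the first
    ``len(motif) - 1`` bases and positions are reported modulo ``len(s)``.
    """
    seq = clean_seq(s)
    motif = clean_seq(motif, allow_iupac=True)
    n, k = len(seq), len(motif)
    if k > n:
        return []
    topology = Topology(topology)
    text = seq + seq[: k - 1] if topology is Topology.CIRCULAR else seq
    hits: set[int] = set()
    for m in (motif, reverse_complement(motif, allow_iupac=True)):
        pat = iupac_regex(m)
        for match in pat.finditer(text):
            hits.add(match.start() % n + 1)
    return sorted(hits)


# ---------------------------------------------------------------------------
# Readers: FASTA targets and BED loci
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[TargetLocus]:
    """Read a (possibly multi-record, line-wrapped) FASTA of target sequences.

    Each record becomes a :class:`TargetLocus` spanning 1..len with the
    record id as both name and chromosome.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA not found: {path}")
    loci = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = clean_seq(str(rec.seq))
        loci.append(
            TargetLocus(
                name=rec.id, chrom=rec.id, start=1, end=len(seq), sequence=seq,
                description=rec.description,
            )
        )
    if not loci:
        raise InputError(f"no FASTA records in {path}")
    return loci


def read_bed(path: str | Path, reference: str | Path | None = None) -> list[TargetLocus]:
    """Read BED3/BED6 loci, converting 0-based half-open to 1-based closed.

    If ``reference`` (a FASTA) is given, sequences are resolved from it;
    otherwise loci are returned without sequence.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"BED not found: {path}")
    ref_seqs: dict[str, str] = {}
    if reference is not None:
        for rec in SeqIO.parse(str(Path(reference)), "fasta"):
            ref_seqs[rec.id] = clean_seq(str(rec.seq))
    loci = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise InputError(f"{path}:{i}: BED needs >= 3 columns")
            chrom, bed_start, bed_end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) >= 4 and cols[3] != "." else f"{chrom}:{bed_start}-{bed_end}"
            start, end = bed_start + 1, bed_end  # 0-based half-open -> 1-based closed
            seq = None
            if ref_seqs:
                if chrom not in ref_seqs:
                    raise InputError(f"{path}:{i}: chrom {chrom!r} not in reference")
                seq = ref_seqs[chrom][bed_start:bed_end]
            loci.append(TargetLocus(name=name, chrom=chrom, start=start, end=end, sequence=seq))
    if not loci:
        raise InputError(f"no BED records in {path}")
    return loci
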