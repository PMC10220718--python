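"""Validation predictors for minicircle products.

Three orthogonal readouts distinguish a covalently closed minicircle from
its linear precursor:

1. **Exonuclease resistance** — an ATP-dependent, plasmid-safe DNase
   degrades linear and nicked species but spares closed circles; the
   surviving mass over the input mass is the circularisation ratio.
2. **Restriction digestion** — with every enzyme cutting at least once,
   a circular molecule yields exactly one fragment fewer than its linear
   counterpart (two single-cutters: 3 fragments linear vs 2 circular).
3. **Junction sequencing** — an inward (junction) PCR amplicon sequenced
   across the joint must contain the rotated-order junction context; a
   read matching only the unrotated linear order demonstrates no junction.

Mass bookkeeping uses molar fraction x length (a proxy for ng), matching
how circularisation efficiency is measured on a spectrophotometer rather
than by molecule counting.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .errors import CoordinateError, InputError, ReadLengthError
from .reaction_sim import (
    Duplex,
    Minicircle,
    NickedCircle,
    StrandPool,
    species_key,
    species_length,
)
from .seqcore import IUPAC_CODES, Topology, clean_seq, find_sites

# ---------------------------------------------------------------------------
# Enzymes and digestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease: IUPAC recognition motif + top-strand cut.

    ``cut_offset`` is the 0-based position of the cut within the motif
    (bases before the cut); ``None`` defaults to the motif midpoint — only
    fragment *lengths* are validated downstream, so the exact offset
    matters little for non-reference enzymes.
    """

    name: str
    recognition: str
    cut_offset: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "recognition", clean_seq(self.recognition, allow_iupac=True)
        )
        if len(self.recognition) < 4:
            raise CoordinateError(f"{self.name}: motif shorter than 4 nt")
        if self.cut_offset is not None and not 0 <= self.cut_offset <= len(self.recognition):
            raise CoordinateError(f"{self.name}: cut_offset {self.cut_offset} out of range")

    @property
    def offset(self) -> int:
        return self.cut_offset if self.cut_offset is not None else len(self.recognition) // 2


def read_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Read a TSV enzyme table with columns name, motif[, cut_offset]."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"enzyme table not found: {path}")
    enzymes = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise InputError(f"{path}: expected header with name/motif columns")
        for row in reader:
            off = row.get("cut_offset")
            enzymes.append(
                Enzyme(
                    name=row["name"],
                    recognition=row["motif"],
                    cut_offset=int(off) if off not in (None, "", ".") else None,
                )
            )
    if not enzymes:
        raise InputError(f"{path}: no enzymes")
    return enzymes


@dataclass
class DigestPattern:
    """Fragment lengths from digesting one molecule with an enzyme set."""

    molecule_id: str
    topology: Topology
    fragment_lengths: list[int]
    cut_positions: list[int] = field(default_factory=list)
    uncut: bool = False

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


def digest(
    molecule: Union[Duplex, NickedCircle, Minicircle],
    enzymes: list[Enzyme],
    molecule_id: str = "molecule",
) -> DigestPattern:
    """Topology-aware restriction digest (fragment lengths only).

    Cut positions from all enzymes are pooled; fragments run between
    consecutive cuts, wrapping through the origin on circles.  Fragment
    lengths always sum to the molecule length.  If no enzyme cuts, the
    single uncut molecule is reported with ``uncut=True``.
    """
    if not enzymes:
        raise InputError("enzyme list is empty")
    if isinstance(molecule, Duplex):
        seq, topology = molecule.top, Topology.LINEAR
    else:
        seq, topology = molecule.sequence, Topology.CIRCULAR
    n = len(seq)

    cuts: set[int] = set()
    for enz in enzymes:
        for site in find_sites(seq, enz.recognition, topology):
            cut = site - 1 + enz.offset  # between-bases index, 0-based
            if topology is Topology.CIRCULAR:
                cuts.add(cut % n)
            elif 0 < cut < n:
                cuts.add(cut)

    if not cuts:
        return DigestPattern(molecule_id, topology, [n], [], uncut=True)

    pos = sorted(cuts)
    if topology is Topology.LINEAR:
        bounds = [0] + pos + [n]
        lengths = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    elif len(pos) == 1:
        lengths = [n]  # a single cut linearises the circle
    else:
        lengths = [b - a for a, b in zip(pos, pos[1:])]
        lengths.append(pos[0] + n - pos[-1])
    return DigestPattern(molecule_id, topology, sorted(lengths), pos)


@dataclass(frozen=True)
class Band:
    """A gel band: apparent size (bp) and how many fragments co-migrate."""

    size: float
    multiplicity: int


def predict_bands(pattern: DigestPattern, resolution: float = 0.05) -> list[Band]:
    """Collapse a digest pattern into descending gel bands.

    Fragments whose sizes differ by less than ``resolution`` (relative to
    their running mean) co-migrate into one band of summed intensity.
    """
    sizes = sorted(pattern.fragment_lengths, reverse=True)
    bands: list[list[int]] = []
    for s in sizes:
        if bands:
            group = bands[-1]
            mean = sum(group) / len(group)
            if abs(mean - s) / ((mean + s) / 2) < resolution:
                group.append(s)
                continue
        bands.append([s])
    return [Band(size=sum(g) / len(g), multiplicity=len(g)) for g in bands]


# ---------------------------------------------------------------------------
# Exonuclease resistance & circularisation ratio
# ---------------------------------------------------------------------------

def dnase_filter(pool: StrandPool) -> StrandPool:
    """Plasmid-safe ATP-dependent DNase: only closed circles survive.

    Linear duplexes, single strands and nicked circles are degraded; the
    survivors are renormalised to a fresh pool (empty pools are returned
    as-is when nothing survives — represented by a zero-entry sentinel).
    """
    survivors = [(sp, f) for sp, f in pool.entries if isinstance(sp, Minicircle)]
    total = sum(f for _, f in survivors)
    if total == 0:
        return _EmptyPool()
    return StrandPool([(sp, f / total) for sp, f in survivors])


class _EmptyPool(StrandPool):
    """Pool with no surviving species (all input was degraded)."""

    def __init__(self) -> None:
        self.entries = []

    def __post_init__(self) -> None:  # pragma: no cover - nothing to validate
        pass


def circularization_ratio(pool_before: StrandPool, pool_after: StrandPool) -> float:
    """Surviving mass / input mass, in percent.

    Species in ``pool_after`` are matched back to ``pool_before`` by
    identity (type + sequence) and weighed with their *original*
    fractions, so post-filter renormalisation does not distort the ratio.
    Mass is molar fraction x length.
    """
    input_mass = pool_before.mass()
    if input_mass <= 0:
        raise CoordinateError("input pool has zero mass")
    before = {}
    for sp, f in pool_before.entries:
        key = species_key(sp)
        before[key] = before.get(key, 0.0) + f * species_length(sp)
    surviving_keys = {species_key(sp) for sp, _ in pool_after.entries}
    surviving_mass = sum(before.get(k, 0.0) for k in surviving_keys)
    return 100.0 * surviving_mass / input_mass


# ---------------------------------------------------------------------------
# Junction sequencing check
# ---------------------------------------------------------------------------


@dataclass
class JunctionReport:
    """Outcome of locating the circle junction context in a Sanger read."""

    expected_context: str
    matched: bool
    mismatch_positions: list[int] = field(default_factory=list)
    read_offset: Optional[int] = None
    context_half: int = 0

    def to_json(self) -> dict:
        return {
            "expected_context": self.expected_context,
            "matched": self.matched,
            "mismatch_positions": self.mismatch_positions,
            "read_offset": self.read_offset,
            "context_half": self.context_half,
        }


def _bases_compatible(read_base: str, expected_base: str) -> bool:
    # reads may carry IUPAC ambiguity calls; they match any compatible base
    return expected_base in IUPAC_CODES.get(read_base, "")


def junction_check(
    mc: Minicircle,
    read: str,
    k: int = 50,
    max_mismatches: int = 5,
) -> JunctionReport:
    """Search a read for the circle's junction context.

    The expected context is the ``k`` bases on either side of the junction
    (circle end followed by circle start).  The best Hamming window in the
    read is reported; if no window is within ``max_mismatches`` the
    junction is absent — which is exactly what a read from the unrotated
    linear molecule produces.
    """
    if k < 10:
        raise CoordinateError(f"context half-width k must be >= 10, got {k}")
    read = clean_seq(read, allow_iupac=True)
    seq = mc.sequence
    if len(seq) < 2 * k:
        raise CoordinateError(f"circle length {len(seq)} < context 2k={2 * k}")
    expected = seq[-k:] + seq[:k]
    if len(read) < len(expected):
        raise ReadLengthError(
            f"read length {len(read)} shorter than junction context {len(expected)}"
        )

    best_offset, best_mm = None, None
    for i in range(len(read) - len(expected) + 1):
        window = read[i: i + len(expected)]
        mm = [j for j, (rb, eb) in enumerate(zip(window, expected))
              if not _bases_compatible(rb, eb)]
        if best_mm is None or len(mm) < len(best_mm):
            best_offset, best_mm = i, mm
            if not mm:
                break
    matched = len(best_mm) <= max_mismatches
    return JunctionReport(
        expected_context=expected,
        matched=matched,
        mismatch_positions=best_mm if matched else [],
        read_offset=best_offset if matched else None,
        context_half=k,
    )


@dataclass(frozen=True)
class _JunctionPrimer:
    """Minimal primer stand-in for inward junction PCR."""

    name: str
    sequence: str
    extension: str = ""

    @property
    def templated(self) -> str:
        return self.sequence


def junction_amplicon(mc: Minicircle, primer_len: int = 20, flank: int = 60) -> str:
    """Inward-PCR amplicon spanning the circle junction.

    The forward primer sits ``flank + primer_len`` bases before the
    junction, the reverse primer the same distance after it; only a
    circular (or otherwise junction-containing) template can yield this
    product, which is the point of the assay.
    """
    from .reaction_sim import simulate_pcr  # local import avoids cycle at module load

    seq = mc.sequence
    n = len(seq)
    if n < 2 * (flank + primer_len):
        raise CoordinateError("circle too small for the requested junction amplicon")
    fwd = _JunctionPrimer("JF", seq[n - flank - primer_len: n - flank])
    rev_region = seq[flank: flank + primer_len]
    from .seqcore import reverse_complement

    rev = _JunctionPrimer("JR", reverse_complement(rev_region))
    return simulate_pcr(mc, fwd, rev).top


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def write_digest_report(patterns: list[DigestPattern], path: str | Path,
                        fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("molecule\ttopology\tn_fragments\tfragment_lengths\tuncut\n")
            for p in patterns:
                fh.write(
                    f"{p.molecule_id}\t{p.topology.value}\t{p.n_fragments}\t"
                    f"{','.join(map(str, p.fragment_lengths))}\t"
                    f"{'enzymes do not cut' if p.uncut else '.'}\n"
                )
    elif fmt == "json":
        payload = [
            {
                "molecule": p.molecule_id,
                "topology": p.topology.value,
                "n_fragments": p.n_fragments,
                "fragment_lengths": p.fragment_lengths,
                "uncut": p.uncut,
            }
            for p in patterns
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise InputError(f"unknown digest report format {fmt!r}")
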