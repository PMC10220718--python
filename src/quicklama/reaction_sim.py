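"""In-silico chemistry: PCR, reannealing, kinase, ligase, circle assembly.

Species model
-------------
A :class:`Duplex` stores both strands 5'->3' with the top strand running
left-to-right (so the bottom strand's 5' end is at the *right* end of the
molecule).  Each end is blunt or carries an :class:`Overhang` — a run of
unpaired bases on one strand.  Polarity follows from geometry: a top-strand
overhang on the right end (or bottom-strand on the left) protrudes 3'; the
mirror cases protrude 5'.

The protocol's species flow:

1. :func:`simulate_pcr` — exact-match, both-strand, inward-facing priming;
   non-templated 5' primer extensions appear in the product.
2. :func:`make_sticky_hybrid` — denature/reanneal an equimolar long/short
   pair; random reassortment leaves half the strands in heteroduplexes
   carrying one cohesive end and one blunt end.
3. :func:`phosphorylate` — T4 polynucleotide kinase; sets every 5'
   phosphate flag (ligases refuse nicks without one).
4. :func:`ligate_cohesive` — T7 DNA ligase joins complementary cohesive
   ends only; blunt ends are never joined.
5. :func:`lama_assemble` / :func:`lama_cycles` / :func:`seal_nicks` —
   annealing one strand of fragment A with one strand of its half-turn
   rotation E closes a circle with two nicks (one per strand, separated by
   the split offset); thermostable ligase seals them into a covalently
   closed minicircle.  Cycle accumulation uses a geometric model: with a
   per-cycle circularisation probability ``p`` the closed fraction after
   ``c`` cycles is ``1 - (1 - p)^c`` (closed circles leave the reactive
   pool).  ``p`` defaults to 0.5, the random-reassortment heteroduplex
   fraction; this accumulation law is a model choice of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .errors import (
    AmbiguousPrimingError,
    AmplificationError,
    CohesionError,
    CoordinateError,
    GeometryError,
    IncompatibleFragmentsError,
    NoProductError,
    UnligatableNickError,
)
from .seqcore import Topology, clean_seq, reverse_complement


@dataclass(frozen=True)
class Overhang:
    """Unpaired bases at a duplex end, read 5'->3' on their own strand."""

    strand: str  # "top" | "bottom"
    bases: str

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise GeometryError(f"bad overhang strand {self.strand!r}")
        object.__setattr__(self, "bases", clean_seq(self.bases))

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Duplex:
    """A linear double-stranded species (see module docstring for geometry)."""

    top: str
    bottom: str
    left_overhang: Optional[Overhang] = None
    right_overhang: Optional[Overhang] = None
    phos5_top: bool = False
    phos5_bottom: bool = False

    def __post_init__(self) -> None:
        self.top = clean_seq(self.top)
        self.bottom = clean_seq(self.bottom)
        lt = len(self.left_overhang) if self._oh(self.left_overhang, "top") else 0
        lb = len(self.left_overhang) if self._oh(self.left_overhang, "bottom") else 0
        rt = len(self.right_overhang) if self._oh(self.right_overhang, "top") else 0
        rb = len(self.right_overhang) if self._oh(self.right_overhang, "bottom") else 0
        # overhang bases must be the actual terminal bases of their strand
        if lt and self.top[:lt] != self.left_overhang.bases:
            raise GeometryError("left top overhang bases inconsistent with strand")
        if lb and self.bottom[-lb:] != self.left_overhang.bases:
            raise GeometryError("left bottom overhang bases inconsistent with strand")
        if rt and self.top[-rt:] != self.right_overhang.bases:
            raise GeometryError("right top overhang bases inconsistent with strand")
        if rb and self.bottom[:rb] != self.right_overhang.bases:
            raise GeometryError("right bottom overhang bases inconsistent with strand")
        top_paired = self.top[lt: len(self.top) - rt]
        bottom_paired = self.bottom[rb: len(self.bottom) - lb]
        if not top_paired or reverse_complement(bottom_paired) != top_paired:
            raise GeometryError("paired region is not Watson-Crick complementary")

    @staticmethod
    def _oh(oh: Optional[Overhang], strand: str) -> bool:
        return oh is not None and oh.strand == strand

    @property
    def is_blunt(self) -> bool:
        return self.left_overhang is None and self.right_overhang is None

    def __len__(self) -> int:
        return len(self.top)


def blunt_duplex(top: str, phos5: bool = False) -> Duplex:
    """Fully base-paired duplex from its top strand."""
    top = clean_seq(top)
    return Duplex(top=top, bottom=reverse_complement(top),
                  phos5_top=phos5, phos5_bottom=phos5)


def flip(d: Duplex) -> Duplex:
    """Rotate a duplex 180 degrees in the plane (top<->bottom, left<->right)."""

    def swap(oh: Optional[Overhang]) -> Optional[Overhang]:
        if oh is None:
            return None
        return Overhang(strand="bottom" if oh.strand == "top" else "top",
                        bases=oh.bases)

    return Duplex(
        top=d.bottom, bottom=d.top,
        left_overhang=swap(d.right_overhang),
        right_overhang=swap(d.left_overhang),
        phos5_top=d.phos5_bottom, phos5_bottom=d.phos5_top,
    )


@dataclass(frozen=True)
class Nick:
    """A single-strand break: position p = break before top-strand base p+1
    (0-based circle coordinates)."""

    strand: str
    position: int
    ligatable: bool = False


@dataclass
class NickedCircle:
    """A circular duplex with 1-2 single-strand breaks."""

    sequence: str
    nicks: list[Nick]

    def __post_init__(self) -> None:
        self.sequence = clean_seq(self.sequence)
        if not 1 <= len(self.nicks) <= 2:
            raise GeometryError("a nicked circle carries 1 or 2 nicks here")
        for nick in self.nicks:
            if not 0 <= nick.position < len(self.sequence):
                raise CoordinateError(f"nick position {nick.position} outside circle")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Minicircle:
    """A covalently closed circular duplex, read from the junction."""

    sequence: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.sequence = clean_seq(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


Species = Union[str, Duplex, NickedCircle, Minicircle]


def species_length(sp: Species) -> int:
    if isinstance(sp, str):
        return len(sp)
    if isinstance(sp, Duplex):
        return len(sp)
    return sp.length


def species_key(sp: Species) -> tuple[str, str]:
    """Identity key (type, canonical sequence) for cross-pool comparison."""
    if isinstance(sp, str):
        return ("ssDNA", sp)
    if isinstance(sp, Duplex):
        return ("Duplex", sp.top)
    if isinstance(sp, NickedCircle):
        return ("NickedCircle", sp.sequence)
    return ("Minicircle", sp.sequence)


@dataclass
class StrandPool:
    """Multiset of species with molar fractions summing to 1."""

    entries: list[tuple[Species, float]]

    def __post_init__(self) -> None:
        total = 0.0
        for sp, frac in self.entries:
            if frac < 0:
                raise CoordinateError(f"negative fraction {frac}")
            total += frac
        if abs(total - 1.0) > 1e-9:
            raise CoordinateError(f"pool fractions sum to {total}, expected 1")

    def fraction(self, kind: type | tuple[type, ...]) -> float:
        return sum(f for sp, f in self.entries if isinstance(sp, kind))

    def mass(self) -> float:
        """Length-weighted (mass-like) pool total, in fraction*bp units."""
        return sum(f * species_length(sp) for sp, f in self.entries)

    def to_json(self) -> list[dict]:
        out = []
        for sp, frac in self.entries:
            rec: dict = {
                "species": species_key(sp)[0],
                "length": species_length(sp),
                "fraction": frac,
            }
            if isinstance(sp, NickedCircle):
                rec["nicks"] = [
                    {"strand": n.strand, "position": n.position,
                     "ligatable": n.ligatable}
                    for n in sp.nicks
                ]
            if isinstance(sp, Duplex):
                rec["cohesive_ends"] = sum(
                    oh is not None for oh in (sp.left_overhang, sp.right_overhang)
                )
            out.append(rec)
        return out


# ---------------------------------------------------------------------------
# Step 1 & 5: PCR
# ---------------------------------------------------------------------------

def _occurrences(needle: str, haystack: str, topology: Topology) -> list[int]:
    """0-based start positions of exact matches (wrapping if circular)."""
    n = len(haystack)
    text = haystack + haystack[: len(needle) - 1] if topology is Topology.CIRCULAR else haystack
    hits, start = [], 0
    while True:
        i = text.find(needle, start)
        if i == -1 or i >= n:
            break
        hits.append(i)
        start = i + 1
    return hits


def simulate_pcr(template: Union[Duplex, Minicircle], fwd, rev) -> Duplex:
    """Amplify a template with exact-match, inward-facing primers.

    Only the templated portion of each primer (sequence minus any 5'
    extension) must match; the product is the blunt, unphosphorylated
    duplex delimited by the primer 5' ends, extension bases included.
    Circular templates are supported (binding and amplicon may span the
    origin).
    """
    if isinstance(template, Minicircle):
        seq, topology = template.sequence, Topology.CIRCULAR
    else:
        seq, topology = template.top, Topology.LINEAR

    f_core, r_core = fwd.templated, rev.templated
    f_sites = _occurrences(f_core, seq, topology)
    r_sites = _occurrences(reverse_complement(r_core), seq, topology)

    for name, sites in (getattr(fwd, "name", "fwd"), f_sites), (getattr(rev, "name", "rev"), r_sites):
        if len(sites) > 1:
            raise AmbiguousPrimingError(name, [p + 1 for p in sites])
    if not f_sites or not r_sites:
        # distinguish wrong-strand binding (an orientation problem) from absence
        f_flip = _occurrences(reverse_complement(f_core), seq, topology)
        r_flip = _occurrences(r_core, seq, topology)
        if (f_sites or f_flip) and (r_sites or r_flip):
            raise NoProductError("primers bind but do not face each other inward")
        raise AmplificationError("no binding site for at least one primer")

    f_start = f_sites[0]
    r_end = r_sites[0] + len(r_core)
    if topology is Topology.LINEAR:
        if f_start >= r_end or r_sites[0] < f_start:
            raise NoProductError("primers face outward on a linear template")
        amplicon = seq[f_start:r_end]
    else:
        n = len(seq)
        length = (r_end - f_start - 1) % n + 1
        amplicon = (seq + seq)[f_start: f_start + length]

    product = fwd.extension + amplicon + reverse_complement(rev.extension) \
        if rev.extension else fwd.extension + amplicon
    return blunt_duplex(product)


# ---------------------------------------------------------------------------
# Step 3: denature/reanneal long+short pairs into sticky hybrids
# ---------------------------------------------------------------------------

def make_sticky_hybrid(long: Duplex, short: Duplex) -> StrandPool:
    """Equimolar denature/reanneal of a long/short duplex pair.

    Under random strand reassortment each of the four top/bottom pairings
    is equally likely: a quarter re-forms each parent and the two
    heteroduplexes (together half the pool) each carry one cohesive end —
    the terminal extension that distinguishes long from short — and one
    blunt end.
    """
    if not (long.is_blunt and short.is_blunt):
        raise GeometryError("reannealing inputs must be blunt PCR products")
    lt, st = long.top, short.top
    if len(lt) <= len(st):
        raise GeometryError("long duplex must be strictly longer than short")
    if lt.endswith(st):
        side, ext = "left", lt[: len(lt) - len(st)]
    elif lt.startswith(st):
        side, ext = "right", lt[len(st):]
    else:
        raise GeometryError(
            "long and short are not related by a terminal extension"
        )

    if side == "right":
        hyb_ls = Duplex(top=lt, bottom=short.bottom,
                        right_overhang=Overhang("top", ext),
                        phos5_top=long.phos5_top, phos5_bottom=short.phos5_bottom)
        hyb_sl = Duplex(top=st, bottom=long.bottom,
                        right_overhang=Overhang("bottom", reverse_complement(ext)),
                        phos5_top=short.phos5_top, phos5_bottom=long.phos5_bottom)
    else:
        hyb_ls = Duplex(top=lt, bottom=short.bottom,
                        left_overhang=Overhang("top", ext),
                        phos5_top=long.phos5_top, phos5_bottom=short.phos5_bottom)
        hyb_sl = Duplex(top=st, bottom=long.bottom,
                        left_overhang=Overhang("bottom", reverse_complement(ext)),
                        phos5_top=short.phos5_top, phos5_bottom=long.phos5_bottom)

    return StrandPool([(long, 0.25), (short, 0.25), (hyb_ls, 0.25), (hyb_sl, 0.25)])


def hybrid_fraction(pool: StrandPool) -> float:
    """Fraction of pool species carrying at least one cohesive end."""
    return sum(
        f for sp, f in pool.entries
        if isinstance(sp, Duplex) and not sp.is_blunt
    )


# ---------------------------------------------------------------------------
# Step 3b: T4 polynucleotide kinase
# ---------------------------------------------------------------------------

def phosphorylate(obj: Union[StrandPool, Duplex]) -> Union[StrandPool, Duplex]:
    """Set every 5'-phosphate flag (idempotent). Accepts a pool or a duplex."""
    if isinstance(obj, Duplex):
        return replace(obj, phos5_top=True, phos5_bottom=True)
    entries = []
    for sp, frac in obj.entries:
        if isinstance(sp, Duplex):
            sp = replace(sp, phos5_top=True, phos5_bottom=True)
        entries.append((sp, frac))
    return StrandPool(entries)


# ---------------------------------------------------------------------------
# Step 4: T7 DNA ligase (cohesive ends only)
# ---------------------------------------------------------------------------

def _single_overhang_end(d: Duplex) -> str:
    ends = [side for side, oh in (("left", d.left_overhang), ("right", d.right_overhang))
            if oh is not None]
    if len(ends) == 0:
        raise CohesionError("blunt ends cannot be joined by a cohesive-end ligase")
    if len(ends) > 1:
        raise CohesionError("ligation input must have exactly one cohesive end")
    return ends[0]


def ligate_cohesive(a: Duplex, b: Duplex) -> Duplex:
    """Join two one-sticky-end duplexes across complementary overhangs.

    The molecules are oriented so that ``a``'s cohesive end meets ``b``'s;
    pairing requires the overhangs to sit on opposite strands (same 3'/5'
    polarity) and to be exact reverse complements.  Both junction nicks
    need a 5' phosphate.  The outer ends stay blunt.
    """
    if _single_overhang_end(a) == "left":
        a = flip(a)
    if _single_overhang_end(b) == "right":
        b = flip(b)
    oa, ob = a.right_overhang, b.left_overhang
    if oa.strand == ob.strand:
        raise CohesionError(
            "overhang polarities incompatible (a 3' end cannot pair with a 5' end)"
        )
    if ob.bases != reverse_complement(oa.bases):
        raise CohesionError(
            f"overhangs {oa.bases} and {ob.bases} are not complementary"
        )
    missing = []
    if not b.phos5_top:
        missing.append("top-strand junction nick (5' end of downstream top strand)")
    if not a.phos5_bottom:
        missing.append("bottom-strand junction nick (5' end of upstream bottom strand)")
    if missing:
        raise UnligatableNickError("; ".join(missing))
    return Duplex(
        top=a.top + b.top,
        bottom=b.bottom + a.bottom,
        left_overhang=a.left_overhang,
        right_overhang=b.right_overhang,
        phos5_top=a.phos5_top,
        phos5_bottom=b.phos5_bottom,
    )


# ---------------------------------------------------------------------------
# Minicircle accumulation
# ---------------------------------------------------------------------------

def lama_assemble(frag_a: Duplex, frag_e: Duplex) -> NickedCircle:
    """Anneal fragment A's top strand with fragment E's bottom strand.

    Because E is A rotated by the split offset ``m``, the two strands pair
    around a circle of length N: A's top-strand ends meet at the junction
    (nick on top at position 0) and E's bottom-strand ends meet at the
    split boundary (nick on bottom at position m).
    """
    if len(frag_a) != len(frag_e):
        raise IncompatibleFragmentsError("fragments A and E differ in length")
    m = (frag_a.top + frag_a.top).find(frag_e.top)
    if m <= 0 or frag_e.top == frag_a.top:
        raise IncompatibleFragmentsError(
            "fragment E is not a proper circular permutation of fragment A"
        )
    return NickedCircle(
        sequence=frag_a.top,
        nicks=[
            Nick("top", 0, ligatable=frag_a.phos5_top),
            Nick("bottom", m, ligatable=frag_e.phos5_bottom),
        ],
    )


def seal_nicks(nc: NickedCircle) -> Minicircle:
    """Ligase-seal every nick; all must carry a 5' phosphate."""
    for nick in nc.nicks:
        if not nick.ligatable:
            raise UnligatableNickError(
                f"nick on {nick.strand} strand at position {nick.position} "
                "lacks a 5' phosphate (run the kinase step first)"
            )
    return Minicircle(sequence=nc.sequence)


def lama_cycles(
    frag_a: Duplex,
    frag_e: Duplex,
    cycles: int,
    p_circ: float = 0.5,
    stochastic: bool = False,
    n_molecules: int = 100_000,
    seed: int = 42,
) -> StrandPool:
    """Run denature/anneal/ligate cycles and return the final pool.

    Deterministic mode reports the closed-form minicircle fraction
    ``1 - (1 - p_circ)^cycles``; the remainder stays as linear A/E.
    Stochastic mode draws per-cycle binomial outcomes over ``n_molecules``
    circle-forming opportunities and converges to the closed form.
    """
    if cycles < 1:
        raise CoordinateError(f"cycles must be >= 1, got {cycles}")
    if not 0.0 <= p_circ <= 1.0:
        raise CoordinateError(f"p_circ must be in [0, 1], got {p_circ}")
    circle = seal_nicks(lama_assemble(frag_a, frag_e))
    if stochastic:
        rng = np.random.default_rng(seed)
        remaining, closed = n_molecules, 0
        for _ in range(cycles):
            k = int(rng.binomial(remaining, p_circ))
            closed += k
            remaining -= k
        frac = closed / n_molecules
    else:
        frac = 1.0 - (1.0 - p_circ) ** cycles
    linear = (1.0 - frac) / 2.0
    return StrandPool([(circle, frac), (frag_a, linear), (frag_e, linear)])
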