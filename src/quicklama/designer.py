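"""Synthesis-plan designer: split point, six primers, fragment definitions.

The design turns a target duplex (fragment A, length N) into the reagents
for PCR/ligation assembly of its minicircle:

* a split point ``m`` (default ``floor(N/2)``) dividing A into part C
  (prefix, ``1..m``) and part D (suffix, ``m+1..N``);
* six primers.  ``P1F/P1R`` amplify fragment A itself.  ``P2F`` starts
  ``overhang_len`` bases inside A; ``P2R`` matches the end of A but carries
  a 5' extension complementary to A's first ``overhang_len`` bases.  ``P3F``
  and ``P3R`` anchor either side of the split.  Pairing them produces the
  four part fragments in long and short forms:

  ======== ============ =======================================
  product  primer pair  top-strand sequence
  ======== ============ =======================================
  fragA    P1F, P1R     A[1..N]
  C-long   P1F, P3R     A[1..m]
  C-short  P2F, P3R     A[overhang_len+1..m]
  D-short  P3F, P1R     A[m+1..N]
  D-long   P3F, P2R     A[m+1..N] + A[1..overhang_len]
  fragE    P3F, P3R     A[m+1..N] + A[1..m]  (rotation of A)
  ======== ============ =======================================

Denature/reanneal of each long/short pair yields heteroduplexes with a
single cohesive (3') end; ligating the C and D heteroduplexes joins the
complementary overhangs and re-creates fragment E, the half-turn circular
permutation of A.  Annealing one strand of A with one strand of E closes a
doubly-nicked circle — the minicircle precursor.

This primer layout is a reconstruction from the protocol's constraints
(six primers total, one 3-base 5' extension on P2R complementary to P1F's
5' end, cohesive-end-only ligation); generated documentation flags it as
reconstructed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp as mt

from .errors import CoordinateError, DesignError
from .seqcore import circular_permute, clean_seq, reverse_complement

PRIMER_NAMES = ("P1F", "P1R", "P2F", "P2R", "P3F", "P3R")

#: PCR pairings: product -> (forward primer, reverse primer)
PCR_PAIRINGS: dict[str, tuple[str, str]] = {
    "fragA": ("P1F", "P1R"),
    "C-long": ("P1F", "P3R"),
    "C-short": ("P2F", "P3R"),
    "D-short": ("P3F", "P1R"),
    "D-long": ("P3F", "P2R"),
    "fragE": ("P3F", "P3R"),
}


class PrimerQualityWarning(UserWarning):
    """A primer could not reach its target melting temperature."""


@dataclass(frozen=True)
class TmConfig:
    """Nearest-neighbor Tm model settings (SantaLucia unified parameters).

    ``na_mM`` is monovalent cation concentration; ``dnac_nM`` the primer
    concentration fed to the duplex-fraction term.
    """

    target_c: float = 60.0
    min_len: int = 18
    max_len: int = 32
    na_mM: float = 50.0
    dnac_nM: float = 25.0
    tolerance_c: float = 5.0


def primer_tm(seq: str, config: TmConfig = TmConfig()) -> float:
    """Nearest-neighbor melting temperature in degC."""
    return float(
        mt.Tm_NN(
            Seq(clean_seq(seq)),
            nn_table=mt.DNA_NN3,
            Na=config.na_mM,
            dnac1=config.dnac_nM,
            dnac2=config.dnac_nM,
            saltcorr=5,
        )
    )


@dataclass
class Primer:
    """A PCR primer written 5'->3'.

    ``anchor`` is the fixed template coordinate (1-based on fragment A):
    for forward primers the position of the primer's 5' base, for reverse
    primers the top-strand position of the amplicon boundary (the primer's
    5' base pairs with this position).  ``extension`` holds 5' bases that
    are not templated at the annealing step (nonempty only for P2R).
    """

    name: str
    sequence: str
    anchor: int
    orientation: str  # "forward" | "reverse"
    extension: str = ""
    tm: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = clean_seq(self.sequence)
        if self.extension:
            self.extension = clean_seq(self.extension)
            if not self.sequence.startswith(self.extension):
                raise DesignError(
                    f"{self.name}: extension must be a 5' prefix of the sequence"
                )
        if self.orientation not in ("forward", "reverse"):
            raise DesignError(f"{self.name}: bad orientation {self.orientation!r}")

    @property
    def templated(self) -> str:
        """The template-matching portion (sequence minus the 5' extension)."""
        return self.sequence[len(self.extension):]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrimerSet:
    """The six primers plus the split geometry they encode."""

    primers: dict[str, Primer]
    split: int
    overhang_len: int

    def __post_init__(self) -> None:
        if set(self.primers) != set(PRIMER_NAMES):
            raise DesignError(
                f"primer set must contain exactly {PRIMER_NAMES}, "
                f"got {sorted(self.primers)}"
            )
        ext = [p.name for p in self.primers.values() if p.extension]
        if ext != ["P2R"]:
            raise DesignError(f"extension must appear on P2R only, found on {ext}")

    def __getitem__(self, name: str) -> Primer:
        return self.primers[name]

    def pair(self, product: str) -> tuple[Primer, Primer]:
        fwd, rev = PCR_PAIRINGS[product]
        return self.primers[fwd], self.primers[rev]


@dataclass
class FragmentPlan:
    """Defined top-strand sequences of every species in the protocol.

    ``junction`` is the (N, 1) adjacency created on the minicircle;
    ``nick_offsets`` are the two single-strand break positions in 0-based
    circle coordinates (position p = break before base p+1), one per
    strand, separated by exactly ``split``.
    """

    frag_a: str
    c_long: str
    c_short: str
    d_long: str
    d_short: str
    frag_e: str
    split: int
    overhang_len: int
    junction: tuple[int, int] = (0, 0)
    nick_offsets: tuple[int, int] = (0, 0)


def choose_split(
    frag_a: str,
    min_length: int = 200,
    min_arm: int = 50,
    window: int = 0,
    tm_config: TmConfig = TmConfig(),
) -> int:
    """Choose the split point ``m`` on fragment A.

    Default is ``floor(N/2)`` — the two cohesive arms of the A/E
    heteroduplex are then as balanced as possible.  With ``window > 0``
    the split may shift within +/- ``window`` to bring the midpoint
    primers (P3F/P3R) closest to the target Tm; both arms must stay at
    least ``min_arm`` nt so the cohesive ends remain long enough to anneal
    stably.
    """
    seq = clean_seq(frag_a)
    n = len(seq)
    if n < min_length:
        raise DesignError(f"target length {n} below design minimum {min_length}")
    m0 = n // 2
    if window <= 0:
        return m0
    candidates = [
        m for m in range(m0 - window, m0 + window + 1)
        if min_arm <= m <= n - min_arm
    ]
    if not candidates:
        raise DesignError("no admissible split point within window")

    def score(m: int) -> tuple[float, int, int]:
        p3f = design_primer(seq, m + 1, "forward", tm_config)
        p3r = design_primer(seq, m, "reverse", tm_config)
        dev = abs(p3f.tm - tm_config.target_c) + abs(p3r.tm - tm_config.target_c)
        return (dev, abs(m - m0), m)

    return min(candidates, key=score)


def design_primer(
    template: str,
    anchor: int,
    orientation: str,
    tm_config: TmConfig = TmConfig(),
    name: str = "primer",
    extension: str = "",
) -> Primer:
    """Design one primer with a forced anchor, extended 3' to reach Tm.

    The primer starts at the anchor (see :class:`Primer` for the anchor
    convention) at ``min_len`` and grows one base at a time until the
    nearest-neighbor Tm reaches the target or ``max_len`` / the fragment
    end is hit; if the target Tm is unreachable the longest admissible
    primer is returned with a warning attached.
    """
    seq = clean_seq(template)
    n = len(seq)
    if not 1 <= anchor <= n:
        raise CoordinateError(f"{name}: anchor {anchor} outside template 1..{n}")

    if orientation == "forward":
        room = n - (anchor - 1)
    elif orientation == "reverse":
        room = anchor
    else:
        raise DesignError(f"{name}: bad orientation {orientation!r}")
    if room < tm_config.min_len:
        raise DesignError(
            f"{name}: only {room} nt available at anchor {anchor}, "
            f"need >= {tm_config.min_len}"
        )
    max_len = min(tm_config.max_len, room)

    def core_at(length: int) -> str:
        if orientation == "forward":
            return seq[anchor - 1 : anchor - 1 + length]
        return reverse_complement(seq[anchor - length : anchor])

    length = tm_config.min_len
    core = core_at(length)
    tm = primer_tm(core, tm_config)
    while tm < tm_config.target_c and length < max_len:
        length += 1
        core = core_at(length)
        tm = primer_tm(core, tm_config)

    notes: list[str] = []
    if tm < tm_config.target_c - tm_config.tolerance_c:
        msg = (
            f"{name}: Tm {tm:.1f} degC below target "
            f"{tm_config.target_c:.1f} degC at maximum length {length}"
        )
        warnings.warn(msg, PrimerQualityWarning, stacklevel=2)
        notes.append(msg)

    return Primer(
        name=name,
        sequence=(extension + core),
        anchor=anchor,
        orientation=orientation,
        extension=extension,
        tm=tm,
        warnings=notes,
    )


def design_primer_set(
    frag_a: str,
    split: Optional[int] = None,
    overhang_len: int = 3,
    tm_config: TmConfig = TmConfig(),
    min_length: int = 200,
) -> PrimerSet:
    """Design all six primers for a target sequence.

    ``split`` defaults to :func:`choose_split`'s answer.  ``overhang_len``
    is the cohesive-end length created by P2R's 5' extension (the extension
    equals the reverse complement of the target's first ``overhang_len``
    bases, so the D-long amplicon ends with a copy of the target's start).
    """
    seq = clean_seq(frag_a)
    n = len(seq)
    if not 2 <= overhang_len <= 6:
        raise DesignError(f"overhang_len must be in [2, 6], got {overhang_len}")
    if split is None:
        split = choose_split(seq, min_length=min_length, tm_config=tm_config)
    if not overhang_len < split < n:
        raise CoordinateError(f"split {split} incompatible with length {n}")

    ext = reverse_complement(seq[:overhang_len])
    primers = {
        "P1F": design_primer(seq, 1, "forward", tm_config, name="P1F"),
        "P1R": design_primer(seq, n, "reverse", tm_config, name="P1R"),
        "P2F": design_primer(seq, overhang_len + 1, "forward", tm_config, name="P2F"),
        "P2R": design_primer(seq, n, "reverse", tm_config, name="P2R", extension=ext),
        "P3F": design_primer(seq, split + 1, "forward", tm_config, name="P3F"),
        "P3R": design_primer(seq, split, "reverse", tm_config, name="P3R"),
    }
    return PrimerSet(primers=primers, split=split, overhang_len=overhang_len)


def fragment_plan(frag_a: str, primer_set: PrimerSet) -> FragmentPlan:
    """Derive the defined sequences of every protocol species."""
    seq = clean_seq(frag_a)
    n, m, oh = len(seq), primer_set.split, primer_set.overhang_len
    if not oh < m < n:
        raise CoordinateError(f"split {m} incompatible with length {n}")
    return FragmentPlan(
        frag_a=seq,
        c_long=seq[:m],
        c_short=seq[oh:m],
        d_short=seq[m:],
        d_long=seq[m:] + seq[:oh],
        frag_e=circular_permute(seq, m),
        split=m,
        overhang_len=oh,
        junction=(n, 1),
        nick_offsets=(0, m),
    )


# ---------------------------------------------------------------------------
# Writers: primer sheet (TSV), annotated GenBank, protocol sheet (JSON)
# ---------------------------------------------------------------------------

def primer_table(primer_set: PrimerSet) -> pd.DataFrame:
    """Primer sheet as a DataFrame (one row per primer, design order)."""
    pairings: dict[str, list[str]] = {name: [] for name in PRIMER_NAMES}
    for product, (fwd, rev) in PCR_PAIRINGS.items():
        pairings[fwd].append(product)
        pairings[rev].append(product)
    rows = []
    for name in PRIMER_NAMES:
        p = primer_set[name]
        rows.append(
            {
                "name": p.name,
                "sequence": p.sequence,
                "anchor": p.anchor,
                "orientation": p.orientation,
                "extension": p.extension or ".",
                "tm": round(p.tm, 2),
                "pcr_pairings": ",".join(pairings[name]),
            }
        )
    return pd.DataFrame(rows)


def write_primer_tsv(primer_set: PrimerSet, path: str | Path) -> None:
    primer_table(primer_set).to_csv(path, sep="\t", index=False)


def plan_record(frag_a: str, primer_set: PrimerSet, name: str = "fragA") -> SeqRecord:
    """Annotated GenBank record of fragment A.

    Features: ``primer_bind`` per primer, ``misc_feature`` for parts C/D,
    the circular junction, and the two nick sites.  Coordinates follow the
    GenBank 1-based inclusive convention (FeatureLocation is 0-based
    half-open internally).
    """
    plan = fragment_plan(frag_a, primer_set)
    seq = plan.frag_a
    n, m = len(seq), plan.split
    record = SeqRecord(Seq(seq), id=name, name=name[:16], description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "linear"

    def misc(start0: int, end0: int, label: str, note: str = "") -> SeqFeature:
        quals = {"label": [label]}
        if note:
            quals["note"] = [note]
        return SeqFeature(FeatureLocation(start0, end0), type="misc_feature",
                          qualifiers=quals)

    record.features.append(misc(0, m, "Part C"))
    record.features.append(misc(m, n, "Part D"))
    record.features.append(
        misc(n - 1, n, "junction",
             note=f"circular junction between positions {n} and 1")
    )
    record.features.append(
        misc(n - 1, n, "nick_top",
             note="top-strand nick at the circular junction")
    )
    record.features.append(
        misc(m - 1, m, "nick_bottom",
             note=f"bottom-strand nick between positions {m} and {m + 1}")
    )
    for pname in PRIMER_NAMES:
        p = primer_set[pname]
        tlen = len(p.templated)
        if p.orientation == "forward":
            loc = FeatureLocation(p.anchor - 1, p.anchor - 1 + tlen, strand=1)
        else:
            loc = FeatureLocation(p.anchor - tlen, p.anchor, strand=-1)
        note = f"Tm {p.tm:.1f} degC; reconstructed layout"
        if p.extension:
            note += f"; non-templated 5' extension {p.extension}"
        record.features.append(
            SeqFeature(loc, type="primer_bind",
                       qualifiers={"label": [pname], "note": [note]})
        )
    return record


def write_genbank(frag_a: str, primer_set: PrimerSet, path: str | Path,
                  name: str = "fragA") -> None:
    SeqIO.write([plan_record(frag_a, primer_set, name=name)], str(path), "genbank")


def read_plan_genbank(path: str | Path) -> SeqRecord:
    """Re-read a plan GenBank record (round-trip partner of write_genbank)."""
    return SeqIO.read(str(path), "genbank")


def protocol_sheet(cycles: int = 5, extension_min: float = 2.0) -> dict:
    """Thermal programs for every bench step, as protocol metadata.

    Temperatures and times mirror the published bench protocol; they are
    documentation for the operator, not simulation parameters.
    """
    pcr = {
        "initial_denaturation": {"temp_c": 95, "time": "2 min"},
        "cycles": 30,
        "denaturation": {"temp_c": 98, "time": "10 s"},
        "annealing": {"temp_c": 52, "time": "30 s"},
        "extension": {"temp_c": 68, "time": f"{extension_min:g} min"},
        "hold": {"temp_c": 4},
    }
    return {
        "step1_fragment_a_pcr": pcr,
        "step2_part_fragment_pcrs": pcr,
        "step3_anneal_and_pnk": {
            "denaturation": {"temp_c": 95, "time": "2 min"},
            "annealing": "cool 5 degC per 3 min down to 30 degC",
            "kinase": {"enzyme": "T4 PNK", "temp_c": 37, "time": "30 min",
                       "inactivation": {"temp_c": 65, "time": "20 min"}},
        },
        "step4_cohesive_ligation": {
            "enzyme": "T7 DNA ligase",
            "note": "ligates cohesive ends only; blunt ends are not joined",
        },
        "step5_fragment_e_pcr": pcr,
        "minicircle_accumulation": {
            "enzyme": "HiFi Taq DNA ligase",
            "denaturation": {"temp_c": 95, "time": "20 s"},
            "cooling": "maximum ramp for 1 min",
            "ligation": {"temp_c": 65, "time": "20 min"},
            "cycles": cycles,
            "cycle_range": [3, 10],
        },
    }


def write_protocol_json(path: str | Path, cycles: int = 5) -> None:
    with open(path, "w") as fh:
        json.dump(protocol_sheet(cycles=cycles), fh, indent=2, sort_keys=True)
        fh.write("\n")
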