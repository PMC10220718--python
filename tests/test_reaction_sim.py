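"""Reaction simulator: PCR, reannealing, kinase, ligase, circle assembly."""

import math

import numpy as np
import pytest

from quicklama import (
    AmbiguousPrimingError,
    AmplificationError,
    CohesionError,
    CoordinateError,
    Duplex,
    FixtureSpec,
    GeometryError,
    IncompatibleFragmentsError,
    Minicircle,
    NoProductError,
    Overhang,
    UnligatableNickError,
    blunt_duplex,
    circular_permute,
    design_primer_set,
    fragment_plan,
    hybrid_fraction,
    lama_assemble,
    lama_cycles,
    ligate_cohesive,
    make_sticky_hybrid,
    phosphorylate,
    random_target,
    reverse_complement,
    seal_nicks,
    simulate_pcr,
)
from quicklama.designer import Primer

from conftest import random_dna


def _fwd(seq: str, name="F", extension=""):
    return Primer(name=name, sequence=extension + seq, anchor=1,
                  orientation="forward", extension=extension, tm=60.0)


def _rev(seq: str, name="R", extension=""):
    return Primer(name=name, sequence=extension + seq, anchor=1,
                  orientation="reverse", extension=extension, tm=60.0)


class TestSimulatePcr:
    def test_self_amplification_identity(self, plan_1kb):
        seq, ps, _ = plan_1kb
        product = simulate_pcr(blunt_duplex(seq), *ps.pair("fragA"))
        assert product.top == seq
        assert product.is_blunt
        assert not product.phos5_top and not product.phos5_bottom

    @pytest.mark.parametrize(
        "name,expected_attr",
        [("C-long", "c_long"), ("C-short", "c_short"),
         ("D-short", "d_short"), ("D-long", "d_long")],
    )
    def test_part_fragments_match_plan(self, plan_1kb, name, expected_attr):
        seq, ps, plan = plan_1kb
        product = simulate_pcr(blunt_duplex(seq), *ps.pair(name))
        assert product.top == getattr(plan, expected_attr)

    def test_frag_e_from_ligation_product(self, plan_1kb):
        # the step-5 PCR off the C+D ligation product yields the rotation of A
        seq, ps, plan = plan_1kb
        precursor = blunt_duplex(plan.frag_e)
        product = simulate_pcr(precursor, *ps.pair("fragE"))
        assert product.top == circular_permute(seq, ps.split)

    def test_junction_pcr_circular_only(self, plan_1kb):
        seq, ps, plan = plan_1kb
        mc = Minicircle(sequence=seq)
        n = len(seq)
        fwd = _fwd(seq[n - 70: n - 50])
        rev = _rev(reverse_complement(seq[50:70]))
        amplicon = simulate_pcr(mc, fwd, rev)
        junction_context = seq[-10:] + seq[:10]
        assert junction_context in amplicon.top
        with pytest.raises(NoProductError):
            simulate_pcr(blunt_duplex(seq), fwd, rev)  # outward on linear

    def test_no_binding_site(self, plan_1kb):
        seq, _, _ = plan_1kb
        t = random_target(FixtureSpec(length=500, seed=99,
                                      forbid_motifs=[seq[:20]]))
        with pytest.raises(AmplificationError):
            simulate_pcr(blunt_duplex(t.sequence), _fwd(seq[:20]),
                         _rev(reverse_complement(t.sequence[-20:])))

    def test_multiple_binding_sites_listed(self):
        seq = "GAATTCACGTACGTACGT" * 2 + "TTTTGGGGCCCCAAAA"
        with pytest.raises(AmbiguousPrimingError) as exc:
            simulate_pcr(blunt_duplex(seq), _fwd("GAATTCACGTACGT"),
                         _rev(reverse_complement(seq[-14:])))
        assert len(exc.value.positions) == 2

    def test_extension_bases_appear_in_product(self, plan_1kb):
        seq, ps, plan = plan_1kb
        product = simulate_pcr(blunt_duplex(seq), *ps.pair("D-long"))
        assert product.top.endswith(seq[:3])  # P2R's non-templated bases


class TestMakeStickyHybrid:
    def test_hybrid_fraction_is_half(self, plan_1kb):
        seq, ps, plan = plan_1kb
        pool = make_sticky_hybrid(blunt_duplex(plan.c_long),
                                  blunt_duplex(plan.c_short))
        assert hybrid_fraction(pool) == pytest.approx(0.5)
        assert sum(f for _, f in pool.entries) == pytest.approx(1.0)
        assert len(pool.entries) == 4

    def test_identical_duplexes_rejected(self, plan_1kb):
        _, _, plan = plan_1kb
        d = blunt_duplex(plan.c_long)
        with pytest.raises(GeometryError):
            make_sticky_hybrid(d, d)

    def test_unrelated_duplexes_rejected(self):
        with pytest.raises(GeometryError):
            make_sticky_hybrid(blunt_duplex("ACGTACGTACGT"),
                               blunt_duplex("TTTTCCCCAA"))

    def test_d_hybrid_overhang_is_target_start(self, plan_1kb):
        seq, ps, plan = plan_1kb
        pool = make_sticky_hybrid(blunt_duplex(plan.d_long),
                                  blunt_duplex(plan.d_short))
        top_oh = [sp for sp, _ in pool.entries
                  if not sp.is_blunt and sp.right_overhang.strand == "top"]
        assert len(top_oh) == 1
        assert top_oh[0].right_overhang.bases == seq[:3]

    def test_hybrids_have_one_sticky_one_blunt_end(self, plan_1kb):
        _, _, plan = plan_1kb
        pool = make_sticky_hybrid(blunt_duplex(plan.d_long),
                                  blunt_duplex(plan.d_short))
        for sp, _ in pool.entries:
            if not sp.is_blunt:
                ends = [sp.left_overhang, sp.right_overhang]
                assert sum(e is not None for e in ends) == 1


class TestPhosphorylate:
    def test_sets_all_flags(self, plan_1kb):
        _, _, plan = plan_1kb
        pool = make_sticky_hybrid(blunt_duplex(plan.c_long),
                                  blunt_duplex(plan.c_short))
        done = phosphorylate(pool)
        assert all(sp.phos5_top and sp.phos5_bottom for sp, _ in done.entries)

    def test_idempotent(self, plan_1kb):
        _, _, plan = plan_1kb
        d = blunt_duplex(plan.c_long)
        once = phosphorylate(d)
        twice = phosphorylate(once)
        assert once == twice


def _sticky_pair(plan, phosphorylated=True):
    """One ligatable D/C heteroduplex pair (3' overhangs)."""
    pool_d = make_sticky_hybrid(blunt_duplex(plan.d_long),
                                blunt_duplex(plan.d_short))
    pool_c = make_sticky_hybrid(blunt_duplex(plan.c_long),
                                blunt_duplex(plan.c_short))
    if phosphorylated:
        pool_d, pool_c = phosphorylate(pool_d), phosphorylate(pool_c)
    d = next(sp for sp, _ in pool_d.entries
             if not sp.is_blunt and sp.right_overhang.strand == "top")
    c = next(sp for sp, _ in pool_c.entries
             if not sp.is_blunt and sp.left_overhang is not None
             and sp.left_overhang.strand == "bottom")
    return d, c


class TestLigateCohesive:
    def test_d_plus_c_reconstructs_rotation(self, plan_1kb):
        seq, ps, plan = plan_1kb
        d, c = _sticky_pair(plan)
        product = ligate_cohesive(d, c)
        assert product.top == seq[ps.split:] + seq[:ps.split]
        assert product.is_blunt

    def test_blunt_ends_never_join(self, plan_1kb):
        _, _, plan = plan_1kb
        with pytest.raises(CohesionError):
            ligate_cohesive(phosphorylate(blunt_duplex(plan.c_long)),
                            phosphorylate(blunt_duplex(plan.d_short)))

    def test_overhang_complementarity_rule(self):
        def with_3prime_top(top):  # right-end 3' overhang "AAC"
            return Duplex(top=top, bottom=reverse_complement(top[:-3]),
                          right_overhang=Overhang("top", top[-3:]),
                          phos5_top=True, phos5_bottom=True)

        def with_3prime_bottom(top, oh):  # left-end 3' overhang on bottom
            bottom = reverse_complement(top) + oh
            return Duplex(top=top, bottom=bottom,
                          left_overhang=Overhang("bottom", bottom[-3:]),
                          phos5_top=True, phos5_bottom=True)

        a = with_3prime_top("ACGTACGTACGTAAC")
        ok = with_3prime_bottom("CCGGCCGGCCGG", "GTT")  # revcomp(AAC)
        bad = with_3prime_bottom("CCGGCCGGCCGG", "AAC")
        joined = ligate_cohesive(a, ok)
        assert joined.top == "ACGTACGTACGTAAC" + "CCGGCCGGCCGG"
        with pytest.raises(CohesionError):
            ligate_cohesive(a, bad)

    def test_missing_phosphate_blocks_ligation(self, plan_1kb):
        _, _, plan = plan_1kb
        d, c = _sticky_pair(plan, phosphorylated=False)
        with pytest.raises(UnligatableNickError):
            ligate_cohesive(d, c)
        d, c = _sticky_pair(plan, phosphorylated=True)
        assert ligate_cohesive(d, c).top == plan.frag_e


class TestLamaAssemble:
    def test_two_nicks_separated_by_split(self, ae_pair):
        a, e = ae_pair
        nc = lama_assemble(a, e)
        assert len(nc.nicks) == 2
        positions = sorted(n.position for n in nc.nicks)
        assert positions[1] - positions[0] == 500
        assert {n.strand for n in nc.nicks} == {"top", "bottom"}

    def test_nick_separation_across_sizes(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(300, 3000))
            seq = random_dna(rng, n)
            m = n // 2
            a = phosphorylate(blunt_duplex(seq))
            e = phosphorylate(blunt_duplex(circular_permute(seq, m)))
            nc = lama_assemble(a, e)
            lo, hi = sorted(nk.position for nk in nc.nicks)
            assert hi - lo == m
            assert nc.length == n

    def test_unrotated_fragment_rejected(self, ae_pair):
        a, _ = ae_pair
        with pytest.raises(IncompatibleFragmentsError):
            lama_assemble(a, a)

    def test_length_mismatch_rejected(self, ae_pair):
        a, _ = ae_pair
        short = phosphorylate(blunt_duplex(a.top[:500]))
        with pytest.raises(IncompatibleFragmentsError):
            lama_assemble(a, short)


class TestSealNicks:
    def test_designed_path_yields_minicircle(self, ae_pair):
        a, e = ae_pair
        mc = seal_nicks(lama_assemble(a, e))
        assert isinstance(mc, Minicircle)
        assert mc.sequence in a.top + a.top  # rotation of fragment A

    def test_unphosphorylated_input_rejected(self, plan_1kb):
        _, _, plan = plan_1kb
        a = blunt_duplex(plan.frag_a)
        e = blunt_duplex(plan.frag_e)
        with pytest.raises(UnligatableNickError):
            seal_nicks(lama_assemble(a, e))


class TestLamaCycles:
    @pytest.mark.parametrize("c,expected", [(1, 0.5), (3, 0.875)])
    def test_closed_form(self, ae_pair, c, expected):
        a, e = ae_pair
        pool = lama_cycles(a, e, cycles=c, p_circ=0.5)
        assert pool.fraction(Minicircle) == pytest.approx(expected)

    def test_closed_form_matches_exhaustive_enumeration(self, ae_pair):
        # enumerate all 2^3 per-cycle outcome paths for one molecule
        a, e = ae_pair
        p = 0.5
        prob_circular = 0.0
        for path in range(8):
            bits = [(path >> i) & 1 for i in range(3)]
            weight = 1.0
            for b in bits:
                weight *= p if b else (1 - p)
            if any(bits):  # closed in at least one cycle
                prob_circular += weight
        pool = lama_cycles(a, e, cycles=3, p_circ=p)
        assert pool.fraction(Minicircle) == pytest.approx(prob_circular)

    def test_monotone_in_cycles(self, ae_pair):
        a, e = ae_pair
        fracs = [lama_cycles(a, e, cycles=c, p_circ=0.3).fraction(Minicircle)
                 for c in range(1, 8)]
        assert all(b >= a_ for a_, b in zip(fracs, fracs[1:]))

    def test_stochastic_converges_to_closed_form(self, ae_pair):
        a, e = ae_pair
        n = 100_000
        pool = lama_cycles(a, e, cycles=3, p_circ=0.5, stochastic=True,
                           n_molecules=n, seed=42)
        expected = 0.875
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(pool.fraction(Minicircle) - expected) <= 3 * se

    def test_bad_cycle_count(self, ae_pair):
        a, e = ae_pair
        with pytest.raises(CoordinateError):
            lama_cycles(a, e, cycles=0)


class TestEndToEndRotation:
    def test_sealed_circle_is_rotation_of_target(self):
        # full design -> assemble -> seal across the working size range
        rng = np.random.default_rng(101)
        for _ in range(100):
            n = int(rng.integers(300, 3000))
            seq = random_dna(rng, n)
            ps = design_primer_set(seq)
            plan = fragment_plan(seq, ps)
            a = phosphorylate(blunt_duplex(plan.frag_a))
            e = phosphorylate(blunt_duplex(plan.frag_e))
            mc = seal_nicks(lama_assemble(a, e))
            assert len(mc.sequence) == n
            assert mc.sequence in seq + seq  # string-rotation oracle
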