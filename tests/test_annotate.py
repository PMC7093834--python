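"""Structural annotation: flanks, boundaries, TIR/TSD, ORF/DDE/GRPR,
intact / full-length / truncated classification."""

import dataclasses

import pytest

from temine._dna import random_dna, revcomp
from temine.annotate import (TECopy, TriadSpec, annotate_copy,
                             classify_element, detect_dde, detect_grpr,
                             detect_tir, detect_tsd, extract_with_flanks,
                             find_orf, refine_boundaries)
from temine.search import Hit
from temine.simulate import SubstitutionParams, evolve_sequence

from .oracles import oracle_tir


def _hit(contig="c", start=0, end=0, strand="+"):
    return Hit(contig=contig, start=start, end=end, strand=strand,
               identity=100.0, length=end - start, score=0)


class TestExtractWithFlanks:
    def test_flank_arithmetic(self, rng):
        genome = {"c": random_dna(10_000, rng)}
        copy = extract_with_flanks(genome, _hit(start=2000, end=3500),
                                   flank=1000)
        assert copy.left_flank == genome["c"][1000:2000]
        assert copy.right_flank == genome["c"][3500:4500]
        assert copy.element_sequence == genome["c"][2000:3500]

    def test_flank_clipped_at_contig_start(self, rng):
        genome = {"c": random_dna(5_000, rng)}
        copy = extract_with_flanks(genome, _hit(start=300, end=1500),
                                   flank=1000)
        assert len(copy.left_flank) == 300

    def test_minus_strand_orientation(self, rng):
        genome = {"c": random_dna(6_000, rng)}
        copy = extract_with_flanks(genome,
                                   _hit(start=2000, end=3000, strand="-"),
                                   flank=500)
        assert copy.element_sequence == revcomp(genome["c"][2000:3000])
        assert copy.left_flank == revcomp(genome["c"][3000:3500])
        assert copy.right_flank == revcomp(genome["c"][1500:2000])

    def test_out_of_contig_rejected(self, rng):
        genome = {"c": random_dna(1_000, rng)}
        with pytest.raises(ValueError):
            extract_with_flanks(genome, _hit(start=500, end=1500))


class TestRefineBoundaries:
    def _copies(self, master, rng, n, k_target=0.0, flank=500, tsd=""):
        out = []
        for _ in range(n):
            elem = master.full_sequence if k_target == 0 else \
                evolve_sequence(master.full_sequence,
                                SubstitutionParams(k_target=k_target,
                                                   indel_rate=0.0005), rng)
            out.append(TECopy(
                contig="c", start=1000 + len(tsd),
                end=1000 + len(tsd) + len(elem), strand="+",
                element_sequence=elem,
                left_flank=random_dna(flank, rng) + tsd,
                right_flank=tsd + random_dna(flank, rng)))
        return out

    def test_identical_copies_recover_planted_coordinates(self, master,
                                                          rng):
        """Identical elements in random flanks: boundaries recover the
        planted coordinates in most constructions.  With five copies, a
        chance (or alignment-induced) agreement of flank bases immediately
        outside the element is indistinguishable from element sequence, so
        a small overrun on a minority of trials is intrinsic; real calls
        are additionally anchored by the TSD (see the tsd argument)."""
        exact = 0
        for _ in range(20):
            copies = self._copies(master, rng, 5)
            refined = refine_boundaries(copies, flank_window=150)
            deltas = [(r.start - c.start, r.end - c.end)
                      for c, r in zip(copies, refined)]
            assert all(abs(a) <= 4 and abs(b) <= 4 for a, b in deltas)
            exact += all(d == (0, 0) for d in deltas)
        assert exact >= 10

    def test_diverged_copies_within_two_bp(self, master, rng):
        copies = self._copies(master, rng, 8, k_target=0.05, tsd="TA")
        refined = refine_boundaries(copies, flank_window=150, tsd="TA")
        for c, r in zip(copies, refined):
            assert abs(r.start - c.start) <= 2
            assert abs(r.end - c.end) <= 2

    def test_shared_flank_extends_boundary(self, master, rng):
        """Copies sharing 50 bp of identical flank (segmental
        duplication): the boundary extends into the shared flank — the
        documented failure mode of conservation-based calling."""
        shared = random_dna(50, rng)
        copies = []
        for _ in range(6):
            copies.append(TECopy(
                contig="c", start=1000, end=1000 + 1550, strand="+",
                element_sequence=master.full_sequence,
                left_flank=random_dna(450, rng) + shared,
                right_flank=random_dna(500, rng)))
        refined = refine_boundaries(copies, flank_window=150)
        assert all(r.start <= c.start - 40 for c, r in zip(copies, refined))

    def test_single_copy_returned_with_warning(self, master, rng):
        copies = self._copies(master, rng, 1)
        with pytest.warns(UserWarning):
            out = refine_boundaries(copies)
        assert out == copies


class TestDetectTir:
    def test_constructed_element(self, rng):
        arm = random_dna(20, rng)
        core = random_dna(800, rng)
        elem = arm + core + revcomp(arm)
        tir = detect_tir(elem)
        assert tir is not None
        assert (tir.left_start, tir.left_end) == (0, 20)
        assert (tir.right_start, tir.right_end) == (820, 840)
        assert tir.mismatches == 0
        assert tir.pentamer == arm[:5]

    def test_master_reports_family_pentamer(self, master):
        tir = detect_tir(master.full_sequence)
        assert tir is not None
        assert tir.pentamer == "CAGTC"
        assert tir.length >= master.tir_length

    def test_no_tir_in_random_sequence(self, rng):
        assert detect_tir(random_dna(1_000, rng), min_len=12) is None or \
            detect_tir(random_dna(1_000, rng), min_len=12).length < 20

    def test_short_element_rejected(self):
        with pytest.raises(ValueError):
            detect_tir("ACGTACGTACG", min_len=10)

    def test_equals_exhaustive_oracle(self, master, rng):
        """Anchored detection equals enumeration over all (offset, offset,
        length) triples on planted and random elements."""
        cases = []
        for _ in range(20):
            arm_len = int(rng.integers(13, 69))
            arm = random_dna(arm_len, rng)
            elem = arm + random_dna(int(rng.integers(400, 1200)), rng) \
                + revcomp(arm)
            cases.append(evolve_sequence(
                elem, SubstitutionParams(k_target=0.03), rng))
        for _ in range(10):
            cases.append(random_dna(int(rng.integers(200, 1500)), rng))
        for seq in cases:
            got = detect_tir(seq)
            want = oracle_tir(seq)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert (got.left_start, got.left_end, got.right_start,
                        got.right_end, got.length, got.mismatches) == want


class TestDetectTsd:
    def _copy(self, left, right):
        return TECopy(contig="c", start=0, end=10, strand="+",
                      element_sequence="A" * 10, left_flank=left,
                      right_flank=right)

    def test_matching_tsds(self):
        tsd = detect_tsd(self._copy("GGGTA", "TACCC"))
        assert (tsd.left, tsd.right, tsd.match) == ("TA", "TA", True)

    def test_mismatching_left(self):
        tsd = detect_tsd(self._copy("GGGCA", "TACCC"))
        assert tsd.match is False

    def test_short_flank_undefined(self):
        tsd = detect_tsd(self._copy("A", "TACCC"))
        assert tsd.left is None
        assert tsd.match is False


class TestFindOrf:
    def test_master_orf_recovered(self, master):
        orf = find_orf(master.full_sequence)
        assert orf is not None
        assert (orf.start, orf.end) == (master.orf_start, master.orf_end)
        assert orf.protein == master.transposase

    def test_internal_stop_kills_long_orf(self, master):
        seq = master.full_sequence
        mid = master.orf_start + 3 * 170
        broken = seq[:mid] + "TAA" + seq[mid + 3:]
        orf = find_orf(broken, min_aa=300)
        assert orf is None

    def test_random_sequence_has_no_long_orf(self, rng):
        found = sum(
            find_orf(random_dna(1_500, rng), min_aa=300) is not None
            for _ in range(30))
        assert found == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            find_orf("")


class TestDetectDde:
    @staticmethod
    def _protein(d2: int, e: int, d1: int = None, length: int = 340):
        d1 = d1 if d1 is not None else d2 - 91
        prot = ["A"] * length
        prot[d1 - 1] = "D"
        prot[d2 - 1] = "D"
        prot[e - 1] = "E"
        return "".join(prot)

    def test_dd35e_labelled(self):
        triad = detect_dde(self._protein(d2=220, e=256))
        assert triad is not None
        assert triad.label == "DD35E"
        assert (triad.d2, triad.e) == (220, 256)

    def test_dd34e_sister_family_labelled(self):
        triad = detect_dde(self._protein(d2=220, e=255))
        assert triad is not None
        assert triad.label == "DD34E"

    def test_poly_alanine_has_no_triad(self):
        assert detect_dde("A" * 340) is None

    def test_short_protein_rejected(self):
        assert detect_dde("MDDE") is None

    def test_spacing_outside_allowed_set_not_reported(self):
        assert detect_dde(self._protein(d2=220, e=250)) is None


class TestDetectGrpr:
    def test_planted_position(self):
        prot = "M" + "A" * 50 + "GRPR" + "A" * 300
        assert detect_grpr(prot) == 51

    def test_c_terminal_occurrence_ignored(self):
        prot = "M" + "A" * 300 + "GRPR" + "A" * 40
        assert detect_grpr(prot) is None

    def test_absent(self):
        assert detect_grpr("MAAAAAA") is None


class TestClassification:
    def _annotated(self, master, rng, flank_tsd=True, break_orf=False,
                   cut_left=0):
        elem = master.full_sequence[cut_left:]
        if break_orf:
            mid = master.orf_start + 3 * 100 + 1
            elem = elem[:mid] + elem[mid + 1:]   # frameshift deletion
        tsd = "TA" if flank_tsd else "GG"
        copy = TECopy(contig="c", start=0, end=len(elem), strand="+",
                      element_sequence=elem,
                      left_flank=random_dna(200, rng) + tsd,
                      right_flank=tsd + random_dna(200, rng))
        return annotate_copy(copy)

    def test_pristine_copy_is_intact(self, master, rng):
        copy = self._annotated(master, rng)
        assert copy.classification == "intact"

    def test_frameshift_downgrades_to_full_length(self, master, rng):
        copy = self._annotated(master, rng, break_orf=True)
        assert copy.classification == "full_length"

    def test_truncation_removing_tir_is_truncated(self, master, rng):
        copy = self._annotated(master, rng, cut_left=200)
        assert copy.classification == "truncated"

    def test_classification_monotone_under_evidence_removal(self, master,
                                                            rng):
        """Removing annotation evidence never upgrades the class."""
        order = {"intact": 2, "full_length": 1, "truncated": 0}
        copy = self._annotated(master, rng)
        base = order[copy.classification]
        no_orf = dataclasses.replace(copy.orf, triad=None)
        copy.orf = no_orf
        assert order[classify_element(copy)] <= base
        mid = order[copy.classification]
        copy.tir = None
        assert order[classify_element(copy)] <= mid

    def test_triadspec_validation(self):
        with pytest.raises(ValueError):
            TriadSpec(d1=10, d2=5, e=40)
        spec = TriadSpec(d1=100, d2=220, e=256)
        assert spec.spacing == 35
        assert spec.label == "DD35E"
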