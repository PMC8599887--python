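"""Probe construction, linearization, junction discrimination and tiling."""

import pytest
from hypothesis import given, strategies as st

from omegaqpcr import (
    ProbeGeometry,
    RepeatTarget,
    arm_melting_temperature,
    build_probe,
    check_ligation_junction,
    default_probe,
    linearize_to_orf,
    revcomp,
    tile_probes,
)
from Bio.SeqUtils import MeltingTemp as mt

from conftest import ORF_88MER, PROBE_88MER


class TestBuildProbe:
    def test_default_segments_reproduce_published_88mer(self, probe):
        assert probe.full_sequence == PROBE_88MER
        assert len(probe.full_sequence) == 88
        assert probe.phosphorylated

    def test_concatenation_order(self):
        p = build_probe("A", "C", "G", "T", "A")
        assert p.full_sequence == "ACGTA"

    def test_rejects_empty_and_non_dna_segments(self):
        with pytest.raises(ValueError):
            build_probe("", "C", "G", "T", "A")
        with pytest.raises(ValueError):
            build_probe("AXC", "C", "G", "T", "A")

    @pytest.mark.parametrize("phase", range(6))
    def test_arms_complementary_to_every_repeat_phase(self, phase):
        """12-nt C-rich arms at any phase are reverse complements of the G strand."""
        unit = "TTAGGG"
        tract = unit * 5
        site5 = tract[phase : phase + 12]
        site3 = tract[phase + 12 : phase + 24]
        p = build_probe(revcomp(site5), "CGCG", "ATAT", "GCGC", revcomp(site3),
                        target=RepeatTarget(unit=unit, n_units=5))
        # brute-force check over all 6 phases: each arm matches exactly one
        ref = unit * 10
        for arm in (p.arm5, p.arm3):
            matches = [
                ph for ph in range(6)
                if ref[ph : ph + len(arm)] == revcomp(arm)
            ]
            assert len(matches) == 1
        assert p.arm_phases() == (phase % 6, (phase + 12) % 6)

    def test_junction_target_is_the_TA_dinucleotide(self, probe):
        assert probe.junction_target == "TA"


class TestLinearizeToOrf:
    def test_default_probe_rotates_to_published_orf(self, probe):
        assert linearize_to_orf(probe).sequence == ORF_88MER

    def test_pf_leading_probe_is_identity_rotation(self):
        # arm5 equals pf, so the forward primer is found at position 0 and
        # the rotation leaves the sequence unchanged
        p = build_probe("CAGT", "AACC", "CAGT", "GGTT", "TTAA")
        assert linearize_to_orf(p).sequence == p.full_sequence

    def test_rotation_is_substring_of_doubled_sequence(self, probe):
        orf = linearize_to_orf(probe).sequence
        assert orf in probe.full_sequence * 2
        assert sorted(orf) == sorted(probe.full_sequence)

    def test_missing_pf_raises(self):
        p = build_probe("AACC", "GGTT", "CAGT", "TTGG", "CCAA")

        class Broken(type(p)):
            @property
            def full_sequence(self):  # primer absent from the strand
                return "AACCGGTTTTGGCCAA"

        broken = Broken(arm5=p.arm5, pr_binding=p.pr_binding, pf=p.pf,
                        hp=p.hp, arm3=p.arm3)
        with pytest.raises(ValueError):
            linearize_to_orf(broken)


class TestLigationJunction:
    def _window(self, probe):
        return revcomp(probe.arm5) + revcomp(probe.arm3)

    def test_canonical_window_ligatable(self, probe):
        assert check_ligation_junction(probe, self._window(probe)) == "ligatable"

    def test_phase_shift_by_one_unit_preserves_verdict(self, probe):
        tract = "TTAGGG" * 20
        w = self._window(probe)
        start = tract.find(w)
        assert start >= 0
        for k in range(3):
            window = tract[start + 6 * k : start + 6 * k + len(w)]
            assert check_ligation_junction(probe, window) == "ligatable"

    @pytest.mark.parametrize("junction_pos", [0, 1])
    def test_exactly_one_of_four_bases_ligatable_at_junction(self, probe, junction_pos):
        """Enumerating all 4 substitutions at a junction-covered base leaves
        exactly the Watson-Crick complementary one ligatable."""
        w = list(self._window(probe))
        idx = len(probe.arm5) - 1 + junction_pos
        verdicts = {}
        for base in "ACGT":
            w2 = w.copy()
            w2[idx] = base
            verdicts[base] = check_ligation_junction(probe, "".join(w2))
        assert sum(v == "ligatable" for v in verdicts.values()) == 1
        canonical = self._window(probe)[idx]
        assert verdicts[canonical] == "ligatable"

    def test_subtelomeric_variant_junction_mismatch(self, probe):
        """A variant base at the junction-covered position aborts ligation."""
        w = list(self._window(probe))
        w[len(probe.arm5)] = "C"  # TTAGGG -> TTCGGG-like variant at the A
        assert check_ligation_junction(probe, "".join(w)) == "mismatch"

    def test_short_window_raises(self, probe):
        with pytest.raises(ValueError):
            check_ligation_junction(probe, "TTAGGG")


class TestTileProbes:
    @pytest.mark.parametrize(
        "length,expected", [(0, 0), (31, 0), (32, 1), (79, 1), (80, 2),
                            (800, 17), (1600, 33)]
    )
    def test_saturating_counts(self, length, expected):
        assert tile_probes(length) == expected

    def test_negative_length_raises(self):
        with pytest.raises(ValueError):
            tile_probes(-1)

    @given(st.integers(min_value=1, max_value=10**6))
    def test_exact_inverse_of_length_formula(self, n):
        assert tile_probes(48 * (n - 1) + 32) == n

    @given(st.integers(min_value=0, max_value=10**5))
    def test_non_decreasing_in_length(self, length):
        assert tile_probes(length + 1) >= tile_probes(length)

    def test_custom_geometry(self):
        g = ProbeGeometry(footprint_hyb=10, occlusion=15)
        assert tile_probes(10, g) == 1
        assert tile_probes(9, g) == 0
        assert tile_probes(40, g) == 3


class TestArmMeltingTemperature:
    def test_gc_rich_melts_higher_than_at_rich(self):
        at = arm_melting_temperature("AATAATAATAATAATA")
        gc = arm_melting_temperature("GGCGGCGGCGGCGGCG")
        assert gc > at

    def test_length_monotone_for_homologous_extension(self):
        arm = "CCCTAACCCTAACCCT"
        assert arm_melting_temperature(arm * 2) >= arm_melting_temperature(arm)

    def test_published_arm_in_generic_oligo_range(self, probe):
        """Advisory check against two nearest-neighbour parameter sets."""
        tm1 = arm_melting_temperature(probe.arm5[:16])
        tm2 = arm_melting_temperature(probe.arm5[:16], nn_table=mt.DNA_NN3)
        assert 40.0 <= tm1 <= 60.0
        assert abs(tm1 - tm2) < 5.0

    def test_too_short_arm_raises(self):
        with pytest.raises(ValueError):
            arm_melting_temperature("ACGTACG")


class TestRepeatTarget:
    def test_tract_generation(self):
        t = RepeatTarget(unit="TTAGGG", n_units=10)
        assert t.tract == "TTAGGG" * 10
        assert t.tract_length == 60

    def test_variant_pattern_validation(self):
        t = RepeatTarget(unit="TTAGGG", n_units=1, variant_pattern="TTXAGGG")
        assert t.variant_tract(2, "C") == "TTCAGGGTTCAGGG"
        with pytest.raises(ValueError):
            RepeatTarget(unit="TTAGGG", variant_pattern="TTXXAGG")

    def test_rejects_bad_unit(self):
        with pytest.raises(ValueError):
            RepeatTarget(unit="TTAGGN")
        with pytest.raises(ValueError):
            RepeatTarget(unit="TTAGGG", n_units=0)
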