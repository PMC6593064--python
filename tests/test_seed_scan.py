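"""Seed-site scanning and SNP effect classification."""

import numpy as np
import pytest

from conftest import random_seq
from seedshift.seed_scan import (SEED_RANK, SNPVariant, classify_snp_effect,
                                 scan_seed_sites)
from seedshift.sequences import NucSequence, SequenceError, complement, reverse_complement

MIRNA = NucSequence("mir_test", "UAGCUGAGGCCAUGCUAGCUAA")  # arbitrary 22-mer guide
CORE6 = reverse_complement(MIRNA.residues[1:7])  # pairs seed positions 2-7
M8 = complement(MIRNA.residues[7])


def _window(core_flank_5="", core_flank_3="", pad5="AAAAAAAAAA", pad3="AAAAAAAAAA"):
    return NucSequence("w", pad5 + core_flank_5 + CORE6 + core_flank_3 + pad3)


class TestScan:
    def test_constructed_8mer(self):
        # N10 + revcomp(seed 2-8) + A + N10 -> one 8mer at [10, 18)
        w = NucSequence("w", "A" * 10 + reverse_complement(MIRNA.residues[1:8]) + "A" + "A" * 10)
        sites = scan_seed_sites(w, MIRNA)
        best = max(sites, key=lambda s: s.rank)
        assert best.seed_class == "8mer"
        assert best.target_interval == (10, 18)

    @pytest.mark.parametrize("m8,a1,expected,interval", [
        (True, True, "8mer", (9, 17)),
        (True, False, "7mer-m8", (9, 16)),
        (False, True, "7mer-A1", (10, 17)),
        (False, False, "6mer", (10, 16)),
    ])
    def test_class_hierarchy(self, m8, a1, expected, interval):
        # U cannot pair the m8 G of this miRNA; G breaks the A1 anchor
        w = _window(core_flank_5=M8 if m8 else "U", core_flank_3="A" if a1 else "G",
                    pad5="A" * 9, pad3="A" * 9)
        sites = [s for s in scan_seed_sites(w, MIRNA) if s.rank > 0]
        assert len(sites) == 1
        assert sites[0].seed_class == expected
        assert sites[0].target_interval == interval

    def test_no_match_in_poly_u(self):
        assert scan_seed_sites(NucSequence("w", "U" * 30), MIRNA) == []

    def test_two_disjoint_sites_in_order(self):
        w = NucSequence("w", "AAAA" + M8 + CORE6 + "G" + "AAAAA" + M8 + CORE6 + "G" + "AA")
        sites = scan_seed_sites(w, MIRNA)
        m7 = [s for s in sites if s.seed_class == "7mer-m8"]
        assert len(m7) == 2
        assert m7[0].target_interval[1] <= m7[1].target_interval[0]

    def test_interval_is_exact_seed_revcomp(self, rng):
        """Any reported site, when extracted, reverse-complements the
        corresponding seed positions residue-by-residue."""
        checked = 0
        for _ in range(40):
            m = NucSequence("m", random_seq(rng, 21))
            # plant the core in a random background so every window has >= 1 site
            core = reverse_complement(m.residues[1:7])
            pos = int(rng.integers(1, 40))
            bg = random_seq(rng, 50)
            w = NucSequence("w", bg[:pos] + core + bg[pos + 6:])
            for site in scan_seed_sites(w, m):
                s, e = site.target_interval
                seg = w[s:e]
                if site.seed_class == "8mer":
                    assert seg[:7] == reverse_complement(m.residues[1:8]) and seg[7] == "A"
                elif site.seed_class == "7mer-m8":
                    assert seg == reverse_complement(m.residues[1:8])
                elif site.seed_class == "7mer-A1":
                    assert seg[:6] == reverse_complement(m.residues[1:7]) and seg[6] == "A"
                elif site.seed_class == "6mer":
                    assert seg == reverse_complement(m.residues[1:7])
                checked += 1
        assert checked > 5

    def test_reversal_coordinate_map(self, rng):
        """Core-only (6mer) matches of the reversed window appear at the
        positions predicted by i -> L - end."""
        for _ in range(20):
            w = random_seq(rng, 40)
            m = NucSequence("m", random_seq(rng, 20))
            fwd = {s.target_interval for s in scan_seed_sites(NucSequence("w", w), m)}
            # compare on the 6mer core anchored coordinates only: reversal breaks
            # the asymmetric m8/A1 flanks, so rebuild cores from both scans
            core = reverse_complement(m.residues[1:7])
            starts_direct = {i for i in range(len(w) - 5) if w[i:i + 6] == core}
            rev = w[::-1]
            starts_from_rev = {len(w) - (i + 6)
                               for i in range(len(rev) - 5) if rev[i:i + 6] == core[::-1]}
            assert starts_direct == starts_from_rev
            for s, e in fwd:
                assert 0 <= s < e <= len(w)

    def test_short_window_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            assert scan_seed_sites(NucSequence("w", "ACGUA"), MIRNA) == []

    def test_short_mirna_rejected(self):
        with pytest.raises(SequenceError):
            scan_seed_sites(NucSequence("w", "A" * 20), NucSequence("m", "ACGUACG"))

    def test_wobble_flag_relaxes_matching(self):
        # replace a core C (pairing miRNA G) with U: dead strict, alive with wobble
        g_pos = CORE6.index("C")
        core_wobbled = CORE6[:g_pos] + "U" + CORE6[g_pos + 1:]
        w = NucSequence("w", "A" * 10 + core_wobbled + "G" + "A" * 10)
        assert all(s.rank == 0 for s in scan_seed_sites(w, MIRNA)) or \
            not scan_seed_sites(w, MIRNA)
        relaxed = scan_seed_sites(w, MIRNA, allow_wobble=True)
        assert any(s.rank >= SEED_RANK["6mer"] for s in relaxed)


class TestClassifySNP:
    def test_site_created_and_destroyed_are_mirror(self):
        w_alt = NucSequence("w", "A" * 10 + M8 + CORE6 + "G" + "A" * 10)
        pos = 11 + 3                      # CORE6[3], inside the 6mer core
        broken = "A" if CORE6[3] != "A" else "C"
        w_ref = w_alt.with_substitution(pos, broken)
        snp = SNPVariant("rs_test", pos, broken, CORE6[3])
        ref_site, alt_site, effect = classify_snp_effect(w_ref, snp, MIRNA)
        assert effect == "site_created"
        assert ref_site is None and alt_site.seed_class == "7mer-m8"
        # swapping the alleles mirrors the label
        snp_sw = SNPVariant("rs_test", pos, CORE6[3], broken)
        _, _, effect_sw = classify_snp_effect(w_alt, snp_sw, MIRNA)
        assert effect_sw == "site_destroyed"

    def test_class_up_when_m8_completed(self):
        # ref lacks the m8 anchor (6mer), alt completes it (7mer-m8)
        w_ref = NucSequence("w", "A" * 9 + "U" + CORE6 + "G" + "A" * 9)
        snp = SNPVariant("rs_test", 9, "U", M8)
        ref_site, alt_site, effect = classify_snp_effect(w_ref, snp, MIRNA)
        assert (ref_site.seed_class, alt_site.seed_class) == ("6mer", "7mer-m8")
        assert effect == "class_up"
        snp_sw = SNPVariant("rs_test", 9, M8, "U")
        _, _, effect_sw = classify_snp_effect(
            w_ref.with_substitution(9, M8), snp_sw, MIRNA)
        assert effect_sw == "class_down"

    def test_snp_outside_site_is_no_change(self):
        w = NucSequence("w", "A" * 10 + M8 + CORE6 + "A" + "A" * 10)
        snp = SNPVariant("rs_test", 0, "A", "C")
        ref_site, alt_site, effect = classify_snp_effect(w, snp, MIRNA)
        assert effect == "no_change" and ref_site is None and alt_site is None

    def test_snp_inconsistent_with_window_rejected(self):
        w = NucSequence("w", "A" * 20)
        with pytest.raises(SequenceError):
            classify_snp_effect(w, SNPVariant("rs", 3, "C", "U"), MIRNA)
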