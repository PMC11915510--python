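import math
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import nucleoquant as nq
from nucleoquant.biophys import (
    PKA_TABLES,
    enumerate_g4_candidates,
    net_charge,
    round_sig,
)
from nucleoquant.errors import ContractError


class TestCsp:
    def test_collapses_to_proton_shift(self):
        assert nq.csp(0.1, 0.0) == 0.1

    def test_nitrogen_scaling(self):
        assert nq.csp(0.0, 0.5) == pytest.approx(0.1, abs=1e-15)

    def test_closed_form_to_machine_precision(self):
        assert nq.csp(0.3, 1.0) == pytest.approx(
            math.sqrt(0.3**2 + (0.2 * 1.0) ** 2), abs=1e-15
        )

    @given(
        st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False)
    )
    def test_sign_symmetry_and_lower_bound(self, h, n):
        v = nq.csp(h, n)
        assert v == nq.csp(-h, n) == nq.csp(h, -n)
        assert v >= abs(h) - 1e-12 and v >= 0.2 * abs(n) - 1e-12

    def test_vectorized(self):
        out = nq.csp([0.1, 0.0], [0.0, 0.5])
        np.testing.assert_allclose(out, [0.1, 0.1])


class TestFlagBindingResidues:
    def test_seventy_percent_loss_flagged(self):
        peaks = [
            nq.PeakRecord("A1", 0.0, 0.0, 100.0, 30.0),
            nq.PeakRecord("A2", 0.0, 0.0, 100.0, 90.0),
        ]
        out = nq.flag_binding_residues(peaks).set_index("residue_id")
        assert bool(out.loc["A1", "volume_loss"])
        assert not bool(out.loc["A2", "volume_loss"])

    def test_equal_shifts_flag_nothing_above_mean(self):
        peaks = [nq.PeakRecord(f"R{i}", 0.1, 0.2, 50.0, 50.0) for i in range(4)]
        out = nq.flag_binding_residues(peaks)
        assert not out.shift_above_mean.any()

    def test_zero_free_volume_skipped_with_warning(self):
        peaks = [
            nq.PeakRecord("Z", 0.0, 0.0, 0.0, 0.0),
            nq.PeakRecord("K", 0.1, 0.0, 10.0, 1.0),
        ]
        with pytest.warns(UserWarning, match="zero free volume"):
            out = nq.flag_binding_residues(peaks)
        assert out.residue_id.tolist() == ["K"]

    def test_mixed_panel_matches_hand_enumeration(self):
        # shifts: 0.10, 0.30, 0.05, 0.2236..., 0.10 -> mean 0.15472;
        # losses: 0.50, 0.80, 0.00, 0.70, 2/3 (not > 2/3)
        peaks = [
            nq.PeakRecord("r1", 0.1, 0.0, 100.0, 50.0),
            nq.PeakRecord("r2", 0.3, 0.0, 100.0, 20.0),
            nq.PeakRecord("r3", 0.05, 0.0, 90.0, 90.0),
            nq.PeakRecord("r4", 0.2, 0.5, 60.0, 18.0),
            nq.PeakRecord("r5", 0.0, 0.5, 30.0, 10.0),
        ]
        out = nq.flag_binding_residues(peaks).set_index("residue_id")
        assert out.volume_loss.tolist() == [False, True, False, True, False]
        assert out.shift_above_mean.tolist() == [False, True, False, True, False]
        assert out.loc["r4", "delta_shift"] == pytest.approx(math.hypot(0.2, 0.1))


class TestMolarConcentration:
    def test_avogadro_self_consistency(self):
        from scipy.constants import Avogadro

        n_for_1uM = Avogadro * 1e-15 * 1e-6  # molecules giving 1 uM in 1 um^3
        assert nq.molar_concentration(n_for_1uM, 1.0) == pytest.approx(1.0)

    def test_cellular_copy_number_bounds(self):
        low = nq.molar_concentration(0.35e6, 2425.0)
        high = nq.molar_concentration(7e6, 1198.0)
        assert round_sig(low) == pytest.approx(0.2)
        assert round_sig(high) == pytest.approx(10.0)

    def test_linearity_and_round_trip(self):
        from scipy.constants import Avogadro

        c = nq.molar_concentration(1e6, 2000.0)
        assert nq.molar_concentration(3e6, 2000.0) == pytest.approx(3 * c)
        assert nq.molar_concentration(1e6, 4000.0) == pytest.approx(c / 2)
        n_back = c * 1e-6 * Avogadro * 2000.0 * 1e-15
        assert n_back == pytest.approx(1e6)

    def test_non_positive_rejected(self):
        with pytest.raises(ContractError):
            nq.molar_concentration(0, 1.0)
        with pytest.raises(ContractError):
            nq.molar_concentration(100.0, -1.0)


class TestIsoelectricPoint:
    def test_glycine_is_termini_midpoint(self):
        t = PKA_TABLES["emboss"]
        assert nq.isoelectric_point("G") == pytest.approx(
            (t["Nterm"] + t["Cterm"]) / 2, abs=0.01
        )

    def test_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(9)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        seq = "".join(rng.choice(list(aas), 50))
        grid = np.arange(0.0, 14.0, 1e-3)
        charges = np.array([net_charge(seq, p) for p in grid])
        oracle = grid[np.abs(charges).argmin()]
        assert nq.isoelectric_point(seq) == pytest.approx(oracle, abs=2e-3)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_monotone_in_charged_residues(self, seq):
        base = nq.isoelectric_point(seq)
        assert nq.isoelectric_point(seq + "R") >= base - 1e-6
        assert nq.isoelectric_point(seq + "D") <= base + 1e-6

    def test_unknown_residue_rejected(self):
        with pytest.raises(ContractError):
            nq.isoelectric_point("ACDX")


def regex_g4_candidates(seq, min_g=2, max_len=20, min_loop=0):
    """Independent enumeration through the regex engine, one pattern per
    (g, l1, l2, l3) combination, lookahead at every position."""
    found = set()
    for g in range(min_g, max_len // 4 + 1):
        budget = max_len - 4 * g
        for l1 in range(min_loop, budget + 1):
            for l2 in range(min_loop, budget - l1 + 1):
                for l3 in range(min_loop, budget - l1 - l2 + 1):
                    pat = re.compile(
                        f"(?=(G{{{g}}}.{{{l1}}}G{{{g}}}.{{{l2}}}"
                        f"G{{{g}}}.{{{l3}}}G{{{g}}}))"
                    )
                    for m in pat.finditer(seq):
                        found.add((m.start(), 4 * g + l1 + l2 + l3, g, (l1, l2, l3)))
    return found


class TestScanG4:
    def test_no_g_tracts_no_hits(self):
        hits, _ = nq.scan_g4("AUAUAUAUAU")
        assert hits == []

    def test_canonical_two_tract_motif(self):
        hits, _ = nq.scan_g4("GGAGGAGGAGG")
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.g_group, h.loops) == (0, 11, 2, (1, 1, 1))

    def test_pure_g_run_collapses_to_one_hit(self):
        hits, _ = nq.scan_g4("GGGGGGGG")
        assert len(hits) == 1
        assert hits[0].g_group == 2 and hits[0].total_len == 8

    def test_collapse_prefers_larger_g_group(self):
        # G3 tracts also contain G2 candidates; the retained hit must be G3
        seq = "GGGAGGGAGGGAGGG"
        hits, _ = nq.scan_g4(seq)
        assert len(hits) == 1 and hits[0].g_group == 3

    def test_retained_hits_never_overlap_and_validate(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGU"), 200, p=[0.2, 0.2, 0.4, 0.2]))
        hits, _ = nq.scan_g4(seq)
        for h in hits:
            # structural validation straight from the characters
            s = seq[h.start : h.end]
            g, (l1, l2, l3) = h.g_group, h.loops
            p = 0
            for loop in (l1, l2, l3, None):
                assert s[p : p + g] == "G" * g
                p += g + (loop if loop is not None else 0)
            assert len(s) == 4 * g + l1 + l2 + l3 <= 20
        for a, b in zip(hits, hits[1:]):
            assert a.end <= b.start

    def test_enumeration_matches_regex_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            seq = "".join(rng.choice(list("ACGT"), 120, p=[0.2, 0.2, 0.4, 0.2]))
            mine = {
                (h.start, h.total_len, h.g_group, h.loops)
                for h in enumerate_g4_candidates(seq)
            }
            assert mine == regex_g4_candidates(seq)

    def test_min_loop_excludes_zero_loops(self):
        hits, _ = nq.scan_g4("GGGGGGGG", min_loop=1)
        assert hits == []

    def test_region_counts_by_start_position(self):
        seq = "GGAGGAGGAGG" + "A" * 10 + "GGTGGTGGTGG"
        regions = [("five_prime", 0, 15), ("three_prime", 15, len(seq))]
        hits, counts = nq.scan_g4(seq, regions=regions)
        assert counts == {"five_prime": 1, "three_prime": 1}
        with pytest.raises(ContractError):
            nq.scan_g4(seq, regions=[("a", 0, 10), ("b", 5, 20)])

    def test_invalid_characters_rejected(self):
        with pytest.raises(ContractError):
            nq.scan_g4("GGXGG")
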