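"""Five-register window scanning against recognition loops."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicepairs.pairing import classify_pair, PairClass
from splicepairs.registers import (REGISTERS, composition_summary,
                                   enumerate_registers, scan_registers,
                                   window_from_flanks)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_force_wc_counts(window: str, loop) -> dict[str, int]:
    """Independent oracle: enumerate every boundary placement directly.

    For the a+b split the covered 11-mer starts at window offset 10-a
    (0-based) and meets the loop residues in descending position order;
    Watson-Crick pairs are recounted from the raw classification table.
    """
    rna = window.upper().replace("T", "U")
    loop_bases = [loop.base_at(p).code for p in sorted(loop.residues, reverse=True)]
    out = {}
    for a, b in REGISTERS:
        stretch = rna[10 - a:21 - a]
        wc = sum(classify_pair(s, l) is PairClass.WATSON_CRICK
                 for s, l in zip(stretch, loop_bases))
        out[f"{a}+{b}"] = wc
    return out


class TestEnumerateRegisters:
    def test_five_registers(self, u5):
        maps = enumerate_registers(u5)
        assert len(maps) == 5
        assert set(maps) == {"6+5", "7+4", "8+3", "9+2", "10+1"}

    def test_each_map_covers_eleven_positions(self, u5):
        for m in enumerate_registers(u5).values():
            assert len(m) == 11

    def test_8_plus_3_equals_proposed_register(self, u5):
        assert enumerate_registers(u5)["8+3"] == u5.pairing_map


class TestScanRegisters:
    def _complement_window(self, u5, register="8+3"):
        """15-nt window fully complementary to the loop under one register."""
        a = int(register.split("+")[0])
        pairing = enumerate_registers(u5)[register]
        window = ["A"] * 15
        for label, loop_pos in pairing.items():
            side, off = label.split(":")
            off = int(off)
            w = 10 + off if off < 0 else 9 + off  # 0-based window index
            window[w] = _COMPLEMENT[u5.base_at(loop_pos).code]
        return "".join(window)

    def test_complementary_window_unambiguous_wc11(self, u5):
        res = scan_registers(self._complement_window(u5), u5)
        assert res.best_registers == ["8+3"]
        assert res.unambiguous
        assert res.wc_counts["8+3"] == 11

    def test_poly_A_window_matches_oracle(self, u5):
        window = "A" * 15
        res = scan_registers(window, u5)
        assert res.wc_counts == brute_force_wc_counts(window, u5)

    def test_tie_reported_not_broken(self, u5):
        """A window with equal maxima in two registers is ambiguous."""
        rng = np.random.default_rng(5)
        nucs = "ACGU"
        for _ in range(500):
            window = "".join(rng.choice(list(nucs), 15))
            res = scan_registers(window, u5)
            if len(res.best_registers) > 1:
                assert not res.unambiguous
                return
        pytest.fail("no tied window found in 500 random draws")

    def test_wc_count_invariant_under_dna_alphabet(self, u5):
        rna = "GCAAUCUGGUACGUA"
        dna = rna.replace("U", "T").lower()
        assert scan_registers(rna, u5).wc_counts == \
            scan_registers(dna, u5).wc_counts

    def test_bad_symbol_rejected(self, u5):
        with pytest.raises(ValueError, match="unknown residue"):
            scan_registers("GCAAUCUGGUACGUX", u5)

    @given(window=st.text(alphabet="ACGT", min_size=15, max_size=15))
    @settings(derandomize=True, max_examples=300)
    def test_scan_equals_exhaustive_oracle(self, u5, window):
        res = scan_registers(window, u5)
        oracle = brute_force_wc_counts(window, u5)
        assert res.wc_counts == oracle
        assert set(res.best_registers) == {
            r for r, c in oracle.items() if c == max(oracle.values())}

    def test_max_dominates_every_register(self, u5):
        rng = np.random.default_rng(17)
        for _ in range(50):
            window = "".join(rng.choice(list("ACGU"), 15))
            counts = scan_registers(window, u5).wc_counts
            assert max(counts.values()) >= counts["8+3"]


class TestComposition:
    def test_all_wc_alignments(self, u5):
        res = scan_registers(
            TestScanRegisters()._complement_window(u5), u5)
        aln = res.alignments["8+3"]
        df = composition_summary([aln, aln])
        assert df.attrs["n_pairs"] == 22
        wc = df[df.pair_class == "watson_crick"]
        assert wc["count"].sum() == 22
        assert wc["percent"].sum() == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, u5):
        rng = np.random.default_rng(3)
        alns = []
        for _ in range(7):
            window = "".join(rng.choice(list("ACGU"), 15))
            res = scan_registers(window, u5)
            alns.append(res.alignments[res.best_registers[0]])
        df = composition_summary(alns)
        assert df["count"].sum() == 11 * 7
        assert df["percent"].sum() == pytest.approx(100.0)

    def test_five_wc_six_isosteric_percent(self, u5):
        """5 WC of 11 pairs = 45.5 %."""
        window = TestScanRegisters()._complement_window(u5)
        # break six WC pairs of the 8+3 register into isosteric U pairs
        w = list(window)
        pairing = enumerate_registers(u5)["8+3"]
        broken = 0
        for label, loop_pos in sorted(pairing.items()):
            if broken == 6:
                break
            side, off = label.split(":")
            off = int(off)
            k = 10 + off if off < 0 else 9 + off
            partner = u5.base_at(loop_pos).code
            sub = "U" if partner != "A" else "C"  # U:* or C:A is isosteric
            if classify_pair(sub, partner) is PairClass.ISOSTERIC:
                w[k] = sub
                broken += 1
        res = scan_registers("".join(w), u5)
        aln = res.alignments["8+3"]
        assert aln.wc_count == 5
        df = composition_summary([aln])
        wc_pct = df.loc[df.pair_class == "watson_crick", "percent"].sum()
        assert wc_pct == pytest.approx(100 * 5 / 11, abs=0.01)

    def test_mixed_loops_rejected(self, u5, u6):
        from splicepairs.registers import RegisterAlignment
        a = scan_registers("A" * 15, u5).alignments["8+3"]
        b = RegisterAlignment(register="8+3", observations=a.observations,
                              loop_name="other")
        with pytest.raises(ValueError, match="mixed"):
            composition_summary([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            composition_summary([])


def test_window_from_flanks():
    up, down = "A" * 12, "C" * 8
    assert window_from_flanks(up, down) == "A" * 10 + "C" * 5
    with pytest.raises(ValueError, match="upstream"):
        window_from_flanks("AAA", down)
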