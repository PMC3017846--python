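import io

import numpy as np
import pytest

from mircane.oracles import fold_oracle_energy
from mircane.structure import (FoldResult, StructureError, amfe, fold, mfei,
                               parse_ct, parse_vienna, pairing_from_dot_bracket,
                               write_vienna)


class TestFold:
    def test_perfect_gc_hairpin(self):
        f = fold("GGGGAAAACCCC")
        assert f.dot_bracket == "((((....))))"
        assert f.mfe_kcal == -12.0
        assert f.n_pairs == 4

    def test_unpairable_sequence_has_zero_energy(self):
        f = fold("AAAAAAA")
        assert f.dot_bracket == "......."
        assert f.mfe_kcal == 0.0

    def test_too_short_sequence_rejected(self):
        with pytest.raises(StructureError):
            fold("ACGU")

    def test_min_loop_respected(self):
        f = fold("GGGGAAAACCCC", min_loop=3)
        for i, j in f.pairs():
            assert j - i - 1 >= 3

    def test_energy_is_position_independent(self):
        # the same hairpin embedded after a neutral prefix keeps its energy
        inner = "GGGGAAAACCCC"
        assert fold("A" * 8 + inner).mfe_kcal == fold(inner).mfe_kcal

    @pytest.mark.parametrize("trial", range(40))
    def test_fold_matches_exhaustive_enumeration(self, trial):
        """The Nussinov DP energy equals brute-force enumeration of all
        nested structures on short random sequences."""
        rng = np.random.default_rng(9000 + trial)
        n = int(rng.integers(10, 28))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        assert fold(seq).mfe_kcal == pytest.approx(fold_oracle_energy(seq))

    def test_structure_is_self_consistent(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=80))
        f = fold(seq)
        # involution and canonical pairs only
        for i, j in f.pairs():
            assert f.pairing[j] == i
            assert frozenset((seq[i], seq[j])) in {
                frozenset("GC"), frozenset("AU"), frozenset("GU")}
        assert pairing_from_dot_bracket(f.dot_bracket) == f.pairing


class TestParsers:
    def test_vienna_parse(self):
        f = parse_vienna(io.StringIO("GGGAAACCC\n(((...))) (-7.4)\n"))
        assert f.n_pairs == 3
        assert f.mfe_kcal == -7.4
        assert f.source == "vienna_file"

    def test_vienna_energy_optional(self):
        f = parse_vienna(io.StringIO(">s\nGGGAAACCC\n(((...)))\n"))
        assert f.mfe_kcal is None

    def test_vienna_roundtrip(self):
        f = fold("GGGGAAAACCCCAAGGCC")
        buf = io.StringIO()
        write_vienna(f, buf, names=["x"])
        again = parse_vienna(io.StringIO(buf.getvalue()))
        assert again.dot_bracket == f.dot_bracket
        assert again.mfe_kcal == pytest.approx(f.mfe_kcal)

    def test_pseudoknot_brackets_rejected(self):
        with pytest.raises(StructureError, match="not supported"):
            parse_vienna(io.StringIO("GGGAAACCC\n[[[...]]]\n"))

    def test_unbalanced_brackets_rejected(self):
        with pytest.raises(StructureError, match="unbalanced"):
            parse_vienna(io.StringIO("GGGAAACCC\n(((...((.\n"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructureError, match="length"):
            parse_vienna(io.StringIO("GGGAAACCC\n(((...))\n"))

    def test_ct_parse(self):
        rows = ["9 dG = -7.4 molecule"]
        seq = "GGGAAACCC"
        partner = [9, 8, 7, 0, 0, 0, 3, 2, 1]
        for i, (base, p) in enumerate(zip(seq, partner), start=1):
            rows.append(f"{i} {base} {i - 1} {i + 1} {p} {i}")
        f = parse_ct(io.StringIO("\n".join(rows)))
        assert f.residues == seq
        assert f.n_pairs == 3
        assert f.mfe_kcal == -7.4

    def test_ct_partner_asymmetry_rejected(self):
        rows = ["2 test", "1 G 0 2 2 1", "2 C 1 3 0 2"]
        with pytest.raises(StructureError, match="pair"):
            parse_ct(io.StringIO("\n".join(rows)))


class TestEnergyIndices:
    def test_amfe_and_mfei_formulas(self):
        assert amfe(-47.0, 100) == pytest.approx(47.0)
        assert mfei(-47.0, 100, 50.0) == pytest.approx(0.94)
        assert mfei(-30.0, 100, 30.0) == pytest.approx(1.0)

    def test_zero_energy_boundary(self):
        assert amfe(0.0, 100) == 0.0
        assert mfei(0.0, 100, 50.0) == 0.0

    def test_zero_gc_rejected(self):
        with pytest.raises(ValueError):
            mfei(-10.0, 100, 0.0)
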