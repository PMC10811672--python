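import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from funcfix import fixtures
from funcfix.design_space import (
    ConservationProfile,
    ResidueSelection,
    build_mask,
    conservation_scores,
    emit_fixed_positions,
    ligand_shell,
    mask_report,
    top_conserved,
)
from funcfix.structio import Msa


class TestLigandShell:
    def test_hand_computed_toy(self, toy_structure):
        # residue 1 at 5.0 A, residue 2's own atom at 9.0 A (min 8.16 A)
        sel = ligand_shell(toy_structure.structure, "LIG", cutoff=7.0)
        assert sorted(sel.positions) == [("A", 1)]
        assert sel.label == "shell"

    def test_matches_generator_truth_at_many_cutoffs(self, toy_30res):
        for cutoff in (1e-9, 3.0, 6.0, 7.0, 10.0, 50.0):
            got = ligand_shell(toy_30res.structure, "LIG", cutoff=cutoff)
            assert got.positions == toy_30res.true_shell(cutoff).positions

    def test_tiny_cutoff_empty(self, toy_structure):
        assert len(ligand_shell(toy_structure.structure, "LIG", cutoff=1e-9)) == 0

    def test_monotone_in_cutoff(self, toy_30res):
        st_ = toy_30res.structure
        prev: frozenset = frozenset()
        for cutoff in (2.0, 4.0, 6.0, 8.0, 12.0, 20.0):
            cur = ligand_shell(st_, "LIG", cutoff=cutoff).positions
            assert prev <= cur
            prev = cur

    def test_unknown_ligand_names_alternatives(self, toy_structure):
        with pytest.raises(KeyError, match="LIG"):
            ligand_shell(toy_structure.structure, "HEM", cutoff=7.0)

    def test_bad_cutoff(self, toy_structure):
        with pytest.raises(ValueError):
            ligand_shell(toy_structure.structure, "LIG", cutoff=0.0)

    def test_peptide_chain_as_ligand_excludes_itself(self):
        # two-chain structure: chain B acts as the substrate
        from funcfix.structio import Atom, Chain, Residue, Structure

        def res(cid, i, x):
            return Residue(chain_id=cid, auth_seq_id=i, res_name="ALA", seq_index=i,
                           atoms=[Atom(name="CA", element="C", coords=[x, 0, 0])])

        st_ = Structure(id="2c", chains=[
            Chain(id="A", residues=[res("A", 1, 0.0), res("A", 2, 4.0), res("A", 3, 30.0)]),
            Chain(id="B", residues=[res("B", 1, 6.0)]),
        ])
        sel = ligand_shell(st_, "B", cutoff=7.0)
        assert sorted(sel.positions) == [("A", 1), ("A", 2)]


class TestConservation:
    def test_identical_sequences_score_one(self):
        msa = Msa(rows=["ACDEF"] * 5, ids=[str(i) for i in range(5)])
        prof = conservation_scores(msa)
        np.testing.assert_array_equal(prof.scores, np.ones(5))

    def test_toy_counts(self):
        # column 2: parent C matched by 3/4 rows; gaps count in denominator
        msa = Msa(rows=["ACD", "ACD", "AC-", "AW-"], ids=list("abcd"))
        prof = conservation_scores(msa)
        np.testing.assert_allclose(prof.scores, [1.0, 0.75, 0.5])

    def test_parent_only_lower_bound(self):
        msa = Msa(rows=["A", "W", "Y", "C"], ids=list("abcd"))
        assert conservation_scores(msa).scores[0] == pytest.approx(0.25)

    def test_parent_gap_columns_skipped(self):
        msa = Msa(rows=["A-C", "AWC"], ids=["p", "h"])
        assert len(conservation_scores(msa)) == 2

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            conservation_scores(Msa(rows=["ACD"], ids=["p"]))

    def test_generator_round_trip_exact(self):
        targets = [1.0, 0.75, 0.5, 0.25, 1.0, 0.5]
        msa, truth = fixtures.make_toy_msa("MKTAYI", 4, targets, seed=3)
        prof = conservation_scores(msa)
        np.testing.assert_array_equal(prof.scores, truth)
        np.testing.assert_array_equal(prof.scores, targets)


class TestTopConserved:
    def profile(self, scores):
        return ConservationProfile(scores=np.asarray(scores, float), n_effective=10)

    def test_extremes(self):
        prof = self.profile([0.9, 0.5, 0.7])
        assert len(top_conserved(prof, 0, "A")) == 0
        assert len(top_conserved(prof, 100, "A")) == 3

    def test_explicit_sort(self):
        scores = [0.1, 0.95, 0.3, 0.8, 0.55, 0.2, 0.9, 0.4, 0.6, 0.05]
        sel = top_conserved(self.profile(scores), 30, "A")
        assert sorted(i for _, i in sel.positions) == [2, 4, 7]  # top-3 scores

    def test_ceiling_rounding(self):
        # 30% of 10 -> 3; 25% of 10 -> ceil(2.5) = 3
        prof = self.profile(np.linspace(1, 0.1, 10))
        assert len(top_conserved(prof, 25, "A")) == 3

    def test_tie_break_ascending_index(self):
        sel = top_conserved(self.profile([0.5, 0.5, 0.5, 0.5]), 50, "A")
        assert sorted(i for _, i in sel.positions) == [1, 2]

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.integers(min_value=0, max_value=100), st.integers(min_value=0, max_value=100))
    def test_nesting_property(self, scores, p1, p2):
        lo, hi = sorted((p1, p2))
        prof = self.profile(scores)
        assert top_conserved(prof, lo, "A").positions <= top_conserved(prof, hi, "A").positions

    def test_paper_style_30_50_70_nested(self):
        rng = np.random.default_rng(42)
        prof = self.profile(rng.random(200))
        s30 = top_conserved(prof, 30, "A").positions
        s50 = top_conserved(prof, 50, "A").positions
        s70 = top_conserved(prof, 70, "A").positions
        assert s30 < s50 < s70
        assert len(s30) == 60 and len(s50) == 100 and len(s70) == 140


class TestBuildMask:
    def test_union_with_empty_is_identity(self, toy_structure):
        st_ = toy_structure.structure
        shell = ResidueSelection(positions=frozenset({("A", 3), ("A", 5)}), label="shell")
        empty = ResidueSelection(positions=frozenset(), label="manual")
        m1 = build_mask(st_, [shell, empty], ("A",))
        m2 = build_mask(st_, [shell], ("A",))
        assert m1.fixed == m2.fixed and m1.free == m2.free

    def test_union_merges_provenance(self, toy_structure):
        st_ = toy_structure.structure
        shell = ResidueSelection(positions=frozenset({("A", 3), ("A", 5), ("A", 9)}), label="shell")
        cons = ResidueSelection(positions=frozenset({("A", 5), ("A", 2)}), label="conserved")
        mask = build_mask(st_, [shell, cons], ("A",))
        assert {i for _, i in mask.fixed} == {2, 3, 5, 9}
        assert set(mask.sources[("A", 5)]) == {"shell", "conserved"}

    def test_partition_invariant(self, toy_structure):
        st_ = toy_structure.structure
        sel = ResidueSelection(positions=frozenset({("A", 1), ("A", 10)}), label="manual")
        mask = build_mask(st_, [sel], ("A",))
        assert mask.fixed | mask.free == {("A", i) for i in range(1, 11)}
        assert not (mask.fixed & mask.free)

    def test_selection_outside_design_chains_rejected(self, toy_structure):
        sel = ResidueSelection(positions=frozenset({("B", 1)}), label="manual")
        with pytest.raises((ValueError, KeyError)):
            build_mask(toy_structure.structure, [sel], ("A",))

    def test_active_site_only_mask(self, toy_structure):
        # no conservation: fixed set is exactly the shell
        shell = ligand_shell(toy_structure.structure, "LIG", cutoff=7.0)
        mask = build_mask(toy_structure.structure, [shell], ("A",))
        assert mask.fixed == shell.positions


class TestEmission:
    def test_empty_mask(self, toy_structure):
        mask = build_mask(toy_structure.structure, [], ("A",))
        assert json.loads(emit_fixed_positions(mask, "name")) == {"name": {"A": []}}

    def test_two_positions(self, toy_structure):
        sel = ResidueSelection(positions=frozenset({("A", 5), ("A", 2)}), label="manual")
        mask = build_mask(toy_structure.structure, [sel], ("A",))
        assert json.loads(emit_fixed_positions(mask, "d")) == {"d": {"A": [2, 5]}}

    def test_two_chain_emission(self):
        from funcfix.structio import Atom, Chain, Residue, Structure

        def chain(cid, n):
            return Chain(id=cid, residues=[
                Residue(chain_id=cid, auth_seq_id=i, res_name="ALA", seq_index=i,
                        atoms=[Atom(name="CA", element="C", coords=[float(i), 0, 0])])
                for i in range(1, n + 1)
            ])

        st_ = Structure(id="t", chains=[chain("A", 3), chain("B", 8)])
        sel = ResidueSelection(positions=frozenset({("A", 1), ("B", 4), ("B", 7)}), label="manual")
        mask = build_mask(st_, [sel], ("A", "B"))
        assert json.loads(emit_fixed_positions(mask, "d")) == {"d": {"A": [1], "B": [4, 7]}}

    def test_byte_identical_across_reconstruction(self, toy_structure):
        st_ = toy_structure.structure
        sel1 = ResidueSelection(positions=frozenset({("A", 4), ("A", 8), ("A", 2)}), label="shell")
        sel2 = ResidueSelection(positions=frozenset({("A", 8), ("A", 2), ("A", 4)}), label="shell")
        assert (emit_fixed_positions(build_mask(st_, [sel1], ("A",)), "x")
                == emit_fixed_positions(build_mask(st_, [sel2], ("A",)), "x"))


class TestMaskReport:
    def test_fully_free(self, toy_structure):
        mask = build_mask(toy_structure.structure, [], ("A",))
        df = mask_report(mask, toy_structure.structure)
        assert df.attrs["n_fixed"] == 0 and df.attrs["fraction_fixed"] == 0.0
        assert (df["status"] == "free").all()

    def test_fraction_and_provenance(self, toy_structure):
        sel = ResidueSelection(positions=frozenset({("A", i) for i in (1, 3, 5, 7)}),
                               label="shell")
        mask = build_mask(toy_structure.structure, [sel], ("A",))
        df = mask_report(mask, toy_structure.structure)
        assert df.attrs["fraction_fixed"] == pytest.approx(0.4)
        fixed_rows = df[df["status"] == "fixed"]
        assert set(fixed_rows["seq_index"]) == {1, 3, 5, 7}
        assert (fixed_rows["provenance"] == "shell").all()
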