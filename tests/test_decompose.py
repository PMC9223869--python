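import numpy as np
import pytest

from hatslens import (
    FragmentPartition,
    Molecule,
    fragment_decompose,
    hats_profile,
    mim_from_molecule,
    substructure_cut,
    weighting_sensitivity,
)
from hatslens import fixtures as fx

from conftest import random_molecule


def random_partition(rng, n_atoms, labels=("core", "R1", "R2")):
    return FragmentPartition(
        {i: str(rng.choice(labels)) for i in range(1, n_atoms + 1)}
    )


class TestFragmentDecompose:
    def test_single_fragment_collects_total(self, chlorobenzene):
        part = FragmentPartition({i: "core" for i in range(1, 13)})
        (res,) = hats_profile(chlorobenzene, schemes=("m",), lags=(5,))
        dec = fragment_decompose(res, 5, part)
        assert set(dec.matrix) == {("core", "core")}
        assert dec.matrix[("core", "core")] == pytest.approx(dec.total)

    def test_two_atom_molecule_all_interfragment(self):
        mol = Molecule(
            ("C", "O"), np.array([[0.0, 0, 0], [1.4, 0, 0]]), bonds={(1, 2)}, name="CO"
        )
        part = FragmentPartition({1: "a", 2: "b"})
        (res,) = hats_profile(mol, schemes=("m",), lags=(1,))
        dec = fragment_decompose(res, 1, part)
        assert dec.cell("a", "b") == pytest.approx(res.values[1])
        assert dec.intra("a") == 0.0 and dec.intra("b") == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_rebinning(self, seed):
        rng = np.random.default_rng(300 + seed)
        mol = random_molecule(rng, max_atoms=15)
        part = random_partition(rng, mol.n_atoms)
        for lag in (0, 2, 5):
            (res,) = hats_profile(mol, schemes=("m",), lags=(lag,))
            dec = fragment_decompose(res, lag, part)
            # independent double loop over the raw pair list
            expected: dict[tuple[str, str], float] = {}
            for p in res.pairs[lag]:
                key = tuple(sorted((part.label_of(p.i), part.label_of(p.j))))
                expected[key] = expected.get(key, 0.0) + p.value
            assert set(dec.matrix) == set(expected)
            for cell, v in expected.items():
                assert dec.matrix[cell] == pytest.approx(v, rel=1e-12, abs=1e-18)

    def test_cells_sum_exactly_to_descriptor(self):
        rng = np.random.default_rng(17)
        mol = random_molecule(rng)
        part = random_partition(rng, mol.n_atoms)
        for res in hats_profile(mol, schemes=("m", "v")):
            for lag in res.values:
                dec = fragment_decompose(res, lag, part)
                assert sum(dec.matrix.values()) == pytest.approx(
                    dec.total, rel=1e-12, abs=1e-15
                )

    def test_hats0_self_terms_go_intra(self, methane):
        part = FragmentPartition({1: "c", 2: "h", 3: "h", 4: "h", 5: "h"})
        (res,) = hats_profile(methane, schemes=("m",), lags=(0,))
        dec = fragment_decompose(res, 0, part)
        assert dec.cell("c", "h") == 0.0
        assert dec.intra("h") == pytest.approx(res.values[0])  # carbon leverage is 0

    def test_invariant_under_label_renaming(self):
        rng = np.random.default_rng(23)
        mol = random_molecule(rng)
        part = random_partition(rng, mol.n_atoms)
        rename = {"core": "PHI", "R1": "X1", "R2": "X2"}
        part2 = FragmentPartition(
            {i: rename[l] for i, l in part.assignment.items()}
        )
        (res,) = hats_profile(mol, schemes=("m",), lags=(3,))
        d1 = fragment_decompose(res, 3, part)
        d2 = fragment_decompose(res, 3, part2)
        for (a, b), v in d1.matrix.items():
            key = tuple(sorted((rename[a], rename[b])))
            assert d2.matrix[key] == pytest.approx(v)

    def test_merging_fragments_aggregates_cells(self):
        rng = np.random.default_rng(29)
        mol = random_molecule(rng)
        fine = random_partition(rng, mol.n_atoms, labels=("a", "b", "c", "d"))
        coarse_map = {"a": "ab", "b": "ab", "c": "cd", "d": "cd"}
        coarse = FragmentPartition(
            {i: coarse_map[l] for i, l in fine.assignment.items()}
        )
        (res,) = hats_profile(mol, schemes=("m",), lags=(2,))
        df = fragment_decompose(res, 2, fine)
        dc = fragment_decompose(res, 2, coarse)
        for (a, b) in {("ab", "ab"), ("ab", "cd"), ("cd", "cd")}:
            expected = sum(
                v
                for (x, y), v in df.matrix.items()
                if tuple(sorted((coarse_map[x], coarse_map[y]))) == (a, b)
            )
            assert dc.matrix.get((a, b), 0.0) == pytest.approx(expected, abs=1e-15)

    def test_fragment_without_lag_pairs_contributes_nothing(self, icosane):
        # hydrogens on carbon 10 vs the rest: pick a fragment whose atoms have
        # no lag-5 partners inside it and check its intra cell is absent/zero
        part = FragmentPartition(
            {
                i: ("tip" if i in (1, 21) else "rest")
                for i in range(1, icosane.n_atoms + 1)
            }
        )
        (res,) = hats_profile(icosane, schemes=("m",), lags=(5,))
        dec = fragment_decompose(res, 5, part)
        # atoms 1 (C1) and 21+ (an H on C1) are 2 bonds apart at most
        assert dec.intra("tip") == 0.0


class TestSubstructureCut:
    def test_keep_all_is_identity(self, chlorobenzene):
        cut, index_map = substructure_cut(chlorobenzene, range(1, 13))
        assert cut.symbols == chlorobenzene.symbols
        assert cut.bonds == chlorobenzene.bonds
        assert np.array_equal(cut.coords, chlorobenzene.coords)
        assert index_map == {i: i for i in range(1, 13)}

    def test_icosane_cut_mean_leverage_ratio(self, icosane):
        keep_c = set(range(1, 13))
        keep_h = {
            j for i, j in icosane.bonds if i in keep_c and icosane.symbols[j - 1] == "H"
        }
        cut, _ = substructure_cut(icosane, keep_c | keep_h)
        # C12 keeps exactly the 25 hydrogens it carried in the parent
        # (3 on the terminal C1, 2 on each of C2..C12; no capping)
        assert cut.n_atoms == 37
        assert mim_from_molecule(cut).mean_leverage == pytest.approx(3.0 / 37.0)
        assert mim_from_molecule(icosane).mean_leverage == pytest.approx(3.0 / 62.0)

    def test_cut_recomputes_rather_than_slices(self, icosane):
        keep_c = set(range(1, 13))
        keep_h = {
            j for i, j in icosane.bonds if i in keep_c and icosane.symbols[j - 1] == "H"
        }
        cut, index_map = substructure_cut(icosane, keep_c | keep_h)
        parent_h = mim_from_molecule(icosane).leverages
        child_h = mim_from_molecule(cut).leverages
        old_of_new = {new: old for old, new in index_map.items()}
        # leverages of surviving atoms change: they are global geometry scores
        diffs = [
            abs(child_h[new - 1] - parent_h[old_of_new[new] - 1])
            for new in range(1, cut.n_atoms + 1)
        ]
        assert max(diffs) > 1e-3

    def test_cutting_halogen_with_lag5_partners_lowers_value(self):
        probe = fx.make_halide_probe("Br")
        (before,) = hats_profile(probe, schemes=("m",), lags=(5,))
        assert any(7 in (p.i, p.j) for p in before.pairs[5])  # Br is atom 7
        cut, _ = substructure_cut(probe, set(range(1, probe.n_atoms + 1)) - {7})
        (after,) = hats_profile(cut, schemes=("m",), lags=(5,))
        assert after.values[5] < before.values[5]

    def test_empty_keep_rejected(self, methane):
        with pytest.raises(ValueError, match="empty"):
            substructure_cut(methane, set())

    def test_out_of_range_keep_rejected(self, methane):
        with pytest.raises(ValueError, match="outside"):
            substructure_cut(methane, {1, 99})


class TestWeightingSensitivity:
    def test_all_carbon_u_equals_m(self, c60):
        part = FragmentPartition(
            {i: ("north" if i <= 30 else "south") for i in range(1, 61)}
        )
        table = weighting_sensitivity(c60, part, 5, schemes=("u", "m"))
        assert np.allclose(table.loc["u"], table.loc["m"])

    def test_bromine_cells_exceed_unweighted(self):
        probe = fx.make_halide_probe("Br")
        part = FragmentPartition(
            {i: ("X" if i == 7 else "ring") for i in range(1, probe.n_atoms + 1)}
        )
        table = weighting_sensitivity(probe, part, 5, schemes=("u", "m"))
        br_cell = "X~ring"
        assert table.loc["m", br_cell] > table.loc["u", br_cell]

    def test_rows_sum_to_descriptor_totals(self, chlorobenzene):
        part = FragmentPartition(
            {i: ("ring" if i <= 6 else "sub") for i in range(1, 13)}
        )
        table = weighting_sensitivity(chlorobenzene, part, 5)
        results = hats_profile(chlorobenzene, schemes=tuple(table.index), lags=(5,))
        for res in results:
            row = table.loc[res.scheme]
            assert row["total"] == pytest.approx(res.values[5])
            assert row.drop("total").sum() == pytest.approx(res.values[5], rel=1e-12)
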