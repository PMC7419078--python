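"""Contact featurization: selections, the 8 Å rule, padding and the split."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ugtshape.contacts import (
    INTERFACE_SELECTIONS,
    ContactMatrix,
    ResidueSelection,
    build_dataset,
    contact_matrix,
    ensemble_contact_matrices,
    load_dataset,
    pad_matrix,
    parse_selection,
    save_dataset,
    split_indices,
)
from ugtshape.errors import EmptyInputError, ParseError
from ugtshape.synthetic import EnsembleSpec, StateSpec, generate_ensemble, helix_anchors


class TestParseSelection:
    # expanding the printed interface lists gives 21/22/22/22/21 residues
    @pytest.mark.parametrize("variant,expected", [
        ("76E1", 21), ("76E2", 22), ("76E4", 22), ("76E5", 22), ("76D1", 21),
    ])
    def test_interface_selection_sizes(self, variant, expected):
        assert len(parse_selection(INTERFACE_SELECTIONS[variant])) == expected

    def test_singleton(self):
        assert parse_selection("17").residue_ids == (17,)

    def test_en_dash_accepted(self):
        assert parse_selection("14–15").residue_ids == (14, 15)

    def test_reversed_range_rejected(self):
        with pytest.raises(ParseError, match="20-18"):
            parse_selection("20-18")

    @pytest.mark.parametrize("text", ["", "  ", "a-b", "3-"])
    def test_bad_tokens_rejected(self, text):
        with pytest.raises(ParseError):
            parse_selection(text)

    def test_duplicates_collapse_and_sort(self):
        assert parse_selection("5, 3, 4-5").residue_ids == (3, 4, 5)


class TestContactMatrix:
    def test_three_residue_example(self):
        # distances: d12 = 5 ≤ 8; d13 = 12 > 8; d23 = 7 ≤ 8
        coords = np.array([[0, 0, 0], [0, 0, 5], [0, 0, 12.0]])
        cm = contact_matrix(coords, [1, 2, 3], ResidueSelection((1, 2, 3)))
        np.testing.assert_array_equal(
            cm.matrix, [[1, 1, 0], [1, 1, 1], [0, 1, 1]]
        )

    def test_single_residue(self):
        cm = contact_matrix(np.zeros((1, 3)), [1], ResidueSelection((1,)))
        np.testing.assert_array_equal(cm.matrix, [[1]])

    def test_cutoff_is_inclusive_at_exactly_8(self):
        coords = np.array([[0, 0, 0], [0, 0, 8.0]])
        cm = contact_matrix(coords, [1, 2], ResidueSelection((1, 2)))
        assert cm.matrix[0, 1] == 1

    def test_missing_residue_named(self):
        with pytest.raises(KeyError, match="9"):
            contact_matrix(np.zeros((2, 3)), [1, 2], ResidueSelection((1, 9)))

    def test_agrees_with_brute_force_on_random_frames(self):
        # oracle: explicit double loop over all residue pairs
        rng = np.random.default_rng(0)
        sel = ResidueSelection(tuple(range(1, 13)))
        for _ in range(120):
            coords = rng.uniform(-10, 10, size=(12, 3))
            cm = contact_matrix(coords, range(1, 13), sel).matrix
            for i in range(12):
                for j in range(12):
                    d = np.linalg.norm(coords[i] - coords[j])
                    assert cm[i, j] == (1 if d <= 8.0 else 0)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(1)
        sel = ResidueSelection(tuple(range(1, 16)))
        for _ in range(25):
            coords = rng.uniform(-12, 12, size=(15, 3))
            rot = Rotation.random(rng=rng).as_matrix()
            moved = coords @ rot.T + rng.uniform(-50, 50, size=3)
            a = contact_matrix(coords, range(1, 16), sel).matrix
            b = contact_matrix(moved, range(1, 16), sel).matrix
            np.testing.assert_array_equal(a, b)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-10, 10, size=(9, 3))
        cm = contact_matrix(coords, range(1, 10), ResidueSelection(tuple(range(1, 10))))
        np.testing.assert_array_equal(cm.matrix, cm.matrix.T)
        assert (np.diag(cm.matrix) == 1).all()


class TestPadMatrix:
    def _matrix(self, size):
        return ContactMatrix(np.eye(size, dtype=np.uint8), ("v", "s", 0), size)

    def test_pad_21_to_22_adds_trailing_zeros(self):
        padded = pad_matrix(self._matrix(21), 22)
        assert padded.size == 22
        assert padded.padded_from == 21
        assert padded.matrix[21, :].sum() == 0
        assert padded.matrix[:, 21].sum() == 0

    def test_pad_is_noop_at_target(self):
        m = self._matrix(22)
        assert pad_matrix(m, 22) is m

    def test_crop_recovers_original(self):
        m = self._matrix(21)
        padded = pad_matrix(m, 25)
        np.testing.assert_array_equal(
            padded.matrix[:padded.padded_from, :padded.padded_from], m.matrix
        )

    def test_shrinking_rejected(self):
        with pytest.raises(ValueError):
            pad_matrix(self._matrix(22), 21)


def _toy_ensemble(n_frames, n_res, seed, variant="v", substrate="s"):
    spec = EnsembleSpec(
        n_frames=n_frames,
        states=(StateSpec("s", helix_anchors(n_res), 1.0),),
        noise_sigma=0.3, seed=seed,
        variant_label=variant, substrate_label=substrate,
    )
    return generate_ensemble(spec)


class TestBuildDataset:
    def test_mixed_sizes_pad_to_common_max(self):
        # mirrors the 21/22-residue interface mix padded to 22×22
        sizes = [21, 22, 22, 22, 21]
        pairs = [
            (_toy_ensemble(4, s, seed=k, variant=f"v{k}"),
             ResidueSelection(tuple(range(1, s + 1))))
            for k, s in enumerate(sizes)
        ]
        ds = build_dataset(pairs, seed=0)
        assert ds.size == 22
        assert ds.n == 20

    def test_split_is_80_20(self):
        ens = _toy_ensemble(100, 8, seed=5)
        ds = build_dataset([(ens, ResidueSelection(tuple(range(1, 9))))], seed=1)
        assert ds.train_indices.size == 80
        assert ds.val_indices.size == 20

    @pytest.mark.parametrize("n,ratio,expected", [(10, 0.8, 8), (7, 0.8, 6),
                                                  (99, 0.8, 79), (5, 0.5, 3)])
    def test_train_size_is_rounded_share(self, n, ratio, expected):
        train, val = split_indices(n, ratio, seed=0)
        assert train.size == expected
        assert train.size + val.size == n

    def test_split_partitions_for_any_n(self):
        for n in (1, 2, 13, 57):
            train, val = split_indices(n, 0.8, seed=3)
            assert sorted(np.concatenate([train, val]).tolist()) == list(range(n))
            assert np.intersect1d(train, val).size == 0

    def test_same_seed_same_split(self):
        ens = _toy_ensemble(50, 6, seed=2)
        sel = ResidueSelection(tuple(range(1, 7)))
        d1 = build_dataset([(ens, sel)], seed=9)
        d2 = build_dataset([(ens, sel)], seed=9)
        np.testing.assert_array_equal(d1.train_indices, d2.train_indices)

    def test_label_multiset_preserved(self):
        pairs = [
            (_toy_ensemble(5, 6, seed=1, variant="a", substrate="x"),
             ResidueSelection(tuple(range(1, 7)))),
            (_toy_ensemble(7, 6, seed=2, variant="b", substrate="y"),
             ResidueSelection(tuple(range(1, 7)))),
        ]
        ds = build_dataset(pairs, seed=0)
        from collections import Counter

        counts = Counter((v, s) for v, s, _ in ds.labels)
        assert counts == {("a", "x"): 5, ("b", "y"): 7}

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            build_dataset([], seed=0)

    def test_serialization_round_trip(self, tmp_path):
        ens = _toy_ensemble(6, 5, seed=8)
        ds = build_dataset([(ens, ResidueSelection(tuple(range(1, 6))))], seed=4)
        path = tmp_path / "ds.npz"
        save_dataset(ds, path)
        back = load_dataset(path)
        np.testing.assert_array_equal(back.matrices, ds.matrices)
        assert back.labels == ds.labels
        np.testing.assert_array_equal(back.train_indices, ds.train_indices)
        assert back.split_seed == ds.split_seed
        assert back.cutoff == ds.cutoff


class TestEnsembleFeaturization:
    def test_matches_per_frame_contact_matrix(self):
        ens = _toy_ensemble(10, 9, seed=6)
        sel = ResidueSelection(tuple(range(1, 10)))
        batch = ensemble_contact_matrices(ens, sel)
        for f, cm in enumerate(batch):
            single = contact_matrix(ens.coords[f], ens.residue_ids, sel)
            np.testing.assert_array_equal(cm.matrix, single.matrix)
            assert cm.labels == (ens.variant_label, ens.substrate_label, f)
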