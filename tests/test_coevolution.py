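"""MSA filtering, MI+APC scoring, below-average nulling and reporting."""

import numpy as np
import pytest

from ugtshape.coevolution import (
    CoevolutionMatrix,
    Msa,
    apply_significance,
    filter_msa,
    mutual_information,
    position_report,
    read_fasta_msa,
    read_score_tsv,
    score_coevolution,
    write_score_tsv,
)
from ugtshape.errors import EmptyInputError
from ugtshape.synthetic import MsaSpec, generate_msa, write_msa_fasta


def _msa(rows, reference_index=0):
    return Msa(ids=[f"s{k}" for k in range(len(rows))], sequences=list(rows),
               reference_index=reference_index)


class TestFilterMsa:
    def test_low_coverage_row_dropped(self):
        # sparse row covers 6/10 = 60% of reference columns < 75%
        reference = "ACDEFGHIKL"
        sparse = "ACD----IKL"
        msa = _msa([reference, "ACDEFGHIK-", sparse])
        kept = filter_msa(msa, min_coverage=0.75, max_identity=1.1)
        assert sparse not in kept.sequences
        assert reference in kept.sequences

    def test_exact_duplicate_of_reference_dropped(self):
        reference = "ACDEFGHIKL"
        msa = _msa([reference, reference])
        kept = filter_msa(msa)
        assert kept.sequences == [reference]

    def test_hand_enumerated_greedy_pass(self):
        # coverage over 8 reference columns; identity greedy in input order:
        # r0 reference kept; r1 cov 8/8 id 7/8=0.875 <= 0.9 kept;
        # r2 identical to r1 (id 1.0) dropped; r3 cov 6/8=0.75 kept,
        # id to r0 = 6/6... construct so it's below cap; r4 cov 5/8 dropped.
        r0 = "ACDEFGHI"
        r1 = "ACDEFGHW"
        r2 = "ACDEFGHW"
        r3 = "PW-QRS-T"
        r4 = "AC---GHI"
        kept = filter_msa(_msa([r0, r1, r2, r3, r4]),
                          min_coverage=0.75, max_identity=0.90)
        assert kept.sequences == [r0, r1, r3]

    def test_reference_always_retained(self):
        reference = "A-A-A-A-"  # would fail its own coverage filter
        other = "ACACACAC"
        kept = filter_msa(_msa([reference, other]), min_coverage=0.75)
        assert reference in kept.sequences
        assert kept.reference == reference

    def test_subset_and_idempotent(self):
        spec = MsaSpec(n_sequences=50, length=12, gap_fraction=0.2, seed=6)
        msa = generate_msa(spec)
        once = filter_msa(msa)
        twice = filter_msa(once)
        assert set(once.sequences) <= set(msa.sequences)
        assert twice.sequences == once.sequences


class TestScoreCoevolution:
    def test_all_identical_columns_score_zero(self):
        msa = _msa(["AAAA", "AAAA", "AAAA"])
        matrix = score_coevolution(msa)
        np.testing.assert_allclose(matrix.raw, 0.0, atol=1e-12)

    def test_perfectly_coupled_pair_attains_maximum(self):
        spec = MsaSpec(n_sequences=2000, length=10,
                       covarying_pairs=((2, 6, 1.0),), seed=9)
        matrix = score_coevolution(generate_msa(spec))
        iu = np.triu_indices(10, k=1)
        best = np.unravel_index(np.argmax(matrix.raw[iu]), (len(iu[0]),))
        i, j = iu[0][best[0]], iu[1][best[0]]
        assert {i, j} == {2, 6}

    def test_independent_columns_near_zero_after_apc(self):
        spec = MsaSpec(n_sequences=5000, length=8, seed=10)
        matrix = score_coevolution(generate_msa(spec))
        assert np.abs(matrix.raw).max() < 0.05

    def test_symmetry_and_zero_diagonal(self):
        spec = MsaSpec(n_sequences=300, length=7,
                       covarying_pairs=((0, 3, 0.7),), seed=11)
        matrix = score_coevolution(generate_msa(spec))
        np.testing.assert_allclose(matrix.raw, matrix.raw.T)
        np.testing.assert_array_equal(np.diag(matrix.raw), 0.0)

    def test_mi_nonnegative_and_symmetric(self):
        spec = MsaSpec(n_sequences=200, length=6, gap_fraction=0.1, seed=12)
        mi = mutual_information(generate_msa(spec))
        assert (mi >= -1e-12).all()
        np.testing.assert_allclose(mi, mi.T)

    def test_single_sequence_rejected(self):
        with pytest.raises(EmptyInputError):
            score_coevolution(_msa(["ACDE"]))


class TestApplySignificance:
    def test_uniform_matrix_nulls_nothing(self):
        raw = np.full((5, 5), 0.3)
        np.fill_diagonal(raw, 0.0)
        raw[:] = 0.3 - np.diag([0.3] * 5)  # constant off-diagonal
        with pytest.warns(UserWarning, match="zero variance"):
            matrix = apply_significance(CoevolutionMatrix(raw=raw))
        off_diag = ~np.eye(5, dtype=bool)
        assert not matrix.null_mask[off_diag].any()

    def test_background_nulled_strong_pair_kept(self):
        rng = np.random.default_rng(13)
        noise = rng.normal(0, 0.01, size=(6, 6))
        raw = (noise + noise.T) / 2
        raw[1, 4] = raw[4, 1] = 1.0
        np.fill_diagonal(raw, 0.0)
        matrix = apply_significance(CoevolutionMatrix(raw=raw))
        assert not matrix.null_mask[1, 4]
        assert matrix.null_mask[0, 2]

    def test_mean_excludes_diagonal(self):
        rng = np.random.default_rng(14)
        sym = rng.normal(size=(7, 7))
        raw = (sym + sym.T) / 2
        np.fill_diagonal(raw, 0.0)
        matrix = apply_significance(CoevolutionMatrix(raw=raw))
        iu = np.triu_indices(7, k=1)
        assert matrix.mean_score == pytest.approx(raw[iu].mean())

    def test_null_mask_matches_definition(self):
        rng = np.random.default_rng(15)
        sym = rng.normal(size=(6, 6))
        raw = (sym + sym.T) / 2
        np.fill_diagonal(raw, 0.0)
        matrix = apply_significance(CoevolutionMatrix(raw=raw))
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert matrix.null_mask[i, j] == (raw[i, j] < matrix.mean_score)


@pytest.fixture(scope="module")
def planted():
    """Planted couplings echoing the G347↔C352 / G347↔C364 query: column 4
    couples to column 7, column 2 to column 9 (0-based)."""
    spec = MsaSpec(n_sequences=1500, length=12,
                   covarying_pairs=((4, 7, 0.9), (2, 9, 0.9)), seed=16)
    return apply_significance(score_coevolution(generate_msa(spec)))


class TestPositionReport:
    def test_planted_partner_ranks_first(self, planted):
        report = position_report(planted, 5)  # 1-based position of column 4
        assert report
        assert report[0][0] == 8  # 1-based partner = column 7

    def test_all_planted_pairs_survive_nulling(self, planted):
        assert not planted.null_mask[4, 7]
        assert not planted.null_mask[2, 9]

    def test_planted_pairs_rank_top_k_in_raw(self, planted):
        iu = np.triu_indices(12, k=1)
        order = np.argsort(planted.raw[iu])[::-1]
        top2 = {(iu[0][k], iu[1][k]) for k in order[:2]}
        assert top2 == {(4, 7), (2, 9)}

    def test_fully_nulled_position_gives_empty_report(self):
        raw = np.zeros((4, 4))
        raw[0, 1] = raw[1, 0] = 1.0  # mean > 0, everything else below it
        matrix = apply_significance(CoevolutionMatrix(raw=raw))
        assert position_report(matrix, 3) == []

    @pytest.mark.parametrize("position", [0, 13])
    def test_out_of_range_position(self, planted, position):
        with pytest.raises(IndexError):
            position_report(planted, position)


class TestIo:
    def test_fasta_round_trip(self, tmp_path):
        spec = MsaSpec(n_sequences=8, length=10, gap_fraction=0.1, seed=17)
        msa = generate_msa(spec)
        path = tmp_path / "msa.fasta"
        write_msa_fasta(msa, path)
        back = read_fasta_msa(path)
        assert back.sequences == msa.sequences
        assert back.ids == msa.ids

    def test_a3m_lowercase_stripped(self, tmp_path):
        path = tmp_path / "msa.a3m"
        path.write_text(">q\nACDEF\n>h\nAcgCDEF\n")
        back = read_fasta_msa(path)
        assert all(len(s) == 5 for s in back.sequences)

    def test_external_score_matrix_round_trip(self, tmp_path):
        rng = np.random.default_rng(18)
        sym = rng.normal(size=(5, 5))
        raw = (sym + sym.T) / 2
        np.fill_diagonal(raw, 0.0)
        matrix = CoevolutionMatrix(raw=raw)
        path = tmp_path / "scores.tsv"
        write_score_tsv(matrix, path, "raw")
        back = read_score_tsv(path)
        np.testing.assert_allclose(back.raw, raw, atol=1e-12)
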