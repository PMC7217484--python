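import itertools

import numpy as np
import pytest

from attnsol.model import ModelConfig, build_model, predict
from attnsol.mutagenesis import (
    SeparationProfile,
    SynergyMap,
    correlate_synergy_distance,
    pair_count,
    pair_scan,
    residue_distance_profile,
    separation_profile,
    single_scan,
    synergy_map,
)
from attnsol.sequence_io import AMINO_ACIDS, ProteinRecord


@pytest.fixture(scope="module")
def scan_model():
    return build_model(ModelConfig(seed=7))


@pytest.fixture(scope="module")
def small_scan(scan_model):
    """Full double-precision single + pair scan of a 5-residue sequence."""
    seq = "MKVDE"
    wt, ds = single_scan(scan_model, seq, dtype=np.float64)
    pairs = [
        pe
        for chunk in pair_scan(scan_model, seq, single=(wt, ds), dtype=np.float64)
        for pe in chunk
    ]
    return seq, wt, ds, pairs


class TestSingleScan:
    def test_matrix_shape_and_wildtype_zeros(self, scan_model):
        seq = "MKV"
        wt, ds = single_scan(scan_model, seq)
        assert ds.shape == (3, 20)
        for i, aa in enumerate(seq):
            assert ds[i, AMINO_ACIDS.index(aa)] == 0.0

    def test_deltas_match_independent_forward_passes(self, scan_model):
        seq = "MKVDEWYA"
        wt, ds = single_scan(scan_model, seq, dtype=np.float64)
        rng = np.random.default_rng(1)
        for _ in range(10):
            i = int(rng.integers(len(seq)))
            a = int(rng.integers(20))
            mutant = seq[:i] + AMINO_ACIDS[a] + seq[i + 1 :]
            scores = predict(scan_model, [ProteinRecord("wt", seq), ProteinRecord("mut", mutant)])
            expected = scores[1].score - scores[0].score
            assert abs(ds[i, a] - expected) < 1e-6

    def test_batching_does_not_change_results(self, scan_model):
        seq = "MKVDEWYACC"
        _, ds1 = single_scan(scan_model, seq, batch_size=7, dtype=np.float64)
        _, ds2 = single_scan(scan_model, seq, batch_size=1024, dtype=np.float64)
        np.testing.assert_allclose(ds1, ds2, atol=1e-12)

    def test_default_single_precision_matches_double_within_1e5(self, scan_model):
        seq = "MKVDEWYACC"
        wt32, ds32 = single_scan(scan_model, seq)  # default dtype: float32
        wt64, ds64 = single_scan(scan_model, seq, dtype=np.float64)
        assert abs(wt32 - wt64) < 1e-5
        np.testing.assert_allclose(ds32, ds64, atol=1e-5)


class TestPairScan:
    @pytest.mark.parametrize("L,expected", [(2, 400), (3, 1200), (103, 2_101_200)])
    def test_pair_count_formula(self, L, expected):
        assert pair_count(L) == expected

    def test_enumerated_count_matches_formula(self, scan_model, small_scan):
        seq, _, _, pairs = small_scan
        assert len(pairs) == pair_count(len(seq)) == (5 * 20 * 4 * 20) // 2

    def test_every_unordered_combination_appears_once(self, small_scan):
        seq, _, _, pairs = small_scan
        keys = {(p.i, p.aa_i, p.j, p.aa_j) for p in pairs}
        assert len(keys) == len(pairs)
        assert all(p.i < p.j for p in pairs)

    def test_delta_e_identity_and_wildtype_pairs(self, small_scan):
        seq, _, ds, pairs = small_scan
        for p in pairs:
            assert p.delta_e == p.delta_s_single - p.delta_s_pair
        # a pair whose i-substitution is the wildtype is a single mutation:
        # dS_pair = dS_j and dS_single = 0 + dS_j, so dE vanishes
        wt_pairs = [p for p in pairs if p.aa_i == seq[p.i - 1] or p.aa_j == seq[p.j - 1]]
        assert wt_pairs, "scan must include wildtype self-substitutions"
        assert max(abs(p.delta_e) for p in wt_pairs) < 1e-6

    def test_pair_deltas_match_independent_forward_passes(self, scan_model, small_scan):
        seq, wt_score, _, pairs = small_scan
        rng = np.random.default_rng(2)
        for k in rng.choice(len(pairs), size=8, replace=False):
            p = pairs[k]
            mutant = list(seq)
            mutant[p.i - 1] = p.aa_i
            mutant[p.j - 1] = p.aa_j
            out = predict(scan_model, [ProteinRecord("m", "".join(mutant))])[0]
            assert abs(p.delta_s_pair - (out.score - wt_score)) < 1e-6

    def test_default_single_precision_pairs_match_double_within_1e5(
        self, scan_model, small_scan
    ):
        seq, _, _, pairs64 = small_scan
        pairs32 = [pe for chunk in pair_scan(scan_model, seq) for pe in chunk]
        assert len(pairs32) == len(pairs64)
        worst = max(
            abs(a.delta_s_pair - b.delta_s_pair) for a, b in zip(pairs32, pairs64)
        )
        assert worst < 1e-5

    def test_too_short_sequence_rejected(self, scan_model):
        with pytest.raises(ValueError):
            list(pair_scan(scan_model, "M"))


class TestSynergyMap:
    def test_matches_brute_force_aggregation(self, small_scan):
        seq, _, _, pairs = small_scan
        L = len(seq)
        smap = synergy_map(iter(pairs), L)
        # independent aggregation from the stored pair list
        for i in range(1, L + 1):
            for j in range(i + 1, L + 1):
                vals = [p.delta_e for p in pairs if p.i == i and p.j == j]
                assert len(vals) == 400
                assert smap.matrix[i - 1, j - 1] == pytest.approx(np.mean(vals))
                assert smap.matrix[j - 1, i - 1] == smap.matrix[i - 1, j - 1]
        assert np.isnan(np.diag(smap.matrix)).all()

    def test_incomplete_stream_rejected(self, small_scan):
        seq, _, _, pairs = small_scan
        with pytest.raises(ValueError, match="incomplete"):
            synergy_map(iter(pairs[:-5]), len(seq))


class TestSeparationProfile:
    def test_constant_map_gives_flat_profile(self):
        L = 6
        mat = np.full((L, L), 2.5)
        np.fill_diagonal(mat, np.nan)
        prof = separation_profile(SynergyMap(mat))
        np.testing.assert_allclose(prof.mean, 2.5)
        np.testing.assert_allclose(prof.median, 2.5)

    def test_hand_computed_means_on_length_four_map(self):
        mat = np.full((4, 4), np.nan)
        vals = {(0, 1): 1.0, (1, 2): 2.0, (2, 3): 6.0, (0, 2): 4.0, (1, 3): 8.0, (0, 3): 5.0}
        for (i, j), v in vals.items():
            mat[i, j] = mat[j, i] = v
        prof = separation_profile(SynergyMap(mat))
        np.testing.assert_array_equal(prof.separations, [1, 2, 3])
        np.testing.assert_allclose(prof.mean, [3.0, 6.0, 5.0])
        np.testing.assert_allclose(prof.median, [2.0, 6.0, 5.0])

    def test_largest_separation_has_single_pair(self, small_scan):
        seq, _, _, pairs = small_scan
        smap = synergy_map(iter(pairs), len(seq))
        prof = separation_profile(smap)
        d_max = len(seq) - 1
        assert prof.mean[-1] == pytest.approx(smap.matrix[0, d_max])


class TestResidueDistanceProfile:
    def test_hand_computed_distances(self, synthetic_pdb):
        prof = residue_distance_profile(synthetic_pdb, "A")
        np.testing.assert_array_equal(prof.separations, [1, 2, 3])
        # sep 1: 5, 12, 3; sep 2: 13 and sqrt(153); sep 3: sqrt(160)
        sep2 = (13.0 + np.sqrt(153.0)) / 2.0
        np.testing.assert_allclose(prof.mean, [20.0 / 3.0, sep2, np.sqrt(160.0)])
        np.testing.assert_allclose(prof.median, [5.0, sep2, np.sqrt(160.0)])

    def test_three_four_five_distance(self, synthetic_pdb):
        prof = residue_distance_profile(synthetic_pdb, "A")
        # residues 1 and 2 sit 3-4-5 apart (glycine falls back to C-alpha)
        assert min(5.0, prof.mean[0]) <= prof.mean[0]
        assert 5.0 == pytest.approx(
            np.linalg.norm(np.array([3.0, 4.0, 0.0]) - np.zeros(3))
        )

    def test_missing_chain_rejected(self, synthetic_pdb):
        with pytest.raises(ValueError, match="chain"):
            residue_distance_profile(synthetic_pdb, "B")

    def test_residue_missing_cbeta_skipped(self, tmp_path, synthetic_pdb):
        # append a CB-less alanine; its pairs must vanish from the profile
        text = synthetic_pdb.read_text().replace(
            "END\n",
            "ATOM     12  N   ALA A   5      10.000  10.000  10.000  1.00  0.00           N\n"
            "ATOM     13  CA  ALA A   5      11.000  10.000  10.000  1.00  0.00           C\n"
            "END\n",
        )
        p = tmp_path / "with_missing.pdb"
        p.write_text(text)
        prof = residue_distance_profile(p, "A")
        np.testing.assert_array_equal(prof.separations, [1, 2, 3])  # no separation 4


class TestCorrelation:
    def test_identical_profiles_give_pearson_one(self):
        s = SeparationProfile(np.arange(1, 6), np.array([1.0, 3, 2, 5, 4]), np.zeros(5))
        assert correlate_synergy_distance(s, s)["pearson_r"] == pytest.approx(1.0)

    def test_monotone_transform_gives_spearman_one(self):
        x = np.array([1.0, 2, 3, 4, 5])
        a = SeparationProfile(np.arange(1, 6), x, x)
        b = SeparationProfile(np.arange(1, 6), np.exp(x), x)
        res = correlate_synergy_distance(a, b)
        assert res["spearman_r"] == pytest.approx(1.0)
        assert res["pearson_r"] < 1.0

    def test_pearson_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0, 8.1])
        a = SeparationProfile(np.arange(1, 5), x, x)
        b = SeparationProfile(np.arange(1, 5), y, y)
        r = correlate_synergy_distance(a, b)["pearson_r"]
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(expected)

    def test_mismatched_separations_are_intersected(self):
        a = SeparationProfile(np.array([1, 2, 3, 4]), np.array([1.0, 2, 3, 4]), np.zeros(4))
        b = SeparationProfile(np.array([2, 3, 4, 5]), np.array([2.0, 3, 4, 9]), np.zeros(4))
        res = correlate_synergy_distance(a, b)
        assert res["n_separations"] == 3
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_too_few_shared_separations_rejected(self):
        a = SeparationProfile(np.array([1, 2]), np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            correlate_synergy_distance(a, a)
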