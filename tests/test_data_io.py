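import numpy as np
import pandas as pd
import pytest
from scipy import stats

from commdyn.data_io import (
    CommunityMatrix,
    binarize,
    rarefy,
    read_asv_table,
    read_metadata,
    repeat_rarefy,
    write_asv_table,
    write_metadata,
)


class TestReadWrite:
    def test_round_trip_is_lossless(self, small_cm, tmp_path):
        path = tmp_path / "asv.tsv"
        write_asv_table(small_cm, path)
        back = read_asv_table(path)
        np.testing.assert_array_equal(back.counts, small_cm.counts)
        assert back.taxon_ids == small_cm.taxon_ids
        assert back.sample_ids == small_cm.sample_ids

    def test_counts_read_exactly_as_in_file(self, tmp_path):
        path = tmp_path / "asv.tsv"
        path.write_text("taxon_id\ts1\ts2\ts3\nta\t1\t0\t2\ntb\t0\t5\t0\n")
        cm = read_asv_table(path)
        np.testing.assert_array_equal(cm.counts, [[1, 0, 2], [0, 5, 0]])

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = tmp_path / "asv.tsv"
        path.write_text("taxon_id\ts1\ts1\nta\t1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_asv_table(path)

    def test_non_integer_cell_rejected(self, tmp_path):
        path = tmp_path / "asv.tsv"
        path.write_text("taxon_id\ts1\nta\t1.5\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_asv_table(path)

    def test_metadata_times_are_days_since_station_start(self, tmp_path):
        path = tmp_path / "meta.tsv"
        meta = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "station": ["A", "A", "B", "B"],
                "date": ["2015-01-10", "2015-03-12", "2015-01-20", "2015-02-19"],
                "salinity": [20.0, 22.0, 30.0, 31.0],
                "temperature": [15.0, 18.0, 15.5, 16.0],
                "pH": [8.0, 8.1, 8.0, 8.0],
                "NOx": [5.0, 4.0, 3.0, 2.0],
                "PO4": [0.5, 0.4, 0.3, 0.2],
            }
        )
        write_metadata(meta, path)
        back, env = read_metadata(path)
        assert back["time"].tolist() == [0.0, 61.0, 0.0, 30.0]
        np.testing.assert_allclose(env.salinity, [20.0, 22.0, 30.0, 31.0])


class TestValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            CommunityMatrix(np.array([[-1]]), ["t"], ["s"])

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CommunityMatrix(np.zeros((2, 1), int), ["t", "t"], ["s"])

    def test_times_must_increase_within_station(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            CommunityMatrix(
                np.zeros((1, 2), int),
                ["t"],
                ["s1", "s2"],
                times=[5.0, 5.0],
                station=["A", "A"],
            )


class TestBinarize:
    def test_positive_counts_become_one(self, small_cm):
        pm = binarize(small_cm)
        np.testing.assert_array_equal(pm.presence, (small_cm.counts > 0).astype(int))

    def test_count_of_one_is_present(self):
        cm = CommunityMatrix(np.array([[1, 0]]), ["t"], ["s1", "s2"])
        assert binarize(cm).presence.tolist() == [[1, 0]]

    def test_all_zero_counts(self):
        cm = CommunityMatrix(np.zeros((2, 2), int), ["t1", "t2"], ["s1", "s2"])
        assert binarize(cm).presence.sum() == 0


class TestRarefy:
    def test_depth_equal_to_total_leaves_column_unchanged(self, small_cm):
        totals = small_cm.sample_sums()
        out = rarefy(small_cm, int(totals.min()), seed=0)
        j = int(np.argmin(totals))
        np.testing.assert_array_equal(out.counts[:, j], small_cm.counts[:, j])

    def test_column_sums_and_monotonicity(self, small_cm):
        out = rarefy(small_cm, 4, seed=1)
        assert (out.counts.sum(axis=0) == 4).all()
        assert (out.counts <= small_cm.counts).all()

    def test_single_taxon_sample_gets_full_depth(self):
        cm = CommunityMatrix(np.array([[50]]), ["t"], ["s"])
        assert rarefy(cm, 7, seed=0).counts[0, 0] == 7

    def test_shallow_samples_reported_by_name(self, small_cm):
        with pytest.raises(ValueError, match="a2"):
            rarefy(small_cm, 6, seed=0)

    def test_reproducible_under_seed(self, small_cm):
        a = rarefy(small_cm, 4, seed=3).counts
        b = rarefy(small_cm, 4, seed=3).counts
        np.testing.assert_array_equal(a, b)

    def test_hypergeometric_moments(self):
        """Rarefied counts match hypergeometric mean/SD for a 2-taxon pool."""
        cm = CommunityMatrix(np.array([[5000], [5000]]), ["t1", "t2"], ["s"])
        draws = np.array(
            [rarefy(cm, 1000, seed=s).counts[0, 0] for s in range(2000)]
        )
        sd = stats.hypergeom(10000, 5000, 1000).std()
        se = sd / np.sqrt(len(draws))
        assert abs(draws.mean() - 500.0) < 3 * se

    def test_richness_monotone_in_depth(self):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(5000, rng.dirichlet(np.full(200, 0.3)), size=4).T
        cm = CommunityMatrix(counts, [f"t{i}" for i in range(200)], list("abcd"))
        rich = []
        for depth in (100, 500, 2000):
            reps = repeat_rarefy(cm, depth, n_rep=30, seed=1)
            rich.append(np.mean([(r.counts > 0).sum(axis=0).mean() for r in reps]))
        assert rich[0] < rich[1] < rich[2]


class TestRepeatRarefy:
    def test_single_repetition_matches_rarefy(self, small_cm):
        reps = repeat_rarefy(small_cm, 4, n_rep=1, seed=9)
        np.testing.assert_array_equal(reps[0].counts, rarefy(small_cm, 4, seed=9).counts)

    def test_full_depth_gives_identical_copies(self):
        cm = CommunityMatrix(np.array([[3], [7]]), ["t1", "t2"], ["s"])
        reps = repeat_rarefy(cm, 10, n_rep=5, seed=0)
        for r in reps:
            np.testing.assert_array_equal(r.counts, cm.counts)

    def test_averaging_shrinks_standard_error(self):
        """SE of the 100-repetition mean richness is ~SD/10 of one repetition."""
        rng = np.random.default_rng(1)
        counts = rng.multinomial(3000, rng.dirichlet(np.full(150, 0.2))).reshape(-1, 1)
        cm = CommunityMatrix(counts, [f"t{i}" for i in range(150)], ["s"])
        single = np.array(
            [(rarefy(cm, 300, seed=s).counts > 0).sum() for s in range(300)]
        )
        means = []
        for block in range(20):
            reps = repeat_rarefy(cm, 300, n_rep=100, seed=10_000 + 100 * block)
            means.append(np.mean([(r.counts > 0).sum() for r in reps]))
        assert np.std(means) < np.std(single) / 9 * 2  # SD/sqrt(100), slack x2
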