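from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from tadcore.genome_model import BinIndex, RatioTrack, TADSet, bin_tad_map
from tadcore.ratio_engine import (
    ImagingParams,
    StructureRatioParams,
    SubsampleParams,
    average_tracks,
    cluster_ratios,
    contact_ratio,
    imaging_ratio,
    pairs_ratio,
    split_track,
    sprite_ratio,
    structure_ratio,
    subsample_correlation,
)


def brute_force_cluster_ratios(cluster, tad_of_bin):
    """Independent oracle: enumerate all unordered member pairs."""
    cluster = list(cluster)
    c = len(cluster)
    out = {}
    for b in cluster:
        if tad_of_bin[b] < 0:
            continue
        n = sum(
            1
            for x, y in combinations(cluster, 2)
            if (b in (x, y))
            and tad_of_bin[x] == tad_of_bin[y]
            and tad_of_bin[x] >= 0
        )
        out[b] = n / (c - 1)
    return out


class TestClusterRatios:
    def test_mixed_tad_cluster(self, index10, tads10):
        # bins 0,1,2 in T1; bin 3 in T2 -> r(b in T1) = 2/3, r(bin 3) = 0
        m = bin_tad_map(tads10, index10)
        recs = cluster_ratios(np.array([0, 1, 2, 3]), m)
        by_bin = {r.bin_id: r.ratio for r in recs}
        assert by_bin[0] == pytest.approx(2 / 3)
        assert by_bin[3] == 0.0

    def test_single_tad_cluster_all_ones(self, index10, tads10):
        m = bin_tad_map(tads10, index10)
        assert all(r.ratio == 1.0 for r in cluster_ratios(np.array([0, 1, 2]), m))

    def test_two_bins_different_tads_both_zero(self, index10, tads10):
        m = bin_tad_map(tads10, index10)
        assert [r.ratio for r in cluster_ratios(np.array([0, 3]), m)] == [0.0, 0.0]

    def test_unassigned_member_inflates_denominator_only(self, index10, tads10):
        m = bin_tad_map(tads10, index10)
        recs = cluster_ratios(np.array([0, 1, 6]), m)  # bin 6 is in the gap
        assert {r.bin_id for r in recs} == {0, 1}
        assert all(r.ratio == pytest.approx(1 / 2) for r in recs)

    def test_small_cluster_rejected(self, index10, tads10):
        m = bin_tad_map(tads10, index10)
        with pytest.raises(ValueError):
            cluster_ratios(np.array([0]), m)

    def test_matches_bruteforce_on_random_clusters(self, rng):
        tad_of_bin = rng.integers(-1, 5, 200)
        for _ in range(50):
            size = rng.integers(2, 12)
            cluster = rng.choice(200, size=size, replace=False)
            got = {r.bin_id: r.ratio for r in cluster_ratios(cluster, tad_of_bin)}
            assert got == pytest.approx(brute_force_cluster_ratios(cluster, tad_of_bin))

    def test_adding_same_tad_member_never_lowers_intra_count(self, rng):
        # the numerator N_ij is monotone in same-TAD membership
        tad_of_bin = rng.integers(0, 4, 50)
        for _ in range(20):
            cluster = rng.choice(50, size=6, replace=False)
            extra = next(
                b for b in range(50)
                if b not in cluster and tad_of_bin[b] == tad_of_bin[cluster[0]]
            )
            before = brute_force_cluster_ratios(cluster, tad_of_bin)
            after = brute_force_cluster_ratios(np.append(cluster, extra), tad_of_bin)
            b0 = cluster[0]
            assert after[b0] * 6 >= before[b0] * 5  # N after >= N before


class TestSpriteRatio:
    def test_mean_over_clusters(self, index10, tads10):
        clusters = [np.array([0, 1]), np.array([0, 3])]  # r(0)=1 then r(0)=0
        t = sprite_ratio(clusters, tads10, index10, min_bin_support=1)
        assert t.values[0] == pytest.approx(0.5)
        assert t.support[0] == 2

    def test_min_support_boundary_is_inclusive(self, index10, tads10):
        clusters = [np.array([0, 1])] * 99
        t99 = sprite_ratio(clusters, tads10, index10, min_bin_support=100)
        assert np.isnan(t99.values[0]) and t99.support[0] == 0
        t100 = sprite_ratio(clusters + [np.array([0, 1])], tads10, index10,
                            min_bin_support=100)
        assert t100.values[0] == 1.0 and t100.support[0] == 100

    def test_intrachrom_partitions_clusters(self):
        index = BinIndex({"chrA": 20_000, "chrB": 20_000}, 10_000)
        tads = TADSet(pd.DataFrame({"chrom": ["chrA", "chrB"],
                                    "start": [0, 0], "end": [20_000, 20_000],
                                    "tad_id": ["TA", "TB"]}))
        # one cluster mixing chromosomes: {A0, A1, B0}
        clusters = [np.array([0, 1, 2])]
        genomewide = sprite_ratio(clusters, tads, index, min_bin_support=1)
        assert genomewide.values[0] == pytest.approx(1 / 2)
        intra = sprite_ratio(clusters, tads, index, min_bin_support=1,
                             mode="intrachrom")
        # sub-cluster {A0, A1}: both r=1; sub-cluster {B0} of size 1 dropped
        assert intra.values[0] == 1.0 and intra.values[1] == 1.0
        assert np.isnan(intra.values[2]) and intra.support[2] == 0

    def test_support_conservation(self, index10, tads10, rng):
        clusters = [np.sort(rng.choice(10, size=rng.integers(2, 6),
                                       replace=False)) for _ in range(30)]
        t = sprite_ratio(clusters, tads10, index10, min_bin_support=0)
        m = bin_tad_map(tads10, index10)
        expected = sum(int((m[c] >= 0).sum()) for c in clusters)
        assert t.support.sum() == expected

    def test_exclude_adjacent_removes_neighbour_tad_members(self, index10, tads10):
        # cluster {0 (T1), 3 (T2), 8 (T3)}: for bin 0, T2 is adjacent ->
        # denominator 2 - 1 = 1, N = 0 -> r = 0; T3 is not adjacent to T1
        clusters = [np.array([0, 3, 8])]
        plain = sprite_ratio(clusters, tads10, index10, min_bin_support=1)
        assert plain.values[0] == 0.0
        excl = sprite_ratio(clusters, tads10, index10, min_bin_support=1,
                            exclude_adjacent=True)
        # bin 0: member 3 (adjacent T2) removed -> denom 1, r = 0/1 = 0
        assert excl.values[0] == 0.0
        # bin 3 (T2): both neighbours T1, T3 adjacent -> denominator 0 -> no record
        assert np.isnan(excl.values[3]) and excl.support[3] == 0

    def test_empty_cluster_list_rejected(self, index10, tads10):
        with pytest.raises(ValueError):
            sprite_ratio([], tads10, index10)


class TestContactRatio:
    def _contacts(self, rows):
        return pd.DataFrame(rows, columns=["bin1", "bin2", "weight"])

    def test_weighted_intra_fraction(self, index10, tads10):
        c = self._contacts([(0, 1, 3.0), (0, 3, 1.0)])
        t = contact_ratio(c, tads10, index10)
        assert t.values[0] == pytest.approx(0.75)

    def test_self_contact_only_is_missing(self, index10, tads10):
        t = contact_ratio(self._contacts([(0, 0, 5.0)]), tads10, index10)
        assert np.isnan(t.values[0]) and t.support[0] == 0

    def test_all_partners_same_tad(self, index10, tads10):
        t = contact_ratio(self._contacts([(0, 1, 1.0), (0, 2, 2.0)]),
                          tads10, index10)
        assert t.values[0] == 1.0

    def test_unassigned_partner_counts_denominator_only(self, index10, tads10):
        t = contact_ratio(self._contacts([(0, 1, 1.0), (0, 6, 1.0)]),
                          tads10, index10)
        assert t.values[0] == pytest.approx(0.5)
        assert np.isnan(t.values[6])  # gap bin gets no ratio


class TestPairsRatio:
    def test_cell_average_and_support(self, index10, tads10):
        cell1 = pd.DataFrame({"bin1": [0], "bin2": [1], "weight": [1.0]})  # r=1
        cell2 = pd.DataFrame({"bin1": [0], "bin2": [3], "weight": [1.0]})  # r=0
        cell3 = pd.DataFrame({"bin1": [4], "bin2": [5], "weight": [1.0]})
        tracks, avg = pairs_ratio([cell1, cell2, cell3], tads10, index10)
        assert avg.values[0] == pytest.approx(0.5) and avg.support[0] == 2
        assert avg.values[4] == 1.0 and avg.support[4] == 1
        assert np.isnan(avg.values[8]) and avg.support[8] == 0


class TestStructureRatio:
    def _model(self, bins, coords, hap=""):
        return pd.DataFrame(
            {"chrom": "chr1", "hap": hap, "start": np.array(bins) * 10_000,
             "bin": bins, "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2]}
        )

    def test_fully_separated_clouds(self, rng):
        index = BinIndex({"chr1": 240_000}, 10_000)
        tads = TADSet(pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 120_000],
                                    "end": [120_000, 240_000],
                                    "tad_id": ["A", "B"]}))
        bins = np.arange(24)
        coords = rng.normal(0, 1, (24, 3))
        coords[12:] += 100.0
        t = structure_ratio([self._model(bins, coords)], tads, index,
                            StructureRatioParams(k=10))
        assert np.all(t.values == 1.0)

    def test_haplotype_mismatch_is_not_intra(self):
        # two haplotype copies interleaved at the same sites: with k=1 the
        # nearest neighbour is always the other haplotype -> ratio 0
        index = BinIndex({"chr1": 40_000}, 10_000)
        tads = TADSet(pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                    "end": [40_000], "tad_id": ["A"]}))
        bins = np.arange(4)
        base = np.column_stack([np.arange(4) * 10.0, np.zeros(4), np.zeros(4)])
        pat = self._model(bins, base, hap="pat")
        mat = self._model(bins, base + np.array([0.1, 0, 0]), hap="mat")
        model = pd.concat([pat, mat], ignore_index=True)
        aware = structure_ratio([model], tads, index,
                                StructureRatioParams(k=1, haplotype_aware=True))
        assert np.all(aware.values == 0.0)
        blind = structure_ratio([model], tads, index, StructureRatioParams(k=1))
        assert np.all(blind.values == 1.0)

    def test_too_few_points_gives_missing(self):
        index = BinIndex({"chr1": 40_000}, 10_000)
        tads = TADSet(pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                    "end": [40_000], "tad_id": ["A"]}))
        model = self._model(np.arange(4), np.eye(4, 3))
        t = structure_ratio([model], tads, index, StructureRatioParams(k=10))
        assert np.isnan(t.values).all()

    def test_split_duplicates_parent_value(self):
        index = BinIndex({"chr1": 40_000}, 20_000)
        vals = np.array([0.7, np.nan])
        track = RatioTrack(vals, np.array([3, 0]))
        fine_track, fine = split_track(track, index, 10_000)
        assert fine.n_bins == 4
        assert fine_track.values[0] == 0.7 and fine_track.values[1] == 0.7
        assert np.isnan(fine_track.values[2]) and np.isnan(fine_track.values[3])


class TestImagingRatio:
    def _setup(self):
        index = BinIndex({"chr1": 100_000}, 10_000)
        seg = pd.DataFrame(
            {"cell_id": [0, 0], "chrom": ["chr1", "chr1"],
             "start": [0, 50_000], "end": [50_000, 100_000],
             "domain_id": [0, 1]}
        )
        return index, seg

    def test_fraction_of_neighbourhood_in_same_domain(self):
        index, seg = self._setup()
        # bin 0 at origin; 4 others within 500 nm: 3 in domain 0, 1 in domain 1
        rows = [(0, "chr1", 0, 10_000, 0.0, 0.0, 0.0)]
        for i, (b, d) in enumerate([(1, 100), (2, 200), (3, 300), (5, 400)]):
            rows.append((0, "chr1", b * 10_000, (b + 1) * 10_000, float(d), 0.0, 0.0))
        rows.append((0, "chr1", 90_000, 100_000, 5000.0, 0.0, 0.0))  # out of range
        imaging = pd.DataFrame(rows, columns=["cell_id", "chrom", "start", "end",
                                              "x", "y", "z"])
        out = imaging_ratio(imaging, seg, index, ImagingParams(500.0))
        assert out[0].values[0] == pytest.approx(3 / 4)

    def test_no_neighbours_within_radius_is_missing(self):
        index, seg = self._setup()
        imaging = pd.DataFrame(
            [(0, "chr1", 0, 10_000, 0.0, 0.0, 0.0),
             (0, "chr1", 10_000, 20_000, 9999.0, 0.0, 0.0)],
            columns=["cell_id", "chrom", "start", "end", "x", "y", "z"],
        )
        out = imaging_ratio(imaging, seg, index, ImagingParams(500.0))
        assert np.isnan(out[0].values[0])

    def test_single_domain_cell_all_ones(self, rng):
        index = BinIndex({"chr1": 100_000}, 10_000)
        seg = pd.DataFrame({"cell_id": [0], "chrom": ["chr1"], "start": [0],
                            "end": [100_000], "domain_id": [0]})
        coords = rng.normal(0, 100, (10, 3))
        imaging = pd.DataFrame(
            [(0, "chr1", b * 10_000, (b + 1) * 10_000, *coords[b])
             for b in range(10)],
            columns=["cell_id", "chrom", "start", "end", "x", "y", "z"],
        )
        out = imaging_ratio(imaging, seg, index, ImagingParams(1e6))
        assert np.all(out[0].values == 1.0)


class TestSubsampleCorrelation:
    def _tracks(self, rng, n_cells=6, n_bins=50):
        return [
            RatioTrack(rng.uniform(0, 1, n_bins), np.ones(n_bins, dtype=int))
            for _ in range(n_cells)
        ]

    def test_full_draw_is_degenerate(self, rng):
        tracks = self._tracks(rng)
        ref = average_tracks(tracks)
        out = subsample_correlation(tracks, ref, SubsampleParams(x=6, repeats=5, seed=0))
        assert np.allclose(out["pearson"], 1.0)
        assert out["pearson"].nunique() == 1

    def test_identical_cells_any_draw(self, rng):
        t = self._tracks(rng, n_cells=1)[0]
        tracks = [t, RatioTrack(t.values.copy(), t.support.copy())]
        out = subsample_correlation(tracks, t, SubsampleParams(x=1, repeats=4, seed=3))
        assert np.allclose(out["spearman"], 1.0)

    def test_seed_reproducibility(self, rng):
        tracks = self._tracks(rng, n_cells=10)
        ref = average_tracks(tracks)
        p = SubsampleParams(x=4, repeats=8, seed=77)
        a = subsample_correlation(tracks, ref, p)
        b = subsample_correlation(tracks, ref, p)
        pd.testing.assert_frame_equal(a, b)

    def test_draw_larger_than_cells_rejected(self, rng):
        tracks = self._tracks(rng, n_cells=3)
        with pytest.raises(ValueError):
            subsample_correlation(tracks, tracks[0], SubsampleParams(x=4))
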