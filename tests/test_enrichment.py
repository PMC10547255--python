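"""Mappable genome, blacklist, binomial enrichment and target calls."""

import math

import numpy as np
import pandas as pd
import pytest

from kzfptools import enrichment as en
from kzfptools import intervals as iv
from kzfptools import synthetic as syn


def peaks_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestComputeMappable:
    def test_kept_and_dropped_zero_regions(self):
        # 200-kb genome; common zero regions of 50 kb (kept) and 30 kb (dropped)
        zero = {"chr1": np.array([[10_000, 60_000], [100_000, 130_000]])}
        mg = en.compute_mappable([zero], {"chr1": 200_000}, exclude_chroms=())
        assert mg.total_length == 150_000

    def test_nearby_runs_merged_before_size_filter(self):
        # two 25-kb runs 50 bp apart merge to >40 kb and are removed together
        zero = {"chr1": np.array([[0, 25_000], [25_050, 50_050]])}
        mg = en.compute_mappable([zero], {"chr1": 200_000}, exclude_chroms=())
        assert mg.total_length == 200_000 - 50_050

    def test_chry_contributes_nothing(self):
        mg = en.compute_mappable([], {"chr1": 100_000, "chrY": 50_000})
        assert mg.total_length == 100_000
        assert "chrY" not in mg.intervals

    def test_intersection_across_experiments(self):
        z1 = {"chr1": np.array([[0, 100_000]])}
        z2 = {"chr1": np.array([[50_000, 150_000]])}
        mg = en.compute_mappable([z1, z2], {"chr1": 400_000}, exclude_chroms=())
        # common zero = [50k,100k) = 50 kb > 40 kb -> removed
        assert mg.total_length == 350_000


class TestBlacklist:
    def test_locus_in_all_experiments_blacklisted(self):
        sets = [peaks_frame([("chr1", 100, 200)]) for _ in range(10)]
        bl = en.build_recurrence_blacklist(sets, min_fraction=1.0)
        assert iv.total_length(bl) == 100
        filtered = en.filter_peaks(peaks_frame([("chr1", 150, 250), ("chr1", 500, 600)]), bl)
        assert filtered["start"].tolist() == [500]

    def test_one_missing_experiment_breaks_unanimity(self):
        sets = [peaks_frame([("chr1", 100, 200)]) for _ in range(9)]
        sets.append(peaks_frame([("chr1", 5000, 5100)]))
        bl = en.build_recurrence_blacklist(sets, min_fraction=1.0)
        assert iv.total_length(bl) == 0

    def test_empty_blacklist_filter_is_identity(self):
        p = peaks_frame([("chr1", 0, 10), ("chr2", 5, 15)])
        assert en.filter_peaks(p, {}).equals(p)

    def test_fractional_threshold(self):
        sets = [peaks_frame([("chr1", 0, 100)]) for _ in range(5)]
        sets += [peaks_frame([("chr1", 900, 1000)]) for _ in range(5)]
        bl = en.build_recurrence_blacklist(sets, min_fraction=0.5)
        assert iv.total_length(bl) == 200


def exact_binomial_tail(k, n, p):
    """Independent closed-form upper tail by direct summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestEnrich:
    def _toy(self, k=30, n=100):
        """G=10,000; one unit with a single 1,000-bp fragment; point peaks."""
        ann = pd.DataFrame(
            [("chr1", 4000, 5000, "+", "U", "F", "C")],
            columns=["chrom", "start", "end", "strand", "subfamily", "family", "class"],
        )
        mp = {"chr1": np.array([[0, 10_000]], dtype=np.int64)}
        rows = [("chr1", 4000 + i, 4001 + i) for i in range(k)]
        rows += [("chr1", 100 + i, 101 + i) for i in range(n - k)]
        return ann, mp, peaks_frame(rows)

    def test_point_peak_toy_matches_exact_tail_sum(self):
        ann, mp, peaks = self._toy()
        res = en.enrich(peaks, ann, mp)
        row = res.iloc[0]
        assert row["p_overlap"] == pytest.approx(0.1)
        assert row["expected"] == pytest.approx(10.0)
        assert row["observed"] == 30
        assert row["p_value"] == pytest.approx(exact_binomial_tail(30, 100, 0.1), rel=1e-9)

    def test_peaks_outside_all_fragments_nothing_significant(self, toy_genome, toy_mappable):
        ann = toy_genome.repeat_annotation
        # park all peaks in an annotation-free corridor
        free = iv.subtract(toy_mappable, iv.from_dataframe(ann))
        biggest = max(((c, a) for c, a in free.items()), key=lambda t: (t[1][:, 1] - t[1][:, 0]).max())
        c, arr = biggest
        i = int(np.argmax(arr[:, 1] - arr[:, 0]))
        s = int(arr[i, 0])
        peaks = peaks_frame([(c, s, s + 1) for _ in range(20)])
        res = en.enrich(peaks, ann, toy_mappable)
        assert (res["observed"] == 0).all()
        assert not (res["fdr"] < 0.05).any()

    def test_saturating_peak_no_enrichment(self):
        ann, mp, _ = self._toy()
        peaks = peaks_frame([("chr1", 0, 10_000)])
        res = en.enrich(peaks, ann, mp)
        assert res.iloc[0]["observed"] == 1
        assert res.iloc[0]["p_overlap"] == 1.0
        assert res.iloc[0]["p_value"] == 1.0

    def test_multi_fragment_overlap_counts_once(self):
        ann = pd.DataFrame(
            [("chr1", 100, 200, "+", "U", "F", "C"), ("chr1", 250, 350, "+", "U", "F", "C")],
            columns=["chrom", "start", "end", "strand", "subfamily", "family", "class"],
        )
        mp = {"chr1": np.array([[0, 10_000]], dtype=np.int64)}
        res = en.enrich(peaks_frame([("chr1", 150, 300)]), ann, mp)
        assert res.iloc[0]["observed"] == 1

    def test_family_level_pools_subfamilies(self):
        ann = pd.DataFrame(
            [
                ("chr1", 100, 200, "+", "A1", "Fam", "C"),
                ("chr1", 400, 500, "+", "A2", "Fam", "C"),
            ],
            columns=["chrom", "start", "end", "strand", "subfamily", "family", "class"],
        )
        mp = {"chr1": np.array([[0, 10_000]], dtype=np.int64)}
        res = en.enrich(peaks_frame([("chr1", 150, 160), ("chr1", 450, 460)]), ann, mp,
                        level="family")
        assert len(res) == 1 and res.iloc[0]["observed"] == 2

    def test_empty_mappable_fails(self):
        ann, _, peaks = self._toy()
        with pytest.raises(ValueError):
            en.enrich(peaks, ann, {})

    def test_adding_overlapping_peak_does_not_raise_p_value(self):
        ann, mp, peaks = self._toy(k=10, n=50)
        res1 = en.enrich(peaks, ann, mp)
        more = pd.concat(
            [peaks, peaks_frame([("chr1", 4500, 4501)])], ignore_index=True
        )
        res2 = en.enrich(more, ann, mp)  # constant width, so w-bar is unchanged
        assert res2.iloc[0]["p_value"] <= res1.iloc[0]["p_value"]


class TestShuffleOracle:
    def test_binomial_agrees_with_oracle_on_toy(self):
        ann = pd.DataFrame(
            [("chr1", 4000, 5000, "+", "U", "F", "C")],
            columns=["chrom", "start", "end", "strand", "subfamily", "family", "class"],
        )
        mp = {"chr1": np.array([[0, 10_000]], dtype=np.int64)}
        peaks = syn.generate_peaks(ann, mp, 100, None, 0.0, 1, seed=3)
        res = en.enrich(peaks, ann, mp)
        orc = en.shuffle_oracle(peaks, ann, mp, n_iter=2000, seed=4)
        p_b = res.iloc[0]["p_value"]
        p_e = orc.iloc[0]["empirical_p"]
        se = max(np.sqrt(p_e * (1 - p_e) / 2000), 1 / 2001)
        assert abs(p_b - p_e) <= 3 * se

    def test_zero_observed_gives_empirical_p_one(self):
        ann = pd.DataFrame(
            [("chr2", 0, 100, "+", "U", "F", "C")],
            columns=["chrom", "start", "end", "strand", "subfamily", "family", "class"],
        )
        mp = {"chr1": np.array([[0, 10_000]]), "chr2": np.array([[0, 1_000]])}
        peaks = peaks_frame([("chr1", 50, 60)])
        orc = en.shuffle_oracle(peaks, ann, mp, n_iter=200, seed=1)
        assert orc.iloc[0]["empirical_p"] == 1.0

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            en.shuffle_oracle(peaks_frame([("chr1", 0, 1)]), pd.DataFrame(), {}, n_iter=10)


class TestClassifyTargets:
    def test_scaled_scores_and_flags_arithmetic(self):
        res = pd.DataFrame(
            {"unit": list("abcd"), "fdr": [1e-10, 10**-9.5, 0.04, 0.2]}
        )
        out = en.classify_targets(res)
        assert np.allclose(out["neg_log10_fdr"], [10, 9.5, -np.log10(0.04), -np.log10(0.2)])
        assert np.allclose(out["scaled_score"], [1.0, 0.95, 0.1398, 0.0699], atol=5e-4)
        assert out["significant"].tolist() == [True, True, True, False]
        assert out["primary"].tolist() == [True, True, False, False]

    def test_single_result_is_primary(self):
        out = en.classify_targets(pd.DataFrame({"unit": ["a"], "fdr": [0.01]}))
        assert out.iloc[0]["scaled_score"] == 1.0 and bool(out.iloc[0]["primary"])

    def test_insignificant_alone_not_primary(self):
        out = en.classify_targets(pd.DataFrame({"unit": ["a"], "fdr": [0.2]}))
        assert not out.iloc[0]["significant"] and not out.iloc[0]["primary"]

    def test_zero_fdr_floored_not_infinite(self):
        out = en.classify_targets(pd.DataFrame({"unit": ["a", "b"], "fdr": [0.0, 1e-4]}))
        assert np.isfinite(out["neg_log10_fdr"]).all()
        assert out.iloc[0]["scaled_score"] == 1.0

    def test_primary_set_invariant_under_monotone_fdr_transform(self):
        fdr = np.array([1e-12, 1e-9, 1e-3, 0.02, 0.3])
        res = pd.DataFrame({"unit": list("abcde"), "fdr": fdr})
        base = en.classify_targets(res)
        # strictly monotone transform of the -log10 scale with fixed max
        trans = pd.DataFrame({"unit": list("abcde"), "fdr": fdr ** 1.0})
        assert en.classify_targets(trans)["primary"].tolist() == base["primary"].tolist()


class TestTargetDispersion:
    def test_two_clusters_three_kzfps(self):
        table, _ = en.target_dispersion(
            {"k1": {"S"}, "k2": {"S"}, "k3": {"S"}},
            {"k1": "Chr 1.1", "k2": "Chr 1.1", "k3": "Chr 2.1"},
        )
        assert table.iloc[0].tolist() == ["S", 3, 2]

    def test_single_kzfp_base_case(self):
        table, _ = en.target_dispersion({"k1": {"S"}}, {"k1": "Chr 1.1"})
        assert table.iloc[0].tolist() == ["S", 1, 1]

    def test_untargeted_unit_absent(self):
        table, _ = en.target_dispersion({"k1": set()}, {})
        assert len(table) == 0

    def test_unclustered_genes_are_singleton_locations(self):
        table, _ = en.target_dispersion(
            {"k1": {"S"}, "k2": {"S"}}, {}
        )
        assert table.iloc[0].tolist() == ["S", 2, 2]

    def test_frequency_matrix_columns_sum_to_one(self):
        table, freq = en.target_dispersion(
            {"k1": {"S", "T"}, "k2": {"S"}, "k3": {"T", "U"}},
            {"k1": "A", "k2": "A", "k3": "B"},
        )
        assert np.allclose(freq.sum(axis=0), 1.0)
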