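import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epiretscore as e
from epiretscore import RegionSet
from epiretscore.annotate import cluster_samples
from scipy.cluster import hierarchy


def brute_force_pairs(a, b, min_overlap_bp):
    pairs = []
    for ra in a:
        for rb in b:
            if ra.chrom == rb.chrom and \
                    min(ra.end, rb.end) - max(ra.start, rb.start) >= min_overlap_bp:
                pairs.append((ra, rb))
    return pairs


def random_region_set(rng, n, n_chrom=2, span=2000):
    regions = set()
    while len(regions) < n:
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(0, span))
        regions.add((chrom, start, start + int(rng.integers(1, 120))))
    return RegionSet(sorted(regions))


class TestIntersectRegions:
    def test_identical_single_region_sets(self):
        a = RegionSet([("chr1", 10, 20)])
        _, st_ = e.intersect_regions(a, a)
        assert (st_.n_shared, st_.pct_a_shared, st_.jaccard) == (1, 100.0, 1.0)

    def test_disjoint_sets(self):
        a = RegionSet([("chr1", 10, 20)])
        b = RegionSet([("chr1", 30, 40)])
        pairs, st_ = e.intersect_regions(a, b)
        assert pairs == [] and st_.n_shared == 0 and st_.jaccard == 0.0

    def test_min_overlap_boundary(self):
        a = RegionSet([("chr1", 0, 100)])
        b = RegionSet([("chr1", 99, 200)])
        assert len(e.intersect_regions(a, b, min_overlap_bp=1)[0]) == 1
        assert len(e.intersect_regions(a, b, min_overlap_bp=2)[0]) == 0

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), min_bp=st.integers(1, 30))
    def test_matches_quadratic_oracle(self, seed, min_bp):
        rng = np.random.default_rng(seed)
        a = random_region_set(rng, int(rng.integers(0, 60)))
        b = random_region_set(rng, int(rng.integers(0, 60)))
        pairs, st_ = e.intersect_regions(a, b, min_overlap_bp=min_bp)
        want = brute_force_pairs(a, b, min_bp)
        assert sorted(pairs) == sorted(want)
        assert st_.n_shared == len({p[0] for p in want})
        assert st_.n_shared_b == len({p[1] for p in want})


class TestSetOverlap:
    def make_lists(self, n_a, n_b, shared):
        common = [f"c{i}" for i in range(shared)]
        a = common + [f"a{i}" for i in range(n_a - shared)]
        b = common + [f"b{i}" for i in range(n_b - shared)]
        return a, b

    def test_printed_count_arithmetic(self):
        a, b = self.make_lists(62, 47, 9)
        st_ = e.set_overlap_stats(a, b)
        assert st_.rounded()[0] == 14.5
        assert st_.n_shared == 9

    def test_case_normalization_and_dedup(self):
        st_ = e.set_overlap_stats(["Axon Guidance", "axon guidance", "Wnt"],
                                  ["AXON GUIDANCE"])
        assert (st_.n_a, st_.n_b, st_.n_shared) == (2, 1, 1)

    def test_identity_and_disjoint(self):
        st_ = e.set_overlap_stats(["x", "y"], ["x", "y"])
        assert st_.pct_a_shared == 100.0 and st_.jaccard == 1.0
        st_ = e.set_overlap_stats(["x"], ["y"])
        assert st_.pct_a_shared == 0.0 and st_.jaccard == 0.0


class TestCpGContext:
    ISLANDS = RegionSet([("chr1", 10_000, 11_000)])

    @pytest.mark.parametrize("region, label", [
        (("chr1", 10_200, 10_300), "island"),
        (("chr1", 11_900, 12_000), "shore"),      # 1 kb from the island edge
        (("chr1", 13_500, 13_600), "shelf"),      # 2.5 kb away
        (("chr1", 21_000, 21_100), "open_sea"),   # 10 kb away
        (("chr2", 10_200, 10_300), "open_sea"),   # wrong chromosome
    ])
    def test_labels(self, region, label):
        ctx = e.annotate_cpg_context(RegionSet([region]), self.ISLANDS)
        assert ctx.labels == (label,)

    def test_every_region_gets_exactly_one_label(self):
        rng = np.random.default_rng(0)
        regions = RegionSet([("chr1", int(s), int(s) + 50)
                             for s in rng.integers(0, 40_000, size=50)])
        ctx = e.annotate_cpg_context(regions, self.ISLANDS)
        assert len(ctx.labels) == 50
        assert set(ctx.labels) <= {"island", "shore", "shelf", "open_sea"}
        assert sum(ctx.fractions.values()) == pytest.approx(1.0)

    def test_collapse_flanks_two_bucket_summary(self):
        regions = RegionSet([("chr1", 10_200, 10_300), ("chr1", 11_900, 12_000)])
        ctx = e.annotate_cpg_context(regions, self.ISLANDS, collapse_flanks=True)
        assert ctx.labels == ("island", "open_sea")

    def test_empty_islands_warns_all_open_sea(self):
        with pytest.warns(UserWarning, match="empty islands"):
            ctx = e.annotate_cpg_context(RegionSet([("chr1", 0, 10)]),
                                         RegionSet([]))
        assert ctx.labels == ("open_sea",)


class TestClustering:
    def planted_table(self, kappa=100.0, seed=0, n_per_group=4, n_sites=80):
        rng = np.random.default_rng(seed)
        means = np.full((n_sites, 2 * n_per_group), 0.3)
        means[:, n_per_group:] += 0.3
        beta = rng.beta(means * kappa, (1 - means) * kappa)
        cols = [f"g1_{i}" for i in range(n_per_group)] + \
               [f"g2_{i}" for i in range(n_per_group)]
        return pd.DataFrame(beta, columns=cols)

    def test_two_planted_groups_recovered(self):
        table = self.planted_table()
        labels = cluster_samples(table).cut(2)
        g1 = {labels[s] for s in table.columns[:4]}
        g2 = {labels[s] for s in table.columns[4:]}
        assert len(g1) == 1 and len(g2) == 1 and g1 != g2

    def test_duplicate_samples_merge_first_at_zero_height(self):
        table = self.planted_table(n_per_group=3)
        table["dup"] = table["g1_0"]
        res = cluster_samples(table)
        first = res.linkage[0]
        assert first[2] == 0.0  # zero merge height
        merged = {res.samples[int(first[0])], res.samples[int(first[1])]}
        assert merged == {"g1_0", "dup"}

    def test_permutation_invariance_of_cophenetic_structure(self):
        table = self.planted_table(seed=3)
        res1 = cluster_samples(table)
        perm = list(np.random.default_rng(1).permutation(table.columns))
        res2 = cluster_samples(table[perm])
        d1 = dict(zip(res1.samples, range(len(res1.samples))))
        coph1 = hierarchy.cophenet(res1.linkage)
        coph2 = hierarchy.cophenet(res2.linkage)

        def pairdist(coph, order, s, t):
            i, j = order[s], order[t]
            i, j = min(i, j), max(i, j)
            n = len(order)
            return coph[n * i + j - ((i + 2) * (i + 1)) // 2]

        d2 = dict(zip(res2.samples, range(len(res2.samples))))
        cols = list(table.columns)
        for s, t in [(cols[0], cols[5]), (cols[1], cols[2]), (cols[3], cols[7])]:
            assert pairdist(coph1, d1, s, t) == pytest.approx(
                pairdist(coph2, d2, s, t))

    def test_missing_cells_pairwise_complete_rescaling(self):
        table = pd.DataFrame({"a": [0.0, 0.0, 0.0, 0.0],
                              "b": [0.4, 0.4, np.nan, np.nan],
                              "c": [0.4, 0.4, 0.4, 0.4]})
        res = cluster_samples(table)
        # a-b observed on 2 of 4 sites: mean |diff| 0.4 rescaled to 4 sites
        ab = res.distances[0]
        ac = res.distances[1]
        assert ab == pytest.approx(ac) == pytest.approx(1.6)

    def test_no_shared_sites_raises_naming_pair(self):
        table = pd.DataFrame({"a": [0.1, np.nan], "b": [np.nan, 0.2]})
        with pytest.raises(ValueError, match="'a' and 'b'"):
            cluster_samples(table)
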