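"""PhyloCCF estimation and clonality classification."""

import numpy as np
import pytest

from phylogd import clonality


class TestMutationCopyNumber:
    @pytest.mark.parametrize(
        "vaf, purity, cn, expected",
        [
            (0.5, 1.0, 2, 1.0),     # fully clonal het diploid
            (1 / 3, 0.5, 4, 2.0),   # (vaf/mu)(mu*cn + 2(1-mu)) = (2/3)*3
            (0.25, 0.5, 2, 1.0),
        ],
    )
    def test_formula(self, vaf, purity, cn, expected):
        tot = 1000
        var = vaf * tot
        out = clonality.estimate_mutation_copy_number(np.array([var]), np.array([tot]), purity, np.array([cn]))
        assert out[0] == pytest.approx(expected)

    def test_zero_coverage_is_missing(self):
        out = clonality.estimate_mutation_copy_number(np.array([0]), np.array([0]), 0.5, np.array([2]))
        assert np.isnan(out[0])

    def test_invalid_purity(self):
        with pytest.raises(ValueError):
            clonality.estimate_mutation_copy_number(np.array([1]), np.array([2]), 0.0, np.array([2]))


class TestPhyloCCF:
    def test_clonal_cluster_mean_one(self):
        var = np.full(20, 50.0)
        tot = np.full(20, 100.0)
        ccf, _ = clonality.phyloccf_per_mutation(var, tot, 1.0, np.full(20, 2.0), np.full(20, 1.0))
        assert np.mean(ccf) == pytest.approx(1.0)

    def test_half_ccf_cluster(self):
        var = np.full(20, 25.0)
        tot = np.full(20, 100.0)
        ccf, _ = clonality.phyloccf_per_mutation(var, tot, 1.0, np.full(20, 2.0), np.full(20, 1.0))
        assert np.mean(ccf) == pytest.approx(0.5)

    def test_clipped_to_band(self):
        var = np.full(5, 100.0)
        tot = np.full(5, 100.0)
        ccf, _ = clonality.phyloccf_per_mutation(var, tot, 0.3, np.full(5, 2.0), np.full(5, 1.0))
        assert np.all(ccf <= clonality.CCF_CLIP)

    def test_simulated_subclone_recovered(self, rng):
        # 50 mutations at true CCF 0.6, 400x, purity 1, diploid
        true_vaf = 0.6 / 2
        tot = rng.poisson(400, size=50)
        var = rng.binomial(tot, true_vaf)
        ccf, _ = clonality.phyloccf_per_mutation(var, tot, 1.0, np.full(50, 2.0), np.full(50, 1.0))
        assert np.mean(ccf) == pytest.approx(0.6, abs=0.05)


class TestClusterStat:
    def test_ci_brackets_mean(self, rng):
        stat = clonality.cluster_stat(rng.normal(0.5, 0.05, size=40), rng=rng)
        assert stat.ci_lo <= stat.mean <= stat.ci_hi
        assert stat.n == 40

    def test_empty_is_missing(self):
        stat = clonality.cluster_stat(np.array([]))
        assert np.isnan(stat.mean)


class TestRegionClonality:
    def test_identical_to_truncal_is_clonal(self):
        vals = np.full(30, 1.0)
        assert clonality.classify_region_clonality(vals, vals) == "clonal"

    def test_zero_mean_is_absent(self):
        assert (
            clonality.classify_region_clonality(np.zeros(10), np.full(50, 1.0))
            == "absent"
        )

    def test_separated_cluster_is_subclonal(self, rng):
        cluster = rng.normal(0.4, 0.05, size=40)
        truncal = rng.normal(1.0, 0.05, size=200)
        status = clonality.classify_region_clonality(
            cluster, truncal, cluster_ci=(0.38, 0.42), truncal_ci=(0.99, 1.01)
        )
        assert status == "subclonal"

    def test_ci_overlap_with_floored_truncal_bound(self, rng):
        # cluster slightly below the truncal level: the 0.9 floor on the
        # truncal lower CI rescues clonality
        cluster = rng.normal(0.93, 0.02, size=30)
        truncal = rng.normal(1.0, 0.01, size=300)
        status = clonality.classify_region_clonality(
            cluster, truncal, cluster_ci=(0.92, 0.94), truncal_ci=(0.999, 1.001)
        )
        assert status == "clonal"

    def test_empty_truncal_invalid(self):
        with pytest.raises(ValueError):
            clonality.classify_region_clonality(np.ones(3), np.array([]))

    def test_raising_ccf_cannot_demote_clonal(self, rng):
        truncal = rng.normal(1.0, 0.05, size=100)
        base = rng.normal(0.95, 0.05, size=30)
        if clonality.classify_region_clonality(base, truncal) == "clonal":
            higher = base + 0.05
            assert clonality.classify_region_clonality(higher, truncal) == "clonal"


class TestTumourLevel:
    @pytest.mark.parametrize(
        "statuses, expected, illusion",
        [
            (["clonal", "clonal", "clonal"], "truncal", False),
            (["clonal", "absent"], "subclonal", True),
            (["subclonal", "subclonal"], "subclonal", False),
            (["absent", "absent"], "absent", False),
            (["clonal", "subclonal"], "subclonal", True),
        ],
    )
    def test_aggregation(self, statuses, expected, illusion):
        status, flag = clonality.tumour_level_clonality(statuses)
        assert status == expected
        assert flag is illusion

    def test_no_regions_invalid(self):
        with pytest.raises(ValueError):
            clonality.tumour_level_clonality([])
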