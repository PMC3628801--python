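import itertools

import numpy as np
import pytest
from scipy import stats

from recessmap.association import (CHI2_NULL_MEDIAN, allelic_chi2, attach_corrected,
                                   genomic_inflation, manhattan_table,
                                   max_t_permutation, run_gwas)
from recessmap.errors import DomainError
from recessmap.simulate import SimConfig, simulate_cohort

from conftest import make_dataset


class TestAllelicChi2:
    @pytest.mark.parametrize("table,chi2,p", [
        ((7, 7, 7, 7), 0.0, 1.0),
        ((14, 0, 2, 12), 21.0, 4.6e-6),       # the best-marker configuration
        ((14, 0, 0, 14), 28.0, 1.2e-7),
    ])
    def test_known_tables(self, table, chi2, p):
        res = allelic_chi2(*table)
        assert res.chi2 == pytest.approx(chi2, abs=1e-12)
        assert res.p == pytest.approx(p, rel=0.05)
        assert not res.degenerate

    def test_zero_margin_is_degenerate_not_error(self):
        res = allelic_chi2(0, 14, 0, 14)       # no alt allele anywhere
        assert (res.chi2, res.p, res.degenerate) == (0.0, 1.0, True)

    def test_symmetric_under_allele_relabelling(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, 4))
            assert allelic_chi2(a, b, c, d).chi2 == \
                pytest.approx(allelic_chi2(b, a, d, c).chi2, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            allelic_chi2(-1, 1, 1, 1)


class TestGenomicInflation:
    def test_null_quantiles_give_unit_lambda(self):
        n = 10_001
        quantiles = stats.chi2.ppf((np.arange(1, n + 1)) / (n + 1), df=1)
        assert genomic_inflation(quantiles) == pytest.approx(1.0, abs=1e-3)

    def test_scale_equivariance(self):
        values = [0.2, 0.7, 1.9, 3.3]
        assert genomic_inflation([2 * v for v in values]) == \
            pytest.approx(2 * genomic_inflation(values), rel=1e-12)

    def test_direct_arithmetic(self):
        assert genomic_inflation([0.1, 0.45, 2.0]) == \
            pytest.approx(0.45 / CHI2_NULL_MEDIAN, rel=1e-9)
        assert CHI2_NULL_MEDIAN == pytest.approx(0.4549364, abs=1e-7)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            genomic_inflation([])


class TestRunGwas:
    def test_identical_frequencies_give_p_one(self):
        ds = make_dataset([[1], [1]], ["case", "control"])
        res = run_gwas(ds)
        assert res[0].p_raw == pytest.approx(1.0)
        assert res[0].chi2 == 0.0

    def test_missing_genotypes_drop_both_alleles(self):
        ds = make_dataset([[2], [-1], [0], [0]],
                          ["case", "case", "control", "control"])
        r = run_gwas(ds)[0]
        assert (r.case_alt_count, r.case_ref_count) == (2, 0)
        assert (r.control_alt_count, r.control_ref_count) == (0, 4)

    def test_planted_signal_is_top_hit(self, default_sim):
        ds, truth = default_sim["ds"], default_sim["truth"]
        results = run_gwas(ds)
        best = min(range(len(results)), key=lambda i: results[i].p_raw)
        lo, hi = truth.planted_interval
        assert lo <= ds.markers[best].position_bp <= hi

    def test_empty_dataset_rejected(self, default_sim):
        with pytest.raises(DomainError):
            run_gwas(default_sim["ds"].subset_markers([]))


def _exhaustive_max_t(ds):
    """Exact max-T p-values over all case-labelings of a tiny cohort."""
    n = ds.n_samples
    n_cases = int(ds.case_mask.sum())
    case_idx = set(np.flatnonzero(ds.case_mask))

    def counts(cases, m):
        ca = cr = oa = orr = 0
        for s in range(n):
            g = int(ds.genotypes[s, m])
            if g < 0:
                continue
            if s in cases:
                ca += g
                cr += 2 - g
            else:
                oa += g
                orr += 2 - g
        return ca, cr, oa, orr

    obs = [allelic_chi2(*counts(case_idx, m)).chi2 for m in range(ds.n_markers)]
    maxes = np.array([
        max(allelic_chi2(*counts(set(combo), m)).chi2 for m in range(ds.n_markers))
        for combo in itertools.combinations(range(n), n_cases)])
    return np.array(obs), np.array([(maxes >= o - 1e-12).mean() for o in obs])


@pytest.fixture(scope="module")
def tiny():
    geno = np.array([[2, 1, 2], [2, 0, 1], [2, 2, 1], [1, 1, 0],
                     [0, 0, 0], [0, 1, 1], [0, 2, 0], [1, 0, 1]], dtype=np.int8)
    return make_dataset(geno, ["case"] * 4 + ["control"] * 4)


class TestMaxTPermutation:

    def test_matches_exhaustive_enumeration(self, tiny):
        # 4 cases vs 4 controls: C(8,4) = 70 labelings enumerated exactly
        n_perm = 50_000
        _, p_exact = _exhaustive_max_t(tiny)
        p_mc = max_t_permutation(tiny, n_perm, seed=7)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert np.all(np.abs(p_mc - p_exact) <= 3 * se + 2.0 / (n_perm + 1))

    def test_null_marker_gets_p_one(self):
        ds = make_dataset([[1], [1], [1], [1]],
                          ["case", "case", "control", "control"])
        assert max_t_permutation(ds, 500, seed=0)[0] == pytest.approx(1.0)

    def test_dominates_raw_p_on_genome_scale_panel(self):
        ds, _ = simulate_cohort(SimConfig(seed=5, n_markers=500))
        results = run_gwas(ds)
        p_corr = max_t_permutation(ds, 1000, seed=1)
        attach_corrected(results, p_corr)
        assert all(r.p_corrected >= r.p_raw - 1e-12 for r in results)

    def test_bit_reproducible(self, tiny):
        a = max_t_permutation(tiny, 2000, seed=123)
        b = max_t_permutation(tiny, 2000, seed=123)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, max_t_permutation(tiny, 2000, seed=124))

    def test_invalid_n_perm(self, tiny):
        with pytest.raises(DomainError):
            max_t_permutation(tiny, 0, seed=1)

    def test_shuffled_labels_rarely_reach_significance(self):
        # permuted-null cohorts should (almost) never yield corrected p < 0.05
        rng = np.random.default_rng(2024)
        flagged = 0
        for _ in range(20):
            geno = rng.binomial(2, rng.uniform(0.1, 0.5, 40), size=(14, 40)).astype(np.int8)
            ds = make_dataset(geno, ["case"] * 7 + ["control"] * 7)
            p_corr = max_t_permutation(ds, 500, seed=int(rng.integers(2**31)))
            flagged += p_corr.min() < 0.05
        assert flagged <= 2


class TestNullCalibration:
    def test_raw_p_tail_fraction_near_alpha(self):
        # a cohort large enough for the chi-square asymptotics to hold
        cfg = SimConfig(seed=0, n_cases=200, n_controls=200, ibd_segment=None,
                        missing_rate=0.0, genotype_error_rate=0.0)
        ds, _ = simulate_cohort(cfg)
        p = np.array([r.p_raw for r in run_gwas(ds)])
        alpha = 0.01
        se = np.sqrt(alpha * (1 - alpha) / p.size)
        assert abs((p < alpha).mean() - alpha) <= 3 * se
        # discreteness of the allele-count tables keeps the p-value
        # distribution slightly conservative; bound the KS distance instead
        # of asserting exact uniformity
        assert stats.kstest(p, "uniform").statistic <= 0.05


def test_manhattan_table_shape(default_sim):
    ds = default_sim["ds"]
    results = run_gwas(ds)
    table = manhattan_table(ds, results)
    assert len(table) == ds.n_markers
    assert {"marker", "chi2", "p_raw", "position_bp"} <= set(table.columns)
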