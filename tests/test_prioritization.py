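import numpy as np
import pytest

from recessmap.errors import ConfigurationError, DomainError
from recessmap.iomodel import ConsequenceCall, CriticalInterval, VariantRecord
from recessmap.prioritization import (PanelGenotypes, flag_snp_clusters,
                                      hard_filter_label, run_cascade)


def make_variant(pos=1000, chrom="chr1", ref="A", alt="G", gt="hom_alt", **qc):
    defaults = dict(qual=500.0, qd=15.0, mq0=0, dp=30, hrun=1, sb=-20.0)
    defaults.update(qc)
    return VariantRecord(chrom, pos, ref, alt, gt, **defaults)


class TestHardFilterLabel:
    def test_high_mq0_fraction_is_hard_to_validate(self):
        assert hard_filter_label(make_variant(mq0=4, dp=30)) == {"HardToValidate"}

    def test_clean_record_passes(self):
        assert hard_filter_label(make_variant(qual=100, qd=10, hrun=0,
                                              sb=-10.0, mq0=0)) == set()

    @pytest.mark.parametrize("qc", [
        {"qd": 4.9}, {"qual": 29.9}, {"hrun": 6}, {"sb": 0.01},
    ])
    def test_each_lowqual_clause_fires(self, qc):
        assert hard_filter_label(make_variant(**qc)) == {"LowQual"}

    def test_thresholds_are_strict_where_printed(self):
        # SB > 0.00 strict; QD < 5.0 strict; HRun > 5 strict; MQ0/DP > 0.1 strict
        assert hard_filter_label(make_variant(sb=0.0, qd=5.0, hrun=5, qual=30.0)) == set()
        assert hard_filter_label(make_variant(mq0=4, dp=40)) == set()   # ratio = 0.1

    def test_zero_depth_with_mq0_reads(self):
        assert "HardToValidate" in hard_filter_label(make_variant(mq0=1, dp=0))
        assert hard_filter_label(make_variant(mq0=0, dp=0)) == set()


class TestSnpClusters:
    def _snvs(self, positions):
        return [make_variant(pos=p) for p in positions]

    def test_three_snvs_within_window_all_flagged(self):
        assert flag_snp_clusters(self._snvs([100, 105, 109])) == [True] * 3

    def test_spread_snvs_unflagged(self):
        assert flag_snp_clusters(self._snvs([100, 105, 120])) == [False] * 3

    def test_pair_is_not_a_cluster(self):
        assert flag_snp_clusters(self._snvs([100, 101])) == [False, False]

    def test_indels_neither_count_nor_get_flagged(self):
        variants = [make_variant(pos=100), make_variant(pos=104, ref="AT", alt="A"),
                    make_variant(pos=108)]
        assert flag_snp_clusters(variants) == [False] * 3

    def test_overlapping_windows_merge(self):
        flags = flag_snp_clusters(self._snvs([100, 104, 108, 112, 300]))
        assert flags == [True, True, True, True, False]

    def test_unsorted_input_rejected(self):
        with pytest.raises(DomainError):
            flag_snp_clusters(self._snvs([200, 100, 300]))


def _cascade_fixture():
    """50 variants built so the cascade counts are exactly [32, 20, 10, 4, 2]."""
    interval = CriticalInterval("chr1", 10_000, 20_000)
    variants, panel_geno = [], {}
    pos = iter(range(1000, 200_000, 100))

    def add(in_interval, gt="hom_alt", in_panel=True, effect=None, **qc):
        p = next(pos)
        while in_interval != (10_000 <= p <= 20_000):
            p = next(pos)
        v = make_variant(pos=p, **qc, gt=gt)
        variants.append(v)
        panel_geno[v.variant_id] = (np.array([0, 1] + [0] * 10, dtype=np.int8)
                                    if in_panel else np.zeros(12, dtype=np.int8))
        return v

    consequences = {}
    # 18 filter-failures (various rules), genotypes irrelevant afterwards
    for i in range(18):
        add(in_interval=False, qd=2.0 if i % 2 else 25.0,
            sb=-5.0 if i % 2 else 1.5)
    # 12 PASS but not homozygous-alt
    for i in range(12):
        add(in_interval=False, gt=["het", "hom_ref", "missing"][i % 3])
    # 10 PASS hom_alt outside the interval
    for _ in range(10):
        add(in_interval=False)
    # 6 PASS hom_alt inside, carried by the panel
    for _ in range(6):
        add(in_interval=True)
    # 4 PASS hom_alt inside, panel-absent: 2 non-synonymous + 2 synonymous
    for effect in ("frameshift", "nonsense", "synonymous", "synonymous"):
        v = add(in_interval=True, in_panel=False)
        consequences[v.variant_id] = ConsequenceCall(
            "c.1del", "p.?", effect, 100, 50 if effect != "synonymous" else 100)
    panel = PanelGenotypes(genotypes=panel_geno, panel_size=12)
    return variants, interval, panel, consequences


class TestRunCascade:
    def test_constructed_counts(self):
        variants, interval, panel, consequences = _cascade_fixture()
        assert len(variants) == 50
        report = run_cascade(variants, interval, panel, consequences)
        assert report.as_dict() == {"filter_pass": 32, "total_homozygous": 20,
                                    "in_interval": 10, "absent_from_panel": 4,
                                    "nonsynonymous": 2}
        assert len(report.surviving_variants) == 2

    def test_counts_non_increasing(self):
        variants, interval, panel, consequences = _cascade_fixture()
        counts = [c for _, c in run_cascade(variants, interval, panel,
                                            consequences).steps]
        assert counts == sorted(counts, reverse=True)

    def test_intersection_steps_are_order_invariant(self):
        variants, interval, panel, consequences = _cascade_fixture()
        report = run_cascade(variants, interval, panel, consequences)
        # recompute the surviving set as an unordered intersection of predicates
        from recessmap.prioritization import apply_hard_filters, _panel_state
        apply_hard_filters(variants)
        expected = {v.variant_id for v in variants
                    if not v.filter_labels
                    and v.proband_genotype == "hom_alt"
                    and interval.start_bp <= v.position_bp <= interval.end_bp
                    and not _panel_state(panel, v.variant_id)[0]
                    and consequences.get(v.variant_id) is not None
                    and consequences[v.variant_id].effect in
                        {"missense", "nonsense", "frameshift"}}
        assert set(report.surviving_variants) == expected

    def test_missing_panel_genotypes_do_not_exclude(self):
        v = make_variant(pos=15_000)
        panel = PanelGenotypes({v.variant_id: np.array([-1] * 12, dtype=np.int8)}, 12)
        cons = {v.variant_id: ConsequenceCall("c.1A>G", "p.K1E", "missense", 10, 10)}
        report = run_cascade([v], CriticalInterval("chr1", 10_000, 20_000), panel, cons)
        assert report.surviving_variants == [v.variant_id]
        assert report.panel_missing[v.variant_id] == 12

    def test_empty_input_gives_zero_counts(self):
        report = run_cascade([], CriticalInterval("chr1", 1, 2_000),
                             PanelGenotypes({}, 12), {})
        assert all(c == 0 for _, c in report.steps)

    def test_chromosome_mismatch_detected(self):
        v = make_variant(chrom="2", pos=15_000)
        with pytest.raises(ConfigurationError):
            run_cascade([v], CriticalInterval("chr2", 10_000, 20_000),
                        PanelGenotypes({}, 12), {})


class TestCascadeOnSimulation:
    def test_planted_pair_survives_with_true_interval(self, default_sim):
        truth = default_sim["truth"]
        interval = CriticalInterval("chr2", *truth.planted_interval)
        report = run_cascade(default_sim["variants"], interval,
                             default_sim["panel"], default_sim["consequences"])
        survivors = set(report.surviving_variants)
        # the causal deletion survives every step, and so does the linked
        # nonsense passenger: genetics alone cannot separate the pair
        assert survivors == {truth.causal_variant_id, truth.passenger_variant_id}

    def test_adversarial_panel_carrier_eliminates_causal(self, default_sim):
        truth = default_sim["truth"]
        panel = default_sim["panel"]
        tampered = PanelGenotypes(dict(panel.genotypes), panel.panel_size)
        carrier = np.zeros(panel.panel_size, dtype=np.int8)
        carrier[0] = 1
        tampered.genotypes[truth.causal_variant_id] = carrier
        report = run_cascade(default_sim["variants"],
                             CriticalInterval("chr2", *truth.planted_interval),
                             tampered, default_sim["consequences"])
        assert truth.causal_variant_id not in report.surviving_variants
        assert truth.passenger_variant_id in report.surviving_variants
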