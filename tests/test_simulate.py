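import numpy as np
import pandas as pd
import pytest

from oracles import brute_metrics

from netreconf.metrics import METRIC_NAMES
from netreconf.simulate import (
    CohortSpec,
    default_atlas,
    events_from_assignments,
    generate_cohort,
    generate_subject,
    make_planted_truth,
    planted_metric_oracle,
)
from netreconf.windows import WindowSpec, make_windows


class TestPlantedTruth:
    def test_event_invariants(self):
        truth = make_planted_truth(0)
        for ev in truth.events:
            if ev.kind == "cohesive":
                assert len(ev.nodes) >= 2
            else:
                assert len(ev.nodes) == 1
            # events consistent with the assignment matrix
            lab = truth.assignments.labels
            for i in ev.nodes:
                assert lab[i, ev.transition] == ev.source
                assert lab[i, ev.transition + 1] == ev.dest

    def test_cohesive_groups_present(self):
        truth = make_planted_truth(1, n_cohesive_groups=5)
        assert any(ev.kind == "cohesive" for ev in truth.events)

    def test_events_round_trip_from_matrix(self):
        truth = make_planted_truth(2)
        assert events_from_assignments(truth.assignments) == truth.events

    def test_determinism(self):
        a = make_planted_truth(3)
        b = make_planted_truth(3)
        np.testing.assert_array_equal(a.assignments.labels, b.assignments.labels)


class TestMetricOracle:
    def test_no_events_means_no_flexibility(self):
        truth = make_planted_truth(4, n_disjoint_movers=0, n_cohesive_groups=0)
        m = planted_metric_oracle(truth)
        assert (m.node["flexibility"] == 0).all()

    def test_single_cohesive_pair_hand_values(self):
        from netreconf.communities import AssignmentMatrix
        from netreconf.simulate import PlantedTruth

        labels = np.array([[1, 1, 1, 1],
                           [1, 1, 2, 2],
                           [2, 2, 2, 2],
                           [1, 1, 2, 2]])
        am = AssignmentMatrix(labels, 4, list("abcd"))
        truth = PlantedTruth(am, events_from_assignments(am), 0.8, 0)
        m = planted_metric_oracle(truth)
        for node in ("b", "d"):  # the co-moving pair
            assert m.node.loc[node, "flexibility"] == pytest.approx(1 / 3)
            assert m.node.loc[node, "cohesion"] == pytest.approx(1 / 3)
            assert m.node.loc[node, "disjointedness"] == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equals_brute_force(self, seed):
        truth = make_planted_truth(seed, n_regions=12, n_windows=8, n_communities=4,
                                   atlas=default_atlas(12, 4), n_disjoint_movers=4,
                                   n_cohesive_groups=2, min_dwell=2)
        m = planted_metric_oracle(truth)
        brute = brute_metrics(truth.assignments.labels, 4)
        for name in METRIC_NAMES:
            np.testing.assert_allclose(m.node[name], brute[name], atol=1e-12)


class TestGenerateSubject:
    def test_default_geometry_aligns_with_windowing(self):
        truth = make_planted_truth(5)
        s = generate_subject(truth, seed=6)
        assert s.signals.shape == (200, 300)
        assert len(make_windows(s.n_timepoints, s.tr_seconds, WindowSpec())) == truth.n_windows

    def test_geometry_mismatch_reports_counts(self):
        truth = make_planted_truth(7, n_windows=10)
        with pytest.raises(ValueError, match="25.*10|10.*25"):
            generate_subject(truth, n_timepoints=300, seed=8)

    def test_full_coupling_separates_communities(self):
        atlas = default_atlas(16, 4)
        truth = make_planted_truth(9, n_regions=16, n_windows=7, n_communities=4,
                                   atlas=atlas, n_disjoint_movers=0,
                                   n_cohesive_groups=0, coupling=1.0)
        s = generate_subject(truth, n_timepoints=120, seed=10)
        corr = np.corrcoef(s.signals)
        init = atlas.to_int_labels(s.region_ids)
        same = init[:, None] == init[None, :]
        off = ~np.eye(16, dtype=bool)
        assert corr[same & off].min() > 0.99
        assert np.abs(corr[~same]).max() < 0.5

    def test_zero_coupling_decorrelates_everything(self):
        atlas = default_atlas(12, 4)
        truth = make_planted_truth(11, n_regions=12, n_windows=25, n_communities=4,
                                   atlas=atlas, n_disjoint_movers=0,
                                   n_cohesive_groups=0, coupling=0.0)
        s = generate_subject(truth, seed=12)
        corr = np.corrcoef(s.signals)
        off = ~np.eye(12, dtype=bool)
        # per-pair correlations are null; allow extreme-value slack on the max
        assert np.abs(corr[off]).mean() < 0.15
        assert np.quantile(np.abs(corr[off]), 0.9) < 0.30
        assert np.abs(corr[off]).max() < 0.5

    def test_variance_roughly_stationary(self):
        truth = make_planted_truth(13)
        s = generate_subject(truth, seed=14)
        first = s.signals[:, :150].var(axis=1)
        second = s.signals[:, 150:].var(axis=1)
        ratio = first / second
        # stationary in distribution: the typical region is balanced, with
        # single-region excursions bounded (slow in-band components make
        # per-realization half-variances fluctuate)
        assert 0.5 < np.median(ratio) < 2.0
        assert 0.5 < ratio.mean() < 2.0
        assert ratio.min() > 0.2 and ratio.max() < 5.0

    def test_determinism(self):
        truth = make_planted_truth(15)
        a = generate_subject(truth, seed=16)
        b = generate_subject(truth, seed=16)
        np.testing.assert_array_equal(a.signals, b.signals)


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        spec = CohortSpec(n_pwms=4, n_hc=3, seed=17)
        c1 = generate_cohort(spec, n_regions=20, make_series=True)
        c2 = generate_cohort(spec, n_regions=20, make_series=True)
        pd.testing.assert_frame_equal(c1.phenotypes, c2.phenotypes)
        for sid in c1.series:
            np.testing.assert_array_equal(c1.series[sid].signals, c2.series[sid].signals)

    def test_phenotype_schema_and_ranges(self):
        spec = CohortSpec(n_pwms=30, n_hc=10, seed=18)
        c = generate_cohort(spec, n_regions=20, make_series=False)
        ph = c.phenotypes
        assert (ph["group"].value_counts()["pwMS"], ph["group"].value_counts()["HC"]) == (30, 10)
        assert ph["fatigue_total"].between(0, 100).all()
        assert ph["fatigue_motor"].between(0, 50).all()
        assert ph.loc[ph.group == "HC", "edss"].isna().all()
        assert ph.loc[ph.group == "pwMS", "dmt_category"].notna().all()

    def test_null_effect_gives_null_correlation(self):
        spec = CohortSpec(effects={"disjointedness": {"fatigue_total": 0.0}}, seed=19)
        c = generate_cohort(spec, n_regions=30, make_series=False)
        ms = c.phenotypes[c.phenotypes.group == "pwMS"]
        r = np.corrcoef(c.planted.loc[ms.index, "disjointedness"], ms["fatigue_total"])[0, 1]
        assert abs(r) < 0.2

    def test_declared_effect_recovered_at_planted_level(self):
        rs = []
        for seed in range(10):
            spec = CohortSpec(effects={"disjointedness": {"fatigue_total": 0.24}},
                              seed=100 + seed)
            c = generate_cohort(spec, n_regions=30, make_series=False)
            ms = c.phenotypes[c.phenotypes.group == "pwMS"]
            rs.append(np.corrcoef(c.planted.loc[ms.index, "disjointedness"],
                                  ms["fatigue_total"])[0, 1])
        se = np.std(rs) / np.sqrt(len(rs))
        assert np.mean(rs) == pytest.approx(0.24, abs=max(3 * se, 0.04))

    def test_unattainable_effect_rejected(self):
        with pytest.raises(ValueError, match="effect"):
            CohortSpec(effects={"disjointedness": {"fatigue_total": 1.2}})
        with pytest.raises(ValueError):
            CohortSpec(effects={"disjointedness": {"fatigue_total": 0.8},
                                "flexibility": {"fatigue_total": 0.7}})

    def test_hc_fatigue_independent_of_metrics(self):
        spec = CohortSpec(n_pwms=10, n_hc=40, seed=20)
        c = generate_cohort(spec, n_regions=30, make_series=False)
        hc = c.phenotypes[c.phenotypes.group == "HC"]
        r = np.corrcoef(c.planted.loc[hc.index, "disjointedness"], hc["fatigue_total"])[0, 1]
        assert abs(r) < 0.45  # small-sample noise only
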