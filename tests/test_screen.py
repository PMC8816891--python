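import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nachr_hts as nh
from nachr_hts.errors import (DegeneratePlateError, InsufficientDataError,
                              UndefinedMetricError)
from nachr_hts.plates import Role


class TestBackgroundSubtraction:
    def _read(self, pairs):
        wells = [f"C{i + 3}" for i in range(len(pairs))]
        return nh.RawPlateRead("P", "R1", "A4B2",
                               {w: b for w, (b, _) in zip(wells, pairs)},
                               {w: f for w, (_, f) in zip(wells, pairs)})

    def test_simple_difference(self):
        net, flagged = nh.subtract_background(self._read([(100, 1000)]))
        assert net["C3"] == 900 and not flagged

    def test_identity_gives_zero(self):
        net, flagged = nh.subtract_background(self._read([(100, 100)]))
        assert net["C3"] == 0 and not flagged

    def test_negative_net_kept_and_flagged(self):
        net, flagged = nh.subtract_background(self._read([(100, 90)]))
        assert net["C3"] == -10
        assert flagged == ["C3"]


class TestNormalization:
    def _net(self, layout, test_value, zero=10.0, pos=1010.0):
        net = {}
        for w, role in layout.role_map.items():
            net[w] = {Role.ZERO_CONTROL: zero, Role.POS_CONTROL: pos}.get(role, test_value)
        return net

    @pytest.mark.parametrize("net_value,expected_nfs", [
        (10.0, 0.0), (1010.0, 1.0), (510.0, 0.5),
    ])
    def test_anchor_points(self, layout, net_value, expected_nfs):
        plate = nh.normalize_plate(self._net(layout, net_value), layout)
        test_well = layout.wells_with_role(Role.TEST)[0]
        assert plate.nfs[test_well] == pytest.approx(expected_nfs)
        assert plate.pct_inhibition[test_well] == pytest.approx(100 * (1 - expected_nfs))

    def test_control_means_anchored_exactly(self, layout, rng):
        net = {w: float(v) for w, v in zip(
            layout.role_map, rng.uniform(0, 2000, 384))}
        plate = nh.normalize_plate(net, layout)
        # the retained-control NFS means must anchor at exactly 0 and 1
        span = plate.retained_pos_net.mean() - plate.retained_zero_net.mean()
        zero_mean_nfs = np.mean([(v - plate.retained_zero_net.mean()) / span
                                 for v in plate.retained_zero_net])
        pos_mean_nfs = np.mean([(v - plate.retained_zero_net.mean()) / span
                                for v in plate.retained_pos_net])
        assert zero_mean_nfs == pytest.approx(0.0, abs=1e-12)
        assert pos_mean_nfs == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=0.2, max_value=5), st.floats(min_value=-50, max_value=50))
    def test_nfs_invariant_under_affine_raw_transform(self, layout, gain, offset):
        rng = np.random.default_rng(5)
        net = {w: float(v) for w, v in zip(layout.role_map, rng.uniform(0, 2000, 384))}
        p1 = nh.normalize_plate(net, layout)
        p2 = nh.normalize_plate({w: gain * v + offset for w, v in net.items()}, layout)
        w = layout.wells_with_role(Role.TEST)[17]
        assert p2.nfs[w] == pytest.approx(p1.nfs[w], rel=1e-9, abs=1e-9)

    def test_degenerate_plate_rejected(self, layout):
        with pytest.raises(DegeneratePlateError):
            nh.normalize_plate(self._net(layout, 500.0, zero=100.0, pos=100.0), layout)


class TestHitCalling:
    def test_zero_variance_threshold(self):
        t = nh.hit_threshold([1.0] * 20)
        assert t == pytest.approx(1.0)
        assert not nh.call_hits([1.0], t).any()  # strict: no hits possible

    def test_known_threshold_arithmetic(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std(ddof=1)  # mean 0, sd 1 exactly
        nfs = 0.98 + 0.05 * x
        assert nh.hit_threshold(nfs) == pytest.approx(0.98 - 3 * 0.05)

    def test_too_few_wells(self):
        with pytest.raises(InsufficientDataError):
            nh.hit_threshold([1.0] * 9)

    def test_exactly_at_threshold_is_not_hit(self):
        assert not nh.call_hits([0.8], 0.8).any()
        assert nh.call_hits([0.1], 0.8).all()

    @given(st.lists(st.floats(min_value=-1, max_value=2, allow_nan=False),
                    min_size=1, max_size=60),
           st.floats(min_value=-0.5, max_value=1.5))
    def test_vectorized_calls_match_per_well_oracle(self, nfs, threshold):
        expected = [v < threshold for v in nfs]  # brute-force rule, well by well
        assert list(nh.call_hits(nfs, threshold)) == expected


class TestConcordance:
    def test_equal_runs_r2_one(self, rng):
        x = rng.uniform(0, 1, 50)
        r2, slope, intercept = nh.replicate_concordance(x, x)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_affine_relation_r2_one(self, rng):
        x = rng.uniform(0, 1, 50)
        r2, slope, intercept = nh.replicate_concordance(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0)

    def test_uncorrelated_noise_near_zero(self):
        rng = np.random.default_rng(123)
        r2, *_ = nh.replicate_concordance(rng.standard_normal(1000),
                                          rng.standard_normal(1000))
        assert r2 < 0.05

    def test_zero_variance_predictor(self):
        with pytest.raises(UndefinedMetricError):
            nh.replicate_concordance([1.0] * 5, [1, 2, 3, 4, 5])


class TestRates:
    def test_adjusted_rate_alpha3beta4(self):
        rates = nh.rates_from_counts(77, 36, 2258, 2298)
        assert round(rates["adjusted_hit_rate"], 3) == 1.594
        assert round(rates["primary_hit_rate"], 2) == 3.41
        assert round(rates["pct_data_passed_qc"], 2) == 98.26

    def test_zero_hits_all_zero(self):
        rates = nh.rates_from_counts(0, 0, 100, 100)
        assert rates["primary_hit_rate"] == 0.0
        assert rates["adjusted_hit_rate"] == 0.0

    def test_zero_evaluable_undefined(self):
        with pytest.raises(UndefinedMetricError):
            nh.rates_from_counts(0, 0, 0, 100)

    def test_adjusted_never_exceeds_primary_all_flag_configurations(self):
        # enumerate every hit-flag configuration for a 4-compound duplicate run
        for flags in itertools.product([0, 1], repeat=8):
            run1, run2 = flags[:4], flags[4:]
            unique = sum(a or b for a, b in zip(run1, run2))
            both = sum(a and b for a, b in zip(run1, run2))
            rates = nh.rates_from_counts(unique, both, 4, 4)
            assert rates["adjusted_hit_rate"] <= rates["primary_hit_rate"]


class TestCompileScreenResult:
    def _plates(self, layout, nfs_by_compound, run_id, qc_ok=True):
        assign = dict(zip(sorted(layout.wells_with_role(Role.TEST))[:len(nfs_by_compound)],
                          nfs_by_compound))
        lay = layout.with_compounds(assign)
        net = {}
        for w, role in lay.role_map.items():
            if role is Role.ZERO_CONTROL:
                net[w] = 0.0
            elif role is Role.POS_CONTROL:
                net[w] = 100.0
            elif role is Role.TEST:
                net[w] = 100.0 * nfs_by_compound[lay.compound_map[w]]
            else:
                net[w] = 100.0
        plate = nh.normalize_plate(net, lay, plate_id=f"P_{run_id}", run_id=run_id)
        return plate

    def test_confirmed_requires_hit_in_every_run(self, layout):
        nfs1 = {"A": 0.1, "B": 0.95, "C": 1.0, **{f"X{i}": 1.0 for i in range(30)}}
        nfs2 = {"A": 0.1, "B": 0.2, "C": 1.0, **{f"X{i}": 1.0 for i in range(30)}}
        p1 = self._plates(layout, nfs1, "R1")
        p2 = self._plates(layout, nfs2, "R2")
        res = nh.compile_screen_result(
            {"R1": [p1], "R2": [p2]}, {"P_R1": True, "P_R2": True},
            list(nfs1), subtype="A4B2")
        t = res.table.set_index("compound_id")
        assert t.loc["A", "confirmed"]
        assert not t.loc["B", "confirmed"] and t.loc["B", "hit_R2"]
        assert res.n_unique_hits == 2 and res.n_confirmed_hits == 1

    def test_failed_plate_makes_compounds_non_evaluable(self, layout):
        nfs = {"A": 0.1, "B": 1.0, **{f"X{i}": 1.0 for i in range(30)}}
        p1 = self._plates(layout, nfs, "R1")
        p2 = self._plates(layout, nfs, "R2")
        res = nh.compile_screen_result(
            {"R1": [p1], "R2": [p2]}, {"P_R1": True, "P_R2": False},
            list(nfs), subtype="A4B2")
        assert res.n_evaluable == 0
        assert not res.table["confirmed"].any()
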