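import numpy as np
import pandas as pd
import pytest

import nachr_hts as nh
from nachr_hts.errors import ConfigurationError, DomainError
from nachr_hts.plates import Role


class TestDeterminism:
    def test_identical_seed_bit_identical_screen(self):
        manifest = nh.make_manifest(204)
        truth, _ = nh.default_truth_library(manifest, seed=3, group_plan={"ALL_THREE": 4})
        ctx = nh.DEFAULT_CONTEXTS["A4B2"]
        out = []
        for _ in range(2):
            reads, _, _ = nh.generate_screen(manifest, truth, ctx,
                                             nh.NoiseModel(seed=5), n_runs=1)
            out.append(reads)
        for r1, r2 in zip(*out):
            assert r1.final == r2.final and r1.baseline == r2.baseline

    def test_different_seed_differs(self):
        manifest = nh.make_manifest(204)
        truth, _ = nh.default_truth_library(manifest, seed=3, group_plan={})
        ctx = nh.DEFAULT_CONTEXTS["A4B2"]
        r1, _, _ = nh.generate_screen(manifest, truth, ctx, nh.NoiseModel(seed=5), 1)
        r2, _, _ = nh.generate_screen(manifest, truth, ctx, nh.NoiseModel(seed=6), 1)
        assert r1[0].final != r2[0].final

    def test_dose_response_seeded_repeatable(self):
        grid = 100e-6 / 3.0 ** np.arange(12)
        t1 = nh.generate_dose_response(0, 100, 1e-7, 1, grid, reps=4, cv=0.05, seed=8)
        t2 = nh.generate_dose_response(0, 100, 1e-7, 1, grid, reps=4, cv=0.05, seed=8)
        pd.testing.assert_frame_equal(t1, t2)


class TestNoiselessLimits:
    def _screen(self, truth_kwargs):
        manifest = nh.make_manifest(8)
        cid = manifest.compound_ids[0]
        truth = {c: nh.CompoundTruth(c) for c in manifest.compound_ids}
        truth[cid] = nh.CompoundTruth(cid, **truth_kwargs)
        noise = nh.NoiseModel(well_cv=0.0, plate_scale_sd=0.0, seed=0)
        reads, layouts, gt = nh.generate_screen(
            manifest, truth, nh.DEFAULT_CONTEXTS["A4B2"], noise, n_runs=1)
        read = reads[0]
        net, _ = nh.subtract_background(read)
        plate = nh.normalize_plate(net, layouts[read.plate_id])
        return cid, plate

    def test_full_inhibitor_nfs_zero(self):
        cid, plate = self._screen(dict(
            is_antagonist_at={"A4B2": True}, ic50={"A4B2": 1e-12},
            efficacy_ceiling=1.0))
        assert plate.compound_nfs()[cid] == pytest.approx(0.0, abs=1e-6)

    def test_inactive_compound_nfs_one(self):
        cid, plate = self._screen(dict(is_antagonist_at={"A4B2": False}))
        assert plate.compound_nfs()[cid] == pytest.approx(1.0, abs=1e-9)

    def test_pipeline_recovers_planted_inhibition_exactly(self):
        # noiseless end-to-end: pct inhibition equals the planted 4PL value
        truth_kwargs = dict(is_antagonist_at={"A4B2": True}, ic50={"A4B2": 10e-6},
                            efficacy_ceiling=0.8)
        cid, plate = self._screen(truth_kwargs)
        t = nh.CompoundTruth(cid, **truth_kwargs)
        planted = 100.0 * t.channel_inhibition("A4B2")  # 0.8/(1+1) = 40%
        assert planted == pytest.approx(40.0)
        well = next(w for w, c in plate.layout.compound_map.items() if c == cid)
        assert plate.pct_inhibition[well] == pytest.approx(planted, rel=1e-9)


class TestCompoundTruth:
    def test_inhibition_law(self):
        t = nh.CompoundTruth("C", {"A3B4": True}, {"A3B4": 10e-6},
                             hill=1.0, efficacy_ceiling=0.9)
        # at conc == ic50 the 4PL gives half the ceiling
        assert t.channel_inhibition("A3B4", 10e-6) == pytest.approx(0.45)
        assert t.channel_inhibition("A4B2", 10e-6) == 0.0

    def test_antagonist_without_ic50_rejected(self):
        with pytest.raises(ConfigurationError):
            nh.CompoundTruth("C", {"A3B4": True})

    def test_artifact_inhibition_only_in_fluorescence(self):
        t = nh.CompoundTruth("C", {"A3B4": False}, artifact_inhibition=0.8)
        assert t.channel_inhibition("A3B4") == 0.0
        assert t.fluorescence_inhibition("A3B4") == pytest.approx(0.8)

    def test_truth_missing_compound_rejected(self):
        manifest = nh.make_manifest(4)
        truth = {manifest.compound_ids[0]: nh.CompoundTruth(manifest.compound_ids[0])}
        with pytest.raises(ConfigurationError):
            nh.generate_screen(manifest, truth, nh.DEFAULT_CONTEXTS["A4B2"],
                               nh.NoiseModel(seed=0))


class TestDoseResponseGenerator:
    GRID = 100e-6 / 3.0 ** np.arange(12)

    def test_cv_zero_exactly_on_curve(self):
        tbl = nh.generate_dose_response(5, 95, 1e-7, 1.2, self.GRID, reps=2, cv=0.0)
        expected = nh.four_pl(tbl["conc_M"], 5, 95, 1e-7, 1.2)
        assert np.allclose(tbl["response"], expected)

    def test_dilution_series_lowest_conc(self):
        assert self.GRID.min() == pytest.approx(100e-6 / 3 ** 11)
        assert self.GRID.min() == pytest.approx(0.565e-9, rel=1e-2)

    def test_nonpositive_conc_rejected(self):
        with pytest.raises(DomainError):
            nh.generate_dose_response(0, 100, 1e-7, 1, [0.0, 1e-7], reps=1, cv=0)


class TestRealizedNoise:
    def test_control_cv_within_factor_two_of_target(self):
        """Monte-Carlo over 120 simulated plates: the realized positive-control
        CV tracks the requested well CV."""
        manifest = nh.make_manifest(204)
        truth = {c: nh.CompoundTruth(c) for c in manifest.compound_ids}
        noise = nh.NoiseModel(well_cv=0.05, seed=13)
        rng = noise.rng()
        ctx = nh.DEFAULT_CONTEXTS["A4B2"]
        cvs = []
        for _ in range(60):  # 60 generate calls x 2 runs = 120 plates
            reads, layouts, _ = nh.generate_screen(manifest, truth, ctx, noise,
                                                   n_runs=2, rng=rng)
            for read in reads:
                net, _ = nh.subtract_background(read)
                pos = [net[w] for w in layouts[read.plate_id].wells_with_role(Role.POS_CONTROL)]
                cvs.append(nh.coefficient_of_variation(pos))
        cvs = np.array(cvs)
        assert 0.5 * 0.05 < cvs.mean() < 2.0 * 0.05
        # per-plate CVs live inside a plausible screening range
        assert np.percentile(cvs, 99) < 0.12

    def test_realized_z_prime_in_excellent_band(self):
        """Across 100 simulated plates the default generator yields Z' in
        the excellent-assay band [0.6, 0.95]."""
        manifest = nh.make_manifest(204)
        truth = {c: nh.CompoundTruth(c) for c in manifest.compound_ids}
        noise = nh.NoiseModel(seed=17)
        rng = noise.rng()
        zs = []
        for subtype in nh.SUBTYPES:
            for _ in range(17):
                reads, layouts, _ = nh.generate_screen(
                    manifest, truth, nh.DEFAULT_CONTEXTS[subtype], noise,
                    n_runs=2, rng=rng)
                for read in reads:
                    net, _ = nh.subtract_background(read)
                    lay = layouts[read.plate_id]
                    pos = [net[w] for w in lay.wells_with_role(Role.POS_CONTROL)]
                    zero = [net[w] for w in lay.wells_with_role(Role.ZERO_CONTROL)]
                    zs.append(nh.z_prime(pos, zero))
        zs = np.array(zs)
        assert zs.size >= 100
        assert np.all(zs >= 0.6) and np.all(zs <= 0.95)

    def test_edge_bias_applied_only_to_border_wells(self):
        manifest = nh.make_manifest(8)
        truth = {c: nh.CompoundTruth(c) for c in manifest.compound_ids}
        ctx = nh.DEFAULT_CONTEXTS["A4B2"]
        clean, layouts, _ = nh.generate_screen(
            manifest, truth, ctx, nh.NoiseModel(well_cv=0, plate_scale_sd=0, seed=0), 1)
        biased, _, _ = nh.generate_screen(
            manifest, truth, ctx,
            nh.NoiseModel(well_cv=0, plate_scale_sd=0, edge_bias=0.3, seed=0), 1)
        lay = layouts[clean[0].plate_id]
        edge = lay.wells_with_role(Role.EDGE_EXCLUDED)[0]
        interior = lay.wells_with_role(Role.POS_CONTROL)[0]
        assert biased[0].final[edge] > clean[0].final[edge]
        assert biased[0].final[interior] == clean[0].final[interior]


class TestPlantedLibrary:
    def test_group_plan_sizes(self):
        manifest = nh.make_manifest(2298)
        truth, groups = nh.default_truth_library(manifest, seed=1)
        counts = groups.value_counts()
        assert counts["A3B4_ONLY"] == 26 and counts["A4B2_ONLY"] == 6
        assert counts["A6_ONLY"] == 5 and counts["BOTH_B2"] == 20
        assert counts["ALL_THREE"] == 10 and counts["NOT_VALIDATED"] == 15
        assert counts["INACTIVE"] == 2298 - 82

    def test_a3b4_selectives_mostly_high_efficacy(self):
        manifest = nh.make_manifest(500)
        truth, groups = nh.default_truth_library(manifest, seed=2)
        sel = [truth[c] for c in groups[groups == "A3B4_ONLY"].index]
        high = [t for t in sel if t.channel_inhibition("A3B4") > 0.75]
        assert len(sel) == 26 and len(high) == 24

    def test_not_validated_are_pure_artifacts(self):
        manifest = nh.make_manifest(500)
        truth, groups = nh.default_truth_library(manifest, seed=2)
        for cid in groups[groups == "NOT_VALIDATED"].index:
            t = truth[cid]
            assert all(t.channel_inhibition(s) == 0 for s in nh.SUBTYPES)
            assert t.artifact_inhibition >= 0.75
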