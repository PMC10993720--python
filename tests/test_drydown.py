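"""Conductance curves and the RWC-plateau g_min estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmincanopy.drydown import (
    DrydownRecord,
    GminEstimationError,
    aggregate_gmin,
    compute_rwc,
    conductance_curve,
    estimate_gmin,
    leaf_area_from_sla,
)
from gmincanopy.psychro import AirState
from gmincanopy.simulate import DrydownSimParams, simulate_drydown

CHAMBER = AirState(20.0, 69.0, 98.0)


class TestComputeRwc:
    @pytest.mark.parametrize(
        "w_fre, w_sat, w_dry, expected",
        [(10.0, 10.0, 4.0, 1.0), (4.0, 10.0, 4.0, 0.0), (8.5, 10.0, 4.0, 0.75)],
    )
    def test_values(self, w_fre, w_sat, w_dry, expected):
        rwc, flagged = compute_rwc(w_fre, w_sat, w_dry)
        assert rwc == pytest.approx(expected) and not flagged

    def test_clamped_with_flag(self):
        rwc, flagged = compute_rwc(10.2, 10.0, 4.0)
        assert rwc == 1.0 and flagged

    def test_degenerate_references_rejected(self):
        with pytest.raises(ValueError):
            compute_rwc(5.0, 4.0, 4.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        scale=st.floats(0.1, 100.0),
        frac=st.floats(0.0, 1.0),
    )
    def test_mass_scale_invariance(self, scale, frac):
        """Multiplying all masses by a constant leaves RWC unchanged."""
        w_sat, w_dry = 10.0, 4.0
        w_fre = w_dry + frac * (w_sat - w_dry)
        base, _ = compute_rwc(w_fre, w_sat, w_dry)
        scaled, _ = compute_rwc(w_fre * scale, w_sat * scale, w_dry * scale)
        assert scaled == pytest.approx(base, abs=1e-9)


class TestLeafArea:
    def test_broadleaf_two_sided(self):
        assert leaf_area_from_sla(15.0, 0.0004, 2.0) == pytest.approx(0.012)

    def test_projected_passthrough(self):
        assert leaf_area_from_sla(15.0, 0.0004, 1.0) == pytest.approx(0.006)

    def test_needle_factor(self):
        assert leaf_area_from_sla(5.0, 0.001, 2.57) == pytest.approx(2.57 * 5.0 * 0.001)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            leaf_area_from_sla(0.0, 0.001)


def _two_point_record(mass_loss=0.010, dt=7200.0, area=0.003):
    return DrydownRecord(
        sample_id="hand",
        times=np.array([0.0, dt]),
        masses=np.array([8.5, 8.5 - mass_loss]),
        w_sat=8.5,
        w_dry=4.0,
        area_two_sided=area,
        chamber=CHAMBER,
    )


class TestConductanceCurve:
    def test_hand_evaluated_conductance(self):
        """0.010 g over 2 h on 0.003 m2 at 20 degC/69%/98 kPa -> J ~ 3.47."""
        curve = conductance_curve(_two_point_record())
        assert curve.conductance[0] == pytest.approx(3.474, abs=2e-3)

    def test_zero_loss_zero_conductance(self):
        curve = conductance_curve(_two_point_record(mass_loss=0.0))
        assert curve.conductance[0] == 0.0

    def test_doubling_area_halves_conductance(self):
        j1 = conductance_curve(_two_point_record(area=0.003)).conductance[0]
        j2 = conductance_curve(_two_point_record(area=0.006)).conductance[0]
        assert j2 == pytest.approx(j1 / 2)

    def test_mass_gain_interval_excluded(self):
        rec = DrydownRecord(
            sample_id="gain",
            times=np.array([0.0, 7200.0, 14400.0]),
            masses=np.array([8.5, 8.49, 8.495]),
            w_sat=8.5,
            w_dry=4.0,
            area_two_sided=0.003,
            chamber=CHAMBER,
        )
        curve = conductance_curve(rec)
        assert curve.excluded.tolist() == [False, True]

    def test_interval_rwc_is_endpoint_mean(self):
        curve = conductance_curve(_two_point_record(mass_loss=0.9))
        rwc0 = (8.5 - 4.0) / 4.5
        rwc1 = (7.6 - 4.0) / 4.5
        assert curve.mean_rwc[0] == pytest.approx(0.5 * (rwc0 + rwc1))

    def test_saturated_chamber_rejected(self):
        rec = DrydownRecord(
            sample_id="sat",
            times=np.array([0.0, 7200.0]),
            masses=np.array([8.5, 8.49]),
            w_sat=8.5,
            w_dry=4.0,
            area_two_sided=0.003,
            chamber=AirState(20.0, 100.0, 98.0),
        )
        with pytest.raises(ValueError, match="VPD"):
            conductance_curve(rec)


class TestEstimateGmin:
    def _plateau_curve(self, j=2.0, rwc=(0.78, 0.70, 0.62, 0.55)):
        rec = simulate_drydown(
            DrydownSimParams(true_gmin=j, closure_rwc=1.0, balance_sd=0.0)
        )
        return conductance_curve(rec)

    def test_noiseless_plateau_exact(self):
        est = estimate_gmin(self._plateau_curve(j=2.0))
        assert est.gmin == pytest.approx(2.0, rel=1e-3)
        assert not est.qc_flags

    def test_window_occupancy_error_names_window(self):
        curve = self._plateau_curve()
        with pytest.raises(GminEstimationError, match="RWC window"):
            estimate_gmin(curve, window=(0.05, 0.10))

    def test_entirely_above_window_errors(self):
        rec = simulate_drydown(
            DrydownSimParams(balance_sd=0.0, duration=18000.0, weighing_interval=3600.0)
        )
        curve = conductance_curve(rec)
        assert curve.mean_rwc.min() > 0.80
        with pytest.raises(GminEstimationError):
            estimate_gmin(curve)

    def test_generator_oracle_recovery(self):
        rec = simulate_drydown(DrydownSimParams(true_gmin=2.0, seed=1))
        est = estimate_gmin(conductance_curve(rec))
        assert est.gmin == pytest.approx(2.0, rel=0.05)

    def test_sloped_plateau_flagged_not_rejected(self):
        curve = self._plateau_curve()
        curve.conductance[:] = 2.0 + 30.0 * curve.mean_rwc  # steep trend
        est = estimate_gmin(curve)
        assert "plateau-not-horizontal" in est.qc_flags

    @pytest.mark.parametrize("gmin", [0.5, 2.0, 10.0])
    @pytest.mark.parametrize("area", [0.001, 0.004, 0.01])
    @pytest.mark.parametrize("rh", [40.0, 69.0, 85.0])
    def test_noiseless_oracle_equivalence_sweep(self, gmin, area, rh):
        """Noiseless drydowns return the true conductance to <0.1% across
        conductance, leaf area and chamber humidity."""
        from gmincanopy.drydown import WATER_MOLAR_MASS
        from gmincanopy.psychro import vpd as _vpd

        chamber = AirState(20.0, rh, 98.0)
        duration, interval = 108000.0, 9000.0
        # size the water pool so the noiseless trajectory ends near RWC 0.4,
        # guaranteeing plateau-window occupancy for every combination
        rate = gmin * area * _vpd(chamber) / 98.0 * WATER_MOLAR_MASS / 1000.0
        water = rate * duration / 0.6
        p = DrydownSimParams(
            true_gmin=gmin,
            stomatal_g0=gmin * 6,
            closure_rwc=1.0,
            leaf_area_two_sided=area,
            balance_sd=0.0,
            chamber=chamber,
            w_sat=0.25 + water,
            w_dry=0.25,
            duration=duration,
            weighing_interval=interval,
        )
        rec = simulate_drydown(p)
        est = estimate_gmin(conductance_curve(rec), min_intervals=2)
        assert est.gmin == pytest.approx(gmin, rel=1e-3)


class TestAggregation:
    def _leaf_table(self):
        rows = []
        # species A: two trees with tree-mean 2.0 and 4.0; species B: one tree 1.0
        for tree, leaf_vals in [("A-t1", [1.5, 2.5]), ("A-t2", [3.5, 4.5])]:
            for i, v in enumerate(leaf_vals):
                rows.append({"species": "A", "tree_id": tree, "gmin": v})
        rows.append({"species": "B", "tree_id": "B-t1", "gmin": 1.0})
        return pd.DataFrame(rows)

    def test_hierarchical_means(self):
        agg = aggregate_gmin(self._leaf_table())
        tree = agg["tree"].set_index("tree_id")
        assert tree.loc["A-t1", "mean"] == pytest.approx(2.0)
        assert tree.loc["A-t2", "mean"] == pytest.approx(4.0)
        species = agg["species"].set_index("species")
        assert species.loc["A", "mean"] == pytest.approx(3.0)  # mean of tree means
        assert species.loc["A", "se"] == pytest.approx(1.0)  # sd(2,4)/sqrt(2)

    def test_single_member_group_has_no_se(self):
        agg = aggregate_gmin(self._leaf_table())
        species = agg["species"].set_index("species")
        assert species.loc["B", "mean"] == pytest.approx(1.0)
        assert np.isnan(species.loc["B", "se"])

    def test_functional_group_level(self):
        agg = aggregate_gmin(
            self._leaf_table(), functional_groups={"A": "broadleaf", "B": "conifer"}
        )
        grp = agg["group"].set_index("group")
        assert grp.loc["broadleaf", "mean"] == pytest.approx(3.0)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            aggregate_gmin(pd.DataFrame({"species": ["A"], "gmin": [1.0]}))
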