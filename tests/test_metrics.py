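"""Estimators, classification rules and hypothesis tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gillflux as gf
from gillflux.metrics import AnalysisConfig, MannitolAssayRecord
from gillflux.simulator import RECORD_COLUMNS, TransportParams


def _record(compartment, time_h, dpm, donor_side="apical", insert_id="i1", mode="BTA"):
    row = {c: "" for c in RECORD_COLUMNS}
    row.update(
        insert_id=insert_id,
        replicate_id=insert_id,
        scenario="manual",
        drug="propranolol",
        condition="asymmetric",
        mode=mode,
        donor_side=donor_side,
        compartment=compartment,
        time_h=time_h,
        aliquot_volume_ml=0.1,
        dpm=dpm,
        ter_kohm_cm2=18.1,
        apical_ph=7.7,
    )
    return row


class TestTerGate:
    def test_threshold_with_tie_retained(self):
        inserts = [("a", 3.0), ("b", 5.0), ("c", 18.1)]
        assert gf.ter_gate(inserts) == ["b", "c"]

    def test_empty_and_all_below(self):
        assert gf.ter_gate([]) == []
        assert gf.ter_gate([("a", 1.0), ("b", 4.9)]) == []

    def test_idempotent_and_order_preserving(self):
        inserts = [("z", 9.0), ("a", 7.0), ("m", 12.0)]
        once = gf.ter_gate(inserts)
        assert once == ["z", "a", "m"]
        assert gf.ter_gate([(i, 99.0) for i in once]) == once

    def test_negative_ter_rejected(self):
        with pytest.raises(ValueError):
            gf.ter_gate([("a", -1.0)])


class TestMannitolPermeability:
    def test_blank_insert_value(self):
        rec = MannitolAssayRecord(
            delta_m_bl=41057.0, m_ap=2.2e5, donor_volume=1.5, duration=24.0, area=0.9
        )
        assert gf.mannitol_permeability(rec) == pytest.approx(3.6e-6, rel=1e-3)

    def test_zero_transfer(self):
        rec = MannitolAssayRecord(delta_m_bl=0.0, m_ap=2.2e5)
        assert gf.mannitol_permeability(rec) == 0.0

    @pytest.mark.parametrize(
        "kwargs", [dict(m_ap=0.0), dict(duration=0.0), dict(area=0.0)]
    )
    def test_invalid_inputs_rejected(self, kwargs):
        base = dict(delta_m_bl=100.0, m_ap=1e5, donor_volume=1.5, duration=24.0, area=0.9)
        base.update(kwargs)
        with pytest.raises(ValueError):
            MannitolAssayRecord(**base)

    def test_equivalent_to_papp_on_same_trajectory(self, compounds, noise_off):
        """The tracer formula and the Papp estimator are the same statistic.

        On one simulated cell-free-insert trajectory, converting the counts
        of the start/end samples the two ways gives the same permeability.
        """
        mannitol = compounds["mannitol"]
        insert = gf.InsertConfig(apical_medium="freshwater", ter=0.0)
        design = gf.AssayDesign(
            mode="BTA", donor_side="apical", sampling_times=(0.0, 24.0)
        )
        res = gf.simulate(
            insert, TransportParams(p_trans=0.0), design, mannitol, noise=noise_off
        )
        config = AnalysisConfig(papp_time=24.0)
        papp = gf.papp_6h(res.records, mannitol, config).papp

        df = res.records.set_index(["compartment", "time_h"])["dpm"] / 0.1  # dpm/mL
        m_ap = df.loc[("apical", 0.0)] * 1.5
        m_bl_end = df.loc[("basal", 24.0)] * (2.0 - 0.1) + df.loc[("basal", 0.0)] * 0.1
        rec = MannitolAssayRecord(
            delta_m_bl=m_bl_end - df.loc[("basal", 0.0)] * 2.0, m_ap=m_ap
        )
        assert gf.mannitol_permeability(rec) == pytest.approx(papp, rel=1e-9)


class TestPapp:
    def test_asymmetric_uptake_example(self, propranolol):
        """Donor 1.5 mL at 1 ug/L, receiver gains 0.0525 ng in 6 h -> 2.7e-6 cm/s."""
        sa = propranolol.specific_activity
        c0 = gf.mass_conc_to_molar(1.0, propranolol.molecular_weight)  # pmol/mL
        gained_pmol = 0.0525e3 / propranolol.molecular_weight  # 0.0525 ng
        conc_basal_6h = gained_pmol / (2.0 - 0.1)  # receiver volume after t=0 aliquot
        rows = [
            _record("apical", 0.0, gf.amount_to_dpm(c0 * 0.1, sa)),
            _record("basal", 0.0, 0.0),
            _record("basal", 6.0, gf.amount_to_dpm(conc_basal_6h * 0.1, sa)),
        ]
        res = gf.papp_6h(pd.DataFrame(rows), propranolol)
        assert res.direction == "A:B"
        assert res.papp == pytest.approx(2.7e-6, rel=1e-3)

    def test_zero_gain_gives_zero(self, propranolol):
        sa = propranolol.specific_activity
        rows = [
            _record("apical", 0.0, gf.amount_to_dpm(0.4, sa)),
            _record("basal", 0.0, 0.0),
            _record("basal", 6.0, 0.0),
        ]
        assert gf.papp_6h(pd.DataFrame(rows), propranolol).papp == 0.0

    def test_missing_samples_named(self, propranolol):
        rows = [_record("basal", 0.0, 0.0), _record("basal", 6.0, 10.0)]
        with pytest.raises(ValueError, match="donor sample at t=0"):
            gf.papp_6h(pd.DataFrame(rows), propranolol)
        rows = [_record("apical", 0.0, 100.0), _record("basal", 0.0, 0.0)]
        with pytest.raises(ValueError, match="receiver sample at t=6"):
            gf.papp_6h(pd.DataFrame(rows), propranolol)

    def test_recovers_known_permeability_within_5_percent(
        self, propranolol, noise_off
    ):
        """Closed-form oracle: at <10% donor depletion the 0->6 h two-point
        slope recovers the generating permeability within 5%."""
        p_eff = 3.0e-6
        params = TransportParams(
            p_trans=p_eff / propranolol.neutral_fraction(7.4), paracellular_scale=0.0
        )
        res = gf.simulate(
            gf.InsertConfig(), params, gf.AssayDesign(), propranolol, noise=noise_off
        )
        depletion = 1.0 - res.apical_conc[1] / res.apical_conc[0]
        assert depletion < 0.10
        est = gf.papp_6h(res.records, propranolol).papp
        assert est == pytest.approx(p_eff, rel=0.05)


class TestTransportRatio:
    def test_equal_papp_unity_no_flags(self):
        tr = gf.transport_ratio(1e-6, 1e-6)
        assert tr.uptake_tr == tr.efflux_tr == 1.0
        assert not tr.active_uptake and not tr.active_efflux

    def test_flagging_at_threshold(self):
        tr = gf.transport_ratio(3.21e-6, 1e-6)
        assert tr.active_uptake and not tr.active_efflux
        assert gf.transport_ratio(1.5e-6, 1e-6).active_uptake  # tie is active

    def test_zero_papp_rejected(self):
        with pytest.raises(ValueError):
            gf.transport_ratio(1e-6, 0.0)

    @given(
        ab=st.floats(min_value=1e-9, max_value=1e-3),
        ba=st.floats(min_value=1e-9, max_value=1e-3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_uptake_times_efflux_is_one(self, ab, ba):
        tr = gf.transport_ratio(ab, ba)
        assert tr.uptake_tr * tr.efflux_tr == pytest.approx(1.0, rel=1e-12)


class TestTimeCourses:
    def test_percent_of_donor_trivial_values(self, propranolol, noise_off):
        params = TransportParams(p_trans=0.0, paracellular_scale=0.0)
        res = gf.simulate(
            gf.InsertConfig(), params, gf.AssayDesign(), propranolol, noise=noise_off
        )
        pct = gf.percent_of_donor(res.records, propranolol)
        donor = pct[pct["compartment"] == "apical"]
        receiver = pct[pct["compartment"] == "basal"]
        np.testing.assert_allclose(donor["percent"], 100.0, rtol=1e-12)
        np.testing.assert_allclose(receiver["percent"], 0.0, atol=1e-12)

    def test_percent_of_donor_requires_t0(self, propranolol):
        rows = [_record("basal", 6.0, 10.0)]
        with pytest.raises(ValueError):
            gf.percent_of_donor(pd.DataFrame(rows), propranolol)

    def test_uptake_curve_exceeds_efflux_curve(self, compounds, noise_off):
        """Calibrated asymmetric propranolol: receiver gain is larger when
        dosing apically than basally at every time from 6 h on."""
        from gillflux.catalog import DRUG_PARAMS

        prop = compounds["propranolol"]
        curves = {}
        for donor in ("apical", "basal"):
            res = gf.simulate(
                gf.InsertConfig(apical_medium="freshwater"),
                DRUG_PARAMS["propranolol"],
                gf.AssayDesign(mode="BTA", donor_side=donor),
                prop,
                noise=noise_off,
            )
            pct = gf.percent_of_donor(res.records, prop)
            receiver = "basal" if donor == "apical" else "apical"
            curves[donor] = (
                pct[pct["compartment"] == receiver].set_index("time_h")["percent"]
            )
        for t in (6.0, 24.0, 30.0, 48.0):
            assert curves["apical"][t] > curves["basal"][t]

    def test_ceta_t0_is_100_both_sides(self, propranolol, noise_off):
        from gillflux.catalog import DRUG_PARAMS

        res = gf.simulate(
            gf.InsertConfig(apical_medium="freshwater"),
            DRUG_PARAMS["propranolol"],
            gf.AssayDesign(mode="CETA"),
            propranolol,
            noise=noise_off,
        )
        pct = gf.ceta_percent_initial(res.records, propranolol)
        at0 = pct[pct["time_h"] == 0.0]
        np.testing.assert_allclose(at0["percent"], 100.0, rtol=1e-12)
        # uptake carrier moves drug into the basal side over time
        end = pct[pct["time_h"] == 48.0].set_index("compartment")["percent"]
        assert end["basal"] > 100.0 > end["apical"]


class TestInhibitionPercent:
    def test_arithmetic(self):
        controls = [2.0e-6, 2.5e-6, 3.0e-6]
        mean = np.mean(controls)
        assert gf.inhibition_percent_of_control([mean], controls)[0] == pytest.approx(
            100.0
        )
        assert gf.inhibition_percent_of_control(
            [0.699 * mean], controls
        )[0] == pytest.approx(69.9)
        assert np.mean(
            gf.inhibition_percent_of_control(controls, controls)
        ) == pytest.approx(100.0)

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValueError):
            gf.inhibition_percent_of_control([1.0], [])
        with pytest.raises(ValueError):
            gf.inhibition_percent_of_control([1.0], [0.0, 0.0])


class TestHypothesisTests:
    def test_pooled_t_textbook_pair(self):
        t, df, p = gf.ttest_equal_var([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_identical_constant_groups(self):
        t, df, p = gf.ttest_equal_var([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            gf.ttest_equal_var([1.0, 1.0], [2.0, 2.0])

    def test_power_on_separated_groups(self):
        """3-SD true separation at n=5 is detected in nearly all replicates."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0.0, 1.0, 5)
            b = rng.normal(3.0, 1.0, 5)
            _, _, p = gf.ttest_equal_var(a, b)
            hits += p < 0.05
        assert hits / n_rep > 0.95

    def test_anova_identical_groups(self):
        f, df1, df2, p = gf.anova_log([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_anova_two_groups_equals_t_squared(self):
        a, b = [1.1, 2.3, 3.2, 1.9], [2.4, 3.5, 2.8]
        f, _, _, p_f = gf.anova_log([a, b])
        t, _, p_t = gf.ttest_equal_var(np.log(a), np.log(b))
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_anova_three_groups_brute_force(self):
        """Hand-computed sums of squares on the log scale."""
        groups = [[1.0, 1.5, 2.0], [2.0, 2.5, 3.0], [4.0, 5.0, 6.0]]
        logged = [np.log(g) for g in groups]
        grand = np.mean(np.concatenate(logged))
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in logged)
        ss_within = sum(((g - np.mean(g)) ** 2).sum() for g in logged)
        f_expected = (ss_between / 2) / (ss_within / 6)
        f, df1, df2, _ = gf.anova_log(groups)
        assert (df1, df2) == (2, 6)
        assert f == pytest.approx(f_expected, rel=1e-12)

    def test_anova_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="non-positive"):
            gf.anova_log([[1.0, 2.0], [0.0, 3.0]])
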