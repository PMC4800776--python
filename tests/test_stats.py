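"""Scattering-group classification, PE slopes, dPE differencing,
regressions, and clustered/marginal/baseline inference."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coraloptics as co
from coraloptics.datamodel import Group
from coraloptics.stats import (
    baseline_compare,
    cell_pe_table,
    classify_scattering_group,
    clustered_rate_model,
    delta_pe,
    marginal_day_comparison,
    pe_slope,
    regress_depe,
)


class TestClassify:
    def test_threshold_with_tie_to_high(self):
        profs = [co.OpticalProfile(species=s, mu_sm=m, r_s=0.5) for s, m in [("a", 2), ("b", 3), ("c", 4)]]
        got = {p.species: p.group for p in classify_scattering_group(profs)}
        assert got == {"a": Group.LOW, "b": Group.HIGH, "c": Group.HIGH}

    def test_default_fixture_species_lists(self, classified_profiles):
        low = {p.species for p in classified_profiles if p.group is Group.LOW}
        assert low == {
            "Merulina sp.", "Pocillopora damicornis",
            "Seriatopora hystrix", "Stylophora pistillata",
        }

    def test_single_species_unassigned(self):
        with pytest.warns(UserWarning):
            out = classify_scattering_group([co.OpticalProfile(species="x", mu_sm=2, r_s=0.5)])
        assert out[0].group is Group.UNASSIGNED

    def test_contradictory_preset_group_raises(self):
        profs = [
            co.OpticalProfile(species="a", mu_sm=2, r_s=0.5, group=Group.HIGH),
            co.OpticalProfile(species="b", mu_sm=4, r_s=0.5),
        ]
        with pytest.raises(ValueError):
            classify_scattering_group(profs)


class TestPESlope:
    def test_noiseless_line_is_exact(self):
        est = pe_slope([(0, 0.60), (2, 0.54), (4, 0.48), (6, 0.42)])
        assert est.slope == pytest.approx(-0.03, abs=1e-12)
        assert est.n == 4

    def test_constant_metric(self):
        assert pe_slope([(0, 0.5), (2, 0.5), (4, 0.5)]).slope == 0.0

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            pe_slope([(0, 0.5)])

    def test_window_filters_points(self):
        est = pe_slope([(-2, 99.0), (0, 0.6), (2, 0.5)], window=(0, 11))
        assert est.slope == pytest.approx(-0.05)
        assert est.n == 2


def pe_frame(values):
    """cell PE table from {(species, temp, light): pe}."""
    return pd.DataFrame(
        [{"species": s, "temperature": t, "light": l, "pe": v} for (s, t, l), v in values.items()]
    )


class TestDeltaPE:
    def test_light_basis_arithmetic(self):
        table = pe_frame({("A", "HT", "HL"): -0.04, ("A", "HT", "CL"): -0.01})
        (d,) = delta_pe(table, "light")
        assert (d.conditioning, d.value) == ("HT", pytest.approx(-0.03))

    def test_identical_cells_give_zero(self):
        table = pe_frame({("A", "HT", "HL"): -0.02, ("A", "HT", "CL"): -0.02})
        (d,) = delta_pe(table, "light")
        assert d.value == 0.0

    def test_missing_cell_skips_with_warning(self):
        table = pe_frame({("A", "HT", "HL"): -0.04})
        with pytest.warns(UserWarning, match="missing cell"):
            assert delta_pe(table, "light") == []

    @given(offsets=st.lists(st.floats(-0.1, 0.1), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_confounder_cancellation(self, offsets):
        """Adding any per-species additive offset constant across light
        levels leaves every light-basis dPE unchanged exactly; same for
        the temperature basis with offsets constant across temperature."""
        base = {}
        for i, sp in enumerate("ABC"):
            for t in ("CT", "HT"):
                for l in ("CL", "HL"):
                    base[(sp, t, l)] = -0.01 * (i + 1) + (0.005 if l == "HL" else 0) + (0.002 if t == "HT" else 0)
        shifted = {k: v + offsets["ABC".index(k[0])] for k, v in base.items()}
        for basis in ("light", "temperature"):
            d0 = delta_pe(pe_frame(base), basis)
            d1 = delta_pe(pe_frame(shifted), basis)
            for a, b in zip(d0, d1):
                # offsets cancel in the difference (up to float rounding)
                assert a.value == pytest.approx(b.value, abs=1e-15)


class TestRegressDePE:
    def test_matches_closed_form_ols(self, classified_profiles):
        rng = np.random.default_rng(5)
        values = {p.species: rng.normal(-0.01, 0.005) for p in classified_profiles}
        res = regress_depe(values, classified_profiles)
        x = np.array([p.mu_sm for p in classified_profiles])
        y = np.array([values[p.species] for p in classified_profiles])
        xc, yc = x - x.mean(), y - y.mean()
        slope = (xc @ yc) / (xc @ xc)
        intercept = y.mean() - slope * x.mean()
        r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_perfectly_linear(self, classified_profiles):
        values = {p.species: 0.004 * p.mu_sm - 0.02 for p in classified_profiles}
        assert regress_depe(values, classified_profiles).r2 == pytest.approx(1.0)

    def test_too_few_species(self, classified_profiles):
        with pytest.raises(ValueError):
            regress_depe({classified_profiles[0].species: -0.01}, classified_profiles)

    def test_null_r2_expectation(self, classified_profiles):
        """Under independence, E[r2] = 1/(n-1) for n species."""
        rng = np.random.default_rng(11)
        r2s = [
            regress_depe(
                {p.species: rng.normal(0, 0.01) for p in classified_profiles},
                classified_profiles,
            ).r2
            for _ in range(500)
        ]
        assert np.mean(r2s) == pytest.approx(1 / 9, abs=0.02)


class TestClusteredRateModel:
    def test_noiseless_recovery(self, noiseless_config, groups):
        table = co.generate_experiment(noiseless_config)
        m = clustered_rate_model(table, "fvfm", groups)
        assert m.slopes["low"] == pytest.approx(-0.0319, abs=1e-9)
        assert m.slopes["high"] == pytest.approx(-0.0144, abs=1e-9)
        assert m.interaction_p < 1e-12

    def test_methods_agree_on_point_estimates(self, default_table, groups):
        results = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("colony_slopes", "cluster_robust", "mixedlm"):
                results[method] = clustered_rate_model(default_table, "fvfm", groups, method=method)
        for g in ("low", "high"):
            vals = [r.slopes[g] for r in results.values()]
            assert max(vals) - min(vals) < 1e-8

    def test_qm_rates_recovered(self, default_table, groups):
        m = clustered_rate_model(default_table, "qm", groups)
        assert m.slopes["low"] == pytest.approx(0.043, abs=0.004)
        assert m.slopes["high"] == pytest.approx(0.011, abs=0.004)
        assert m.interaction_p < 0.01


class TestMarginal:
    def test_normalized_difference_constructed(self, groups):
        """Low group at 0.9x baseline, high at 1.0x -> difference 0.1."""
        rows = []
        for sp, grp in groups.items():
            for ram in ("r1", "r2"):
                base = 0.6 if grp == "low" else 0.5
                rows.append({"species": sp, "colony": f"{sp}-C1", "ramet": ram,
                             "temperature": "HT", "light": "HL", "day": 0, "fvfm": base})
                rows.append({"species": sp, "colony": f"{sp}-C1", "ramet": ram,
                             "temperature": "HT", "light": "HL", "day": 4,
                             "fvfm": base * (0.9 if grp == "low" else 1.0)})
        table = co.ObservationTable(pd.DataFrame(rows))
        c = marginal_day_comparison(table, "fvfm", 4, groups, normalize_to_initial=True)
        assert c.difference == pytest.approx(0.1, abs=1e-12)

    def test_divergence_detected_at_late_day(self, default_table, groups):
        c = marginal_day_comparison(default_table, "fvfm", 10, groups, normalize_to_initial=True)
        assert c.difference > 0  # low group lost more of its baseline
        assert c.p < 0.05

    def test_missing_day_errors(self, default_table, groups):
        with pytest.raises(ValueError):
            marginal_day_comparison(default_table, "fvfm", 7, groups)


class TestBaseline:
    def test_sign_matches_generator(self, default_table, groups):
        b = baseline_compare(default_table, "fvfm", groups)
        assert b.difference < 0  # low group has the higher Fv/Fm baseline
        assert b.p < 0.001

    def test_no_baseline_errors(self, groups):
        df = pd.DataFrame(
            [{"species": "Merulina sp.", "colony": "c", "ramet": "r",
              "temperature": "HT", "light": "HL", "day": 2, "fvfm": 0.5}]
        )
        with pytest.raises(ValueError):
            baseline_compare(co.ObservationTable(df), "fvfm", groups)


class TestCellPETable:
    def test_noiseless_cells_match_config(self, noiseless_config, groups):
        table = co.generate_experiment(noiseless_config)
        cells = cell_pe_table(table, "fvfm")
        for _, r in cells.iterrows():
            g = groups[r["species"]]
            expected = noiseless_config.fvfm_slopes[(g, f"{r['temperature']}-{r['light']}")]
            assert r["pe"] == pytest.approx(expected, abs=1e-12)
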