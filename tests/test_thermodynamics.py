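import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermokin import thermodynamics as td
from thermokin.constants import CODATA, COMPAT
from thermokin.inactivation import InactivationFit, d_value, half_life
from thermokin.mm_kinetics import MMResult
from thermokin.units import Temperature

T60 = Temperature(60.0)
TEMPS = [Temperature(c) for c in (60, 70, 80, 90, 100)]


def arrhenius_rates(Ea_kJ, lnA, temps, R=CODATA.R):
    return [math.exp(lnA - Ea_kJ * 1000 / (R * t.kelvin)) for t in temps]


class TestArrheniusFit:
    def test_exact_recovery_noiseless(self):
        k = arrhenius_rates(50.0, 10.0, TEMPS)
        fit = td.arrhenius_fit(TEMPS, k, "1/min")
        assert fit.Ea == pytest.approx(50.0, rel=1e-9)
        assert fit.lnA == pytest.approx(10.0, rel=1e-9)
        assert fit.Ea == pytest.approx(-fit.slope * CODATA.R / 1000, rel=1e-12)

    def test_reference_kin_column_gives_ea_near_63(self, reference_inactivation):
        temps, kins = zip(*reference_inactivation)
        fit = td.arrhenius_fit(list(temps), list(kins), "1/min", COMPAT)
        assert fit.Ea == pytest.approx(63.1, abs=0.2)

    def test_two_point_closed_form(self):
        t1, t2 = Temperature(60), Temperature(90)
        k1, k2 = 2.0e-3, 1.7e-2
        fit = td.arrhenius_fit([t1, t2], [k1, k2], "1/min")
        ea_closed = (
            CODATA.R * math.log(k2 / k1) / (1 / t1.kelvin - 1 / t2.kelvin) / 1000
        )
        assert fit.Ea == pytest.approx(ea_closed, rel=1e-12)

    def test_insufficient_or_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            td.arrhenius_fit([T60], [1e-3])
        with pytest.raises(ValueError):
            td.arrhenius_fit(TEMPS, [1e-3, -1, 1e-3, 1e-3, 1e-3])


class TestEnthalpy:
    def test_reference_value_at_optimum(self):
        assert td.enthalpy_of_activation(50.31, T60, COMPAT) == pytest.approx(
            47.54, abs=0.005
        )

    def test_reference_value_at_80C(self):
        assert td.enthalpy_of_activation(50.31, Temperature(80), COMPAT) == pytest.approx(
            47.37, abs=0.005
        )

    def test_zero_when_ea_equals_rt(self):
        ea = COMPAT.R_kJ * T60.kelvin
        assert td.enthalpy_of_activation(ea, T60, COMPAT) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_decreasing_in_temperature(self):
        vals = [td.enthalpy_of_activation(50.0, t) for t in TEMPS]
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestGibbsFromRate:
    def test_inactivation_free_energy_at_optimum(self):
        dg = td.gibbs_from_rate(2.10e-3, "1/min", T60, COMPAT)
        assert dg == pytest.approx(98.97, abs=0.01)

    def test_inactivation_free_energy_at_100C(self):
        dg = td.gibbs_from_rate(31.2e-3, "1/min", Temperature(100), COMPAT)
        assert dg == pytest.approx(102.84, abs=0.01)

    def test_zero_at_eyring_frequency(self):
        k = COMPAT.kB * T60.kelvin / COMPAT.h
        assert td.gibbs_from_rate(k, "1/s", T60, COMPAT) == pytest.approx(0.0, abs=1e-9)

    def test_unit_sensitivity_is_rt_ln60(self):
        # same physical rate expressed in s^-1 instead of min^-1 shifts dG
        # by exactly R*T*ln(60); the unit tag is never silently converted
        k_per_min = 1e-3
        dmin = td.gibbs_from_rate(k_per_min, "1/min", T60)
        dsec = td.gibbs_from_rate(k_per_min / 60.0, "1/s", T60)
        assert dsec - dmin == pytest.approx(
            CODATA.R_kJ * T60.kelvin * math.log(60), rel=1e-12
        )
        # identical numeric value with a different tag is used as-is
        assert td.gibbs_from_rate(k_per_min, "1/s", T60) == dmin

    def test_strictly_decreasing_in_k(self):
        ks = [1e-4, 1e-3, 1e-2, 1e-1]
        dgs = [td.gibbs_from_rate(k, "1/min", T60) for k in ks]
        assert all(b < a for a, b in zip(dgs, dgs[1:]))

    def test_missing_unit_tag_rejected(self):
        with pytest.raises(ValueError):
            td.gibbs_from_rate(1e-3, "", T60)


class TestEntropyGibbs:
    def test_signed_entropy_reference_case(self):
        assert td.entropy_from_HG(47.20, 102.52, Temperature(100)) == pytest.approx(
            -148.3, abs=0.05
        )

    def test_activation_entropy_reference_case(self):
        assert td.entropy_from_HG(32.68, 74.36, T60) == pytest.approx(-125.1, abs=0.1)

    def test_zero_when_dh_equals_dg(self):
        assert td.entropy_from_HG(50.0, 50.0, T60) == 0.0

    def test_gibbs_helmholtz_reference_case(self):
        assert td.gibbs_from_HS(32.68, -125.0, T60) == pytest.approx(74.32, abs=0.01)

    def test_dg_equals_dh_at_zero_entropy(self):
        assert td.gibbs_from_HS(47.0, 0.0, T60) == 47.0

    @settings(derandomize=True, max_examples=50)
    @given(
        dh=st.floats(-200, 200),
        dg=st.floats(-200, 200),
        tc=st.floats(1.0, 150.0),
    )
    def test_roundtrip_identity_to_1e9(self, dh, dg, tc):
        T = Temperature(tc)
        ds = td.entropy_from_HG(dh, dg, T)
        assert td.gibbs_from_HS(dh, ds, T) == pytest.approx(dg, abs=1e-9)


class TestEyringFit:
    def eyring_rates(self, dh, ds, temps, c=CODATA):
        return [
            c.kB * t.kelvin / c.h
            * math.exp(-(dh * 1000 - t.kelvin * ds) / (c.R * t.kelvin))
            for t in temps
        ]

    def test_exact_recovery_noiseless(self):
        k = self.eyring_rates(45.0, -150.0, TEMPS)
        out = td.eyring_fit(TEMPS, k)
        assert out["dH"] == pytest.approx(45.0, rel=1e-9)
        assert out["dS"] == pytest.approx(-150.0, rel=1e-9)

    def test_two_point_closed_form(self):
        temps = [Temperature(60), Temperature(100)]
        k = self.eyring_rates(45.0, -150.0, temps)
        x = np.array([1 / t.kelvin for t in temps])
        y = np.log(np.array(k) / np.array([t.kelvin for t in temps]))
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        out = td.eyring_fit(temps, k)
        assert out["dH"] == pytest.approx(-slope * CODATA.R / 1000, rel=1e-12)
        assert out["dS"] == pytest.approx(
            CODATA.R * (intercept - math.log(CODATA.kB / CODATA.h)), rel=1e-12
        )

    def test_consistent_with_gibbs_from_rate(self):
        k = self.eyring_rates(45.0, -150.0, TEMPS)
        out = td.eyring_fit(TEMPS, k)
        for t, ki in zip(TEMPS, k):
            dg = td.gibbs_from_rate(ki, "1/s", t)
            assert dg == pytest.approx(
                td.gibbs_from_HS(out["dH"], out["dS"], t), abs=1e-6
            )


class TestSummaries:
    def test_compat_activation_summary_reference_fixture(self, reference):
        kx = reference["kinetics"]
        mm = MMResult(Km=kx["Km_mM"], Vmax=kx["Vmax_U_mg"],
                      Km_stderr=0, Vmax_stderr=0, ssr=0)
        out = td.activation_summary(
            mm, T60, mode="compat",
            Ea=kx["Ea_kJ_mol"], dH_override=kx["dH_kJ_mol"],
            dS_override=-kx["dS_magnitude_J_mol_K"],
            kcat_override=kx["kcat_per_s"],
            efficiency_override=kx["efficiency_per_M_s"],
        )
        assert out["dG"]["value"] == pytest.approx(74.32, abs=0.01)
        assert out["dG_ET"]["value"] == pytest.approx(-2.67, abs=0.01)
        assert round(out["Ka"]["value"], 2) == 0.07

    def test_strict_summary_tags_every_field(self):
        mm = MMResult(Km=13.72, Vmax=2.657, Km_stderr=0, Vmax_stderr=0,
                      ssr=0, kcat=7.971e-4, efficiency=0.0581)
        out = td.activation_summary(mm, T60, mode="strict", Ea=35.04)
        for key, rec in out.items():
            assert {"value", "unit", "method", "mode"} <= set(rec), key
            assert rec["mode"] == "strict"

    def test_inactivation_thermo_table_reference_dH_column(self, reference_inactivation):
        fits = [
            InactivationFit(T, k, 0.0, 1.0, half_life(k),
                            d_value(k, T, "compat"), "compat")
            for T, k in reference_inactivation
        ]
        table = td.inactivation_thermo_table(fits, Ea_in=50.31, constants=COMPAT)
        np.testing.assert_allclose(
            table["dH_kJ_mol"], [47.54, 47.46, 47.37, 47.29, 47.21], atol=0.005
        )

    def test_thermo_table_satisfies_gibbs_helmholtz_identity(self, reference_inactivation):
        fits = [
            InactivationFit(T, k, 0.0, 1.0, half_life(k), d_value(k), "standard")
            for T, k in reference_inactivation
        ]
        table = td.inactivation_thermo_table(fits, Ea_in=50.31, constants=COMPAT)
        for _, row in table.iterrows():
            T = Temperature(row["temperature_C"])
            dg = td.gibbs_from_HS(row["dH_kJ_mol"], row["dS_J_mol_K"], T)
            assert dg == pytest.approx(row["dG_kJ_mol"], abs=1e-9)

    def test_single_row_with_supplied_ea(self):
        fit = InactivationFit(T60, 2.1e-3, 0, 1.0, half_life(2.1e-3),
                              d_value(2.1e-3), "standard")
        table = td.inactivation_thermo_table([fit], Ea_in=50.31, constants=COMPAT)
        assert len(table) == 1
        assert table.iloc[0]["dG_kJ_mol"] == pytest.approx(98.97, abs=0.01)
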