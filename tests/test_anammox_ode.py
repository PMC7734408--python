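import numpy as np
import pytest

from isoanammox.anammox_ode import (
    IDX,
    ModelParams,
    fluxes,
    init_state,
    observables,
    rhs,
    simulate,
)
from isoanammox.isotope_core import R15_AIR, rayleigh_delta

X_CANON = 0.3 / 1.3

EXP_A_EPS = dict(
    eps15_amx=32.5, eps15_amxnir=13.7, eps15_nxr=-77.8,
    eps18_amxnir=3.1, eps18_nxr=-20.6,
)

INIT_CONC = {"nh4": 3.0, "no2": 4.0, "no3": 0.05}
INIT_DELTAS = {"d15_no3": 5.0, "d18_no2": 3.0, "d18_no3": 3.0}


class TestFluxes:
    def test_no_nitrate_production_when_x_zero(self):
        y = init_state({"nh4": 2.0, "no2": 2.0})
        amx, amxnir, nxr = fluxes(y, ModelParams(x=0.0))
        assert nxr == 0.0
        assert amx == amxnir > 0

    def test_canonical_stoichiometry_flux_ratio(self):
        y = init_state({"nh4": 2.0, "no2": 2.0})
        _, amxnir, nxr = fluxes(y, ModelParams(x=X_CANON))
        assert nxr / amxnir == pytest.approx(0.3)

    def test_no_substrate_no_flux(self):
        y = init_state({"no2": 2.0})
        assert fluxes(y, ModelParams())[0] == 0.0

    def test_invalid_x_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(x=1.0)


class TestInitState:
    def test_reference_ratios_at_zero_delta(self):
        y = init_state({"nh4": 1.0, "no2": 1.0, "no3": 1.0})
        assert y[IDX["nh4_15"]] / y[IDX["nh4_14"]] == pytest.approx(R15_AIR)

    def test_atom_counting(self):
        y = init_state({"no2": 1.0, "no3": 2.0})
        assert y[IDX["no2_o16"]] + y[IDX["no2_o18"]] == pytest.approx(2.0)
        assert y[IDX["no3_o16"]] + y[IDX["no3_o18"]] == pytest.approx(6.0)

    def test_observables_round_trip(self):
        deltas = {"d15_nh4": 7.0, "d15_no2": -20.0, "d18_no2": 3.5,
                  "d15_no3": 9.0, "d18_no3": 2.0}
        conc = {"nh4": 1.2, "no2": 3.4, "no3": 0.6}
        y = init_state(conc, deltas)
        df = observables([0.0], y[None, :])
        for sp in conc:
            assert df[f"conc_{sp}"].iloc[0] == pytest.approx(conc[sp], abs=1e-12)
        for k, v in deltas.items():
            assert df[k].iloc[0] == pytest.approx(v, abs=1e-10)

    def test_delta_for_absent_species_warns(self):
        with pytest.warns(UserWarning):
            init_state({"nh4": 1.0}, {"d15_no2": 5.0})


class TestLimits:
    def test_no_fractionation_keeps_deltas_constant(self):
        p = ModelParams(x=X_CANON)  # all eps zero, no exchange
        df = simulate(init_state(INIT_CONC, INIT_DELTAS), p, np.linspace(0, 20, 6))
        assert np.allclose(df["d15_nh4"], df["d15_nh4"].iloc[0], atol=1e-8)
        assert np.allclose(df["d15_no2"], df["d15_no2"].iloc[0], atol=1e-8)

    def test_new_nitrate_oxygen_inherits_two_thirds_nitrite(self):
        # with all eps = 0 the nitrate produced carries
        # 2/3 d18O_NO2 + 1/3 d18O_water
        p = ModelParams(x=X_CANON, d18_water=-8.0, eps18_h2onxr=0.0)
        y0 = init_state({"nh4": 3.0, "no2": 4.0}, {"d18_no2": 3.0})
        df = simulate(y0, p, np.linspace(0, 10, 5))
        expected = 2.0 / 3.0 * 3.0 + 1.0 / 3.0 * -8.0
        assert df["d18_no3"].iloc[-1] == pytest.approx(expected, abs=1e-6)

    def test_fast_exchange_pins_nitrite_at_equilibrium(self):
        p = ModelParams(k_amo14n=0.0, k_exch=3.0, d18_water=-8.0)
        y0 = init_state({"no2": 4.0}, {"d18_no2": 30.0})
        df = simulate(y0, p, np.linspace(0, 8, 5))
        assert df["d18_no2"].iloc[-1] == pytest.approx(-8.0 + 13.0, abs=1e-4)

    def test_zero_rates_constant_trajectory(self):
        p = ModelParams(k_amo14n=0.0, k_exch=0.0)
        y0 = init_state(INIT_CONC, INIT_DELTAS)
        df = simulate(y0, p, np.linspace(0, 10, 4))
        assert np.allclose(df["conc_nh4"], INIT_CONC["nh4"], atol=1e-12)
        assert np.allclose(df["d15_no3"], 5.0, atol=1e-10)


class TestRayleighOracle:
    def test_ammonium_follows_rayleigh(self):
        p = ModelParams(x=0.0, k_amo14n=0.05, eps15_amx=32.5)
        df = simulate(init_state({"nh4": 3.0, "no2": 10.0}, {}), p,
                      np.linspace(0, 30, 8))
        f = np.exp(-0.05 * df["time_h"].to_numpy())
        expected = rayleigh_delta(0.0, 32.5, f)
        assert np.max(np.abs(df["d15_nh4"].to_numpy() - expected)) < 0.05

    def test_nitrite_follows_rayleigh_with_composite_epsilon(self):
        # NXR and AMXNIR occur in fixed proportion, so residual nitrite is
        # Rayleigh with the flux-weighted alpha
        x = 0.2
        p = ModelParams(x=x, k_amo14n=0.05, eps15_nxr=-77.8, eps15_amxnir=13.7)
        df = simulate(init_state({"nh4": 3.0, "no2": 4.0}, {}), p,
                      np.linspace(0, 30, 8))
        w = x / (1 - x)
        inv_alpha = (w / 1.000 / (1 - 77.8e-3) + 1 / (1 + 13.7e-3)) / (w + 1)
        eps_eff = (1 / inv_alpha - 1) * 1000
        f = df["conc_no2"].to_numpy() / df["conc_no2"].iloc[0]
        expected = rayleigh_delta(0.0, eps_eff, f)
        assert np.max(np.abs(df["d15_no2"].to_numpy() - expected)) < 0.05


class TestConservation:
    @pytest.mark.parametrize("k_exch", [0.0, 0.05])
    def test_total_n_conserved_both_isotopes(self, k_exch):
        p = ModelParams(x=X_CANON, k_exch=k_exch, **EXP_A_EPS)
        from scipy.integrate import solve_ivp

        y0 = init_state(INIT_CONC, INIT_DELTAS)
        sol = solve_ivp(rhs, (0, 40), y0, args=(p,), rtol=1e-9, atol=1e-12)
        ys = sol.y.T
        for iso in ("14", "15"):
            tot = sum(ys[:, IDX[f"{sp}_{iso}"]] for sp in ("nh4", "no2", "no3", "n2"))
            assert np.max(np.abs(tot / tot[0] - 1.0)) < 1e-8

    def test_exchange_conserves_nitrite_oxygen(self):
        # exchange swaps atoms with water 1:1: with reactions off the total
        # nitrite O pool is exactly constant while its ratio relaxes
        from scipy.integrate import solve_ivp

        p = ModelParams(k_amo14n=0.0, k_exch=0.5, d18_water=229.0)
        y0 = init_state({"no2": 4.0}, {"d18_no2": 3.0})
        sol = solve_ivp(rhs, (0, 20), y0, args=(p,), rtol=1e-10, atol=1e-13)
        o_tot = sol.y[IDX["no2_o16"]] + sol.y[IDX["no2_o18"]]
        assert np.max(np.abs(o_tot / o_tot[0] - 1.0)) < 1e-10

    def test_stoichiometric_identities_along_run(self):
        p = ModelParams(x=X_CANON, **EXP_A_EPS)
        df = simulate(init_state(INIT_CONC, INIT_DELTAS), p, np.linspace(0, 30, 9))
        nh4_cons = df["conc_nh4"].iloc[0] - df["conc_nh4"]
        no3_prod = df["conc_no3"] - df["conc_no3"].iloc[0]
        no2_cons = df["conc_no2"].iloc[0] - df["conc_no2"]
        ratio3 = (no3_prod / nh4_cons).to_numpy()[1:]
        ratio2 = (no2_cons / nh4_cons).to_numpy()[1:]
        assert np.allclose(ratio3, 0.3, atol=1e-3)
        assert np.allclose(ratio2, 1.3, atol=2e-3)


class TestDirectionAndSolvers:
    def test_inverse_nxr_enriches_instantaneous_nitrate(self):
        # small inverse eps: initial nitrate product is heavier than the
        # nitrite substrate by ~|eps|
        p = ModelParams(x=X_CANON, eps15_nxr=-5.0)
        y0 = init_state({"nh4": 3.0, "no2": 4.0}, {"d15_no2": 0.0})
        df = simulate(y0, p, np.linspace(0, 0.05, 3))
        assert df["d15_no3"].iloc[-1] == pytest.approx(5.0, abs=0.1)

    def test_rk4_matches_adaptive(self):
        p = ModelParams(x=0.16, k_amo14n=0.05, **EXP_A_EPS)
        y0 = init_state(INIT_CONC, INIT_DELTAS)
        t = np.linspace(0, 24, 7)
        df_a = simulate(y0, p, t, method="adaptive")
        df_r = simulate(y0, p, t, method="rk4", n_substeps=40)
        for col in ("d15_nh4", "d15_no2", "d15_no3", "d18_no2", "d18_no3"):
            assert np.max(np.abs(df_a[col] - df_r[col])) < 0.01

    def test_bad_time_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate(init_state(INIT_CONC), ModelParams(), [0.0, 0.0, 1.0])
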