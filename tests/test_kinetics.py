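"""Kinetic sub-models: production, remodelling, balance and coupling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipogrid as lg
from lipogrid.composition import NMOL_PER_MOLECULE, surface_counts
from lipogrid.kinetics import (
    HDL_SCALING_GROUP,
    MOLECULES_PER_NMOL,
    Parameter,
    build_system,
    discretized_lognormal_input,
    hdl_production_field,
    hdl_rate_fields,
    nascent_vldl_moments,
    steady_state,
    vldl_rate_fields,
)

RATE = 60.0  # nmol VLDL-TG/h


class TestParameterSet:
    def test_wild_type_has_16_parameters(self, params):
        assert len(params) == 16
        assert len(params.free_names) == 16

    def test_nascent_fraction_bounded(self, params):
        with pytest.raises(ValueError):
            params.with_values({"hdl_prod_small_frac": 1.5})

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(KeyError):
            params.with_values({"not_a_param": 1.0})
        with pytest.raises(KeyError):
            params.scaled({"not_a_param": 0.5})

    def test_transform_metadata_split(self, params):
        kinds = {p.name: p.transform for p in params}
        assert kinds["hdl_sel_rate"] == "log"
        assert kinds["vldl_nascent_diameter"] == "linear"
        assert kinds["hdl_prod_small_frac"] == "linear"

    def test_invalid_parameter_definitions_rejected(self):
        with pytest.raises(ValueError):
            Parameter("x", 1.0, "exp", (0.1, 10.0), "")
        with pytest.raises(ValueError):
            Parameter("x", 1.0, "log", (-1.0, 10.0), "")
        with pytest.raises(ValueError):
            Parameter("x", 1.0, "linear", (5.0, 1.0), "")


class TestHDLProduction:
    def test_total_input_equals_production_parameter(self, model, params):
        field = hdl_production_field(model, params)
        assert field.sum() == pytest.approx(params["hdl_prod_rate"], rel=1e-12)

    def test_pure_small_type(self, model, params):
        p = params.with_values({"hdl_prod_small_frac": 1.0})
        field = hdl_production_field(model, p)
        # nascent HDL carries minimal TG: everything enters on the first row
        assert field[1:, :].sum() == 0.0
        mean_tc = (field * model.hdl.n_tc).sum() / field.sum()
        assert mean_tc == pytest.approx(24.0, rel=0.05)

    def test_even_split_is_linear_mixture(self, model, params):
        f0 = hdl_production_field(model, params.with_values({"hdl_prod_small_frac": 0.0}))
        f1 = hdl_production_field(model, params.with_values({"hdl_prod_small_frac": 1.0}))
        fh = hdl_production_field(model, params.with_values({"hdl_prod_small_frac": 0.5}))
        np.testing.assert_allclose(fh, 0.5 * f0 + 0.5 * f1, rtol=1e-12)
        # each type contributes half of the particle flux
        assert f0.sum() == pytest.approx(f1.sum(), rel=1e-12)

    def test_larger_type_is_larger(self, model, params):
        f0 = hdl_production_field(model, params.with_values({"hdl_prod_small_frac": 0.0}))
        f1 = hdl_production_field(model, params.with_values({"hdl_prod_small_frac": 1.0}))
        tc0 = (f0 * model.hdl.n_tc).sum() / f0.sum()
        tc1 = (f1 * model.hdl.n_tc).sum() / f1.sum()
        assert tc0 > tc1


class TestVLDLProduction:
    def test_tg_scaling_exact(self, model, params):
        field = lg.vldl_production_field(model, params["vldl_nascent_diameter"], RATE)
        simulated = (field * model.vldl.n_tg).sum() * NMOL_PER_MOLECULE
        assert simulated == pytest.approx(RATE, rel=1e-9)

    def test_rate_doubling_preserves_shape(self, model, params):
        d = params["vldl_nascent_diameter"]
        f1 = lg.vldl_production_field(model, d, RATE)
        f2 = lg.vldl_production_field(model, d, 2 * RATE)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_unrepresentable_diameter_rejected(self, model):
        with pytest.raises(ValueError):
            lg.vldl_production_field(model, 500.0, RATE)
        with pytest.raises(ValueError):
            lg.vldl_production_field(model, 45.0, -1.0)

    def test_discretized_moments_match_monte_carlo(self, model, rng):
        """Cell-integrated log-normal versus dense sampling of the
        continuous distribution restricted to the grid support."""
        mean_tg, mean_ce = nascent_vldl_moments(model, 45.0)
        cv = model.vldl_nascent_cv
        dist = discretized_lognormal_input(model.vldl, mean_tg, mean_ce, cv)
        sigma2 = np.log(1 + cv**2)
        n = 400_000
        tg = rng.lognormal(np.log(mean_tg) - sigma2 / 2, np.sqrt(sigma2), n)
        ce = rng.lognormal(np.log(mean_ce) - sigma2 / 2, np.sqrt(sigma2), n)
        grid = model.vldl.grid
        keep = (
            (tg >= grid.tg_min)
            & (tg <= grid.tg_max)
            & (ce >= grid.ce_min)
            & (ce <= grid.ce_max)
        )
        # bin samples into the same index cells the discretization uses
        i_idx = np.clip(np.rint(lg.index_of_tg(tg[keep], grid)), 1, grid.i_max)
        j_idx = np.clip(np.rint(lg.index_of_ce(ce[keep], grid)), 1, grid.j_max)
        mc = np.zeros_like(dist)
        np.add.at(mc, (i_idx.astype(int) - 1, j_idx.astype(int) - 1), 1.0)
        mc /= mc.sum()
        np.testing.assert_allclose(dist, mc, atol=0.005)
        # the TG ladder is fine enough for the mean to carry over too
        assert (dist * model.vldl.n_tg).sum() == pytest.approx(
            tg[keep].mean(), rel=0.02
        )


class TestRateFields:
    def test_zero_state_zero_fluxes(self, model, params):
        zero = np.zeros_like(model.hdl.n_tg)
        fl = lg.hdl_remodelling_fluxes(model, zero, params, vldl_pl_release=5.0)
        for name, field in fl.particle.items():
            if name != "prod":
                assert np.all(field == 0.0)

    def test_no_surface_remnants_no_accumulation(self, model, params):
        rates = hdl_rate_fields(model, params, vldl_pl_release=0.0)
        assert np.all(rates["chol"] == 0.0)
        assert np.all(rates["trig"] == 0.0)

    def test_boundary_fluxes_are_zero(self, model, params):
        rates = hdl_rate_fields(model, params, 5.0)
        assert np.all(rates["lip"][0, :] == 0.0)  # no lipolysis below tg_min
        assert np.all(rates["sel"][:, 0] == 0.0)
        assert np.all(rates["chol"][:, -1] == 0.0)  # closed top
        assert np.all(rates["trig"][-1, :] == 0.0)
        v = vldl_rate_fields(model, params)
        assert np.all(v["lip_universal"][0, :] == 0.0)
        assert np.all(v["lip_vldl"][0, :] == 0.0)
        assert np.all(v["sel"][:, 0] == 0.0)

    def test_remodelling_conserves_particles(self, model, params, rng):
        """Remodelling only moves particles between states: summed over
        the grid its net contribution to d(state)/dt is zero."""
        state = rng.uniform(0, 1e12, model.hdl.n_tg.shape)
        rates = hdl_rate_fields(model, params, 5.0)
        no_upt = {k: v for k, v in rates.items() if k != "upt"}
        zero_prod = np.zeros_like(state)
        out = lg.rhs(state, no_upt, zero_prod)
        assert abs(out.sum()) <= 1e-10 * (state.sum())

    def test_universal_lipolysis_shared_between_submodels(self, model, params):
        """The universal lipolysis law evaluated on the VLDL grid uses the
        same two parameters as the HDL sub-model."""
        comp = model.vldl
        rel_tg = comp.n_tg / (comp.n_tg + comp.n_ce)
        expected = params["lip_rate"] * rel_tg ** params["lip_exp"] * comp.n_tg
        dtg = np.diff(comp.n_tg[:, 0])
        rates = vldl_rate_fields(model, params)
        got = rates["lip_universal"][1:, :] * dtg[:, None]
        np.testing.assert_allclose(got, expected[1:, :], rtol=1e-12)

    def test_constant_catabolism_limit(self, model, params):
        """With the surface term off, uptake is uniform first-order."""
        p = params.with_values({"vldl_upt_surf_rate": 1e-30})
        rates = vldl_rate_fields(model, p)
        total = rates["upt_const"] + rates["upt_surface"]
        np.testing.assert_allclose(total, params["vldl_upt_const"], rtol=1e-12)

    def test_negative_inputs_rejected(self, model, params, rng):
        with pytest.raises(ValueError):
            hdl_rate_fields(model, params, vldl_pl_release=-1.0)
        state = -np.ones_like(model.hdl.n_tg)
        with pytest.raises(ValueError):
            lg.hdl_remodelling_fluxes(model, state, params, 1.0)


class TestRhs:
    def test_zero_state_zero_production(self, model, params):
        rates = hdl_rate_fields(model, params, 5.0)
        zero = np.zeros_like(model.hdl.n_tg)
        np.testing.assert_array_equal(lg.rhs(zero, rates, zero), zero)

    def test_global_particle_balance(self, model, params, rng):
        """Sum of d/dt over the grid telescopes to production - uptake."""
        state = rng.uniform(0, 1e12, model.hdl.n_tg.shape)
        rates = hdl_rate_fields(model, params, 5.0)
        prod = hdl_production_field(model, params)
        total = lg.rhs(state, rates, prod).sum()
        expected = prod.sum() - (rates["upt"] * state).sum()
        assert total == pytest.approx(expected, rel=1e-10)

    def test_lipid_mass_ledger_oracle(self, model, params, rng):
        """d/dt of total TG mass from the rhs equals the independent
        molecular ledger: production + accumulation - lipolysis -
        catabolism, each converted through the index-step sizes."""
        state = rng.uniform(0, 1e12, model.hdl.n_tg.shape)
        rates = hdl_rate_fields(model, params, 5.0)
        prod = hdl_production_field(model, params)
        dmass = (lg.rhs(state, rates, prod) * model.hdl.n_tg).sum()
        fl = lg.hdl_remodelling_fluxes(model, state, params, 5.0)
        ledger = (
            fl.total_lipid_flux("prod", "TG")
            + fl.total_lipid_flux("trig", "TG")
            - fl.total_lipid_flux("lip", "TG")
            - fl.total_lipid_flux("upt", "TG")
        )
        assert dmass == pytest.approx(ledger, rel=1e-9)

    def test_non_finite_state_reported(self, model, params):
        rates = hdl_rate_fields(model, params, 5.0)
        state = np.zeros_like(model.hdl.n_tg)
        state[2, 2] = np.nan
        with pytest.raises(FloatingPointError):
            lg.rhs(state, rates, np.zeros_like(state))


class TestSteadyState:
    def test_zero_production_zero_state(self, model, params):
        rates = vldl_rate_fields(model, params)
        state, diag = steady_state(rates, np.zeros_like(model.vldl.n_tg))
        assert np.all(state == 0.0)
        assert diag.converged

    def test_rhs_vanishes_at_steady_state(self, model, params, coupled):
        rates = vldl_rate_fields(model, params)
        res = lg.rhs(coupled.vldl_state, rates, coupled.vldl_production)
        assert np.abs(res).max() <= 1e-8 * coupled.vldl_state.max()

    def test_linearity_production_doubling(self, model, params):
        """All rate laws are first-order in the state, so doubling the
        particle production doubles the steady state exactly."""
        rates = hdl_rate_fields(model, params, 5.0)
        prod = hdl_production_field(model, params)
        s1, _ = steady_state(rates, prod)
        s2, _ = steady_state(rates, 2.0 * prod)
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-9)

    def test_time_integration_agrees_with_linear_solve(self, model, params):
        from scipy.integrate import solve_ivp

        rates = hdl_rate_fields(model, params, 5.0)
        prod = hdl_production_field(model, params)
        state, diag = steady_state(rates, prod)
        assert diag.method == "linear_solve"
        m, p = build_system(rates, prod)
        sol = solve_ivp(
            lambda t, y: m @ y + p,
            (0, 500.0),
            np.zeros(p.size),
            method="BDF",
            jac=m,
            rtol=1e-10,
            atol=1e-4 * p.max(),
        )
        np.testing.assert_allclose(
            sol.y[:, -1], state.ravel(), rtol=1e-5, atol=1e-7 * state.max()
        )

    def test_no_steady_state_without_catabolism_is_flagged(self, model, params):
        rates = vldl_rate_fields(model, params)
        rates["upt_const"] = np.zeros_like(rates["upt_const"])
        rates["upt_surface"] = np.zeros_like(rates["upt_surface"])
        prod = lg.vldl_production_field(model, params["vldl_nascent_diameter"], RATE)
        state, diag = steady_state(rates, prod, t_max=50.0)
        assert not diag.converged  # reported, not raised

    def test_states_non_negative(self, model, params, coupled):
        assert coupled.vldl_state.min() >= 0.0
        assert coupled.hdl_state.min() >= 0.0


class TestBalancesAtSteadyState:
    def test_particle_balance_each_submodel(self, model, params, coupled):
        vl = lg.vldl_remodelling_and_uptake_fluxes(
            model, coupled.vldl_state, params, coupled.vldl_production
        )
        prod = vl.total_particle_flux("prod")
        upt = vl.total_particle_flux("upt_const") + vl.total_particle_flux("upt_surface")
        assert upt == pytest.approx(prod, rel=1e-6)
        hd = lg.hdl_remodelling_fluxes(model, coupled.hdl_state, params, coupled.pl_release)
        assert hd.total_particle_flux("upt") == pytest.approx(
            hd.total_particle_flux("prod"), rel=1e-6
        )

    def test_lipid_balance_each_species(self, model, params, coupled):
        """Influx equals efflux for TG and CE in both sub-models, with
        particle fluxes converted to molecular fluxes by the composition
        model."""
        vl = lg.vldl_remodelling_and_uptake_fluxes(
            model, coupled.vldl_state, params, coupled.vldl_production
        )
        tg_in = vl.total_lipid_flux("prod", "TG")
        tg_out = (
            vl.total_lipid_flux("lip_universal", "TG")
            + vl.total_lipid_flux("lip_vldl", "TG")
            + vl.total_lipid_flux("upt_const", "TG")
            + vl.total_lipid_flux("upt_surface", "TG")
        )
        assert tg_out == pytest.approx(tg_in, rel=1e-6)
        ce_in = vl.total_lipid_flux("prod", "CE")
        ce_out = (
            vl.total_lipid_flux("sel", "CE")
            + vl.total_lipid_flux("upt_const", "CE")
            + vl.total_lipid_flux("upt_surface", "CE")
        )
        assert ce_out == pytest.approx(ce_in, rel=1e-6)
        hd = lg.hdl_remodelling_fluxes(model, coupled.hdl_state, params, coupled.pl_release)
        assert hd.total_lipid_flux("lip", "TG") + hd.total_lipid_flux(
            "upt", "TG"
        ) == pytest.approx(
            hd.total_lipid_flux("prod", "TG") + hd.total_lipid_flux("trig", "TG"),
            rel=1e-6,
        )
        assert hd.total_lipid_flux("sel", "CE") + hd.total_lipid_flux(
            "upt", "CE"
        ) == pytest.approx(
            hd.total_lipid_flux("prod", "CE") + hd.total_lipid_flux("chol", "CE"),
            rel=1e-6,
        )

    def test_boundary_occupancy_negligible_at_operating_point(self, coupled):
        assert coupled.vldl_diag.boundary_mass_fraction < 0.01
        assert coupled.hdl_diag.boundary_mass_fraction < 0.05


def test_flux_decomposition_exports_long_table(model, params, coupled, tmp_path):
    fl = lg.vldl_remodelling_and_uptake_fluxes(
        model, coupled.vldl_state, params, coupled.vldl_production
    )
    df = fl.to_frame()
    assert set(df["process"]) == set(fl.particle)
    assert len(df) == len(fl.particle) * model.vldl.grid.n_states
    path = tmp_path / "fluxes.tsv"
    df.to_csv(path, sep="\t", index=False)
    assert path.stat().st_size > 0


class TestCoupling:
    def test_pl_release_matches_surface_ledger_oracle(self, model, params, coupled):
        """Independent re-derivation: every shrink step sheds the
        difference in surface PL between source and target composition."""
        grid = model.vldl.grid
        fl = lg.vldl_remodelling_and_uptake_fluxes(
            model, coupled.vldl_state, params, coupled.vldl_production
        )
        total = 0.0
        n_tg, n_ce = model.vldl.n_tg, model.vldl.n_ce
        for name in ("lip_universal", "lip_vldl"):
            flux = fl.particle[name]
            for i in range(1, grid.i_max):
                for j in range(grid.j_max):
                    if flux[i, j] == 0:
                        continue
                    _, pl_src = surface_counts(n_tg[i, j], n_ce[i, j], model.surface_table, grid)
                    _, pl_dst = surface_counts(n_tg[i - 1, j], n_ce[i - 1, j], model.surface_table, grid)
                    total += flux[i, j] * (pl_src - pl_dst)
        flux = fl.particle["sel"]
        for i in range(grid.i_max):
            for j in range(1, grid.j_max):
                if flux[i, j] == 0:
                    continue
                _, pl_src = surface_counts(n_tg[i, j], n_ce[i, j], model.surface_table, grid)
                _, pl_dst = surface_counts(n_tg[i, j - 1], n_ce[i, j - 1], model.surface_table, grid)
                total += flux[i, j] * (pl_src - pl_dst)
        assert coupled.pl_release == pytest.approx(total * NMOL_PER_MOLECULE, rel=1e-9)

    def test_coupled_equals_manual_wiring(self, model, params, coupled):
        rates = hdl_rate_fields(model, params, coupled.pl_release)
        prod = hdl_production_field(model, params)
        state, _ = steady_state(rates, prod)
        np.testing.assert_allclose(state, coupled.hdl_state, rtol=1e-12)

    def test_no_vldl_production_means_no_hdl_accumulation(self, model, params):
        from dataclasses import replace

        mean_tg, mean_ce = nascent_vldl_moments(model, params["vldl_nascent_diameter"])
        silent = replace(model, vldl_production_override=(mean_tg, mean_ce, 0.0))
        coupled = lg.couple_submodels(silent, params, RATE)
        assert np.all(coupled.vldl_state == 0.0)
        assert coupled.pl_release == 0.0
        rates = hdl_rate_fields(model, params, coupled.pl_release)
        assert np.all(rates["chol"] == 0.0)
        assert np.all(rates["trig"] == 0.0)


class TestHDLDegeneracy:
    @pytest.mark.parametrize("factor", [0.25, 4.0])
    def test_joint_rescaling_leaves_hdl_steady_state_invariant(
        self, model, params, coupled, factor
    ):
        scaled = lg.hdl_joint_rescaling(params, factor)
        rates = hdl_rate_fields(model, scaled, coupled.pl_release)
        prod = hdl_production_field(model, scaled)
        state, _ = steady_state(rates, prod)
        np.testing.assert_allclose(state, coupled.hdl_state, rtol=1e-9)

    def test_fluxes_rescale_by_the_common_factor(self, model, params, coupled):
        scaled = lg.hdl_joint_rescaling(params, 2.0)
        base = lg.hdl_remodelling_fluxes(model, coupled.hdl_state, params, coupled.pl_release)
        new = lg.hdl_remodelling_fluxes(model, coupled.hdl_state, scaled, coupled.pl_release)
        for proc in ("prod", "lip", "sel", "chol", "trig", "upt"):
            np.testing.assert_allclose(
                new.particle[proc], 2.0 * base.particle[proc], rtol=1e-12
            )

    def test_group_membership(self):
        assert set(HDL_SCALING_GROUP) == {
            "hdl_prod_rate",
            "lip_rate",
            "hdl_sel_rate",
            "hdl_chol_rate",
            "hdl_trig_rate",
            "hdl_upt_rate",
        }


@settings(max_examples=10, deadline=None, derandomize=True)
@given(data=st.data())
def test_random_parameter_draws_yield_valid_steady_states(data, model, params):
    """Within-bounds random kinetic parameters always produce a
    non-negative steady state obeying the particle balance."""
    draws = {}
    rng_vals = {}
    for p in params:
        lo, hi = p.bounds
        if p.transform == "log":
            val = 10 ** data.draw(
                st.floats(np.log10(lo), np.log10(hi)), label=p.name
            )
        else:
            val = data.draw(st.floats(lo, hi), label=p.name)
        draws[p.name] = val
    # keep the nascent diameter representable under the default ratio
    draws["vldl_nascent_diameter"] = min(max(draws["vldl_nascent_diameter"], 32.0), 65.0)
    pset = params.with_values(draws)
    coupled = lg.couple_submodels(model, pset, RATE)
    assert coupled.vldl_state.min() >= 0.0
    assert coupled.hdl_state.min() >= 0.0
    if coupled.converged:
        vl = lg.vldl_remodelling_and_uptake_fluxes(
            model, coupled.vldl_state, pset, coupled.vldl_production
        )
        prod = vl.total_particle_flux("prod")
        upt = vl.total_particle_flux("upt_const") + vl.total_particle_flux("upt_surface")
        assert upt == pytest.approx(prod, rel=1e-6)
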