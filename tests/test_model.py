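"""Unit and property tests for the microstate Marcus model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import reesfel as rf

KBT_298 = rf.K_B_EV_PER_K * 298.0


class TestSurfaces:
    @pytest.mark.parametrize(
        "i, x, fel, expected",
        [
            # both terms vanish at the global minimum
            (0, 0.0, rf.FelSpec(a=0.01, b=2, x_gs=0.2, m=3), 0.0),
            # top-microstate minimum equals the landscape span
            (9, 9 * 0.153, rf.FelSpec(a=0.00178, b=2, x_gs=0.153, m=10), 0.14418),
            # hand evaluation: 0.5*0.01 + 0.0025
            (1, 0.0, rf.FelSpec(a=0.0025, b=1, x_gs=0.1, m=2), 0.0075),
        ],
    )
    def test_gs_free_energy(self, i, x, fel, expected):
        assert rf.gs_free_energy(i, x, fel) == pytest.approx(expected, abs=1e-12)

    def test_p38_span_rounds_to_reported_precision(self):
        fel = rf.FelSpec(a=0.00178, b=2, x_gs=0.153, m=10)
        assert round(fel.span, 3) == 0.144

    def test_index_error_names_i_and_m(self):
        fel = rf.FelSpec(a=0.01, b=2, x_gs=0.1, m=4)
        with pytest.raises(IndexError, match="i=7.*m=4"):
            rf.gs_free_energy(7, 0.0, fel)
        with pytest.raises(IndexError):
            rf.ct_free_energy(-1, 0.0, fel, rf.P38A_LIGAND)

    def test_ct_minimum_single_state(self, p38_ligand):
        fel = rf.FelSpec(a=0.0, b=1, x_gs=0.0, m=1)
        val = rf.ct_free_energy(0, p38_ligand.x_ct, fel, p38_ligand)
        assert val == pytest.approx(p38_ligand.dg_ctgs0, abs=1e-12)

    def test_ct_state0_at_origin(self, p38_ligand, p38_fel):
        # 0.5*0.891^2 + 3.347
        val = rf.ct_free_energy(0, 0.0, p38_fel, p38_ligand)
        assert val == pytest.approx(0.5 * 0.891**2 + 3.347, abs=1e-12)
        assert val == pytest.approx(3.744, abs=5e-4)

    def test_ct_top_state_minimum(self, p38_ligand):
        fel = rf.FelSpec(a=0.002, b=2, x_gs=0.15, m=6)
        x_top = (fel.m - 1) * fel.x_gs + p38_ligand.x_ct
        val = rf.ct_free_energy(fel.m - 1, x_top, fel, p38_ligand)
        expected = fel.a * (fel.m - 1) ** fel.b + p38_ligand.dg_ctgsn
        assert val == pytest.approx(expected, abs=1e-12)


class TestWeights:
    def test_single_state(self):
        fel = rf.FelSpec(a=0.0, b=1, x_gs=0.0, m=1)
        w = rf.boltzmann_weights(2.5, fel)
        assert w.weights == pytest.approx([1.0])

    def test_symmetric_two_state(self):
        fel = rf.FelSpec(a=0.0, b=1, x_gs=0.1, m=2)
        w = rf.boltzmann_weights(0.05, fel)
        assert w.weights == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_two_state_ratio_matches_direct_evaluation(self):
        fel = rf.FelSpec(a=0.01, b=1, x_gs=0.1, m=2)
        w = rf.boltzmann_weights(0.0, fel)
        # G0 = 0, G1 = 0.5*0.01 + 0.01 = 0.015 eV
        expected_ratio = math.exp(-0.015 / KBT_298)
        assert w.weights[1] / w.weights[0] == pytest.approx(expected_ratio, rel=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        x=st.floats(-5, 5),
        a=st.floats(0, 0.2),
        b=st.floats(0.5, 3),
        x_gs=st.floats(0, 0.5),
        m=st.integers(1, 12),
    )
    def test_normalization(self, x, a, b, x_gs, m):
        fel = rf.FelSpec(a=a, b=b, x_gs=x_gs, m=m)
        w = rf.boltzmann_weights(x, fel)
        assert abs(w.weights.sum() - 1.0) < 1e-12
        assert np.all(w.weights >= 0)

    def test_stabilized_at_extreme_energies(self):
        # enormous offsets would overflow a naive exponential
        fel = rf.FelSpec(a=50.0, b=2, x_gs=0.1, m=5)
        w = rf.boltzmann_weights(40.0, fel)
        assert np.isfinite(w.weights).all()
        assert abs(w.weights.sum() - 1.0) < 1e-12


class TestTransitionEnergies:
    def test_abs_state0_at_origin(self, p38_ligand, p38_fel):
        val = rf.microstate_abs_energy(0, 0.0, p38_fel, p38_ligand)
        assert val == pytest.approx(3.347 + 0.5 * 0.891**2, abs=1e-12)

    def test_abs_top_state_at_origin(self, p38_ligand, p38_fel):
        val = rf.microstate_abs_energy(p38_fel.m - 1, 0.0, p38_fel, p38_ligand)
        assert val == pytest.approx(3.223 + 0.5 * 0.891**2, abs=1e-12)

    def test_stokes_shift_identity(self, p38_ligand, p38_fel):
        # abs(i, 0) - em(i) = 2 * reorg for every microstate
        reorg = p38_ligand.reorg()
        for i in range(p38_fel.m):
            stokes = rf.microstate_abs_energy(
                i, 0.0, p38_fel, p38_ligand
            ) - rf.microstate_em_energy(i, p38_fel, p38_ligand)
            assert stokes == pytest.approx(2 * reorg, abs=1e-12)

    def test_gap_recovery_identity(self, p38_ligand, p38_fel):
        # (abs(i, 0) + em(i)) / 2 = CT-GS gap of state i
        for i in range(p38_fel.m):
            mean = 0.5 * (
                rf.microstate_abs_energy(i, 0.0, p38_fel, p38_ligand)
                + rf.microstate_em_energy(i, p38_fel, p38_ligand)
            )
            assert mean == pytest.approx(
                rf.ct_gap(i, p38_fel, p38_ligand), abs=1e-12
            )

    def test_emission_endpoints_in_nm(self, p38_ligand, p38_fel):
        em0 = rf.microstate_em_energy(0, p38_fel, p38_ligand)
        emn = rf.microstate_em_energy(9, p38_fel, p38_ligand)
        assert em0 == pytest.approx(2.950, abs=1e-3)
        assert emn == pytest.approx(2.826, abs=1e-3)
        assert rf.energy_to_wavelength(em0) == pytest.approx(420.3, abs=0.1)
        assert rf.energy_to_wavelength(emn) == pytest.approx(438.7, abs=0.1)

    def test_strict_surfaces_mode_restores_cross_term(self, p38_ligand, p38_fel):
        cfg = rf.ModelConfig()
        i, x = 3, 0.4
        loose = rf.microstate_abs_energy(i, x, p38_fel, p38_ligand, cfg)
        strict = rf.microstate_abs_energy(
            i, x, p38_fel, p38_ligand, cfg, strict_surfaces=True
        )
        assert strict - loose == pytest.approx(
            cfg.kappa * i * p38_fel.x_gs * p38_ligand.x_ct, abs=1e-12
        )
        # strict mode equals the vertical surface separation
        gs = rf.gs_free_energy(i, x, p38_fel, cfg)
        ct = rf.ct_free_energy(i, x, p38_fel, p38_ligand, cfg)
        assert strict == pytest.approx(ct - gs, abs=1e-12)


def _brute_force_ensemble(x, fel, lig, cfg):
    """Independent pure-python oracle: explicit loops, math.exp only."""
    gs = [
        0.5 * cfg.kappa * (x - i * fel.x_gs) ** 2 + fel.a * i**fel.b
        for i in range(fel.m)
    ]
    gmin = min(gs)
    pops = [math.exp(-(g - gmin) / cfg.kbt) for g in gs]
    z = sum(pops)
    reorg = 0.5 * cfg.kappa * lig.x_ct**2
    if fel.m == 1:
        gaps = [lig.dg_ctgs0]
    else:
        gaps = [
            lig.dg_ctgs0 + i / (fel.m - 1) * (lig.dg_ctgsn - lig.dg_ctgs0)
            for i in range(fel.m)
        ]
    abs_e = sum(
        (gaps[i] + reorg - cfg.kappa * x * lig.x_ct) * pops[i] / z
        for i in range(fel.m)
    )
    em_e = sum((gaps[i] - reorg) * pops[i] / z for i in range(fel.m))
    return abs_e, em_e


class TestEnsemble:
    def test_single_state_emission_constant(self, p38_ligand):
        fel = rf.FelSpec(a=0.0, b=1, x_gs=0.0, m=1)
        xs = np.linspace(-1, 2, 301)
        em = rf.ensemble_em_energy(xs, fel, p38_ligand)
        assert em.max() - em.min() < 1e-12

    def test_equal_weight_point_is_arithmetic_mean(self, p38_ligand):
        fel = rf.FelSpec(a=0.0, b=1, x_gs=0.1, m=2)
        x = fel.x_gs / 2  # symmetric point: weights [0.5, 0.5]
        em = rf.ensemble_em_energy(x, fel, p38_ligand)
        e0 = rf.microstate_em_energy(0, fel, p38_ligand)
        e1 = rf.microstate_em_energy(1, fel, p38_ligand)
        assert em == pytest.approx(0.5 * (e0 + e1), abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        x=st.floats(-1, 2),
        a=st.floats(0, 0.05),
        b=st.floats(0.8, 3),
        x_gs=st.floats(0.01, 0.3),
        m=st.integers(1, 5),
    )
    def test_matches_brute_force_oracle(self, x, a, b, x_gs, m):
        cfg = rf.ModelConfig()
        lig = rf.P38A_LIGAND
        fel = rf.FelSpec(a=a, b=b, x_gs=x_gs, m=m)
        abs_o, em_o = _brute_force_ensemble(x, fel, lig, cfg)
        assert rf.ensemble_abs_energy(x, fel, lig, cfg) == pytest.approx(
            abs_o, abs=1e-12
        )
        assert rf.ensemble_em_energy(x, fel, lig, cfg) == pytest.approx(
            em_o, abs=1e-12
        )

    def test_red_shift_when_top_gap_smaller(self, p38_ligand):
        # dg_ctgsn < dg_ctgs0: emission energy non-increasing along x
        fel = rf.FelSpec(a=0.0025, b=2, x_gs=0.15, m=10)
        xs = rf.ModelConfig().x_grid()
        em = rf.ensemble_em_energy(xs, fel, p38_ligand)
        assert np.all(np.diff(em) <= 1e-12)

    def test_blue_shift_when_top_gap_larger(self):
        lig = rf.LigandPhotophysics(x_ct=0.89, dg_ctgs0=3.223, dg_ctgsn=3.346)
        fel = rf.FelSpec(a=0.0025, b=2, x_gs=0.15, m=10)
        xs = rf.ModelConfig().x_grid()
        em = rf.ensemble_em_energy(xs, fel, lig)
        assert np.all(np.diff(em) >= -1e-12)

    def test_fig2_emission_limits(self, fig_ligand):
        fel = rf.FelSpec(a=0.0025, b=1, x_gs=0.1, m=10)
        em_lo = rf.ensemble_em_energy(-1.0, fel, fig_ligand)
        em_hi = rf.ensemble_em_energy(2.0, fel, fig_ligand)
        assert em_lo == pytest.approx(fig_ligand.dg_ctgs0 - fig_ligand.reorg(), abs=2e-3)
        assert em_hi == pytest.approx(fig_ligand.dg_ctgsn - fig_ligand.reorg(), abs=2e-3)


class TestValidation:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            rf.ModelConfig(kappa=0)
        with pytest.raises(ValueError):
            rf.ModelConfig(x_min=2, x_max=-1)
        with pytest.raises(ValueError):
            rf.ModelConfig(n_grid=2)
        with pytest.raises(ValueError):
            rf.ModelConfig(temperature_K=0)

    def test_fel_invariants(self):
        with pytest.raises(ValueError):
            rf.FelSpec(a=-0.1, b=2, x_gs=0.1, m=5)
        with pytest.raises(ValueError):
            rf.FelSpec(a=0.1, b=0, x_gs=0.1, m=5)
        with pytest.raises(ValueError):
            rf.FelSpec(a=0.1, b=2, x_gs=0.1, m=0)

    def test_weight_container_invariants(self):
        with pytest.raises(ValueError):
            rf.MicrostateWeights(x=0.0, weights=np.array([0.7, 0.7]), log_z=0.0)
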