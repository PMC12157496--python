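"""Chemotherapy: diffusion solver, decay/uptake, chemoprotection, schedule."""

import math

import numpy as np
import pytest

from astroabm.chemo import (
    death_probability,
    death_probability_field,
    decay_and_uptake,
    diffuse,
    effective_concentration,
    is_dosing,
    pro_moore_counts,
    update_treatment_state,
)
from astroabm.config import ChemoParams
from astroabm.lattice import CellKind, LatticeState

from conftest import make_grid


def explicit_diffusion_oracle(field, diffusion, t_final, dt):
    """Forward-Euler reference with the same conservative Neumann stencil."""
    c = field.astype(float).copy()
    steps = int(round(t_final / dt))
    for _ in range(steps):
        lap = np.zeros_like(c)
        lap[1:-1, :] += c[2:, :] + c[:-2, :] - 2 * c[1:-1, :]
        lap[0, :] += c[1, :] - c[0, :]
        lap[-1, :] += c[-2, :] - c[-1, :]
        lap[:, 1:-1] += c[:, 2:] + c[:, :-2] - 2 * c[:, 1:-1]
        lap[:, 0] += c[:, 1] - c[:, 0]
        lap[:, -1] += c[:, -2] - c[:, -1]
        c = c + dt * diffusion * lap
    return c


class TestDiffusion:
    def test_uniform_field_unchanged_under_neumann(self):
        u = np.full((12, 12), 0.7)
        out = diffuse(u, 3.0, dosing=False)
        assert np.allclose(out, 0.7, atol=1e-12)

    def test_mass_conserved_zero_flux(self, rng):
        f = rng.random((17, 23))
        out = diffuse(f, 8.0, dosing=False)
        assert out.sum() == pytest.approx(f.sum(), rel=1e-12)
        for _ in range(20):
            out = diffuse(out, 8.0, dosing=False)
        assert out.sum() == pytest.approx(f.sum(), rel=1e-10)

    def test_adi_converges_to_explicit_oracle(self):
        """One hot site on a 10x10 grid: the ADI solution approaches a
        refined forward-Euler solution as the ADI step is refined."""
        f = np.zeros((10, 10))
        f[4, 5] = 1.0
        d = 0.4
        oracle = explicit_diffusion_oracle(f, d, t_final=1.0, dt=0.001)
        errors = []
        for n_sub in (1, 5, 25):
            adi = f.copy()
            for _ in range(n_sub):
                adi = diffuse(adi, d, dosing=False, dt=1.0 / n_sub)
            errors.append(np.abs(adi - oracle).max())
            assert adi.sum() == pytest.approx(1.0, rel=1e-10)
        assert errors[2] < errors[1] < errors[0]  # refinement converges
        assert errors[2] < 2e-3

    def test_dirichlet_boundary_held_and_influx(self):
        f = np.zeros((12, 12))
        out = diffuse(f, 2.0, dosing=True, boundary_conc=1.0)
        assert np.allclose(out[0, :], 1.0) and np.allclose(out[:, -1], 1.0)
        assert out[1:-1, 1:-1].max() > 0  # drug moved inward
        assert out.sum() > f.sum()

    def test_negativity_clamped_and_nonfinite_rejected(self):
        f = np.zeros((8, 8))
        assert (diffuse(f, 1.0, dosing=False) >= 0).all()
        f[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            diffuse(f, 1.0, dosing=False)


class TestDecayAndUptake:
    def test_no_decay_no_tumor_is_identity(self):
        occ = make_grid((6, 6), neutral=[(2, 2)])
        f = np.full((6, 6), 0.5)
        assert np.array_equal(decay_and_uptake(f, occ, 1.0, 0.3), f)

    def test_uptake_applies_to_post_decay_value(self):
        occ = make_grid((3, 3), tumors=[(1, 1)])
        f = np.ones((3, 3))
        out = decay_and_uptake(f, occ, 0.9, 0.1)
        assert out[1, 1] == pytest.approx(0.81)
        assert out[0, 0] == pytest.approx(0.9)

    def test_full_decay_zeroes_field(self, rng):
        occ = make_grid((5, 5), tumors=[(2, 2)])
        out = decay_and_uptake(rng.random((5, 5)), occ, 0.0, 0.5)
        assert (out == 0).all()

    def test_mass_strictly_decreasing_with_decay(self, rng):
        occ = make_grid((9, 9), tumors=[(4, 4)])
        f = rng.random((9, 9)) + 0.1
        total = f.sum()
        for _ in range(5):
            f = diffuse(f, 2.0, dosing=False)
            f = decay_and_uptake(f, occ, 0.9, 0.05)
            assert f.sum() < total
            total = f.sum()


class TestChemoprotection:
    def test_complete_blockade(self):
        assert effective_concentration(5.0, 8, 1.0) == 0.0

    def test_no_gap_junction_factor(self):
        assert effective_concentration(0.8, 5, 0.0) == pytest.approx(0.8)

    def test_partial_protection(self):
        assert effective_concentration(1.0, 4, 0.5) == pytest.approx(0.75)

    def test_monotone_in_pro_neighbors(self):
        ceffs = [effective_concentration(1.0, n, 0.7) for n in range(9)]
        assert (np.diff(ceffs) < 0).all()
        deaths = [death_probability(c, 10.0, 0.5) for c in ceffs]
        assert (np.diff(deaths) < 0).all()  # survival rises with Npro

    def test_pro_moore_counts(self):
        occ = make_grid((5, 5), tumors=[(2, 2)],
                        pro=[(1, 1), (1, 2), (3, 3), (0, 0)])
        counts = pro_moore_counts(occ)
        assert counts[2, 2] == 3  # (0,0) outside the Moore neighborhood
        assert counts[0, 1] == 3  # (0,0), (1,1), (1,2) adjacent; (3,3) not

    def test_fully_shielded_death_is_drug_independent(self):
        """With Gf=1 and all 8 Moore neighbors pro-metastatic, the kill
        probability equals 1/(1+exp(k*T)) whatever the local drug."""
        params = ChemoParams(gap_junction_factor=1.0)
        occ = make_grid((5, 5), tumors=[(2, 2)],
                        pro=[(x, y) for x in range(1, 4) for y in range(1, 4)
                             if (x, y) != (2, 2)])
        expected = 1.0 / (1.0 + math.exp(params.kill_steepness * params.kill_half_conc))
        for level in (0.0, 1.0, 50.0):
            drug = np.full((5, 5), level)
            field = death_probability_field(drug, occ, params)
            assert field[2, 2] == pytest.approx(expected, rel=1e-12)


class TestDeathProbability:
    def test_half_at_threshold(self):
        assert death_probability(0.5, 10.0, 0.5) == 0.5

    def test_untreated_survival(self):
        assert death_probability(0.0, 10.0, 2.0) < 2.1e-9

    def test_derived_value(self):
        assert death_probability(2.0, 5.0, 1.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-5.0)), rel=1e-12
        )

    def test_monte_carlo_matches_sigmoid(self):
        rng = np.random.default_rng(321)
        p = death_probability(0.6, 10.0, 0.5)
        n = 20000
        freq = (rng.random(n) < p).mean()
        se = math.sqrt(p * (1 - p) / n)
        assert freq == pytest.approx(p, abs=4 * se)


class TestScheduler:
    def make_state(self, n_tumor):
        occ = make_grid((60, 60))
        occ.ravel()[:n_tumor] = CellKind.TUMOR
        return LatticeState(occupancy=occ, drug=np.zeros((60, 60)))

    def test_below_threshold_never_doses(self):
        state = self.make_state(2999)
        assert update_treatment_state(state, ChemoParams()) is False
        assert not state.treatment_active

    def test_reaching_threshold_activates(self):
        state = self.make_state(3000)
        assert update_treatment_state(state, ChemoParams()) is True
        assert state.treatment_active and state.treatment_start_step == 0

    def test_cycle_pattern_14_on_7_off(self):
        params = ChemoParams()
        flags = [is_dosing(t, params) for t in range(43)]
        assert flags[:14] == [True] * 14
        assert flags[14:21] == [False] * 7
        assert flags[21:35] == [True] * 14
        assert flags[42] is True  # cycles forever

    def test_untreated_control_never_doses(self):
        state = self.make_state(50000 // 10)
        assert update_treatment_state(state, None) is False
        assert not state.treatment_active

    def test_treatment_persists_below_threshold(self):
        params = ChemoParams(start_threshold=100)
        state = self.make_state(150)
        assert update_treatment_state(state, params)
        # tumor shrinks below threshold: treatment continues cycling
        state.occupancy[:] = 0
        state.timestep = 20
        assert state.treatment_active
        assert update_treatment_state(state, params) is False  # rest phase
        state.timestep = 21
        assert update_treatment_state(state, params) is True
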