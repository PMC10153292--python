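"""Model builder: state layout, wiring, compiled-vs-interpreted agreement."""

import numpy as np
import pytest

from segpol import (GridSpec, GuardConfig, build_grid, build_model,
                    load_catalog, rhs_from_reactions, single_cell_model)
from segpol.model import MEMBRANE, MRNAS, N_SPECIES_PER_CELL
from segpol.simulate import SimulationConfig, SteadyStateConfig, find_steady_state, integrate


class TestStructure:
    def test_1x4_has_132_state_variables(self, model_1x4):
        assert model_1x4.n_states == 132

    def test_2x3_has_198_state_variables(self):
        assert build_model(GridSpec(2, 3)).n_states == 33 * 6

    def test_catalog_counts(self):
        cat = load_catalog()
        assert len(cat) == 53
        assert len(cat.sampled_names) == 48

    def test_ptc0_hh0_ranges(self):
        cat = load_catalog()
        for name in ("PTC0", "HH0"):
            assert (cat[name].lo, cat[name].hi) == (1.0, 1000.0)

    def test_species_index_roundtrip(self, model_1x4):
        seen = set()
        for i in range(model_1x4.n_states):
            name = model_1x4.species_name(i)
            seen.add(name)
            base, cell = name.rsplit("_", 2)[0], name.split("_")[-2:]
            cell = (int(cell[0]), int(cell[1]))
            if base[-1].isdigit():
                assert model_1x4.species_index(base[:-1], cell, int(base[-1])) == i
            else:
                assert model_1x4.species_index(base, cell) == i
        assert len(seen) == model_1x4.n_states

    def test_side_argument_required_iff_membrane(self, model_1x4):
        for nm in MRNAS:
            with pytest.raises(KeyError):
                model_1x4.species_index(nm, 0, 3)
        for nm in MEMBRANE:
            with pytest.raises(KeyError):
                model_1x4.species_index(nm, 0)

    def test_missing_parameter_is_a_named_error(self):
        from segpol.catalog import ParameterSet
        cat = load_catalog()
        vals = {e.name: e.default for e in cat.entries}
        del vals["kappa_CNen"]
        with pytest.raises(KeyError, match="kappa_CNen"):
            ParameterSet(vals, catalog=cat)


class TestNeighborEwgTotal:
    def test_zero_state_gives_zero(self, model_1x4):
        assert model_1x4.neighbor_ewg_total(np.zeros(132), 0) == 0.0

    def test_uniform_faces_give_six_c(self, model_1x4):
        x = np.zeros(132)
        for c in range(4):
            for s in range(1, 7):
                x[model_1x4.species_index("EWG", c, s)] = 0.25
        assert model_1x4.neighbor_ewg_total(x, 2) == pytest.approx(6 * 0.25)

    def test_spot_value_on_one_apposed_face(self, model_1x4, grid_1x4):
        # put EWG only on the face of (0,2) apposed to side 1 of (0,1)
        ncell, nside = grid_1x4.neighbor((0, 1), 1)
        x = np.zeros(132)
        x[model_1x4.species_index("EWG", ncell, nside)] = 0.7
        assert model_1x4.neighbor_ewg_total(x, (0, 1)) == pytest.approx(0.7)

    def test_ewg_totals_partition_all_faces(self, model_1x4, rng):
        # apposition is a bijection, so summing EWG_T over cells counts
        # every membrane face exactly once
        x = np.zeros(132)
        for c in range(4):
            for s in range(1, 7):
                x[model_1x4.species_index("EWG", c, s)] = rng.uniform()
        total = sum(model_1x4.neighbor_ewg_total(x, c) for c in range(4))
        faces = sum(x[model_1x4.species_index("EWG", c, s)]
                    for c in range(4) for s in range(1, 7))
        assert total == pytest.approx(faces)


class TestRhs:
    def test_compiled_kernel_matches_reaction_table(self, model_1x4, rng):
        """The njit kernel and the interpreted reaction-table evaluator are
        independent renderings of the same network; they must agree."""
        for _ in range(5):
            y = rng.uniform(0, 1, 132)
            np.testing.assert_allclose(
                model_1x4.rhs(0.0, y), rhs_from_reactions(model_1x4, y),
                rtol=1e-12, atol=1e-14)

    def test_guarded_rhs_finite_for_any_finite_state(self, model_1x4, rng):
        for scale in (1.0, 1e3, 1e8):
            y = rng.uniform(-scale, scale, 132)
            assert np.all(np.isfinite(model_1x4.rhs(0.0, y)))

    def test_trajectories_stay_nonnegative(self, model_1x4, crisp_ic):
        traj = integrate(model_1x4, crisp_ic, SimulationConfig(t_end=300))
        assert not traj.failed
        assert traj.states.min() >= -1e-9

    def test_spatial_symmetry_preserved(self, model_1x4, rng):
        """Identical cells + uniform state stay identical in every cell."""
        cell = rng.uniform(0, 1, 33)
        x0 = np.tile(cell, 4)
        traj = integrate(model_1x4, x0, SimulationConfig(t_end=200))
        assert not traj.failed
        final = traj.final_state.reshape(4, 33)
        for c in range(1, 4):
            np.testing.assert_allclose(final[c], final[0], rtol=1e-7, atol=1e-9)

    def test_wingless_conserved_between_iwg_and_ewg_pools(self, grid_1x4):
        """With wingless synthesis and decay switched off, exo/endocytosis
        and lateral transfer only move protein between IWG and the six EWG
        pools: the total is a conserved quantity."""
        params = load_catalog().defaults().replace(
            H_wg=1e30, H_IWG=1e30, H_EWG=1e30)
        m = build_model(grid_1x4, params)
        rng = np.random.default_rng(5)
        x0 = rng.uniform(0, 1, 132)
        for c in range(4):  # no wg mRNA -> no translation influx
            x0[m.species_index("wg", c)] = 0.0
        idx = [m.species_index("IWG", c) for c in range(4)] + [
            m.species_index("EWG", c, s) for c in range(4) for s in range(1, 7)]
        traj = integrate(m, x0, SimulationConfig(t_end=500))
        assert not traj.failed
        totals = traj.states[:, idx].sum(axis=1)
        np.testing.assert_allclose(totals, totals[0], rtol=1e-7)


class TestSingleCell:
    def test_species_count_is_33(self):
        m = single_cell_model(fixed_neighbor_inputs={
            "EWG": np.zeros(6), "HH": np.zeros(6), "PTC": np.zeros(6)})
        assert m.n_states == 33

    def test_missing_fixed_input_rejected(self):
        with pytest.raises(KeyError):
            single_cell_model(fixed_neighbor_inputs={"EWG": np.zeros(6)})
        with pytest.raises(KeyError):
            single_cell_model(fixed_neighbor_inputs=None)

    def test_zero_fixed_inputs_silence_en_transcription(self):
        m = single_cell_model(fixed_neighbor_inputs={
            "EWG": np.zeros(6), "HH": np.zeros(6), "PTC": np.zeros(6)})
        y = np.zeros(33)
        i_en = m.species_index("en", 0)
        y[i_en] = 0.5
        d_en = np.log(2.0) / m.params["H_en"]
        # pure decay: the guarded inducer term is eps-order, i.e. zero
        assert m.rhs(0.0, y)[i_en] == pytest.approx(-d_en * 0.5, rel=1e-9)

    def test_reproduces_full_model_cell_at_steady_state(self, model_1x4, crisp_ic):
        """Freeze one cell's cross-cell inputs at a 4-cell steady state; the
        single-cell model must hold that cell's state as its own fixed point."""
        res = find_steady_state(model_1x4, crisp_ic, SteadyStateConfig())
        assert res.found, "default parameters should relax to a fixed point"
        state = res.state
        cell = 1
        fixed = {"EWG": np.zeros(6), "HH": np.zeros(6), "PTC": np.zeros(6)}
        for s in range(1, 7):
            n, t = model_1x4.grid.neighbor((0, cell), s)
            for nm in fixed:
                fixed[nm][s - 1] = state[model_1x4.species_index(nm, n, t)]
        m1 = single_cell_model(fixed_neighbor_inputs=fixed)
        y = state[33 * cell: 33 * (cell + 1)]
        assert np.max(np.abs(m1.rhs(0.0, y))) <= 1e-4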