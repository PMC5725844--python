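"""Per-tick cell rules: fluctuation, cycle/mitosis, movement, ligand release."""

import numpy as np
import pytest

from scratchsim import initialize, update_density, validate_params
from scratchsim import cells as cell_rules
from scratchsim.world import BLUE, GREEN, LIGHT_GREEN, ORANGE, PERIWINKLE, RED

from conftest import add_cells


def bare_world(**overrides):
    p = validate_params({"scratch_line": -32, **overrides})
    with pytest.warns(UserWarning):
        return initialize(p)


class TestUpdateParams:
    def test_zero_deviation_keeps_mu_at_configured_rate(self):
        w = bare_world(deviation_from_avg=0.0)
        add_cells(w, [(0.0, 0.0)], released=True, color=GREEN)
        update_density(w)
        for _ in range(50):
            cell_rules.update_params(w)
            assert w.mu[0] == pytest.approx(0.23)

    def test_fluctuation_is_centred_on_configured_rate(self):
        w = bare_world(deviation_from_avg=0.3)
        add_cells(w, [(float(x), 0.0) for x in range(-20, 20)])
        update_density(w)
        mus = []
        for _ in range(400):
            cell_rules.update_params(w)
            mus.append(w.mu.copy())
        mus = np.concatenate(mus)
        assert mus.mean() == pytest.approx(0.23, abs=0.005)
        assert mus.max() <= 0.23 + 0.3 + 1e-9
        assert mus.min() >= 0.23 - 0.3 - 1e-9

    def test_cycle_advances_one_tick(self):
        w = bare_world()
        add_cells(w, [(0.0, 0.0)], cycle=10)
        update_density(w)
        cell_rules.update_params(w)
        assert w.cycle[0] == 11

    def test_phase_transition_at_boundary(self):
        w = bare_world()
        add_cells(w, [(0.0, 0.0)], cycle=w.schedule.g1_end - 1)
        update_density(w)
        assert w.cell(0).phase == "G1"
        cell_rules.update_params(w)
        assert w.cell(0).phase == "S"


class TestMitosis:
    def prime_for_division(self, w, coords, **kw):
        add_cells(w, coords, cycle=w.schedule.total_ticks - 1, **kw)
        update_density(w)
        cell_rules.update_params(w)

    def test_blue_parent_spawns_periwinkle_daughter(self):
        w = bare_world(deviation_from_avg=0.0)
        self.prime_for_division(w, [(0.0, 0.0)], color=BLUE)
        assert w.n_cells == 2
        assert w.color[1] == PERIWINKLE
        assert not w.released[1]
        assert w.cycle[0] == 0 and w.cycle[1] == 0

    def test_green_parent_spawns_untracked_light_green(self):
        w = bare_world(deviation_from_avg=0.0)
        self.prime_for_division(
            w, [(0.0, 0.0)], color=GREEN, released=True, tracked=True
        )
        assert w.color[1] == LIGHT_GREEN
        assert w.released[1]  # green daughters are released from birth
        assert not w.tracked[1]  # daughters never join the tracked cohort

    def test_no_open_space_skips_daughter(self):
        w = bare_world(crowding_threshold=1)
        ring = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
        add_cells(w, ring)
        self.prime_for_division(w, [(0.0, 0.0)])
        assert w.n_cells == 9  # parent + ring, no daughter
        assert w.cycle[-1] == 0  # parent's cycle restarted anyway


class TestCellDiffuse:
    def test_crowded_patch_behind_forces_east_step(self):
        w = bare_world(randomness=0.0)
        add_cells(w, [(0.0, 0.0), (-1.0, 0.0), (-1.0, 0.0), (-1.0, 0.0)])
        update_density(w)
        x0 = w.x[0]
        cell_rules.cell_diffuse(w)
        assert w.x[0] > x0
        assert w.y[0] == pytest.approx(0.0)

    def test_unique_open_direction_is_taken(self):
        w = bare_world(randomness=0.0, crowding_threshold=1, deviation_from_avg=0.0)
        ring = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                if (dx, dy) not in ((0, 0), (1, 0))]
        add_cells(w, [(0.0, 0.0)])
        add_cells(w, ring)
        update_density(w)
        cell_rules.cell_diffuse(w)
        step = np.sqrt(2.0) * 0.23 * w.params.dt_effective
        assert w.x[0] == pytest.approx(step)
        assert w.y[0] == pytest.approx(0.0)

    def test_enclosed_cell_is_stationary(self):
        w = bare_world(randomness=0.0, crowding_threshold=1)
        ring = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
        add_cells(w, [(0.0, 0.0)])
        add_cells(w, ring)
        update_density(w)
        cell_rules.cell_diffuse(w)
        assert w.x[0] == pytest.approx(0.0)
        assert w.y[0] == pytest.approx(0.0)

    def test_pure_random_walk_statistics(self):
        # randomness 1: isotropic steps of length sqrt(2)*mu*dt
        w = bare_world(randomness=1.0, deviation_from_avg=0.0)
        n = 500
        coords = [(0.0, 0.0)] * n
        add_cells(w, coords)
        update_density(w)
        cell_rules.cell_diffuse(w)
        dx, dy = w.x, w.y
        step = np.sqrt(2.0) * 0.23 * w.params.dt_effective
        assert np.hypot(dx, dy) == pytest.approx(step, rel=1e-9)
        assert abs(dx.mean()) < 3 * step / np.sqrt(n)
        assert abs(dy.mean()) < 3 * step / np.sqrt(n)

    def test_positions_stay_in_bounds(self):
        w = bare_world(randomness=1.0)
        add_cells(w, [(w.x_min, w.y_min), (w.x_max, w.y_max)])
        update_density(w)
        for _ in range(30):
            cell_rules.cell_diffuse(w)
        assert (w.x >= w.x_min - 0.5).all() and (w.x <= w.x_max + 0.5).all()
        assert (w.y >= w.y_min - 0.5).all() and (w.y <= w.y_max + 0.5).all()


class TestLigandProduction:
    def test_blue_cell_past_line_turns_red_and_hatches_four(self):
        w = bare_world()
        w.params = validate_params({"scratch_line": 0})
        add_cells(w, [(2.0, 0.0)], color=BLUE)
        update_density(w)
        spawned = cell_rules.l_production(w)
        assert w.color[0] == RED
        assert w.released[0]
        assert spawned == 4
        assert w.n_ligands == 4

    def test_released_cell_spawn_rate_is_five_percent(self):
        w = bare_world()
        w.params = validate_params({"scratch_line": 0})
        add_cells(w, [(5.0, 0.0)], color=RED, released=True)
        update_density(w)
        events = 0
        total = 0
        for _ in range(2000):
            before = w.n_ligands
            cell_rules.l_production(w)
            got = w.n_ligands - before
            events += got > 0
            total += got
        # binomial(2000, 0.05) spawn events of uniform 1..4 molecules
        assert 60 <= events <= 140
        assert total / max(events, 1) == pytest.approx(2.5, abs=0.5)

    def test_red_cell_reverts_only_under_adhesion(self):
        for adhesion, expect_color in ((True, BLUE), (False, RED)):
            w = bare_world(cellular_adhesion=adhesion)
            w.params = validate_params(
                {"scratch_line": 0, "cellular_adhesion": adhesion}
            )
            add_cells(w, [(2.0, 0.0)], color=RED, released=True)
            add_cells(w, [(3.0, 0.0), (3.0, 0.0)])  # two cells in the path ahead
            update_density(w)
            cell_rules.l_production(w)
            assert w.color[0] == expect_color
            assert w.released[0] == (expect_color == RED)

    def test_green_cells_never_revert(self):
        w = bare_world(cellular_adhesion=True)
        w.params = validate_params({"scratch_line": 0, "cellular_adhesion": True})
        add_cells(w, [(2.0, 0.0)], color=GREEN, released=True, tracked=True)
        add_cells(w, [(3.0, 0.0), (3.0, 0.0)])
        update_density(w)
        cell_rules.l_production(w)
        assert w.color[0] == GREEN
        assert w.released[0]

    def test_orange_daughter_transitions_mirror_red(self):
        w = bare_world(cellular_adhesion=True)
        w.params = validate_params({"scratch_line": 0, "cellular_adhesion": True})
        add_cells(w, [(2.0, 0.0)], color=ORANGE, released=True)
        add_cells(w, [(3.0, 0.0), (3.0, 0.0)])
        update_density(w)
        cell_rules.l_production(w)
        assert w.color[0] == PERIWINKLE
        assert not w.released[0]
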