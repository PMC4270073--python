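"""Population dynamics: growth, adhesion, fragmentation, and bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from clumpclock import OscillatorParams, Population, density_after_doublings, init_population


class TestInitPopulation:
    def test_single_cell_delta_phase(self, params):
        pop = init_population(1, params, phase_mode="delta", phase=0.0)
        assert pop.n_cells == 1
        assert pop.n_clumps == 1
        assert pop.phase[0] == 0.0

    def test_uniform_phases_pass_ks_test(self, params):
        pop = init_population(1000, params, phase_mode="uniform", seed=1)
        assert pop.n_clumps == 1000
        stat = stats.kstest(pop.phase, "uniform", args=(0, params.period))
        assert stat.pvalue > 0.01

    def test_nonpositive_size_rejected(self, params):
        with pytest.raises(ValueError):
            init_population(0, params)

    def test_unknown_phase_mode_rejected(self, params):
        with pytest.raises(ValueError):
            init_population(5, params, phase_mode="gaussian")


class TestStep:
    def test_null_dynamics_only_advance_phase(self, frozen_params):
        pop = init_population(50, frozen_params, phase_mode="uniform", seed=2)
        before_phase = pop.phase.copy()
        before_labels = pop.clump_labels.copy()
        pop.step(1.0)
        assert pop.n_cells == 50
        np.testing.assert_array_equal(pop.clump_labels, before_labels)
        np.testing.assert_allclose(
            pop.phase, (before_phase + 1.0) % frozen_params.period
        )

    def test_invalid_dt_rejected(self, params):
        pop = init_population(5, params, seed=0)
        with pytest.raises(ValueError):
            pop.step(0.0)
        with pytest.raises(ValueError):
            pop.step(-1.0)
        with pytest.raises(ValueError):
            pop.step(params.doubling_time)  # coarser than doubling_time/4

    def test_wall_labeled_founder_builds_lineage_clump(self, clonal_params):
        # one labeled single cell at the start of the adhesive window grows
        # inside it: one clump, exactly one labeled cell, unlabeled daughters,
        # one lineage (divisions exactly at the window edge bud off, so stay
        # strictly inside)
        pop = init_population(1, clonal_params, phase_mode="delta", phase=0.0)
        pop.label_walls()
        pop.run(8.0)
        assert pop.n_clumps == 1
        assert pop.n_cells == 2 ** 4  # 8 hr of divisions every 2 hr
        assert int(pop.wall.sum()) == 1
        assert np.unique(pop.lineage).size == 1

    def test_cell_count_never_decreases_and_sizes_sum(self, params):
        pop = init_population(100, params, phase_mode="uniform", seed=3)
        for _ in range(40):
            before = pop.n_cells
            pop.step(0.5)
            assert pop.n_cells >= before
            assert int(pop.clump_sizes().sum()) == pop.n_cells

    def test_daughters_inherit_everything_but_wall_label(self, clonal_params):
        pop = init_population(4, clonal_params, phase_mode="delta", phase=2.0)
        pop.cfp[:2] = True
        pop.genotype[:] = 7
        pop.label_walls()
        pop.run(4.0)
        assert pop.n_cells == 16
        for label in np.unique(pop.clump_labels):
            members = pop.clump_labels == label
            assert np.unique(pop.lineage[members]).size == 1
            assert np.unique(pop.cfp[members]).size == 1
        assert (pop.genotype == 7).all()
        assert int(pop.wall.sum()) == 4  # only the founders

    def test_phase_advances_exactly_dt_without_division(self, frozen_params):
        pop = init_population(20, frozen_params, phase_mode="delta", phase=23.5)
        pop.step(1.0)
        np.testing.assert_allclose(pop.phase, 0.5)

    def test_doubling_calibration_matches_closed_form(self):
        # expected growth is N0 * 2**(t/tau) under the hazard model
        p = OscillatorParams(doubling_time=2.0, fragmentation_rate=0.0)
        pop = init_population(4000, p, phase_mode="uniform", seed=4)
        pop.run(6.0)
        expected = 4000 * 2 ** (6.0 / 2.0)
        assert abs(pop.n_cells - expected) / expected < 0.10

    def test_deterministic_mode_doubles_exactly(self, clonal_params):
        pop = init_population(10, clonal_params, phase_mode="delta", phase=12.0)
        pop.run(6.0)
        assert pop.n_cells == 10 * 2 ** 3

    def test_clump_size_cap_enforced(self):
        p = OscillatorParams(
            division_mode="deterministic",
            phase_jitter_sd=0.0,
            fragmentation_rate=0.0,
            max_tracked_clump=4,
        )
        pop = init_population(1, p, phase_mode="delta", phase=0.0)
        pop.run(6.0)  # 8-cell clump exceeds the cap of 4
        with pytest.raises(RuntimeError):
            pop.clump_labels


class TestSonicate:
    def test_breaks_one_clump_to_singletons(self, params):
        pop = Population.from_clump_sizes([10], params)
        pop.sonicate()
        assert pop.n_clumps == 10
        assert pop.n_cells == 10

    def test_noop_on_singletons(self, params):
        pop = init_population(5, params, seed=0)
        pop.sonicate()
        assert pop.n_clumps == 5

    def test_clump_count_equals_cell_count_after(self, params):
        pop = init_population(30, params, phase_mode="uniform", seed=5)
        pop.run(12.0)
        n = pop.n_cells
        pop.sonicate()
        assert pop.n_clumps == n


class TestReadhere:
    def test_zero_stick_prob_forms_no_bonds(self, frozen_params):
        pop = init_population(100, frozen_params, phase_mode="delta", phase=1.0)
        pop.readhere(1.5, stick_prob=0.0)
        assert pop.n_clumps == 100

    def test_outside_window_forms_no_bonds(self, frozen_params):
        pop = init_population(
            100, frozen_params, phase_mode="delta", phase=frozen_params.period - 1.0
        )
        pop.readhere(1.5, stick_prob=1.0)
        assert pop.n_clumps == 100

    def test_pairwise_sticking_mixes_colors_evenly(self, frozen_params):
        # equal CFP+/CFP- mix, forced pairing: ~half of 2-cell clumps mixed
        pop = init_population(2000, frozen_params, phase_mode="delta", phase=1.0, seed=6)
        pop.cfp[:1000] = True
        pop.readhere(1.5, stick_prob=1.0, seed=7)
        labels = pop.clump_labels
        sizes = np.bincount(labels)
        mixed = sum(
            1
            for lbl in np.flatnonzero(sizes == 2)
            if np.unique(pop.cfp[labels == lbl]).size == 2
        )
        frac = mixed / (sizes == 2).sum()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(1000)

    def test_requires_singletons(self, params):
        pop = Population.from_clump_sizes([3, 1], params)
        with pytest.raises(ValueError):
            pop.readhere(1.5, stick_prob=0.5)


class TestDilute:
    def test_tenfold_dilution_of_singletons(self, params):
        pop = init_population(10_000, params, phase_mode="uniform", seed=8)
        pop.dilute(pop.density / 10)
        # hypergeometric tolerance, 3 SD
        assert abs(pop.n_cells - 1000) <= 3 * np.sqrt(1000 * 0.9)

    def test_target_at_or_above_current_rejected(self, params):
        pop = init_population(100, params, seed=0)
        with pytest.raises(ValueError):
            pop.dilute(pop.density)

    def test_whole_clumps_only(self, params):
        sizes = [5, 3, 1, 7, 2, 4, 6, 1, 1, 8]
        pop = Population.from_clump_sizes(sizes, params, seed=9)
        pop.dilute_to_count(15)
        kept = sorted(pop.clump_sizes().tolist())
        # every kept clump size existed in the input multiset
        remaining = list(sizes)
        for s in kept:
            assert s in remaining
            remaining.remove(s)


class TestLabelWalls:
    def test_labels_all_current_cells_idempotently(self, params):
        pop = init_population(10, params, seed=0)
        pop.label_walls().label_walls()
        assert pop.wall.all()

    def test_only_preexisting_cells_labeled_after_division(self, clonal_params):
        pop = init_population(6, clonal_params, phase_mode="delta", phase=0.0)
        pop.label_walls()
        original = set(pop.cell_id.tolist())
        pop.run(2.0)  # exactly one division each
        assert pop.n_cells == 12
        labeled = set(pop.cell_id[pop.wall].tolist())
        assert labeled == original


class TestLineageInvariants:
    def test_lineage_and_color_purity_over_trajectory(self, params):
        # with re-adhesion disabled, clumps never mix founders or CFP states
        pop = init_population(50, params, phase_mode="uniform", seed=10)
        pop.cfp[:25] = True
        for _ in range(28):
            pop.step(0.5)
            labels = pop.clump_labels
            for lbl in np.unique(labels):
                members = labels == lbl
                assert np.unique(pop.lineage[members]).size == 1
                assert np.unique(pop.cfp[members]).size == 1

    def test_single_wall_label_per_clump(self, params):
        pop = init_population(40, params, phase_mode="uniform", seed=11)
        pop.label_walls()
        pop.run(14.0)
        labels = pop.clump_labels
        for lbl in np.unique(labels):
            assert int(pop.wall[labels == lbl].sum()) <= 1


def test_density_after_doublings_closed_form():
    assert density_after_doublings(10.0, 16) == 10 * 2 ** 16
    with pytest.raises(ValueError):
        density_after_doublings(0.0, 4)


def test_population_frame_roundtrip(params, tmp_path):
    pop = Population.from_clump_sizes([3, 1, 2], params)
    frame = pop.to_frame()
    assert len(frame) == 6
    assert set(frame.columns) >= {"cell_id", "clump_id", "lineage_id", "phase"}
    pop.write_tsv(tmp_path / "pop.tsv")
    assert (tmp_path / "pop.tsv").exists()
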