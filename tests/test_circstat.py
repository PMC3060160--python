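"""Circular-linear regression, CP/CD estimation and population statistics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import itdcode as it
from itdcode._wrap import circ_dist, resultant_length, wrap_half
from itdcode.circstat import (
    CellCharacteristics,
    PhaseFrequencyCurve,
    bandwise_cd_tonotopy,
    bootstrap_cp_cd_sem,
    cells_from_table,
    cells_to_table,
    characterize_cell,
    circ_linear_corr,
    circ_linear_fit,
    population_cp_cd_stats,
    quarter_octave_bands,
)
from itdcode.tuning import CyclicGaussianParams

FREQS = np.linspace(600.0, 1000.0, 5)
CD_BOUNDS = (-3e-3, 3e-3)  # s (i.e. +-3 ms)


class TestCircLinearFit:
    def test_antiphasic_cell_has_cp_half_cd_zero(self):
        """A trougher (ipsi excitation / contra inhibition) peaks at 0.5 cycles."""
        fit = circ_linear_fit(FREQS, np.full(5, 0.5), CD_BOUNDS, grid_step=1e-5)
        assert fit.slope == pytest.approx(0.0, abs=1e-7)
        assert fit.offset == pytest.approx(0.5, abs=1e-6)
        assert fit.resultant_length == pytest.approx(1.0, abs=1e-9)

    def test_pure_delay_line_has_cp_zero(self):
        """A Jeffress-style delay line: best IPD = f * CD, zero phase offset."""
        fit = circ_linear_fit(FREQS, FREQS * 0.3e-3, CD_BOUNDS, grid_step=1e-5)
        assert fit.slope * 1e3 == pytest.approx(0.3, abs=1e-5)  # CD in ms
        assert fit.offset == pytest.approx(0.0, abs=1e-5)
        assert fit.resultant_length == pytest.approx(1.0, abs=1e-9)

    def test_slope_matches_brute_force_grid_oracle(self):
        """The two-stage maximizer agrees with an exhaustive R_V grid search."""
        rng = np.random.default_rng(11)
        phi = wrap_half(0.12 + FREQS * (-0.8e-3) + rng.normal(0, 0.02, 5))
        fit = circ_linear_fit(FREQS, phi, CD_BOUNDS, grid_step=1e-5)
        grid = np.arange(CD_BOUNDS[0], CD_BOUNDS[1] + 5e-6, 1e-5)
        rv = [resultant_length(phi - m * FREQS) for m in grid]
        m_star = grid[int(np.argmax(rv))]
        assert abs(fit.slope - m_star) <= 1e-5  # within one refinement step
        assert max(rv) <= fit.resultant_length + 1e-12

    def test_rv_bounds_and_identical_residuals(self):
        phi = wrap_half(0.3 + FREQS * 0.5e-3)
        fit = circ_linear_fit(FREQS, phi, CD_BOUNDS, grid_step=1e-5)
        assert 0.0 <= fit.resultant_length <= 1.0
        assert fit.resultant_length == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, max_examples=25)
    @given(shift=st.floats(-0.5, 0.5))
    def test_offset_equivariance_under_phase_shift(self, shift):
        rng = np.random.default_rng(7)
        phi = wrap_half(0.1 + FREQS * (-0.4e-3) + rng.normal(0, 0.03, 5))
        a = circ_linear_fit(FREQS, phi, CD_BOUNDS, grid_step=2e-5)
        b = circ_linear_fit(FREQS, wrap_half(phi + shift), CD_BOUNDS, grid_step=2e-5)
        assert b.slope == pytest.approx(a.slope, abs=2e-5)
        assert abs(circ_dist(b.offset, a.offset + shift)) < 1e-3

    def test_slope_rescales_with_x(self):
        rng = np.random.default_rng(13)
        phi = wrap_half(0.1 + FREQS * (-0.4e-3) + rng.normal(0, 0.01, 5))
        a = circ_linear_fit(FREQS, phi, CD_BOUNDS, grid_step=1e-5)
        s = 1e-3  # refit against frequency in kHz
        b = circ_linear_fit(FREQS * s, phi, (CD_BOUNDS[0] / s, CD_BOUNDS[1] / s),
                            grid_step=1e-5 / s)
        assert b.slope * s == pytest.approx(a.slope, abs=2e-5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            circ_linear_fit([1.0, 2.0], [0.1, 0.2], CD_BOUNDS)
        with pytest.raises(ValueError):
            circ_linear_fit(np.ones(5), np.full(5, 0.3), CD_BOUNDS)

    def test_edge_hit_flagged(self):
        # a slope just outside the search interval pulls the maximizer to it
        phi = wrap_half(FREQS * 1.2e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = circ_linear_fit(FREQS, phi, (-1e-3, 1e-3), grid_step=1e-5)
        assert fit.at_edge


class TestCharacterizeCell:
    def test_noiseless_recovery(self):
        shape = CyclicGaussianParams(10, 50, 0.15, 0.0)
        cp_true, cd_true = 0.1, -0.2  # cycles, ms
        phi = wrap_half(cp_true + cd_true * 1e-3 * FREQS)
        curve = PhaseFrequencyCurve("c1", tuple(FREQS), tuple(phi))
        cell = characterize_cell(curve, [shape] * 5, bf=800.0)
        assert abs(circ_dist(cell.cp, cp_true)) < 0.02
        assert cell.cd == pytest.approx(cd_true, abs=0.02)
        assert -0.5 < cell.cp <= 0.5
        assert cell.cd_scaled == pytest.approx(cell.cd * 1e-3 * cell.bf)

    def test_shape_is_elementwise_mean(self):
        shapes = [
            CyclicGaussianParams(10, 40, 0.10, 0.0),
            CyclicGaussianParams(20, 60, 0.20, 0.0),
            CyclicGaussianParams(30, 50, 0.15, 0.0),
        ]
        phi = wrap_half(0.2 + 0.0 * FREQS[:3])
        curve = PhaseFrequencyCurve("c", tuple(FREQS[:3]), tuple(phi))
        cell = characterize_cell(curve, shapes, bf=800.0)
        assert cell.shape.baseline == pytest.approx(20.0)
        assert cell.shape.amplitude == pytest.approx(50.0)
        assert cell.shape.width == pytest.approx(0.15)


class TestPopulationStats:
    @staticmethod
    def _line_population(n=40, seed=0, noise=0.0):
        """Cells exactly on CP = 0.2 - CD / (2 ms per cycle)."""
        rng = np.random.default_rng(seed)
        shape = CyclicGaussianParams(10, 50, 0.15, 0.0)
        cells = []
        for i in range(n):
            cd = rng.uniform(-0.6, 0.6)  # ms
            cp = 0.2 - cd / 2.0 + (rng.normal(0, noise) if noise else 0.0)
            cells.append(
                CellCharacteristics(f"c{i}", 900.0, float(wrap_half(cp)), cd, shape)
            )
        return cells

    def test_line_recovered_with_two_ms_per_cycle_slope(self):
        stats = population_cp_cd_stats(self._line_population())
        assert stats.ms_per_cycle == pytest.approx(2.0, rel=0.02)
        assert stats.slope < 0
        assert stats.correlation > 0.9
        assert stats.p_value < 0.01

    def test_shuffled_cp_rarely_significant(self):
        """Shuffling CP across cells destroys the correlation in >= 90/100 seeds."""
        cells = self._line_population(n=50, noise=0.05)
        cp = np.array([c.cp for c in cells])
        cd = np.array([c.cd for c in cells])
        n_sig = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, p = circ_linear_corr(cp[rng.permutation(50)], cd)
            n_sig += p < 0.05
        assert n_sig <= 10

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            population_cp_cd_stats(self._line_population(n=3))


class TestBandwiseTonotopy:
    @staticmethod
    def _tonotopic_population(n_per_band=12, seed=1):
        """Constant-best-phase cells with CD proportional to 1/BF."""
        rng = np.random.default_rng(seed)
        shape = CyclicGaussianParams(10, 50, 0.15, 0.0)
        edges = quarter_octave_bands(500.0, 4)
        cells = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            for i in range(n_per_band):
                bf = rng.uniform(lo, hi)
                cds = rng.uniform(-0.4, 0.4)  # cycles; CD = cds/BF ~ 1/BF
                cp = wrap_half(0.2 - cds)
                cells.append(
                    CellCharacteristics(
                        f"b{lo:.0f}_{i}", float(bf), float(cp),
                        float(cds / (1e-3 * bf)), shape,
                    )
                )
        return cells, edges

    def test_cd_slope_magnitude_tracks_bf(self):
        cells, edges = self._tonotopic_population()
        res = bandwise_cd_tonotopy(cells, edges)
        assert len(res.slope) == 4
        # slope of CP vs CD (cycles/ms) ~ -BF*1e-3: ms-per-cycle shrinks with BF
        ms_per_cycle = 1.0 / np.abs(res.slope)
        assert np.all(np.diff(ms_per_cycle) < 0)
        assert res.bf_slope_correlation < -0.9  # steeper (more negative) at high BF

    def test_identical_cd_distribution_gives_flat_slopes(self):
        shape = CyclicGaussianParams(10, 50, 0.15, 0.0)
        edges = quarter_octave_bands(500.0, 2)
        cells = []
        for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            for i, (cd, cp) in enumerate([(-0.2, 0.3), (0.0, 0.2), (0.2, 0.1),
                                          (0.4, 0.0)]):
                cells.append(
                    CellCharacteristics(f"{b}_{i}", (lo + hi) / 2, cp, cd, shape)
                )
        res = bandwise_cd_tonotopy(cells, edges)
        assert res.slope[0] == pytest.approx(res.slope[1], abs=1e-6)

    def test_underfilled_band_skipped(self):
        cells, edges = self._tonotopic_population(n_per_band=12)
        # move all but 2 cells out of the first band
        first = [c for c in cells if c.bf < edges[1]][2:]
        kept = [c for c in cells if c not in first]
        with pytest.warns(UserWarning, match="skipped"):
            res = bandwise_cd_tonotopy(kept, edges)
        assert len(res.slope) == 3

    def test_empty_band_set_rejected(self):
        with pytest.raises(ValueError):
            bandwise_cd_tonotopy([], [800.0])


class TestBootstrapSem:
    @staticmethod
    def _measurements(cell, model, n_reps, seed=0):
        return it.generate_experiment(
            [cell], model, it.ExperimentProtocol(n_reps=n_reps), seed=seed
        )

    def test_zero_variance_gives_zero_sem(self, ridge_cell):
        quiet = it.RateNoiseModel(noise_scale=0.0)
        df = self._measurements(ridge_cell, quiet, n_reps=3)
        sem_cp, sem_cds = bootstrap_cp_cd_sem(df, quiet, quiet.duration,
                                              n_surrogates=3, seed=1)
        assert sem_cp == pytest.approx(0.0, abs=1e-6)
        assert sem_cds == pytest.approx(0.0, abs=1e-6)

    def test_reproducible_and_shrinks_with_repetitions(self, ridge_cell, model):
        noisy = model.with_noise_scale(4.0)
        df3 = self._measurements(ridge_cell, noisy, n_reps=3)
        df12 = self._measurements(ridge_cell, noisy, n_reps=12)
        a = bootstrap_cp_cd_sem(df3, noisy, noisy.duration, n_surrogates=4, seed=2)
        b = bootstrap_cp_cd_sem(df3, noisy, noisy.duration, n_surrogates=4, seed=2)
        assert a == b  # determinism contract
        c = bootstrap_cp_cd_sem(df12, noisy, noisy.duration, n_surrogates=4, seed=2)
        assert c[0] < a[0]

    def test_surrogate_count_validated(self, ridge_cell, model):
        df = self._measurements(ridge_cell, model, n_reps=3)
        with pytest.raises(ValueError):
            bootstrap_cp_cd_sem(df, model, model.duration, n_surrogates=1)


def test_cell_table_round_trip(small_population):
    table = cells_to_table(small_population)
    back = cells_from_table(table)
    for a, b in zip(small_population, back):
        assert a.cell_id == b.cell_id
        assert a.cp == pytest.approx(b.cp)
        assert a.cd == pytest.approx(b.cd)
        assert a.shape.width == pytest.approx(b.shape.width)
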