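"""Three-region segmentation, intersections, confinement, hysteresis."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from lyoglass import synthetic as syn
from lyoglass import transitions as tr
from lyoglass.config import TransitionSettings
from lyoglass.reference import REFERENCE_FITS


def _series(ref, grid, noise=0.0, seed=0, **overrides):
    spec = syn.PiecewiseModelSpec.from_reference(
        ref, temperature_k=grid, noise_sd_cm=noise, seed=seed, **overrides
    )
    return syn.simulate_temperature_series(spec, label=ref.label)


class TestFitThreeRegions:
    def test_noiseless_f2_recovers_printed_parameters_exactly(self, fine_grid_k):
        ref = REFERENCE_FITS["F2"]
        fit = tr.fit_three_regions(_series(ref, fine_grid_k))
        for got, want in zip(fit.slopes, ref.slopes):
            assert got == pytest.approx(want, rel=1e-9)
        assert fit.sse < 1e-10
        assert fit.tg_beta_k == pytest.approx(ref.tg_beta_k, abs=1e-6)
        assert fit.tg_alpha_k == pytest.approx(ref.tg_alpha_k, abs=1e-6)

    def test_breakpoints_bracket_transitions(self, fine_grid_k):
        ref = REFERENCE_FITS["F1"]
        fit = tr.fit_three_regions(_series(ref, fine_grid_k))
        i, j = fit.break_indices
        t = fine_grid_k
        step = t[1] - t[0]
        assert t[i - 1] - step <= fit.tg_beta_k <= t[i] + step
        assert t[j - 1] - step <= fit.tg_alpha_k <= t[j] + step

    def test_single_line_degenerates_with_balanced_tie_break(self):
        t = np.arange(100.0, 160.0, 5.0)  # 12 points
        s = tr.TemperatureSeries(t, 1.0 + 0.05 * t)
        fit = tr.fit_three_regions(s)
        assert fit.sse < 1e-12
        for m in fit.slopes:
            assert m == pytest.approx(0.05, abs=1e-9)
        assert fit.region_counts == (4, 4, 4)  # most balanced split wins

    def test_selected_split_beats_brute_force_rescan(self, coarse_grid_k):
        ref = REFERENCE_FITS["F3"]
        s = _series(ref, coarse_grid_k, noise=0.05, seed=5)
        fit = tr.fit_three_regions(s)
        # independent re-scan of every admissible breakpoint pair
        n = len(s)
        best = np.inf
        for i in range(3, n - 5):
            for j in range(i + 3, n - 2):
                sse = 0.0
                for a, b in ((0, i), (i, j), (j, n)):
                    x, y = s.temperature_k[a:b], s.absorption_cm[a:b]
                    w = 1.0 / s.sd_cm[a:b] ** 2
                    coef = np.polyfit(x, y, 1, w=np.sqrt(w))
                    sse += float(np.sum(w * (y - np.polyval(coef, x)) ** 2))
                best = min(best, sse)
        assert fit.sse <= best * (1 + 1e-9)

    def test_noisy_breakpoint_recovery_monte_carlo(self, coarse_grid_k):
        """Breakpoints land within one grid step in >= 90% of seeds."""
        ref = REFERENCE_FITS["F1"]
        step = coarse_grid_k[1] - coarse_grid_k[0]
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            s = _series(ref, coarse_grid_k, noise=0.05, seed=seed)
            fit = tr.fit_three_regions(s)
            ok = (
                abs(fit.tg_beta_k - ref.tg_beta_k) <= step
                and abs(fit.tg_alpha_k - ref.tg_alpha_k) <= step
            )
            hits += ok
        assert hits >= 0.9 * n_seeds

    def test_too_few_points_rejected(self):
        t = np.arange(100.0, 140.0, 5.0)
        with pytest.raises(ValueError, match="at least 9"):
            tr.fit_three_regions(tr.TemperatureSeries(t, np.ones_like(t)))


class TestIntersect:
    def test_simple_crossing(self):
        a = tr.LinearFit(1.0, 0.0, 0, 0, 0, 2)
        b = tr.LinearFit(-1.0, 2.0, 0, 0, 0, 2)
        assert tr.intersect(a, b) == pytest.approx(1.0)

    def test_parallel_guard(self):
        a = tr.LinearFit(0.0, 0.0, 0, 0, 0, 2)
        b = tr.LinearFit(1e-9, 0.0, 0, 0, 0, 2)
        with pytest.raises(tr.NoIntersectionError) as err:
            tr.intersect(a, b, rtol=1e-6)
        assert err.value.slope_difference == pytest.approx(-1e-9)

    def test_noiseless_f1_lines_cross_at_printed_transitions(self, fine_grid_k):
        ref = REFERENCE_FITS["F1"]
        fit = tr.fit_three_regions(_series(ref, fine_grid_k))
        assert tr.intersect(fit.regions[0], fit.regions[1]) == pytest.approx(262.0, abs=1e-6)
        assert tr.intersect(fit.regions[1], fit.regions[2]) == pytest.approx(336.0, abs=1e-6)


class TestClassifyMobility:
    def test_published_slope_table_reproduces_qualitative_split(self):
        """Plateau formulations are confined; monotonic ones are not."""
        for label, ref in REFERENCE_FITS.items():
            result = tr.result_from_slopes(
                ref.slopes, ref.slope_ses, ref.tg_beta_k, ref.tg_alpha_k, label
            )
            want = "confined" if ref.confined else "unconfined"
            assert result.mobility_class == want, label

    def test_equal_slopes_are_unconfined(self):
        result = tr.result_from_slopes((0.01, 0.05, 0.05), (0.001, 0.001, 0.001), 200, 300)
        assert result.mobility_class == "unconfined"

    def test_statistically_unsupported_decrease_is_unconfined(self):
        # large drop but even larger slope uncertainty: no confinement call
        result = tr.result_from_slopes((0.01, 0.05, 0.02), (0.001, 0.002, 0.02), 200, 300)
        assert result.mobility_class == "unconfined"


class TestCompareCycles:
    def test_identical_series_no_hysteresis(self, fine_grid_k):
        s = _series(REFERENCE_FITS["F2"], fine_grid_k)
        rep = tr.compare_cycles(s, s)
        assert not rep.hysteresis
        assert rep.delta_m3 == 0.0

    def test_constant_offset_no_hysteresis(self, fine_grid_k):
        s1 = _series(REFERENCE_FITS["F4"], fine_grid_k)
        s2 = tr.TemperatureSeries(s1.temperature_k, s1.absorption_cm + 3.0)
        rep = tr.compare_cycles(s1, s2)
        assert not rep.hysteresis
        assert rep.delta_m3 == pytest.approx(0.0, abs=1e-9)

    def test_flat_then_rising_region3_is_flagged(self, fine_grid_k):
        ref = REFERENCE_FITS["F2"]
        c1 = _series(ref, fine_grid_k, noise=0.02, seed=1, slopes=(0.021, 0.054, 0.0))
        c2 = _series(ref, fine_grid_k, noise=0.02, seed=2, slopes=(0.021, 0.054, 0.05))
        rep = tr.compare_cycles(c1, c2)
        assert rep.hysteresis
        assert rep.delta_m3 == pytest.approx(0.05, abs=0.01)


class TestTabulate:
    def test_seven_formulations_ordering_preserved(self, fine_grid_k):
        labels = ["F1", "F2", "F3", "F4", "F5", "F6", "F7"]
        fits = [tr.fit_three_regions(_series(REFERENCE_FITS[l], fine_grid_k)) for l in labels]
        table = tr.tabulate(fits)
        assert list(table["label"]) == labels
        row = table[table.label == "F6"].iloc[0]
        assert row.m1 == pytest.approx(0.0033, rel=1e-6)
        assert row.tg_beta_k == pytest.approx(135.0, abs=1e-6)
        assert row.tg_alpha_k == pytest.approx(262.0, abs=1e-6)

    def test_missing_label_gets_default(self, fine_grid_k):
        fit = tr.fit_three_regions(
            _series(REFERENCE_FITS["F1"], fine_grid_k)
        )
        fit.label = ""
        table = tr.tabulate([fit])
        assert table.label[0] == "series_0"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tr.tabulate([])


@given(
    scale=st.floats(0.1, 100.0),
    offset=st.floats(-50.0, 50.0),
    shift=st.floats(-30.0, 30.0),
)
def test_transition_temperatures_affine_invariant(scale, offset, shift):
    """Tg is invariant under absorption rescaling; temperature shifts move it."""
    grid = np.arange(100.0, 381.0, 10.0)
    ref = REFERENCE_FITS["F3"]
    base = _series(ref, grid)
    fit0 = tr.fit_three_regions(base)
    moved = tr.TemperatureSeries(
        base.temperature_k + shift, scale * base.absorption_cm + offset
    )
    fit1 = tr.fit_three_regions(moved)
    assert fit1.tg_beta_k == pytest.approx(fit0.tg_beta_k + shift, abs=1e-5)
    assert fit1.tg_alpha_k == pytest.approx(fit0.tg_alpha_k + shift, abs=1e-5)


def test_noise_monotonicity_of_breakpoint_error(coarse_grid_k):
    """More noise never improves expected breakpoint recovery."""
    ref = REFERENCE_FITS["F1"]
    med_errors = []
    for sd in (0.01, 0.05, 0.15):
        errs = []
        for seed in range(30):
            fit = tr.fit_three_regions(_series(ref, coarse_grid_k, noise=sd, seed=seed))
            errs.append(
                abs(fit.tg_beta_k - ref.tg_beta_k) + abs(fit.tg_alpha_k - ref.tg_alpha_k)
            )
        med_errors.append(np.median(errs))
    assert med_errors[0] <= med_errors[1] + 1e-9 <= med_errors[2] + 2e-9
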