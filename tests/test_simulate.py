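"""Agent-based labeling simulator against the closed-form model."""

import numpy as np
import pytest

from edukin import (
    CellCycleParams,
    EmptyPopulationError,
    LabelingProtocol,
    ParameterError,
    advance_and_label,
    expected_cumulative_li,
    init_population,
    measure_li,
    simulate_experiment,
)


def binom_se_percent(p_frac, n):
    return 100.0 * np.sqrt(p_frac * (1 - p_frac) / n)


class TestProtocol:
    def test_invalid_protocols_rejected(self):
        with pytest.raises(ParameterError):
            LabelingProtocol("pulse", 0.0, 0.0, (1.0,))  # zero duration
        with pytest.raises(ParameterError):
            LabelingProtocol("cumulative", 0.0, 48.0, (5.0, 5.0))  # not increasing
        with pytest.raises(ParameterError):
            LabelingProtocol("cumulative", 2.0, 48.0, (1.0,))  # sample before start
        with pytest.raises(ParameterError):
            LabelingProtocol("drip", 0.0, 1.0, (1.0,))  # unknown kind

    def test_negative_exposure_start_for_preamputation_labeling(self):
        p = LabelingProtocol.pulse(duration=0.25, start=-24.0)
        assert p.exposure_end == pytest.approx(-23.75)


class TestInitPopulation:
    def test_stratified_growth_fraction_is_exact(self):
        p = CellCycleParams(tc=20, ts=5, gf=80)
        pop = init_population(1000, p, seed=0)
        assert int(pop.cycling.sum()) == 800

    def test_quiescent_cell_never_labels(self):
        # gf so small that round(n*gf/100) = 0: a single quiescent cell
        pop = init_population(1, CellCycleParams(tc=20, ts=5, gf=0.0001), seed=0)
        proto = LabelingProtocol.cumulative([100.0])
        advance_and_label(pop, proto, 100.0)
        c = measure_li(pop)
        assert c.n_labeled == 0 and not pop.cycling.any()

    def test_empty_population_rejected(self):
        p = CellCycleParams(tc=20, ts=5, gf=80)
        with pytest.raises(EmptyPopulationError):
            init_population(0, p)

    def test_uniform_age_s_occupancy_matches_ts_over_tc(self):
        # Monte-Carlo: fraction of cycling cells in S at init -> Ts/Tc
        p = CellCycleParams(tc=20, ts=5, gf=100)
        hits = total = 0
        for seed in range(400):
            pop = init_population(10, p, seed=seed)
            in_s = (pop.age >= p.s_start) & (pop.age < p.s_end)
            hits += int(in_s.sum())
            total += 10
        frac = hits / total
        se = np.sqrt(0.25 * 0.75 / total)
        assert abs(frac - p.ts / p.tc) < 3 * se

    def test_reproducible_under_seed(self):
        p = CellCycleParams(tc=20, ts=5, gf=60)
        a = init_population(100, p, seed=7)
        b = init_population(100, p, seed=7)
        np.testing.assert_array_equal(a.age, b.age)


class TestAdvanceAndLabel:
    def test_cumulative_past_breakpoint_labels_all_cycling(self):
        p = CellCycleParams(tc=20, ts=5, gf=100)
        proto = LabelingProtocol.cumulative([p.breakpoint + 0.1])
        pop = init_population(500, p, seed=1)
        advance_and_label(pop, proto, proto.sampling_times[0])
        assert measure_li(pop).li == pytest.approx(100.0)

    def test_pulse_then_k_cycles_halves_label_k_times(self):
        p = CellCycleParams(tc=10, ts=2, gf=100)
        proto = LabelingProtocol.pulse_wait(0.25, chase_times=[10.25, 20.25, 30.25])
        pop = init_population(300, p, seed=2)
        advance_and_label(pop, proto, 0.25)
        labeled = pop.label_intensity > 0
        assert labeled.any()
        for k, t in enumerate(proto.sampling_times, start=1):
            advance_and_label(pop, proto, t)
            np.testing.assert_allclose(
                np.unique(pop.label_intensity[labeled]), [2.0**-k]
            )
            np.testing.assert_array_equal(
                np.unique(pop.divisions_since_label[labeled]), [k]
            )

    def test_cumulative_empirical_matches_closed_form(self):
        # simulator-vs-model oracle at n = 20000
        p = CellCycleParams(tc=33.2, ts=1.3, gf=85.7)
        proto = LabelingProtocol.cumulative([5.0, 10.0, 24.0, 48.0])
        pop = init_population(20000, p, seed=11)
        for t in proto.sampling_times:
            advance_and_label(pop, proto, t)
            li = measure_li(pop).li
            expected = expected_cumulative_li(p, t)
            se = binom_se_percent(expected / 100, 20000)
            assert abs(li - expected) <= 3 * max(se, 1e-9), f"t={t}"

    def test_renewal_conserves_population_size(self):
        p = CellCycleParams(tc=10, ts=2, gf=100)
        pop = init_population(777, p, seed=3)
        advance_and_label(pop, LabelingProtocol.pulse(0.25), 35.0)
        assert len(pop) == 777

    def test_growth_mode_doubles_per_cycle(self):
        p = CellCycleParams(tc=10, ts=2, gf=100)
        pop = init_population(200, p, seed=4)
        advance_and_label(pop, LabelingProtocol.pulse(0.25), 20.0, mode="growth")
        # every cell divides exactly twice in two full cycles
        assert len(pop) == 800

    def test_labeled_fraction_monotone_in_exposure_duration(self):
        p = CellCycleParams(tc=25.7, ts=7.3, gf=76.0)
        lis = []
        for dur in (0.25, 2.0, 8.0, 20.0, 40.0):
            proto = LabelingProtocol(
                kind="cumulative", exposure_start=0.0,
                exposure_duration=dur, sampling_times=(dur,),
            )
            pop = init_population(5000, p, seed=5)
            advance_and_label(pop, proto, dur)
            lis.append(measure_li(pop).li)
        assert all(b >= a for a, b in zip(lis, lis[1:]))

    def test_short_pulse_li_converges_to_s_phase_fraction(self):
        p = CellCycleParams(tc=25.7, ts=7.3, gf=76.0)
        pop = init_population(100000, p, seed=6)
        advance_and_label(pop, LabelingProtocol.pulse(0.01), 0.01)
        li = measure_li(pop).li
        expected = p.s_fraction_percent
        se = binom_se_percent(expected / 100, 100000)
        assert abs(li - expected) <= 4 * se

    def test_cannot_advance_backwards(self):
        p = CellCycleParams(tc=10, ts=2, gf=50)
        pop = init_population(10, p, seed=0, time=5.0)
        with pytest.raises(ParameterError):
            advance_and_label(pop, LabelingProtocol.pulse(0.25), 1.0)


class TestMeasure:
    def test_all_unlabeled_gives_zero_li(self):
        p = CellCycleParams(tc=10, ts=2, gf=50)
        pop = init_population(100, p, seed=0)
        assert measure_li(pop).li == 0.0

    def test_threshold_semantics_for_diluted_labels(self):
        p = CellCycleParams(tc=10, ts=2, gf=50)
        pop = init_population(200, p, seed=0)
        pop.label_intensity[:50] = 1.0
        assert measure_li(pop, detection_threshold=1 / 16).li == pytest.approx(25.0)
        pop.label_intensity[:50] = 1 / 32  # below threshold: scored unlabeled
        assert measure_li(pop, detection_threshold=1 / 16).li == 0.0


class TestSimulateExperiment:
    def test_row_cardinality(self):
        p = CellCycleParams(tc=20, ts=4, gf=70)
        proto = LabelingProtocol.cumulative([1, 2, 5, 10, 20])
        df = simulate_experiment(p, proto, n_cells=50, n_specimens=4, seed=0)
        assert len(df) == 20

    def test_same_seed_identical_tables(self):
        p = CellCycleParams(tc=20, ts=4, gf=70)
        proto = LabelingProtocol.cumulative([1, 5, 20])
        a = simulate_experiment(p, proto, 100, 3, seed=9)
        b = simulate_experiment(p, proto, 100, 3, seed=9)
        assert a.equals(b)

    def test_mean_li_tracks_closed_form(self, params_1dpa):
        proto = LabelingProtocol.cumulative([0.25, 5, 10, 24, 48])
        df = simulate_experiment(params_1dpa, proto, n_cells=2000, n_specimens=6, seed=13)
        for t, sub in df.groupby("time_h"):
            expected = expected_cumulative_li(params_1dpa, t)
            sem = max(sub.li_percent.sem(), 1e-9)
            # plateau times have no sampling noise (stratified GF), so allow
            # the binomial floor as well
            floor = binom_se_percent(expected / 100, 2000 * 6)
            assert abs(sub.li_percent.mean() - expected) <= 3 * max(sem, floor)

    def test_zero_specimens_rejected(self):
        p = CellCycleParams(tc=20, ts=4, gf=70)
        with pytest.raises(ParameterError):
            simulate_experiment(p, LabelingProtocol.cumulative([1, 2, 3]), 10, 0)
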