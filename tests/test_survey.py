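import numpy as np
import pytest

from coralprev import (
    Frame,
    InfeasibleGeometryError,
    MarkedPattern,
    PointPattern,
    Protocol,
    Station,
    Transect,
    count_in_transect,
    generate_poisson,
    mark_random,
    place_stations,
    place_transects,
    run_survey,
)
from coralprev.survey import FIGURE_PROTOCOLS, survey_to_csv


def marked_from_coords(frame, coords, flags):
    return MarkedPattern(PointPattern(frame, coords), np.asarray(flags, dtype=bool))


class TestPlaceStations:
    def test_single_station_inside_frame(self):
        frame = Frame(1500.0, 200.0)
        for s in range(20):
            (st,) = place_stations(frame, 1, side=100.0, seed=s)
            assert 0 <= st.x <= frame.width - st.side
            assert 0 <= st.y <= frame.height - st.side

    def test_separation_constraint_is_enforced(self):
        from scipy.spatial.distance import pdist

        frame = Frame(1500.0, 200.0)
        stations = place_stations(frame, 4, side=100.0, min_separation=400.0, seed=0)
        centers = np.array([s.center for s in stations])
        assert pdist(centers).min() >= 400.0

    def test_impossible_separation_raises(self):
        # two station centers cannot be further apart than the frame diagonal
        with pytest.raises(InfeasibleGeometryError):
            place_stations(Frame(200.0, 200.0), 2, side=100.0, min_separation=500.0,
                           seed=0, max_attempts=50)

    def test_four_stations_at_500m_do_not_fit_study_frame(self):
        # centers live in a 1400x100 m box: the best possible min pairwise
        # distance is sqrt((1400/3)^2 + 100^2) ~ 477 m, so 500 m is infeasible
        with pytest.raises(InfeasibleGeometryError):
            place_stations(Frame(1500.0, 200.0), 4, side=100.0, min_separation=500.0,
                           seed=0, max_attempts=2000)

    def test_station_larger_than_frame_raises(self):
        with pytest.raises(InfeasibleGeometryError):
            place_stations(Frame(50.0, 50.0), 1, side=100.0, seed=0)


class TestPlaceTransects:
    def test_forced_placement_when_transect_fills_station(self):
        st = Station(10.0, 20.0, side=100.0)
        (tr,) = place_transects(st, 1, length=100.0, width=100.0, seed=0)
        assert (tr.x, tr.y) == (10.0, 20.0)

    def test_transects_stay_inside_station(self):
        st = Station(0.0, 0.0, side=100.0)
        for tr in place_transects(st, 5, length=50.0, width=2.0, seed=1):
            assert st.x <= tr.x and tr.x + tr.length <= st.x + st.side
            assert st.y <= tr.y and tr.y + tr.width <= st.y + st.side

    def test_oversized_transect_rejected(self):
        with pytest.raises(ValueError):
            place_transects(Station(0.0, 0.0, 100.0), 1, length=120.0, width=2.0, seed=0)

    def test_different_seeds_give_different_placements(self):
        st = Station(0.0, 0.0, side=100.0)
        a = place_transects(st, 3, 25.0, 2.0, seed=1)
        b = place_transects(st, 3, 25.0, 2.0, seed=2)
        assert any(x != y for x, y in zip(a, b))


class TestCountInTransect:
    def test_hand_count_with_center_in_rule(self):
        marked = marked_from_coords(
            Frame(100.0, 100.0),
            [[1.0, 0.5], [1.0, 1.5], [11.0, 0.5]],
            [True, False, False],
        )
        count = count_in_transect(marked, Transect(0.0, 0.0, 10.0, 1.0))
        assert (count.n_total, count.n_diseased) == (1, 1)

    def test_empty_pattern_counts_zero(self):
        marked = marked_from_coords(Frame(100.0, 100.0), np.empty((0, 2)), [])
        count = count_in_transect(marked, Transect(0.0, 0.0, 10.0, 1.0))
        assert (count.n_total, count.n_diseased) == (0, 0)

    def test_abutting_transects_partition_boundary_points(self):
        marked = marked_from_coords(Frame(100.0, 100.0), [[10.0, 0.5]], [False])
        first = count_in_transect(marked, Transect(0.0, 0.0, 10.0, 1.0))
        second = count_in_transect(marked, Transect(10.0, 0.0, 10.0, 1.0))
        assert (first.n_total, second.n_total) == (0, 1)


class TestRunSurvey:
    def test_pooled_counts_are_sums_over_transects(self, tiny_marked):
        res = run_survey(tiny_marked, FIGURE_PROTOCOLS["25x2"], seed=0)
        assert res.pooled_total == sum(c.n_total for c in res.per_transect)
        assert res.pooled_diseased == sum(c.n_diseased for c in res.per_transect)
        assert len(res.per_transect) == 5

    def test_zero_prevalence_population_gives_zero_estimate(self, small_frame):
        marked = mark_random(generate_poisson(small_frame, 0.63, seed=1), 0.0, seed=2)
        res = run_survey(marked, FIGURE_PROTOCOLS["25x2"], seed=3)
        assert res.prevalence_estimate == 0.0
        assert res.prevalence_interval.lower == 0.0

    def test_empty_population_flags_undefined_prevalence(self, small_frame):
        marked = MarkedPattern(PointPattern(small_frame, np.empty((0, 2))), np.empty(0, bool))
        res = run_survey(marked, FIGURE_PROTOCOLS["10x1"], seed=0)
        assert not res.prevalence_defined
        assert np.isnan(res.prevalence_estimate)
        assert res.prevalence_interval is None

    def test_field_protocol_pooled_total_scale(self, study_population):
        # 24 transects x 50 m^2 at 0.63 /m^2 -> ~756 colonies per survey
        from coralprev.survey import FIELD_PROTOCOL

        totals = [
            run_survey(study_population, FIELD_PROTOCOL, seed=s).pooled_total
            for s in range(15)
        ]
        assert np.mean(totals) == pytest.approx(756, rel=0.05)

    def test_small_protocol_pooled_total_scale(self, study_population):
        # five 10x1 transects sample 50 m^2 -> ~31.5 colonies
        totals = [
            run_survey(study_population, FIGURE_PROTOCOLS["10x1"], seed=s).pooled_total
            for s in range(40)
        ]
        assert np.mean(totals) == pytest.approx(31.5, rel=0.1)

    def test_density_and_prevalence_unbiased(self, study_population):
        res = [run_survey(study_population, FIGURE_PROTOCOLS["50x2"], seed=s) for s in range(150)]
        dens = np.array([r.density_estimate for r in res])
        prev = np.array([r.prevalence_estimate for r in res])
        assert dens.mean() == pytest.approx(
            study_population.pattern.intensity, abs=3 * dens.std() / np.sqrt(len(dens))
        )
        assert prev.mean() == pytest.approx(
            study_population.prevalence, abs=3 * prev.std() / np.sqrt(len(prev))
        )

    def test_survey_does_not_mutate_population(self, tiny_marked):
        before = tiny_marked.pattern.points.copy()
        flags = tiny_marked.diseased.copy()
        run_survey(tiny_marked, FIGURE_PROTOCOLS["10x2"], seed=5)
        assert np.array_equal(tiny_marked.pattern.points, before)
        assert np.array_equal(tiny_marked.diseased, flags)

    def test_reproducible_under_seed(self, tiny_marked):
        a = run_survey(tiny_marked, FIGURE_PROTOCOLS["25x2"], seed=9)
        b = run_survey(tiny_marked, FIGURE_PROTOCOLS["25x2"], seed=9)
        assert [c.n_total for c in a.per_transect] == [c.n_total for c in b.per_transect]

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            Protocol(0, 5, 10.0, 1.0)
        with pytest.raises(ValueError):
            Protocol(1, 5, 10.0, 0.0)


def test_survey_csv_has_transect_and_summary_rows(tmp_path, tiny_marked):
    import pandas as pd

    res = run_survey(tiny_marked, FIGURE_PROTOCOLS["10x2"], seed=0)
    path = tmp_path / "survey.csv"
    survey_to_csv(res, path)
    df = pd.read_csv(path)
    assert len(df) == 6  # 5 transects + pooled summary
    assert df.iloc[-1]["n_total"] == res.pooled_total
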