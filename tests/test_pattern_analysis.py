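"""Per-second aggregation, dominant-emotion patterns, interval grids,
condition differences and the comparative-error screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cyberface as cf
from cyberface import pattern_analysis as pat
from cyberface.reference import reference_interval_grids

from conftest import make_recording

EM = list(cf.EMOTIONS)


class TestPerSecondMeans:
    def test_constant_stream(self):
        rec = make_recording({"happiness": 0.4}, n_frames=90, fps=30, fill=0.1)
        s = cf.per_second_means(rec)
        assert len(s) == 3
        assert np.allclose(s["happiness"], 0.4)

    def test_block_means(self):
        rec = make_recording(
            {"happiness": [0.0] * 30 + [1.0] * 30}, n_frames=60, fps=30, fill=0.1
        )
        s = cf.per_second_means(rec)
        assert s["happiness"].tolist() == pytest.approx([0.0, 1.0])

    def test_60fps_half_and_half(self):
        rec = make_recording(
            {"sadness": [0.2] * 30 + [0.6] * 30}, n_frames=60, fps=60, fill=0.1
        )
        s = cf.per_second_means(rec)
        assert s["sadness"].iloc[0] == pytest.approx(0.4)

    def test_trailing_partial_second_dropped(self):
        rec = make_recording(n_frames=75, fps=30, fill=0.1)  # 2.5 s
        assert len(cf.per_second_means(rec)) == 2


class TestDominant:
    def test_clear_argmax(self):
        s = pd.DataFrame({e: [0.1] for e in EM})
        s["sadness"] = 0.3
        assert cf.dominant_per_second(s).iloc[0] == "sadness"

    def test_tie_break_canonical_order(self):
        s = pd.DataFrame({e: [0.1] for e in EM})
        s["happiness"] = 0.2
        s["anger"] = 0.2
        assert cf.dominant_per_second(s).iloc[0] == "happiness"

    def test_all_zero_second_flagged(self):
        s = pd.DataFrame({e: [0.0] for e in EM})
        labels = cf.dominant_per_second(s)
        assert labels.iloc[0] == "happiness"  # canonical tie-break
        assert labels.attrs["n_all_zero"] == 1

    def test_agrees_with_bruteforce_argmax(self):
        rng = np.random.default_rng(42)
        vals = rng.random((1000, 7))
        series = pd.DataFrame(vals, columns=EM)
        got = cf.dominant_per_second(series)
        for i in range(1000):
            best, best_v = None, -1.0
            for e in EM:  # pairwise scan in canonical order
                if series[e].iloc[i] > best_v:
                    best, best_v = e, series[e].iloc[i]
            assert got.iloc[i] == best


class TestGroupPercentages:
    def test_simple_ratio(self):
        doms = {}
        for i in range(14):
            lab = "sadness" if i < 7 else "anger"
            doms[f"S{i}"] = pd.Series([lab] * 10, index=range(1, 11))
        gp = cf.group_percentages(doms)
        assert gp.percentages.loc[10, "sadness"] == pytest.approx(50.0)
        assert (gp.n_subjects == 14).all()

    def test_single_subject_is_all_or_nothing(self):
        doms = {"S1": pd.Series(["fear", "disgust"], index=[1, 2])}
        gp = cf.group_percentages(doms)
        assert sorted(gp.percentages.loc[1].tolist()) == [0, 0, 0, 0, 0, 0, 100]

    def test_row_sums_100_and_on_record_denominator(self):
        rng = np.random.default_rng(0)
        doms = {
            f"S{i}": pd.Series(
                rng.choice(EM, size=120 + 5 * i), index=range(1, 121 + 5 * i)
            )
            for i in range(6)
        }
        gp = cf.group_percentages(doms)
        assert np.allclose(gp.percentages.sum(axis=1), 100.0)
        assert gp.n_subjects.loc[120] == 6
        assert gp.n_subjects.loc[140] == 2  # only the two longest recordings

    def test_law_of_large_numbers_uniform_labels(self):
        rng = np.random.default_rng(2)
        n_subj, n_sec = 10_000, 20
        doms = {
            f"S{i}": pd.Series(rng.choice(EM, size=n_sec), index=range(1, n_sec + 1))
            for i in range(n_subj)
        }
        gp = cf.group_percentages(doms)
        assert np.abs(gp.percentages.to_numpy() - 100 / 7).max() < 1.0


class TestIntervalGrid:
    def test_constant_pattern(self):
        pct = pd.DataFrame(0.0, index=range(1, 146), columns=EM)
        pct["sadness"] = 100.0
        gp = pat.GroupPattern(pct, pd.Series(14, index=pct.index))
        grid = cf.interval_means(gp)
        assert (grid.loc["sadness"] == 100.0).all()
        assert grid.drop(index="sadness").to_numpy().sum() == 0

    def test_idempotent_on_reference_fixture(self):
        """A pattern already constant within each interval passes through."""
        ref = reference_interval_grids()["inclusion"]
        tl = cf.DEFAULT_TIMELINE
        pct = pd.DataFrame(index=range(1, 146), columns=EM, dtype=float)
        for i, (lo, hi) in tl.intervals.items():
            for e in EM:
                pct.loc[lo:hi, e] = ref.loc[e, i]
        gp = pat.GroupPattern(pct, pd.Series(14, index=pct.index))
        grid = cf.interval_means(gp)
        pd.testing.assert_frame_equal(grid, ref, atol=1e-9, rtol=0, check_names=False)

    def test_computed_grid_columns_sum_100(self, cohort_series):
        doms = {
            sid: cf.dominant_per_second(s)
            for (sid, c), s in cohort_series.items()
            if c == "inclusion"
        }
        grid = cf.interval_means(cf.group_percentages(doms))
        sums = grid.sum(axis=0)
        assert np.allclose(sums[~sums.isna()], 100.0, atol=1e-6)


class TestConditionDifference:
    def test_reference_cells(self):
        grids = reference_interval_grids()
        diff = cf.condition_difference(grids["exclusion"], grids["inclusion"])
        assert diff.loc["anger", 9] == pytest.approx(-24.07, abs=1e-9)
        assert diff.loc["contempt", 10] == pytest.approx(-16.14, abs=1e-9)

    def test_identical_grids_give_zero(self):
        g = reference_interval_grids()["inclusion"]
        assert (cf.condition_difference(g, g).to_numpy() == 0).all()

    def test_shape_mismatch_errors(self):
        g = reference_interval_grids()["inclusion"]
        with pytest.raises(ValueError):
            cf.condition_difference(g, g.iloc[:5])


class TestExtremes:
    def test_reference_interval_extremes(self):
        grids = reference_interval_grids()
        incl = cf.extremes_per_interval(grids["inclusion"])
        excl = cf.extremes_per_interval(grids["exclusion"])
        assert incl.loc[1, "most"] == "sadness"
        assert excl.loc[5, "most"] == "contempt"

    def test_degenerate_column(self):
        grid = pd.DataFrame(0.0, index=EM, columns=[1])
        grid.loc["fear", 1] = 100.0
        ext = cf.extremes_per_interval(grid)
        assert ext.loc[1, "most"] == "fear"
        assert ext.loc[1, "least"] == "happiness"  # first zero in canonical order


class TestComparativeError:
    def test_observed_cohort_not_significant(self):
        ce = cf.comparative_error(8.40, 32.70, 14, 14)
        assert ce.ce == pytest.approx(28.54, abs=0.01)
        assert ce.diff == pytest.approx(24.30)
        assert not ce.significant

    def test_hypothetical_n20_significant(self):
        ce = cf.comparative_error(8.40, 32.70, 20, 20)
        assert ce.ce == pytest.approx(23.88, abs=0.01)
        assert ce.significant

    def test_zero_difference_never_significant(self):
        ce = cf.comparative_error(50, 50, 14, 14)
        assert ce.diff == 0 and not ce.significant

    @given(
        p1=st.floats(0, 100),
        p2=st.floats(0, 100),
        n1=st.integers(1, 200),
        n2=st.integers(1, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_and_monotonicity(self, p1, p2, n1, n2):
        a = cf.comparative_error(p1, p2, n1, n2)
        b = cf.comparative_error(p2, p1, n2, n1)
        assert a.ce == pytest.approx(b.ce)
        bigger_n = cf.comparative_error(p1, p2, n1 + 10, n2 + 10)
        assert bigger_n.ce <= a.ce + 1e-12
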