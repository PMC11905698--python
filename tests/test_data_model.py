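import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from survtarget import (
    DiscretizationSpec,
    WideSurvivalData,
    discretize_followup,
    read_wide_csv,
    validate,
    write_wide_csv,
)

SPEC4 = DiscretizationSpec(boundaries=(1.0, 2.0, 3.0, 4.0))


def make_data(censor, event, exposure=None):
    censor = np.atleast_2d(np.asarray(censor, dtype=float))
    event = np.atleast_2d(np.asarray(event, dtype=float))
    n = censor.shape[0]
    return WideSurvivalData(
        baseline=pd.DataFrame({"L": np.zeros(n)}),
        exposure=np.zeros(n, dtype=int) if exposure is None else exposure,
        censor=censor,
        event=event,
    )


class TestDiscretize:
    @pytest.mark.parametrize(
        "time,ev,expected_event,expected_censor",
        [
            (1.0, 1, [1, 1, 1, 1], [0, 0, 0, 0]),  # event at the first boundary
            (0.5, 1, [1, 1, 1, 1], [0, 0, 0, 0]),
            (2.5, 0, [0, 0, np.nan, np.nan], [0, 0, 1, 1]),  # censored in interval 3
            (4.0, 0, [0, 0, 0, 0], [0, 0, 0, 0]),  # complete event-free follow-up
            (3.2, 1, [0, 0, 0, 1], [0, 0, 0, 0]),
        ],
    )
    def test_single_subject(self, time, ev, expected_event, expected_censor):
        out = discretize_followup(np.array([time]), np.array([ev]), SPEC4)
        np.testing.assert_array_equal(out.event[0], np.asarray(expected_event, dtype=float))
        np.testing.assert_array_equal(out.censor[0], np.asarray(expected_censor, dtype=float))

    def test_administrative_censoring_flag(self):
        out = discretize_followup(
            np.array([4.0]), np.array([0]), SPEC4, administrative_censor_at_end=True
        )
        assert out.censor[0, 3] == 1.0 and np.isnan(out.event[0, 3])

    def test_uniform_cohort_is_valid_and_round_trips(self):
        rng = np.random.default_rng(42)
        times = rng.uniform(0.01, 4.0, size=100)
        events = (rng.uniform(size=100) < 0.5).astype(int)
        out = discretize_followup(times, events, SPEC4)
        assert validate(out) == []
        # every subject with a terminal event contributes exactly one event
        n_events = np.nansum(np.diff(np.column_stack([np.zeros(100), out.event]), axis=1) == 1)
        assert n_events == events.sum()

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(followup_time=[-1.0], event_indicator=[0]), "negative"),
            (dict(followup_time=[5.0], event_indicator=[1]), "exceeds"),
        ],
    )
    def test_bad_inputs(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            discretize_followup(
                np.asarray(kwargs["followup_time"]),
                np.asarray(kwargs["event_indicator"]),
                SPEC4,
            )

    def test_non_monotone_boundaries_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            DiscretizationSpec(boundaries=(1.0, 1.0, 3.0))

    @given(
        times=hst.lists(hst.floats(0.001, 4.0), min_size=1, max_size=40),
        seed=hst.integers(0, 2**16),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_discretize_always_validates(self, times, seed):
        times = np.asarray(times)
        events = (np.random.default_rng(seed).uniform(size=times.size) < 0.5).astype(int)
        out = discretize_followup(times, events, SPEC4)
        assert validate(out) == []


class TestValidate:
    def test_clean_row(self):
        assert validate(make_data([0, 0, 0, 0], [0, 0, 1, 1])) == []

    def test_event_reversal_flagged(self):
        report = validate(make_data([0, 0, 0, 0], [0, 1, 0, np.nan]))
        assert [(v.rule, v.interval) for v in report] == [("absorbing-event", 3)]

    def test_event_observed_after_censoring_flagged(self):
        report = validate(make_data([1, 1, 1, 1], [0, np.nan, np.nan, np.nan]))
        assert [(v.rule, v.interval) for v in report] == [("missing-after-censoring", 1)]

    def test_censoring_reversal_flagged(self):
        report = validate(make_data([0, 1, 0, 1], [0, np.nan, np.nan, np.nan]))
        assert ("absorbing-censoring", 3) in [(v.rule, v.interval) for v in report]

    def test_non_indicator_entry_flagged(self):
        report = validate(make_data([0, 0, 0, 0], [0, 0.5, 1, 1]))
        assert [(v.rule, v.interval) for v in report] == [("domain", 2)]


class TestCsvRoundTrip:
    def test_write_then_read(self, tmp_path, cohort2000):
        data = cohort2000.data
        path = tmp_path / "wide.csv"
        write_wide_csv(data, path)
        back = read_wide_csv(
            path,
            Yvar=[f"Y{t}" for t in range(1, 5)],
            Cvar=[f"C{t}" for t in range(1, 5)],
            Avar="A",
            L0var=["L"],
        )
        np.testing.assert_array_equal(back.exposure, data.exposure)
        np.testing.assert_allclose(back.censor, data.censor)
        np.testing.assert_allclose(back.event, data.event)
        np.testing.assert_allclose(back.baseline["L"], data.baseline["L"])

    def test_unknown_column_named_in_error(self, tmp_path, cohort2000):
        path = tmp_path / "wide.csv"
        write_wide_csv(cohort2000.data, path)
        with pytest.raises(ValueError, match="Y9"):
            read_wide_csv(path, Yvar=["Y9"], Cvar=["C1"], Avar="A", L0var=["L"])
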