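"""Event I/O, MFI, quadrant analytics, morphology gating, and the t-test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import condx
from condx import (
    ChannelMap,
    QuadrantGates,
    compute_mfi,
    double_positive_timecourse,
    ifc_gate,
    quadrant_summary,
    read_events,
    t_test_two_sample,
    write_events,
)
from condx.errors import (
    ChannelMappingError,
    DomainError,
    EmptyGateError,
    FormatError,
    SchemaError,
)
from condx.fcs import read_fcs, write_fcs


def make_events(red, blue, time_s=0.0):
    n = len(red)
    return pd.DataFrame(
        {
            "time_s": np.full(n, time_s),
            "fsc": np.ones(n),
            "ssc": np.ones(n),
            "red": np.asarray(red, dtype=float),
            "blue": np.asarray(blue, dtype=float),
        }
    )


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        events = make_events([500.0, 10.0, 100.0], [10.0, 500.0, 100.0])
        path = tmp_path / "events.csv"
        write_events(events, path)
        back = read_events(path, format="csv")
        assert len(back) == 3
        pd.testing.assert_frame_equal(back, events)

    def test_channel_map_renames_csv_columns(self, tmp_path):
        frame = pd.DataFrame({"YL1-A": [1.0, 2.0], "BL1-A": [3.0, 4.0]})
        path = tmp_path / "raw.csv"
        frame.to_csv(path, index=False)
        events = read_events(path, format="csv", channel_map=ChannelMap(red="YL1-A", blue="BL1-A"))
        assert list(events["red"]) == [1.0, 2.0]
        assert list(events["blue"]) == [3.0, 4.0]

    def test_missing_channel_names_available_parameters(self, tmp_path):
        frame = pd.DataFrame({"BL1-A": [1.0], "FSC-A": [2.0]})
        path = tmp_path / "raw.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ChannelMappingError) as excinfo:
            read_events(path, format="csv", channel_map=ChannelMap(red="YL9-A", blue="BL1-A"))
        assert "YL9-A" in str(excinfo.value)
        assert "FSC-A" in str(excinfo.value)  # names what *is* available

    def test_unknown_format(self, tmp_path):
        path = tmp_path / "x.bin"
        path.write_text("")
        with pytest.raises(FormatError):
            read_events(path, format="lmd")


class TestFcs:
    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "FSC-A": rng.uniform(0, 1e4, 200),
                "SSC-A": rng.uniform(0, 1e4, 200),
                "YL1-A": rng.uniform(0, 1e5, 200),
                "BL1-A": rng.uniform(0, 1e5, 200),
            }
        ).astype(np.float32)
        path = tmp_path / "events.fcs"
        write_fcs(frame, path)
        back = read_fcs(path)
        assert list(back.columns) == list(frame.columns)
        assert np.allclose(back.to_numpy(), frame.to_numpy(), rtol=0, atol=0)
        assert back.attrs["fcs_version"].startswith("FCS3")

    def test_read_through_channel_map(self, tmp_path):
        frame = pd.DataFrame({"YL1-A": [10.0, 20.0], "BL1-A": [1.0, 2.0]}).astype(np.float32)
        path = tmp_path / "events.fcs"
        write_fcs(frame, path)
        events = read_events(path, format="fcs", channel_map=ChannelMap(red="YL1-A", blue="BL1-A"))
        assert list(events["red"]) == [10.0, 20.0]

    def test_fcs_requires_channel_map(self, tmp_path):
        frame = pd.DataFrame({"A": [1.0]}).astype(np.float32)
        path = tmp_path / "e.fcs"
        write_fcs(frame, path)
        with pytest.raises(ChannelMappingError):
            read_events(path, format="fcs")

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "junk.fcs"
        path.write_bytes(b"NOTFCS" + b" " * 100)
        with pytest.raises(FormatError):
            read_fcs(path)


class TestMfi:
    def test_arithmetic_mean(self):
        events = make_events([100.0, 200.0, 300.0], [0.0, 0.0, 0.0])
        assert compute_mfi(events, "red") == 200.0

    def test_single_event_identity(self):
        assert compute_mfi(make_events([42.0], [0.0]), "red") == 42.0

    def test_median_option(self):
        events = make_events([1.0, 2.0, 1000.0], [0.0] * 3)
        assert compute_mfi(events, "red", statistic="median") == 2.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        red = rng.lognormal(5, 1, 500)
        events = make_events(red, np.zeros(500))
        shuffled = events.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert compute_mfi(events, "red") == pytest.approx(
            compute_mfi(shuffled, "red"), rel=1e-12
        )

    def test_empty_gate_error(self):
        events = make_events([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(EmptyGateError):
            compute_mfi(events, "red", gate=lambda e: e["red"] > 1e9)

    def test_unknown_channel(self):
        with pytest.raises(SchemaError):
            compute_mfi(make_events([1.0], [1.0]), "green")


class TestQuadrants:
    def test_enumerated_example_with_boundary_event(self):
        # the (100,100) event sits exactly on both thresholds and is negative
        # under the strict ">" convention
        events = make_events(
            [500.0, 500.0, 10.0, 10.0, 100.0, 101.0],
            [10.0, 500.0, 10.0, 500.0, 100.0, 101.0],
        )
        summary = quadrant_summary(events, QuadrantGates(100.0, 100.0))
        assert summary.n_double_positive == 2
        assert summary.n_red_only == 1
        assert summary.n_blue_only == 1
        assert summary.n_double_negative == 2

    def test_zero_thresholds_make_all_positive_events_dp(self):
        events = make_events([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        summary = quadrant_summary(events, QuadrantGates(0.0, 0.0))
        assert summary.n_double_positive == 3

    def test_fraction_identities(self):
        events = make_events([500.0, 10.0], [500.0, 10.0])
        summary = quadrant_summary(events, QuadrantGates(100.0, 100.0))
        assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    @given(
        st.lists(
            st.tuples(st.floats(0, 1e6), st.floats(0, 1e6)), min_size=1, max_size=60
        ),
        st.floats(0, 1e6),
        st.floats(0, 1e6),
    )
    def test_quadrant_counts_partition_events(self, rb, red_thr, blue_thr):
        red, blue = zip(*rb)
        summary = quadrant_summary(make_events(red, blue), QuadrantGates(red_thr, blue_thr))
        total = (
            summary.n_double_positive
            + summary.n_red_only
            + summary.n_blue_only
            + summary.n_double_negative
        )
        assert total == summary.n_total == len(rb)

    def test_negative_threshold_rejected(self):
        with pytest.raises(DomainError):
            QuadrantGates(-1.0, 0.0)


class TestTimecourse:
    def test_series_assembly_and_ordering(self):
        tables = [
            make_events([500, 500], [10, 10], time_s=0.0),
            make_events([500, 500], [500, 10], time_s=30.0),
            make_events([500, 500], [500, 500], time_s=60.0),
        ]
        course = double_positive_timecourse(tables, QuadrantGates(100.0, 100.0))
        assert list(course["dp_fraction"]) == [0.0, 0.5, 1.0]
        assert list(course["time_s"]) == [0.0, 30.0, 60.0]

    def test_unordered_timepoints_rejected(self):
        tables = [
            make_events([1], [1], time_s=30.0),
            make_events([1], [1], time_s=0.0),
        ]
        with pytest.raises(DomainError):
            double_positive_timecourse(tables, QuadrantGates(0.0, 0.0))

    def test_single_timepoint_rejected(self):
        with pytest.raises(DomainError):
            double_positive_timecourse([make_events([1], [1])], QuadrantGates(0.0, 0.0))

    def test_generated_early_curve_is_monotone(self, early):
        config = condx.ExchangeAssayConfig(
            rates=early,
            n_droplets_per_timepoint=5000,
            dead_time=12.0,
            timepoints=(0.0, 10.0, 20.0, 40.0, 80.0, 160.0),
        )
        result = condx.generate_exchange_assay(config, seed=13)
        course = double_positive_timecourse(result.tables, condx.default_gates(config))
        dp = course["dp_fraction"].to_numpy()
        two_se = 2 * np.sqrt(0.25 / 5000)
        assert np.all(np.diff(dp) >= -two_se)


class TestIfcGate:
    def test_identity_at_zero_thresholds(self):
        events = condx.generate_ifc_events(100, 100, seed=3)
        gated = ifc_gate(events, aspect_min=0.0, area_min=0.0)
        assert len(gated) == len(events)

    def test_debris_removed_condensates_recovered(self):
        events = condx.generate_ifc_events(1000, 1000, seed=5)
        gated = ifc_gate(events, aspect_min=0.7, area_min=5.0)
        kept_labels = gated["label"].value_counts()
        recovery = kept_labels.get("condensate", 0) / 1000
        contamination = kept_labels.get("debris", 0) / 1000
        assert recovery >= 0.95
        assert contamination < 0.05

    def test_idempotence(self):
        events = condx.generate_ifc_events(200, 200, seed=7)
        once = ifc_gate(events, aspect_min=0.8, area_min=2.0)
        twice = ifc_gate(once, aspect_min=0.8, area_min=2.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_morphology_columns(self):
        with pytest.raises(SchemaError):
            ifc_gate(make_events([1.0], [1.0]), aspect_min=0.5, area_min=1.0)


class TestTTest:
    def test_identical_samples(self):
        stat, p = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == 0.0
        assert p == 1.0

    def test_clear_separation(self):
        stat, p = t_test_two_sample([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert abs(stat) > 10
        assert p < 0.001

    def test_hand_computed_pooled_formula(self):
        # means 0.5 vs 1.5, pooled SD √0.5, SE √0.5·√(1/2+1/2) ⇒ |t| = √2, df 2
        a, b = [0.0, 1.0], [1.0, 2.0]
        stat, p = t_test_two_sample(a, b)
        # independent closed-form pooled-variance computation
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_manual = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert stat == pytest.approx(t_manual, rel=1e-12)
        assert stat == pytest.approx(-math.sqrt(2.0), rel=1e-12)
        from scipy.stats import t as t_dist

        assert p == pytest.approx(2 * t_dist.sf(math.sqrt(2.0), df=2), rel=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(DomainError):
            t_test_two_sample([1.0], [1.0, 2.0])
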