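"""Session I/O, classification, binning and behavioral derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import navmanifold as nm
from navmanifold.session import SpikeTable, circular_shift_spikes


def _spike_table(times_by_unit, region="SUB", width=0.6, rates=None):
    rows = []
    for uid, ts in times_by_unit.items():
        for t in ts:
            rows.append((uid, t))
    spikes = pd.DataFrame(rows, columns=["unit_id", "t_s"])
    units = pd.DataFrame({
        "unit_id": list(times_by_unit),
        "region": region,
        "width_ms": width,
        "rate_hz": rates if rates is not None else 1.0,
    })
    return SpikeTable(spikes=spikes, units=units)


class TestIO:
    def test_round_trip(self, sub_session, tmp_path):
        nm.write_session(tmp_path / "s", sub_session["session"])
        loaded = nm.read_session(tmp_path / "s")
        assert len(loaded.spikes.units) == len(sub_session["session"].spikes.units)
        assert np.allclose(loaded.spikes.spikes["t_s"],
                           sub_session["session"].spikes.spikes["t_s"])

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            nm.read_session(tmp_path)

    def test_negative_spike_time_rejected(self):
        with pytest.raises(ValueError):
            _spike_table({0: [-1.0, 0.5]})

    def test_unsorted_spikes_rejected(self):
        with pytest.raises(ValueError):
            _spike_table({0: [2.0, 1.0]})


class TestClassification:
    @pytest.mark.parametrize("region,width,rate,expected", [
        ("CA1", 0.5, 5.0, "CA1 principal"),
        ("CA1", 0.5, 12.0, "excluded"),     # rate ceiling applies to CA1
        ("SUB", 0.5, 12.0, "SUB principal"),  # no SUB rate ceiling
        ("SUB", 0.3, 5.0, "excluded"),      # narrow spike
        ("CA1", 0.5, 0.05, "excluded"),     # silent
    ])
    def test_threshold_rules(self, region, width, rate, expected):
        units = pd.DataFrame({"unit_id": [0], "region": [region],
                              "width_ms": [width], "rate_hz": [rate]})
        assert nm.classify_units(units)[0] == expected

    def test_quality_metrics_applied_when_present(self):
        units = pd.DataFrame({
            "unit_id": [0, 1], "region": "SUB", "width_ms": 0.6, "rate_hz": 3.0,
            "iso_dist": [25.0, 15.0], "isi_idx": 0.1, "amp_uv": 80.0,
        })
        labels = nm.classify_units(units)
        assert labels[0] == "SUB principal" and labels[1] == "excluded"

    @settings(max_examples=50, deadline=None)
    @given(width=st.floats(0.1, 1.0), rate=st.floats(0.0, 20.0))
    def test_pure_threshold_function(self, width, rate):
        units = pd.DataFrame({"unit_id": [0], "region": ["CA1"],
                              "width_ms": [width], "rate_hz": [rate]})
        label = nm.classify_units(units)[0]
        expected = width > 0.4 and 0.1 < rate < 10.0
        assert (label == "CA1 principal") == expected

    def test_select_session_thresholds(self):
        def units(n_good, n_slow=0):
            return pd.DataFrame({
                "unit_id": range(n_good + n_slow), "region": "SUB", "width_ms": 0.6,
                "rate_hz": [3.0] * n_good + [0.05] * n_slow,
            })
        assert nm.select_session(units(12), "SUB")
        assert not nm.select_session(units(9), "SUB")
        assert not nm.select_session(units(9, n_slow=3), "SUB")


class TestBinning:
    def test_rate_arithmetic(self):
        st_ = _spike_table({0: [0.1, 0.2, 0.3]})
        b = nm.bin_activity(st_, (0.0, 0.512), sqrt=False)
        assert b.rates[0, 0] == pytest.approx(3 / 0.512)

    def test_sqrt_transform(self):
        st_ = _spike_table({0: [0.1, 0.2]})
        b = nm.bin_activity(st_, (0.0, 0.5), bin_s=0.5, sqrt=True)
        assert b.rates[0, 0] == pytest.approx(2.0)
        assert b.ledger.sqrt

    def test_zero_variance_zscore_row(self):
        st_ = _spike_table({0: [i + 0.25 for i in range(10)]})
        with pytest.warns(UserWarning):
            b = nm.bin_activity(st_, (0.0, 10.0), bin_s=1.0, sqrt=False, zscore=True)
        assert np.all(b.rates == 0)

    def test_binning_conserves_spikes(self, sub_session):
        session = sub_session["session"]
        b = nm.bin_activity(session.spikes, (0.0, session.t_end), sqrt=False)
        total = (b.rates * b.bin_s).sum()
        t1 = b.edges[-1]
        in_range = (session.spikes.spikes["t_s"] < t1).sum()
        assert total == pytest.approx(in_range)

    def test_right_edge_goes_to_next_bin(self):
        st_ = _spike_table({0: [0.512]})
        b = nm.bin_activity(st_, (0.0, 1.024), sqrt=False)
        assert b.rates[0, 0] == 0 and b.rates[1, 0] > 0

    def test_invalid_bin_width(self, sub_session):
        with pytest.raises(ValueError):
            nm.bin_activity(sub_session["session"].spikes, (0, 10), bin_s=0)


class TestCircularShift:
    def test_preserves_counts_and_rates(self, sub_session):
        session = sub_session["session"]
        rng = np.random.default_rng(0)
        shifted = circular_shift_spikes(session.spikes, (0.0, session.t_end), rng)
        for uid in session.spikes.unit_ids:
            assert len(shifted.times_of(uid)) == len(session.spikes.times_of(uid))


class TestBehaviorDerivation:
    def test_speed_arithmetic(self):
        # displacement of 5.12 cm across one 512-ms bin = 10 cm/s before smoothing
        n = 400
        t = np.arange(n) * 0.0256
        x = 10.0 * t  # constant 10 cm/s
        pos = pd.DataFrame({"t_s": t, "x_cm": x, "y_cm": np.zeros(n)})
        edges = np.arange(0, 10.0, 0.512)
        beh = nm.derive_behavior(pos, None, edges, task="openfield")
        mid = beh.frame["speed_cms"].to_numpy()[5:-5]
        assert np.allclose(mid, 10.0, atol=0.2)

    def test_stationary_speed_zero(self):
        n = 400
        pos = pd.DataFrame({"t_s": np.arange(n) * 0.0256,
                            "x_cm": np.full(n, 50.0), "y_cm": np.full(n, 50.0)})
        beh = nm.derive_behavior(pos, None, np.arange(0, 10.0, 0.512), task="openfield")
        assert np.allclose(beh.frame["speed_cms"], 0.0)

    def test_linearization_closure(self, sub_session):
        """Derived u matches generator ground truth (r > 0.99) on run frames."""
        truth = sub_session["truth"].latents
        beh = sub_session["behavior"].frame
        # ground-truth u at the tracking frame nearest each bin center
        t = np.arange(len(truth)) * 0.0256
        idx = np.searchsorted(t, beh["t_s"].to_numpy())
        idx = np.clip(idx, 0, len(truth) - 1)
        u_true = truth["u"].to_numpy()[idx]
        ok = np.isfinite(beh["u"].to_numpy()) & np.isfinite(u_true)
        r = np.corrcoef(beh["u"].to_numpy()[ok], u_true[ok])[0, 1]
        assert r > 0.99


class TestHeadDirectionEqualization:
    def test_counts_match_after_masking(self):
        rng = np.random.default_rng(0)
        hd = rng.uniform(-np.pi, np.pi, 300)
        choice = rng.choice(["L", "R"], 300, p=[0.6, 0.4])
        keep = nm.equalize_head_direction(hd, choice, np.random.default_rng(1))
        width = np.deg2rad(20)
        hb = np.floor(((hd + np.pi) % (2 * np.pi)) / width).astype(int)
        for b in np.unique(hb):
            sel = keep & (hb == b)
            assert np.sum(sel & (choice == "L")) == np.sum(sel & (choice == "R"))

    def test_already_equal_keeps_all(self):
        hd = np.zeros(10)
        choice = np.array(["L", "R"] * 5)
        keep = nm.equalize_head_direction(hd, choice, np.random.default_rng(0))
        assert keep.all()

    def test_single_choice_rejected(self):
        with pytest.raises(ValueError):
            nm.equalize_head_direction(np.zeros(5), np.array(["L"] * 5),
                                       np.random.default_rng(0))
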