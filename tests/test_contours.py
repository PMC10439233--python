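"""Contour I/O, acoustic features, selection rules and the ecotype test."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stenella.contours import (
    ContourError,
    SelectionRules,
    WhistleContour,
    apply_selection_rules,
    extract_features,
    features_table,
    mann_whitney_by_ecotype,
    read_contours,
    write_contours,
)

from conftest import make_contour


class TestReadContours:
    def test_long_csv_two_whistles(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "whistle_id,time_ms,freq_hz\n"
            "a,0,5000\na,10,5500\na,20,6000\n"
            "b,0,7000\nb,10,7100\nb,20,7200\n"
        )
        cs = read_contours(path)
        assert [c.whistle_id for c in cs] == ["a", "b"]
        assert all(len(c) == 3 for c in cs)

    def test_raven_selection_duration(self, tmp_path):
        path = tmp_path / "r.txt"
        path.write_text(
            "Selection\tBegin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)\n"
            "1\t0.5\t1.2\t5000\t9000\n"
        )
        (c,) = read_contours(path, format="raven_selection")
        assert extract_features(c).duration == pytest.approx(0.7)

    def test_duplicate_timestamp_names_whistle(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("whistle_id,time_ms,freq_hz\nw9,0,5000\nw9,0,5100\n")
        with pytest.raises(ContourError, match="w9"):
            read_contours(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("whistle_id,time_ms,freq_hz\na,0,5000\na,ten,6000\n")
        with pytest.raises(ContourError, match="line 3"):
            read_contours(path)

    def test_roundtrip_preserves_traces(self, tmp_path, small_dataset):
        cs, _ = small_dataset
        write_contours(cs[:5], tmp_path / "out.csv")
        back = read_contours(tmp_path / "out.csv")
        assert [c.whistle_id for c in back] == [c.whistle_id for c in cs[:5]]
        np.testing.assert_allclose(back[0].freqs, cs[0].freqs)
        assert back[0].meta["ecotype"] == cs[0].meta["ecotype"]


class TestExtractFeatures:
    def test_constant_contour(self, flat_contour):
        f = extract_features(flat_contour)
        assert f.duration == pytest.approx(1.0)
        assert f.min_freq == f.max_freq == f.start_freq == f.end_freq == f.peak_freq == 5.0
        assert f.delta_freq == 0.0

    def test_linear_sweep(self, linear_sweep):
        f = extract_features(linear_sweep)
        assert f.duration == pytest.approx(0.5)
        assert (f.min_freq, f.max_freq) == (5.0, 10.0)
        assert (f.start_freq, f.end_freq) == (5.0, 10.0)
        assert f.delta_freq == pytest.approx(5.0)

    def test_peak_freq_from_amplitude_track(self):
        c = make_contour([5.0, 7.3, 9.0], amps=[-20, -5, -18])
        assert extract_features(c).peak_freq == pytest.approx(7.3)

    def test_too_short_contour_rejected(self):
        with pytest.raises(ContourError):
            WhistleContour("x", [0.0], [5000.0])

    @given(st.floats(min_value=-1e4, max_value=1e4))
    @settings(max_examples=25, deadline=None)
    def test_time_offset_invariance(self, offset):
        c = make_contour(np.linspace(6, 9, 30))
        assert extract_features(c.shifted(offset)) == extract_features(c)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_delta_freq_identity(self, seed):
        rng = np.random.default_rng(seed)
        c = make_contour(rng.uniform(1, 20, size=rng.integers(2, 60)))
        f = extract_features(c)
        assert f.delta_freq == pytest.approx(f.max_freq - f.min_freq)
        assert f.min_freq <= min(f.start_freq, f.end_freq, f.peak_freq)
        assert max(f.start_freq, f.end_freq, f.peak_freq) <= f.max_freq


class TestSelectionRules:
    def rules(self):
        return SelectionRules()

    def test_frequency_cap(self):
        hot = make_contour([20.0, 23.0], whistle_id="hot", recording_id="r")
        kept, rejected = apply_selection_rules([hot], self.rules(), {"hot": 10.0})
        assert kept == [] and rejected[0][1] == "above_fmax"

    def test_min_gap(self):
        a = make_contour([5, 6], duration_ms=100, whistle_id="a", recording_id="r")
        b = make_contour([5, 6], duration_ms=100, whistle_id="b", recording_id="r")
        snr = {"a": 10.0, "b": 10.0}
        kept, rejected = apply_selection_rules(
            [a, b], self.rules(), snr, onsets={"a": 0.0, "b": 250.0}
        )
        assert [c.whistle_id for c in kept] == ["a"]
        assert rejected[0][1] == "min_gap"

    def test_all_pass(self):
        cs = [
            make_contour([15, 15.5], duration_ms=100, whistle_id=f"w{i}", recording_id="r")
            for i in range(3)
        ]
        snr = {c.whistle_id: 10.0 for c in cs}
        onsets = {f"w{i}": i * 500.0 for i in range(3)}
        kept, rejected = apply_selection_rules(cs, self.rules(), snr, onsets)
        assert len(kept) == 3 and not rejected

    def test_low_snr(self):
        c = make_contour([5, 6], whistle_id="q", recording_id="r")
        kept, rejected = apply_selection_rules([c], self.rules(), {"q": 3.0})
        assert rejected[0][1] == "low_snr"

    def test_idempotent(self, small_dataset):
        cs, _ = small_dataset
        snr = {c.whistle_id: 10.0 for c in cs}
        onsets = {c.whistle_id: i * 5000.0 for i, c in enumerate(cs)}
        kept, _ = apply_selection_rules(cs, self.rules(), snr, onsets)
        kept2, rejected2 = apply_selection_rules(kept, self.rules(), snr, onsets)
        assert [c.whistle_id for c in kept2] == [c.whistle_id for c in kept]
        assert not rejected2


class TestMannWhitney:
    @staticmethod
    def table(x, y, param="duration"):
        return pd.DataFrame(
            {param: list(x) + list(y), "ecotype": ["coastal"] * len(x) + ["offshore"] * len(y)}
        )

    def test_identical_groups_not_significant(self):
        res = mann_whitney_by_ecotype(self.table([1, 2, 3], [1, 2, 3]), params=["duration"])
        assert res.loc["duration", "p_raw"] == pytest.approx(1.0, abs=0.05)
        assert not res.loc["duration", "significant"]

    def test_fully_separated_small_groups(self):
        res = mann_whitney_by_ecotype(self.table([1, 2, 3], [10, 11, 12]), params=["duration"])
        # U=0 for the lower group; the exact two-sided p for n=3,3 is 2/20
        assert res.loc["duration", "p_raw"] == pytest.approx(0.1)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(1)
        # groups tuned to give p_raw around 0.01 would be fragile; instead
        # check the adjustment rule directly on a moderate shift
        df = self.table(rng.normal(0, 1, 30), rng.normal(1, 1, 30))
        for p in range(6):
            df[f"extra{p}"] = df["duration"]
        params = ["duration"] + [f"extra{p}" for p in range(6)]
        res = mann_whitney_by_ecotype(df, params=params)
        for p in params:
            assert res.loc[p, "p_adjusted"] == pytest.approx(
                min(1.0, 7 * res.loc[p, "p_raw"])
            )

    def test_empty_group_errors(self):
        df = self.table([1.0, 2.0], [])
        with pytest.raises(ValueError):
            mann_whitney_by_ecotype(df, params=["duration"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_exhaustive_permutation(self, seed):
        """Exact p equals the proportion of label permutations with a U at
        least as extreme, for small untied samples."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.8, 1, 6)
        res = mann_whitney_by_ecotype(self.table(x, y), params=["duration"])
        pooled = np.concatenate([x, y])
        n1 = len(x)
        mu = n1 * len(y) / 2

        def ustat(idx):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            return sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)

        u_obs = ustat(range(n1))
        perms = [ustat(c) for c in combinations(range(len(pooled)), n1)]
        p_exact = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in perms])
        assert res.loc["duration", "p_raw"] == pytest.approx(p_exact, abs=1e-9)
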