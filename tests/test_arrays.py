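"""Probe-table I/O, flag filtering, normalization and ratio computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ago2seed.arrays import (compute_log2_ratio, collapse_duplicate_features,
                             filter_flags, lowess_normalize,
                             percentile_scale_normalize, read_probe_table,
                             write_probe_table)
from ago2seed.errors import (NormalizationError, ProbeTableFormatError,
                             ProbeValidationError)
from conftest import make_sample


class TestProbeTableIO:
    def test_valid_file_parses_all_rows(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text("probe_id\tfeature_id\tcy5\tcy3\tflag\n" +
                        "".join(f"P{i}\tf{i}\t{10.5 * (i + 1)}\t\t0\n"
                                for i in range(5)))
        sample = read_probe_table(path)
        assert len(sample.probes) == 5
        assert not sample.two_channel

    def test_missing_flag_column_is_a_format_error(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("probe_id\tfeature_id\tcy5\tcy3\nP0\tf0\t1.0\t\n")
        with pytest.raises(ProbeTableFormatError, match="flag"):
            read_probe_table(path)

    def test_negative_intensity_is_a_validation_error(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("probe_id\tfeature_id\tcy5\tcy3\tflag\n"
                        "P0\tf0\t-3.0\t\t0\n")
        with pytest.raises(ProbeValidationError, match="line"):
            read_probe_table(path)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rows=st.lists(st.tuples(st.floats(0, 1e6, allow_nan=False, width=32),
                                   st.floats(0.0, 1e6, allow_nan=False, width=32),
                                   st.integers(-100, 100)),
                         min_size=1, max_size=30))
    def test_write_read_roundtrip_preserves_fields(self, rows, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        cy5 = [round(r[0], 6) for r in rows]
        cy3 = [round(r[1], 6) for r in rows]
        flags = [r[2] for r in rows]
        sample = make_sample(cy5, cy3=cy3, flags=flags, arm="mrna_total")
        write_probe_table(sample, tmp / "x.tsv")
        back = read_probe_table(tmp / "x.tsv", arm="mrna_total")
        assert list(back.probes["probe_id"]) == list(sample.probes["probe_id"])
        np.testing.assert_allclose(back.probes["cy5"], cy5, atol=1e-6)
        np.testing.assert_allclose(back.probes["cy3"], cy3, atol=1e-6)
        assert list(back.probes["flag"]) == flags


class TestFlagFilter:
    def test_negative_flags_are_removed(self):
        sample = make_sample([1, 2, 3], flags=[0, -50, 100])
        assert len(filter_flags(sample).probes) == 2

    def test_all_nonnegative_is_identity(self):
        sample = make_sample([1, 2, 3], flags=[0, 5, 100])
        pd.testing.assert_frame_equal(filter_flags(sample).probes, sample.probes)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-100, 100), min_size=1, max_size=50))
    def test_matches_brute_force_filter(self, flags):
        sample = make_sample(list(range(1, len(flags) + 1)), flags=flags)
        kept = filter_flags(sample).probes["cy5"].tolist()
        expected = [float(i + 1) for i, f in enumerate(flags) if f >= 0]
        assert kept == expected


class TestPercentileScaling:
    def test_hand_computed_cohort_reference(self):
        # 75th percentiles 100 and 400 -> geometric-mean reference 200
        a = make_sample([100.0] * 4, sample_id="a")
        b = make_sample([400.0] * 4, sample_id="b")
        _, factors = percentile_scale_normalize([a, b])
        assert factors == pytest.approx([2.0, 0.5])

    def test_single_sample_scale_factor_is_one(self):
        a = make_sample([5.0, 10.0, 20.0])
        _, factors = percentile_scale_normalize([a])
        assert factors == pytest.approx([1.0])

    def test_scaling_preserves_within_sample_ratios(self):
        a = make_sample([10.0, 40.0, 160.0], sample_id="a")
        b = make_sample([1.0, 2.0, 3.0], sample_id="b")
        scaled, _ = percentile_scale_normalize([a, b])
        ratios = scaled[0].probes["cy5"].to_numpy()
        assert ratios[1] / ratios[0] == pytest.approx(4.0)
        assert ratios[2] / ratios[1] == pytest.approx(4.0)

    def test_idempotent_second_pass(self):
        rng = np.random.default_rng(3)
        samples = [make_sample(rng.lognormal(3, 1, 50), sample_id=f"s{i}")
                   for i in range(4)]
        scaled, _ = percentile_scale_normalize(samples)
        _, factors2 = percentile_scale_normalize(scaled)
        np.testing.assert_allclose(factors2, 1.0, atol=1e-12)

    def test_all_zero_sample_is_an_error(self):
        with pytest.raises(NormalizationError):
            percentile_scale_normalize([make_sample([0.0, 0.0])])


class TestLowess:
    @staticmethod
    def _two_channel(rng, n=200, trend=0.0):
        a = rng.normal(10, 1.5, n)
        m = trend * (a - a.mean())
        cy5 = np.exp2(a + m / 2)
        cy3 = np.exp2(a - m / 2)
        return make_sample(cy5, cy3=cy3, arm="mrna_total")

    def test_flat_null_correction_is_zero(self):
        rng = np.random.default_rng(0)
        sample = self._two_channel(rng, trend=0.0)
        out = lowess_normalize(sample)
        m = np.log2(out.probes["cy5"] / out.probes["cy3"])
        assert np.abs(m).max() < 1e-9

    def test_planted_curvature_is_removed(self):
        rng = np.random.default_rng(1)
        sample = self._two_channel(rng, trend=0.5)
        out = lowess_normalize(sample)
        m = np.log2(out.probes["cy5"] / out.probes["cy3"])
        assert np.median(np.abs(m)) < 0.05

    def test_differential_probe_survives_normalization(self):
        # a 4-fold probe is rank-inconsistent, excluded from the fit set,
        # and must keep its signal after correction
        rng = np.random.default_rng(2)
        n = 200
        a = rng.normal(10, 1.0, n)
        cy5, cy3 = np.exp2(a), np.exp2(a)
        cy5[0] = np.exp2(a[0] + 2.0)  # M = +2 for probe 0
        sample = make_sample(cy5, cy3=cy3, arm="mrna_total")
        out = lowess_normalize(sample)
        m0 = np.log2(out.probes["cy5"][0] / out.probes["cy3"][0])
        assert m0 >= 1.8

    def test_too_few_rank_consistent_probes_is_an_error(self):
        rng = np.random.default_rng(4)
        # anti-correlated channels: ranks maximally inconsistent
        vals = np.sort(rng.lognormal(3, 1, 30))
        sample = make_sample(vals, cy3=vals[::-1].copy(), arm="mrna_total")
        with pytest.raises(NormalizationError, match="rank_tolerance"):
            lowess_normalize(sample, rank_tolerance=0.001)

    def test_preserves_a_values(self):
        rng = np.random.default_rng(5)
        sample = self._two_channel(rng, trend=0.3)
        out = lowess_normalize(sample)
        a_in = 0.5 * np.log2(sample.probes["cy5"] * sample.probes["cy3"])
        a_out = 0.5 * np.log2(out.probes["cy5"] * out.probes["cy3"])
        np.testing.assert_allclose(a_out, a_in, atol=1e-9)


class TestLog2Ratio:
    def test_four_fold_is_two(self):
        t = make_sample([400.0], sample_id="t")
        c = make_sample([100.0], sample_id="c")
        assert compute_log2_ratio(t, c).iloc[0] == pytest.approx(2.0)

    def test_equal_intensities_are_zero(self):
        t = make_sample([123.0, 7.0], sample_id="t")
        assert compute_log2_ratio(t, t).tolist() == pytest.approx([0.0, 0.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(1e-3, 1e6, allow_nan=False),
                              st.floats(1e-3, 1e6, allow_nan=False)),
                    min_size=1, max_size=20))
    def test_matches_elementwise_log2_division(self, pairs):
        t = make_sample([p[0] for p in pairs], sample_id="t")
        c = make_sample([p[1] for p in pairs], sample_id="c")
        got = compute_log2_ratio(t, c)
        expected = sorted((f"f{i}", np.log2(a / b))
                          for i, (a, b) in enumerate(pairs))
        np.testing.assert_allclose(got.to_numpy(), [v for _, v in expected],
                                   rtol=1e-12)

    def test_within_array_two_channel_ratio(self):
        s = make_sample([800.0, 100.0], cy3=[100.0, 100.0], arm="mrna_total")
        ratio = compute_log2_ratio(s)
        assert ratio.tolist() == pytest.approx([3.0, 0.0])

    def test_duplicate_probes_collapse_to_median(self):
        s = make_sample([2.0, 4.0, 8.0, 5.0], feature_ids=["x", "x", "x", "y"])
        out = collapse_duplicate_features(s)
        med = out.probes.set_index("feature_id")["cy5"]
        assert med["x"] == pytest.approx(4.0)
        assert med["y"] == pytest.approx(5.0)
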