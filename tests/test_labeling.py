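import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from hrvpipe import labeling
from hrvpipe.exceptions import InvalidParameterError, ValidationError
from hrvpipe.labeling import (
    AgeBandReference,
    LabelingConfig,
    band_for_age,
    build_reference_table,
    fit_normal,
    label_table,
    typicality_score,
    write_reference_csv,
)


class TestReferenceTable:
    def test_printed_anchor_bands(self, refs):
        young = band_for_age(refs, 25.0)
        assert (young.median_low_s, young.median_high_s) == (0.0041, 0.0048)
        assert (young.range_low_s, young.range_high_s) == (0.0013, 0.0161)
        older = band_for_age(refs, 65.0)
        assert (older.range_low_s, older.range_high_s) == (0.0005, 0.0104)
        # the printed 60-69 medians have inverted bounds; read as 2.04-2.07 ms
        assert older.median_low_s == pytest.approx(0.00204)
        assert older.median_high_s == pytest.approx(0.00207)

    def test_bands_partition_span_without_overlap(self, refs):
        assert [b.age_low for b in refs] == [20, 30, 40, 50, 60, 70, 80]
        for prev, nxt in zip(refs, refs[1:]):
            assert prev.age_high == nxt.age_low
        for band in refs:
            assert band.range_low_s < band.median_low_s
            assert band.median_low_s <= band.median_high_s
            assert band.median_high_s < band.range_high_s
            assert band.sigma_ms > 0

    def test_overlapping_file_bands_rejected(self, tmp_path):
        bad = pd.DataFrame(
            {
                "age_low": [20, 35],
                "age_high": [40, 60],
                "median_low_s": [0.004, 0.003],
                "median_high_s": [0.005, 0.004],
                "range_low_s": [0.001, 0.001],
                "range_high_s": [0.016, 0.012],
            }
        )
        path = tmp_path / "refs.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            build_reference_table(path)

    def test_file_round_trip(self, refs, tmp_path):
        path = tmp_path / "refs.csv"
        write_reference_csv(refs, path)
        reloaded = build_reference_table(path)
        assert len(reloaded) == len(refs)
        for a, b in zip(refs, reloaded):
            assert a.range_low_s == pytest.approx(b.range_low_s)
            assert a.mu_ms == pytest.approx(b.mu_ms)


class TestFitNormal:
    def test_sigma_spans_coverage_mass(self, refs):
        band = refs[0]
        expected_sigma = 14.8 / (2 * norm.ppf(0.98))
        assert band.sigma_ms == pytest.approx(expected_sigma, rel=1e-6)
        assert band.sigma_ms == pytest.approx(3.603, abs=5e-4)

    def test_default_center_is_range_midpoint(self, refs):
        band = refs[0]
        assert band.mu_ms == pytest.approx(1000 * (0.0013 + 0.0161) / 2)

    def test_median_midpoint_center(self):
        band = AgeBandReference(20, 30, 0.0041, 0.0048, 0.0013, 0.0161)
        mu, _ = fit_normal(band, coverage=0.96, center="median_midpoint")
        assert mu == pytest.approx(4.45)

    def test_sigma_shrinks_as_coverage_grows(self):
        band = AgeBandReference(20, 30, 0.0041, 0.0048, 0.0013, 0.0161)
        sigmas = [fit_normal(band, coverage=c)[1] for c in (0.5, 0.8, 0.96, 0.999)]
        assert all(a > b for a, b in zip(sigmas, sigmas[1:]))

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValidationError):
            AgeBandReference(20, 30, 0.004, 0.004, 0.004, 0.004)

    def test_coverage_self_consistency(self, refs):
        """Draws from the fitted normal land in the total range ~coverage often."""
        band = refs[0]
        draws = np.random.default_rng(1).normal(band.mu_ms, band.sigma_ms, 100_000)
        frac = np.mean((draws >= 1000 * band.range_low_s) & (draws <= 1000 * band.range_high_s))
        assert frac == pytest.approx(0.96, abs=0.003)


class TestTypicalityScore:
    def test_center_scores_one(self, refs):
        band = refs[0]
        out = typicality_score(band.mu_ms, band)
        assert out.score == pytest.approx(1.0)
        assert out.in_range and out.boundary_distance_ms == 0.0

    @pytest.mark.parametrize("side", ["low", "high"])
    def test_boundary_score_is_one_minus_coverage(self, refs, side):
        band = refs[0]
        edge = 1000 * (band.range_low_s if side == "low" else band.range_high_s)
        out = typicality_score(edge, band)
        assert out.score == pytest.approx(2 * (1 - 0.98), rel=1e-9)

    def test_one_sigma_beyond_boundary_decays_efold(self, refs):
        band = refs[0]
        out = typicality_score(1000 * band.range_high_s + band.sigma_ms, band)
        assert out.score == pytest.approx(0.04 * math.exp(-1), rel=1e-9)
        assert out.score == pytest.approx(0.01472, abs=5e-5)
        assert not out.in_range
        assert out.boundary_distance_ms == pytest.approx(band.sigma_ms)

    def test_continuity_at_both_boundaries(self, refs):
        for band in refs:
            for edge_s in (band.range_low_s, band.range_high_s):
                edge = 1000 * edge_s
                eps = 1e-6 * band.sigma_ms
                inside = typicality_score(edge - eps if edge_s == band.range_high_s else edge + eps, band)
                outside = typicality_score(edge + eps if edge_s == band.range_high_s else edge - eps, band)
                assert abs(inside.score - outside.score) < 1e-6

    def test_monotone_decay_outside_range(self, refs):
        band = refs[0]
        hi = 1000 * band.range_high_s
        scores = [typicality_score(hi + d, band).score for d in (0.5, 1.0, 2.0, 5.0, 20.0)]
        assert all(a > b for a, b in zip(scores, scores[1:]))
        lo = 1000 * band.range_low_s
        scores = [typicality_score(max(lo - d, 0.0), band).score for d in (0.2, 0.4, 0.8, 1.2)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_two_sided_symmetry_in_z(self, refs):
        band = refs[0]
        for dz in (0.3, 0.9, 1.5):
            up = typicality_score(band.mu_ms + dz * band.sigma_ms, band)
            down = typicality_score(band.mu_ms - dz * band.sigma_ms, band)
            assert up.score == pytest.approx(down.score, rel=1e-9)

    def test_literal_cdf_mode_is_monotone_across_band(self, refs):
        band = refs[0]
        config = LabelingConfig(mode="literal_cdf")
        grid = np.linspace(1000 * band.range_low_s, 1000 * band.range_high_s, 25)
        scores = [typicality_score(x, band, config).score for x in grid]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_unfitted_band_rejected(self):
        band = AgeBandReference(20, 30, 0.0041, 0.0048, 0.0013, 0.0161)
        with pytest.raises(InvalidParameterError):
            typicality_score(5.0, band)

    @given(st.floats(0.0, 500.0), st.integers(0, 6))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_score_always_a_probability(self, rmssd_ms, band_idx):
        band = _REFS[band_idx]
        out = typicality_score(rmssd_ms, band)
        assert 0.0 <= out.score <= 1.0
        assert out.in_range == (out.boundary_distance_ms == 0.0)


_REFS = build_reference_table()


class TestLabelTable:
    def test_band_centers_score_one(self, refs):
        rows = pd.DataFrame(
            {
                "record_id": [f"r{i}" for i in range(len(refs))],
                "age": [b.age_low + 5.0 for b in refs],
                "rmssd": [b.mu_ms / 1000.0 for b in refs],
            }
        )
        labeled, report = label_table(rows, refs)
        np.testing.assert_allclose(labeled["target"], 1.0)
        assert report["n_in_range"] == len(refs)

    def test_unsupported_age_flagged_and_excluded(self, refs, caplog):
        rows = pd.DataFrame({"record_id": ["a", "b"], "age": [19.0, 25.0],
                             "rmssd": [0.006, 0.006]})
        labeled, report = label_table(rows, refs)
        assert list(labeled["record_id"]) == ["b"]
        assert report["n_excluded_age"] == 1

    def test_targets_stay_in_unit_interval(self, labeled_table):
        assert labeled_table["target"].between(0.0, 1.0).all()
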