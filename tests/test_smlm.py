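import numpy as np
import pandas as pd
import pytest

from _oracles import rayleigh_fwhm
from irifkit.stack_io import OrteMatrix
from irifkit.smlm import (
    characterize_peaks,
    compare_curves,
    count_tags,
    curve_from_orte,
    distance_frequency,
    merge_blinking,
)
from irifkit.synthetic import PointPatternSpec, generate_smlm_pattern


def _orte(x, y, precision=10.0, z_section=0, channel="gH2AX"):
    n = len(x)
    return OrteMatrix(
        df=pd.DataFrame(
            {
                "x_nm": x, "y_nm": y,
                "z_section": np.full(n, z_section, dtype=int),
                "frame": np.arange(n),
                "precision_nm": np.full(n, precision, dtype=float),
                "channel": channel,
            }
        )
    )


class TestMergeBlinking:
    def test_coincident_events_become_one_point(self):
        merged = merge_blinking(_orte([100.0, 100.0], [50.0, 50.0]))
        assert len(merged) == 1

    def test_within_precision_merges_to_weighted_centroid(self):
        merged = merge_blinking(_orte([100.0, 105.0], [0.0, 0.0], precision=10.0))
        assert len(merged) == 1
        assert merged.df.loc[0, "x_nm"] == pytest.approx(102.5)

    def test_beyond_precision_stays_separate(self):
        merged = merge_blinking(_orte([100.0, 150.0], [0.0, 0.0], precision=10.0))
        assert len(merged) == 2

    def test_idempotent(self):
        orte = generate_smlm_pattern(PointPatternSpec(seed=13, cluster_sigma_nm=8.0))
        once = merge_blinking(orte)
        twice = merge_blinking(once)
        assert len(once) <= len(orte)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_channels_and_sections_not_mixed(self):
        df = pd.concat(
            [
                _orte([0.0], [0.0], z_section=0).df,
                _orte([1.0], [0.0], z_section=1).df,
            ],
            ignore_index=True,
        )
        merged = merge_blinking(OrteMatrix(df=df))
        assert len(merged) == 2  # same position, different 500-nm sections


class TestCountTags:
    def test_single_section_gets_all_counts(self):
        counts = count_tags(_orte([0.0, 1.0, 2.0], [0.0, 0.0, 0.0], z_section=3))
        assert len(counts) == 1
        assert counts.loc[0, "n_tags"] == 3
        assert counts.loc[0, "z_section"] == 3

    def test_conservation_and_exact_recovery(self, rng):
        alloc = {0: 5, 1: 8, 2: 3}
        frames = []
        for z, n in alloc.items():
            frames.append(_orte(rng.random(n) * 1000, rng.random(n) * 1000, z_section=z).df)
        counts = count_tags(OrteMatrix(df=pd.concat(frames, ignore_index=True)))
        assert counts["n_tags"].sum() == sum(alloc.values())
        assert dict(zip(counts["z_section"], counts["n_tags"])) == alloc


class TestDistanceFrequency:
    def test_two_points_single_bin(self):
        curve = distance_frequency(np.array([[0.0, 0.0], [100.0, 0.0]]), 10.0, 1000.0)
        assert curve.counts.sum() == 1
        assert curve.counts[10] == 1  # bin [100, 110)

    def test_three_collinear_points(self):
        pts = np.array([[0.0, 0.0], [1000.0, 0.0], [2000.0, 0.0]])
        curve = distance_frequency(pts, 10.0, 2500.0)
        assert curve.counts[100] == 2  # two 1000-nm pairs
        assert curve.counts[200] == 1  # one 2000-nm pair

    def test_fewer_than_two_points_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            distance_frequency(np.zeros((1, 2)))

    def test_rigid_motion_invariance(self, rng):
        pts = rng.random((60, 2)) * 800
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([123.0, -456.0])
        a = distance_frequency(pts)
        b = distance_frequency(moved)
        assert np.array_equal(a.counts, b.counts)

    def test_pair_count_conservation(self, rng):
        pts = rng.random((40, 2)) * 500
        curve = distance_frequency(pts, 10.0, r_max_nm=10000.0)
        assert curve.counts.sum() == 40 * 39 // 2
        assert curve.rel_freq.sum() == pytest.approx(1.0)


class TestCharacterizePeaks:
    def test_clustered_pattern_peak_below_150nm(self):
        orte = generate_smlm_pattern(PointPatternSpec(seed=0, cluster_sigma_nm=25.0))
        peak = characterize_peaks(curve_from_orte(orte))
        assert peak is not None
        assert peak.peak_position_nm < 150.0

    def test_csr_pattern_reports_no_peak(self):
        orte = generate_smlm_pattern(
            PointPatternSpec(n_clusters=50, offspring_per_cluster=20,
                             background_fraction=1.0, seed=1)
        )
        assert characterize_peaks(curve_from_orte(orte)) is None

    def test_peak_width_recovers_rayleigh_fwhm(self):
        """Intra-cluster pairwise distances are Rayleigh with scale
        sigma * sqrt(2); the median detected FWHM must land within 30% of
        the closed-form FWHM."""
        widths = []
        for seed in range(20):
            orte = generate_smlm_pattern(PointPatternSpec(seed=seed, cluster_sigma_nm=25.0))
            peak = characterize_peaks(curve_from_orte(orte))
            assert peak is not None
            widths.append(peak.peak_width_nm)
        expected = rayleigh_fwhm(25.0 * np.sqrt(2.0))
        assert abs(np.median(widths) - expected) / expected <= 0.30

    def test_denser_clusters_increase_excess_area(self):
        areas = []
        for offspring in (20, 40):
            vals = []
            for seed in range(8):
                orte = generate_smlm_pattern(
                    PointPatternSpec(offspring_per_cluster=offspring, seed=seed)
                )
                peak = characterize_peaks(curve_from_orte(orte))
                vals.append(peak.excess_area)
            areas.append(np.mean(vals))
        assert areas[1] > areas[0]

    def test_uncovered_baseline_range_is_an_error(self):
        curve = distance_frequency(np.array([[0.0, 0.0], [100.0, 0.0]]), 10.0, 300.0)
        with pytest.raises(ValueError, match="baseline range"):
            characterize_peaks(curve, baseline_range_nm=(400.0, 800.0))


class TestCompareCurves:
    def _curves(self, spec, n):
        return [
            curve_from_orte(generate_smlm_pattern(spec.__class__(**{**spec.__dict__, "seed": s})))
            for s in range(n)
        ]

    def test_identical_conditions_zero_difference(self):
        curves = self._curves(PointPatternSpec(), 3)
        table = compare_curves({"a": curves, "b": curves})
        piv = table.pivot(index="r_nm", columns="condition", values="mean_rel_freq")
        assert np.allclose(piv["a"], piv["b"])

    def test_clustered_condition_has_higher_small_r_frequency(self):
        clustered = self._curves(PointPatternSpec(background_fraction=0.0), 3)
        csr = self._curves(PointPatternSpec(background_fraction=1.0), 3)
        table = compare_curves({"clustered": clustered, "csr": csr})
        small = table[table["r_nm"] < 60]
        m = small.groupby("condition")["mean_rel_freq"].mean()
        assert m["clustered"] > m["csr"]

    def test_single_curve_spread_missing(self):
        curves = self._curves(PointPatternSpec(), 2)
        table = compare_curves({"a": curves[:1], "b": curves})
        assert table.loc[table["condition"] == "a", "sd_rel_freq"].isna().all()
        assert table.loc[table["condition"] == "b", "sd_rel_freq"].notna().all()

    def test_differing_bin_grids_error(self):
        orte = generate_smlm_pattern(PointPatternSpec(seed=2))
        a = curve_from_orte(orte, bin_width_nm=10.0)
        b = curve_from_orte(orte, bin_width_nm=20.0)
        with pytest.raises(ValueError, match="bin grids"):
            compare_curves({"a": [a], "b": [b]})
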