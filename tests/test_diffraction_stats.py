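import math

import gemmi
import numpy as np
import pandas as pd
import pytest

from shockjet import diffraction_stats as ds
from shockjet import synthio

CELL = (55.7, 158.1, 67.7, 90.0, 90.0, 90.0)


def peaks(*rows):
    return pd.DataFrame(rows, columns=["d", "I", "sigma"])


class TestImageResolution:
    def test_best_qualifying_peak_wins_with_inclusive_boundary(self):
        p = peaks((2.2, 3.5, 1.0), (2.8, 4.0, 1.0), (3.4, 9.0, 1.0))
        assert ds.image_resolution(p) == pytest.approx(2.8)

    def test_no_qualifying_peak_gives_none(self):
        p = peaks((2.2, 3.0, 1.0), (3.0, 3.9, 1.0))
        assert ds.image_resolution(p) is None

    def test_single_qualifying_peak(self):
        assert ds.image_resolution(peaks((3.0, 8.0, 1.0))) == 3.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ds.image_resolution(peaks())

    def test_matches_brute_force_oracle_on_random_lists(self, rng):
        """image_resolution equals a min-scan oracle over 1000 random peak lists."""
        for _ in range(1000):
            n = rng.integers(1, 30)
            p = peaks(*zip(
                rng.uniform(1.5, 20, n),
                rng.uniform(0, 40, n),
                rng.uniform(0.5, 5, n),
            ))
            thr = rng.uniform(2, 6)
            best = None
            for _, row in p.iterrows():  # independent brute-force scan
                if row["I"] / row["sigma"] >= thr:
                    if best is None or row["d"] < best:
                        best = row["d"]
            got = ds.image_resolution(p, thr)
            if best is None:
                assert got is None
            else:
                assert got == pytest.approx(best)


class TestBinByProbeEnergy:
    def test_median_and_error_of_mean(self):
        out = ds.bin_by_probe_energy(
            np.array([0.5, 0.5, 0.5]), np.array([3.0, 3.2, 3.4]), np.array([0.0, 1.0])
        )
        assert out.loc[0, "n"] == 3
        assert out.loc[0, "median_resolution"] == pytest.approx(3.2)
        assert out.loc[0, "sem"] == pytest.approx(np.std([3.0, 3.2, 3.4], ddof=1) / math.sqrt(3))

    def test_single_value_bin_has_no_sem(self):
        out = ds.bin_by_probe_energy(np.array([0.5]), np.array([3.0]), np.array([0.0, 1.0]))
        assert out.loc[0, "median_resolution"] == 3.0
        assert out.loc[0, "sem"] is None

    def test_empty_bin_reported_without_statistics(self):
        out = ds.bin_by_probe_energy(np.array([0.1]), np.array([3.0]), np.array([0.0, 0.05, 0.2]))
        assert out.loc[0, "n"] == 0
        assert pd.isna(out.loc[0, "median_resolution"])


class TestEqualizeEnergyDistributions:
    def test_per_bin_minimum_rule(self):
        a = np.concatenate([np.full(10, 0.25), np.full(20, 0.75)])
        b = np.concatenate([np.full(15, 0.25), np.full(5, 0.75)])
        ia, ib = ds.equalize_energy_distributions(a, b, np.array([0.0, 0.5, 1.0]), seed=1)
        assert [(a[ia] < 0.5).sum(), (a[ia] >= 0.5).sum()] == [10, 5]
        assert [(b[ib] < 0.5).sum(), (b[ib] >= 0.5).sum()] == [10, 5]

    def test_identical_distributions_unchanged(self):
        a = np.linspace(0.1, 0.9, 40)
        ia, ib = ds.equalize_energy_distributions(a, a.copy(), np.array([0.0, 0.5, 1.0]), seed=2)
        assert ia.size == ib.size == 40

    def test_disjoint_supports_give_empty_selection(self):
        a = np.full(10, 0.2)
        b = np.full(10, 0.8)
        ia, ib = ds.equalize_energy_distributions(a, b, np.array([0.0, 0.5, 1.0]), seed=3)
        assert ia.size == 0 and ib.size == 0


def obs_from_rows(rows, cell=CELL, sg="P212121"):
    df = pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigma", "image_id"])
    return ds.ReflectionObservations(df, cell, sg)


class TestMerge:
    def test_multiplicity_counts_observations(self):
        obs = obs_from_rows([
            (1, 0, 0, 10.0, 1.0, 0), (1, 0, 0, 12.0, 1.0, 1), (1, 0, 0, 14.0, 1.0, 2),
            (0, 1, 0, 5.0, 1.0, 0),
        ])
        m = ds.merge(obs).records.set_index(["h", "k", "l"])
        assert m.loc[(1, 0, 0), "multiplicity"] == 3
        assert m.loc[(1, 0, 0), "I"] == pytest.approx(12.0)
        assert m.loc[(0, 1, 0), "multiplicity"] == 1

    def test_friedel_mates_merge_to_one_record(self):
        obs = obs_from_rows([(1, 2, 3, 10.0, 1.0, 0), (-1, -2, -3, 20.0, 1.0, 1)])
        m = ds.merge(obs).records
        assert len(m) == 1
        assert m["I"].iloc[0] == pytest.approx(15.0)

    def test_single_observations_pass_through(self):
        obs = obs_from_rows([(1, 2, 3, 10.0, 1.0, 0), (2, 3, 4, 7.0, 1.0, 0)])
        m = ds.merge(obs).records
        assert sorted(m["I"]) == [7.0, 10.0]

    def test_multiplicity_sum_conserved_on_random_observations(self, rng):
        ref = synthio.wilson_intensities(d_min=5.0, b_iso=30.0)
        obs = synthio.generate_reflection_observations(ref, 15, seed=9, obs_fraction=0.4)
        m = ds.merge(obs)
        assert m.records["multiplicity"].sum() == len(obs.df)


class TestHalfSetMetrics:
    def test_identical_halves_reach_metric_limits(self):
        ref = synthio.wilson_intensities(d_min=4.0, b_iso=30.0, dispersion=True, seed=1)
        obs = synthio.generate_reflection_observations(
            ref, n_images=8, scale_sd=0.0, noise_sd=0.0, seed=2, obs_fraction=0.6
        )
        out = ds.half_set_metrics(obs, seed=0)["overall"]
        assert out["rsplit_pct"] == pytest.approx(0.0, abs=1e-9)
        assert out["cc_half"] == pytest.approx(1.0, abs=1e-12)
        assert out["cc_star"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_rsplit(self):
        # halves I1=(100,50), I2=(90,60): 2^(-1/2)*(10+10)/150 = 9.43%
        obs = obs_from_rows([
            (1, 1, 1, 100.0, 1.0, 0), (2, 2, 2, 50.0, 1.0, 0),
            (1, 1, 1, 90.0, 1.0, 1), (2, 2, 2, 60.0, 1.0, 1),
        ])
        out = ds.half_set_metrics(obs, n_bins=1, seed=0)["overall"]
        assert out["rsplit_pct"] == pytest.approx(100 * 20 / 150 / math.sqrt(2), rel=1e-9)

    def test_single_image_rejected(self):
        obs = obs_from_rows([(1, 1, 1, 10.0, 1.0, 0)])
        with pytest.raises(ValueError, match=">= 2 images"):
            ds.half_set_metrics(obs)


class TestCCStar:
    @pytest.mark.parametrize("cc,expected", [(0.705, 0.909), (0.857, 0.961)])
    def test_published_conversion_values(self, cc, expected):
        assert round(ds.cc_star(cc), 3) == expected

    def test_monotone_increasing_on_unit_interval(self):
        grid = np.linspace(0.01, 1.0, 50)
        vals = [ds.cc_star(c) for c in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert ds.cc_star(1.0) == 1.0

    def test_nonpositive_cc_gives_nan(self):
        assert math.isnan(ds.cc_star(-0.2))


def brute_force_unique_p212121(cell, d_min, d_max):
    """Independent oracle: non-negative octant under mmm with explicit
    2_1 screw-axis absence rules (h00 h odd, 0k0 k odd, 00l l odd)."""
    a, b, c = cell[:3]
    out = set()
    for h in range(int(a / d_min) + 2):
        for k in range(int(b / d_min) + 2):
            for l in range(int(c / d_min) + 2):
                if h == k == l == 0:
                    continue
                if k == l == 0 and h % 2:
                    continue
                if h == l == 0 and k % 2:
                    continue
                if h == k == 0 and l % 2:
                    continue
                d = 1.0 / math.sqrt((h / a) ** 2 + (k / b) ** 2 + (l / c) ** 2)
                if d_min <= d <= d_max:
                    out.add((h, k, l))
    return out


class TestCompleteness:
    def test_full_unique_list_is_100_percent(self):
        ref = synthio.wilson_intensities(d_min=5.0, d_max=40.0, b_iso=30.0)
        obs = obs_from_rows(
            [(h, k, l, i, 1.0, 0) for (h, k, l, i) in
             ref[["h", "k", "l", "I"]].itertuples(index=False)]
        )
        m = ds.merge(obs)
        assert ds.completeness(m, (40.0, 5.0)) == pytest.approx(100.0)

    def test_half_list_is_50_percent(self):
        ref = synthio.wilson_intensities(d_min=5.0, d_max=40.0, b_iso=30.0)
        half = ref.iloc[::2]
        obs = obs_from_rows(
            [(h, k, l, i, 1.0, 0) for (h, k, l, i) in
             half[["h", "k", "l", "I"]].itertuples(index=False)]
        )
        m = ds.merge(obs)
        expected = 100.0 * len(half) / len(ref)
        assert ds.completeness(m, (40.0, 5.0)) == pytest.approx(expected, abs=0.2)

    def test_unique_enumeration_matches_brute_force_oracle(self):
        mine = ds.unique_reflections(CELL, "P212121", 5.0, 40.0)
        oracle = brute_force_unique_p212121(CELL, 5.0, 40.0)
        assert mine == oracle

    def test_screw_axis_absences_excluded(self):
        uniq = ds.unique_reflections(CELL, "P212121", 5.0, 100.0)
        assert (2, 0, 0) in uniq and (3, 0, 0) not in uniq
        assert (0, 2, 0) in uniq and (0, 3, 0) not in uniq
        assert (0, 0, 2) in uniq and (0, 0, 3) not in uniq

    def test_inverted_limits_rejected(self):
        ref = synthio.wilson_intensities(d_min=6.0, b_iso=30.0)
        obs = synthio.generate_reflection_observations(ref, 3, seed=1)
        with pytest.raises(ValueError):
            ds.completeness(ds.merge(obs), (5.0, 40.0))

    def test_non_decreasing_as_observations_added(self):
        ref = synthio.wilson_intensities(d_min=6.0, b_iso=30.0)
        obs = synthio.generate_reflection_observations(ref, 10, seed=4, obs_fraction=0.1)
        df = obs.df
        values = []
        for n in (2, 5, 10):
            sub = ds.ReflectionObservations(
                df[df["image_id"] < n], obs.cell, obs.space_group
            )
            values.append(ds.completeness(ds.merge(sub), (30.0, 6.0)))
        assert values[0] <= values[1] <= values[2] <= 100.0


class TestWilsonB:
    def test_planted_b_recovered_exactly_without_noise(self):
        ref = synthio.wilson_intensities(d_min=2.5, b_iso=50.0)
        obs = synthio.generate_reflection_observations(
            ref, 4, scale_sd=0.0, noise_sd=0.0, seed=5, obs_fraction=0.9
        )
        assert ds.wilson_b(ds.merge(obs)) == pytest.approx(50.0, abs=0.5)

    def test_planted_b_with_noise_recovered_within_5_percent(self):
        ref = synthio.wilson_intensities(d_min=2.5, b_iso=47.4)
        obs = synthio.generate_reflection_observations(
            ref, 20, scale_sd=0.05, noise_sd=0.05, seed=6, obs_fraction=0.3
        )
        assert ds.wilson_b(ds.merge(obs)) == pytest.approx(47.4, rel=0.05)

    def test_flat_intensities_give_zero_b(self):
        ref = synthio.wilson_intensities(d_min=3.0, b_iso=30.0)
        ref = ref.assign(I=100.0)
        obs = synthio.generate_reflection_observations(
            ref, 4, scale_sd=0.0, noise_sd=0.0, seed=7, obs_fraction=0.9
        )
        assert ds.wilson_b(ds.merge(obs)) == pytest.approx(0.0, abs=1e-6)

    def test_too_few_bins_rejected(self):
        obs = obs_from_rows([(1, 1, 1, 10.0, 1.0, 0), (2, 2, 2, 9.0, 1.0, 0)])
        with pytest.raises(ValueError):
            ds.wilson_b(ds.merge(obs))


def step_intensity_observations(d_cut, lo=0.01, hi=1000.0, dip=None, seed=0):
    """Observations whose merged I/sigma is high above d_cut and ~0 below
    (or inside a [d1, d2] dip), with constant absolute noise."""
    ref = synthio.wilson_intensities(d_min=2.5, b_iso=0.0, base_intensity=1.0)
    inten = np.where(ref["d"] >= d_cut, hi, lo)
    if dip is not None:
        d1, d2 = dip
        inten = np.where((ref["d"] >= d1) & (ref["d"] <= d2), lo, hi)
    ref = ref.assign(I=inten)
    return synthio.generate_reflection_observations(
        ref, 12, scale_sd=0.0, noise_sd=3.0, seed=seed,
        obs_fraction=0.5, relative_noise=False,
    )


class TestAutoResolutionCutoff:
    def test_monotone_crossing_found_at_bin_edge(self):
        d_cut = 3.2
        obs = step_intensity_observations(d_cut)
        cutoff = ds.auto_resolution_cutoff(obs, n_bins=20)
        # cutoff is the inner edge of the last passing bin, i.e. within one
        # bin width of the planted crossing (the straddling bin may pass)
        assert d_cut - 0.15 <= cutoff <= d_cut + 0.25

    def test_all_bins_passing_gives_overall_d_min(self):
        obs = step_intensity_observations(10.0, lo=1000.0, hi=1000.0)
        m = ds.merge(obs)
        assert ds.auto_resolution_cutoff(obs, n_bins=10) == pytest.approx(m.d_min)

    def test_first_crossing_rule_ignores_recovery(self):
        # I/sigma dips below 1 only in [3.4, 3.8] A and recovers at higher res
        obs = step_intensity_observations(None, dip=(3.4, 3.8))
        cutoff = ds.auto_resolution_cutoff(obs, n_bins=20)
        # terminates at the dip (within one bin) and never reaches the
        # recovered high-resolution region below 3.4 A
        assert 3.5 <= cutoff <= 3.9

    def test_unusable_data_rejected(self):
        obs = step_intensity_observations(100.0)  # every bin fails
        with pytest.raises(ValueError, match="no usable data"):
            ds.auto_resolution_cutoff(obs, n_bins=10)


class TestVolumeBinning:
    def test_equal_volume_bins_have_equal_population_on_uniform_s3(self):
        # d sampled exactly uniform in 1/d^3 -> bin counts differ by <= 1
        s3 = np.linspace(1 / 20.0**3, 1 / 2.5**3, 1201)[:-1] + 1e-9
        d = s3 ** (-1 / 3.0)
        edges = ds._volume_bin_edges(20.0, 2.5, 12)
        idx = ds._assign_volume_bins(d, edges)
        counts = np.bincount(idx, minlength=12)
        assert counts.max() - counts.min() <= 1
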