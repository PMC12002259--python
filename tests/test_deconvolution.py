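"""Histogram deconvolution: calibration, mixture fitting, AIC, counts."""

import numpy as np
import pandas as pd
import pytest

from ringpool import (
    CalibrationModel,
    EventList,
    counts_to_concentrations,
    deconvolve,
    fit_sd_calibration,
    select_components,
)
from ringpool.deconvolution import PeakSet, Peak, aic_least_squares


def gaussian_events(rng, components, mass_min=40.0):
    """Draw events from a list of (center, sd, n) Gaussian components."""
    masses = np.concatenate(
        [rng.normal(c, s, size=n) for c, s, n in components]
    )
    return EventList(
        masses=masses[masses >= mass_min], concentration_nM=100.0
    )


class TestSdCalibration:
    def test_exact_line_through_two_points(self):
        calib = fit_sd_calibration([(100.0, 10.0), (300.0, 20.0)])
        assert calib.sd_slope == pytest.approx(0.05)
        assert calib.sd_intercept == pytest.approx(5.0)
        assert calib.sd(200.0) == pytest.approx(15.0)

    def test_narrow_sample_peak_below_line_is_allowed(self):
        # a well-defined 279.6 kDa ring with SD 15.6 kDa may undercut the
        # calibration standards: the line is only an upper bound
        calib = fit_sd_calibration([(100.0, 10.0), (300.0, 20.0)])
        assert 15.6 < calib.sd(279.6)

    def test_noisy_recovery(self, rng):
        masses = np.linspace(60, 800, 12)
        sds = 0.04 * masses + 6.0 + rng.normal(0, 0.5, size=masses.size)
        calib = fit_sd_calibration(np.column_stack([masses, sds]))
        assert calib.sd_slope == pytest.approx(0.04, abs=0.01)
        assert calib.sd_intercept == pytest.approx(6.0, abs=3.0)
        assert len(calib.residuals) == masses.size

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_sd_calibration([(100.0, 10.0), (100.0, 12.0)])

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            CalibrationModel(sd_slope=0.05, sd_intercept=5.0,
                             mass_min=100.0, mass_max=50.0)


class TestSelectComponents:
    def test_argmin_aic(self):
        assert select_components([(1, 100.0), (2, 40.0), (3, 45.0)]) == 2

    def test_tie_breaks_toward_smaller_k(self):
        assert select_components([(1, 50.0), (2, 50.0 - 1e-12)]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_components([])

    def test_aic_formula(self):
        assert aic_least_squares(100, 50.0, 6) == pytest.approx(
            100 * np.log(0.5) + 12
        )


class TestDeconvolve:
    CALIB = CalibrationModel(sd_slope=0.05, sd_intercept=5.0)

    def test_single_undecamer_peak(self, rng):
        """One Gaussian at the 11-mer mass of the truncated construct."""
        events = gaussian_events(rng, [(278.3, 15.6, 5000)])
        peaks = deconvolve(events, monomer_mass=25.3, calib=self.CALIB)
        assert len(peaks.peaks) == 1
        (p,) = peaks.peaks
        assert p.center == pytest.approx(278.3, abs=2.0)
        assert p.assigned_n == 11
        assert p.area_fraction == 1.0

    def test_two_components_area_ratio(self, rng):
        events = gaussian_events(
            rng, [(48.4, 7.4, 4000), (484.0, 24.0, 1000)]
        )
        peaks = deconvolve(events, monomer_mass=48.4, calib=self.CALIB)
        fracs = sorted(p.area_fraction for p in peaks.peaks)
        assert len(peaks.peaks) == 2
        # 4:1 ratio; monomer events below 40 kDa are lost but the fitted
        # Gaussian area restores the full component weight
        assert fracs[-1] == pytest.approx(0.8, abs=0.03)
        assert fracs[0] == pytest.approx(0.2, abs=0.03)

    def test_small_contaminant_pruned(self, rng):
        """A planted 1.5% component falls below the 2% area rule."""
        events = gaussian_events(
            rng, [(278.3, 15.6, 5000), (120.0, 10.0, 76)]
        )
        peaks = deconvolve(events, monomer_mass=25.3, calib=self.CALIB)
        assert len(peaks.peaks) == 1
        assert peaks.peaks[0].assigned_n == 11

    def test_area_fractions_sum_to_one(self, rng):
        events = gaussian_events(
            rng, [(48.4, 7.4, 2000), (96.8, 9.8, 1000), (484.0, 24.0, 500)]
        )
        peaks = deconvolve(events, monomer_mass=48.4, calib=self.CALIB)
        assert sum(p.area_fraction for p in peaks.peaks) == pytest.approx(1.0)

    def test_sd_bounded_by_calibration(self, rng):
        events = gaussian_events(
            rng, [(48.4, 7.4, 2000), (484.0, 40.0, 2000)]  # 40 > calib sd
        )
        peaks = deconvolve(events, monomer_mass=48.4, calib=self.CALIB)
        for p in peaks.peaks:
            assert p.sd <= self.CALIB.sd(p.center) + 1e-6

    def test_detection_limit_respected(self, rng):
        """Events below mass_min never enter the histogram."""
        masses = np.concatenate(
            [rng.normal(278.3, 15.6, 3000), np.full(500, 25.0)]
        )
        events = EventList(masses=masses)
        peaks = deconvolve(events, monomer_mass=25.3, calib=self.CALIB)
        assert peaks.n_events == int(np.sum(masses >= self.CALIB.mass_min))
        assert all(p.center >= self.CALIB.mass_min for p in peaks.peaks)

    def test_cluster_label_beyond_n_max(self, rng):
        ring = 11 * 25.3
        events = gaussian_events(
            rng, [(278.3, 15.6, 3000), (2 * ring, 25.0, 1000)]
        )
        # no ring larger than 13 protomers: a 2x-ring species is a cluster
        peaks = deconvolve(events, monomer_mass=25.3, calib=self.CALIB, n_max=13)
        labels = {p.label for p in peaks.peaks}
        assert "cluster" in labels
        cluster = next(p for p in peaks.peaks if p.label == "cluster")
        assert cluster.assigned_n is None

    def test_too_few_events_rejected(self, rng):
        events = gaussian_events(rng, [(278.3, 15.6, 30)])
        with pytest.raises(ValueError, match=">= 50"):
            deconvolve(events, monomer_mass=25.3, calib=self.CALIB)

    def test_aic_selects_true_component_count(self):
        """Bimodal 2000-event fixtures: true k chosen in >= 90% of seeds."""
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            r = np.random.default_rng(1000 + seed)
            events = gaussian_events(
                r, [(96.8, 9.8, 1300), (484.0, 24.0, 700)]
            )
            peaks = deconvolve(events, monomer_mass=48.4, calib=self.CALIB)
            hits += len(peaks.peaks) == 2
        assert hits >= 0.9 * n_rep

    def test_round_trip_centers_and_areas(self, rng):
        """Generate from a known peak set, deconvolve, recover it."""
        comps = [(48.4, 7.4, 2500), (145.2, 12.3, 1500), (484.0, 24.0, 1000)]
        events = gaussian_events(rng, comps)
        peaks = deconvolve(events, monomer_mass=48.4, calib=self.CALIB)
        got = {p.assigned_n: p for p in peaks.peaks}
        assert set(got) == {1, 3, 10}
        total = sum(n for _, _, n in comps)
        for (center, sd, n), j in zip(comps, (1, 3, 10)):
            p = got[j]
            assert p.center == pytest.approx(center, abs=0.5 * sd / np.sqrt(p.area) + 1.0)
            assert p.area_fraction == pytest.approx(n / total, abs=0.03)


class TestCountsToConcentrations:
    def _peakset(self, peaks):
        return PeakSet(
            peaks=peaks, n_components=len(peaks),
            aic_table=pd.DataFrame({"k": [len(peaks)], "aic": [0.0], "rss": [0.0]}),
            monomer_mass=48.4, residual_norm=0.0, n_events=1000,
        )

    def test_single_monomer_peak(self):
        ps = self._peakset(
            [Peak(48.4, 7.4, 1000.0, 1.0, 1, "1-mer")]
        )
        table = counts_to_concentrations(ps, nominal_total=10.0)
        assert table["conc_nM"].tolist() == [10.0]

    def test_equal_areas_monomer_undecamer(self):
        """Equal fractions at n=1 and n=11 at 12 nM nominal give 1 nM each."""
        ps = self._peakset(
            [Peak(48.4, 7.4, 500.0, 0.5, 1, "1-mer"),
             Peak(532.4, 30.0, 500.0, 0.5, 11, "11-mer")]
        )
        table = counts_to_concentrations(ps, nominal_total=12.0)
        assert table["conc_nM"].tolist() == pytest.approx([1.0, 1.0])

    def test_protomer_mass_balance(self):
        ps = self._peakset(
            [Peak(48.4, 7.4, 600.0, 0.6, 1, "1-mer"),
             Peak(96.8, 9.8, 300.0, 0.3, 2, "2-mer"),
             Peak(484.0, 29.2, 100.0, 0.1, 10, "10-mer")]
        )
        table = counts_to_concentrations(ps, nominal_total=50.0)
        assert float((table["n"] * table["conc_nM"]).sum()) == pytest.approx(50.0)

    def test_clusters_excluded_and_all_cluster_rejected(self):
        only_cluster = self._peakset(
            [Peak(1064.8, 40.0, 100.0, 1.0, None, "cluster")]
        )
        with pytest.raises(ValueError, match="no protomer-assigned"):
            counts_to_concentrations(only_cluster, nominal_total=10.0)
        mixed = self._peakset(
            [Peak(48.4, 7.4, 900.0, 0.9, 1, "1-mer"),
             Peak(1064.8, 40.0, 100.0, 0.1, None, "cluster")]
        )
        table = counts_to_concentrations(mixed, nominal_total=10.0)
        assert len(table) == 1 and table["conc_nM"].iloc[0] == pytest.approx(10.0)
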