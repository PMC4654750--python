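"""Zoom-scan pipeline: extraction, filtering, charge determination, masses."""

import numpy as np
import pytest

from cysmap import composition_of, monoisotopic_mass
from cysmap.constants import C13_C12_SPACING, PROTON_MASS
from cysmap.simulate import (
    AcquisitionModel,
    RunEntry,
    simulate_run,
    simulate_zoom_scan,
)
from cysmap.theoretical import record_from_species
from cysmap.zoomscan import (
    IsotopomerSeries,
    ScanError,
    ZoomScan,
    average_from_series,
    cluster_observations,
    denoise,
    extract_zoom_scans,
    find_series_and_charge,
    monoisotopic_from_series,
    observation_from_scan,
    process_run,
    quality_filter,
)


def make_scan(mz, intensity, scan_id="s1", rt=0.0, precursor=None):
    mz = np.asarray(mz, dtype=float)
    return ZoomScan(
        scan_id=scan_id,
        retention_time=rt,
        precursor_mz=precursor if precursor is not None else float(mz[0]),
        mz=mz,
        intensity=np.asarray(intensity, dtype=float),
        window_low=float(mz.min()) - 1.0,
        window_high=float(mz.max()) + 1.0,
    )


def series_scan(start_mz, charge, rel_intensities, base_offset=0.0):
    mz = start_mz + np.arange(len(rel_intensities)) * C13_C12_SPACING / charge
    return make_scan(mz + base_offset, rel_intensities)


class TestQualityFilterAndDenoise:
    def test_low_tic_scans_discarded(self):
        scans = [
            make_scan([500.0, 500.3], [600.0, 400.0]),
            make_scan([600.0, 600.3], [60000.0, 50000.0]),
        ]
        kept = quality_filter(scans, min_tic=1e4)
        assert len(kept) == 1 and kept[0].tic > 1e4

    def test_min_tic_zero_is_identity(self):
        scans = [make_scan([500.0], [1.0])]
        assert quality_filter(scans, min_tic=0.0) == scans

    def test_three_percent_rule(self):
        scan = make_scan([100.0, 101.0, 102.0], [100.0, 5.0, 2.0])
        clean = denoise(scan)
        assert clean.intensity.tolist() == [100.0, 5.0]

    def test_zero_threshold_is_identity(self):
        scan = make_scan([100.0, 101.0], [100.0, 0.5])
        assert denoise(scan, 0.0).n_peaks == 2

    def test_single_peak_unchanged(self):
        scan = make_scan([100.0], [10.0])
        assert denoise(scan).n_peaks == 1

    def test_denoise_idempotent(self):
        scan = make_scan(
            [100.0, 100.5, 101.0, 101.5], [100.0, 50.0, 10.0, 4.0]
        )
        once = denoise(scan)
        twice = denoise(once)
        assert np.array_equal(once.mz, twice.mz)
        assert np.array_equal(once.intensity, twice.intensity)

    def test_quality_filter_and_denoise_commute_with_scan_order(self):
        scans = [
            make_scan([500.0, 500.3], [9e4, 2e3], scan_id=str(i))
            for i in range(3)
        ]
        fwd = [denoise(s) for s in quality_filter(scans, 1e4)]
        rev = [denoise(s) for s in quality_filter(list(reversed(scans)), 1e4)]
        assert {s.scan_id for s in fwd} == {s.scan_id for s in rev}


# denoise needs a non-empty scan; build the empty case explicitly
def _empty_scan():
    return ZoomScan(
        scan_id="empty",
        retention_time=0.0,
        precursor_mz=500.0,
        mz=np.array([]),
        intensity=np.array([]),
        window_low=499.0,
        window_high=502.0,
    )


def test_denoise_rejects_empty_scan():
    with pytest.raises(ScanError, match="empty"):
        denoise(_empty_scan())


class TestFindSeriesAndCharge:
    @pytest.mark.parametrize("charge", [1, 2, 4, 8, 12])
    def test_charge_from_spacing(self, charge):
        scan = series_scan(800.0, charge, [30.0, 100.0, 80.0, 40.0, 10.0])
        series = find_series_and_charge(scan)
        assert series.charge == charge
        assert series.mz.size == 5

    def test_quarter_dalton_spacing_is_charge_four(self):
        mz = 443.724 + np.arange(5) * 0.2508
        series = find_series_and_charge(make_scan(mz, [50, 100, 80, 40, 15]))
        assert series.charge == 4

    def test_noise_peak_between_isotopomers_ignored(self):
        mz = list(800.0 + np.arange(4) * C13_C12_SPACING / 3) + [800.1, 801.6]
        scan = make_scan(mz, [40.0, 100.0, 70.0, 30.0, 8.0, 6.0])
        series = find_series_and_charge(scan)
        assert series.charge == 3
        assert series.mz.size == 4

    def test_chimeric_scan_rejected(self):
        # a consistent 3-member series plus a dominant unrelated peak
        mz = list(800.0 + np.arange(3) * C13_C12_SPACING / 2) + [802.7]
        scan = make_scan(mz, [50.0, 80.0, 30.0, 500.0])
        with pytest.raises(ScanError, match="chimeric"):
            find_series_and_charge(scan)

    def test_no_consistent_series_rejected(self):
        scan = make_scan([700.0, 700.4, 701.1], [10.0, 100.0, 20.0])
        with pytest.raises(ScanError):
            find_series_and_charge(scan)

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ScanError):
            find_series_and_charge(make_scan([700.0], [1.0]))


class TestMassFromSeries:
    def make_series(self, mz, intensity, charge):
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        return IsotopomerSeries(
            mz=mz,
            intensity=intensity,
            charge=charge,
            base_peak_index=int(np.argmax(intensity)),
            spacing_rmsd=0.0,
        )

    def test_monoisotopic_from_lowest_member(self):
        series = self.make_series(
            443.724 + np.arange(4) * C13_C12_SPACING / 4, [50, 100, 80, 40], 4
        )
        assert monoisotopic_from_series(series) == pytest.approx(
            1770.866, abs=0.01
        )

    def test_singly_charged(self):
        series = self.make_series([100.0, 101.0034], [100.0, 10.0], 1)
        assert monoisotopic_from_series(series) == pytest.approx(
            98.992724, abs=1e-5
        )

    def test_average_is_midpoint_for_equal_intensities(self):
        m1, m2 = 1000.0, 1001.003
        series = self.make_series(
            [m1 + PROTON_MASS, m2 + PROTON_MASS], [50.0, 50.0], 1
        )
        assert average_from_series(series) == pytest.approx(
            (m1 + m2) / 2, abs=1e-9
        )

    def test_single_weighted_member_average_equals_mono(self):
        # all intensity on the monoisotopic member: average == mono
        series = self.make_series([500.0, 500.5], [100.0, 0.0], 2)
        assert average_from_series(series) == pytest.approx(
            monoisotopic_from_series(series), abs=1e-9
        )

    def test_zero_total_intensity_rejected(self):
        series = self.make_series([500.0, 500.5], [0.0, 0.0], 2)
        with pytest.raises(ScanError):
            average_from_series(series)


class TestRoundTrips:
    def test_noise_free_scan_recovers_theory(self, fig2_species, noise_free_model):
        truth = record_from_species("fig2", fig2_species)
        sim = simulate_zoom_scan(fig2_species, 4, noise_free_model)
        obs = observation_from_scan(sim.scan)
        assert obs.charge == 4
        ppm = (
            (obs.neutral_monoisotopic - truth.monoisotopic_mass)
            / truth.monoisotopic_mass
            * 1e6
        )
        assert abs(ppm) < 0.1
        assert obs.n_isotopomers >= 5  # >=5 isotopomers above 3% for 3.3 kDa
        assert obs.nmd == pytest.approx(truth.nmd, abs=0.01)
        # 3% cutoff truncates the envelope tail: average within 40 ppm
        avg_ppm = (
            (obs.neutral_average - truth.average_mass) / truth.average_mass * 1e6
        )
        assert abs(avg_ppm) < 40.0

    def test_charge_invariance_of_observations(self, fig2_species, noise_free_model):
        obs = [
            observation_from_scan(
                simulate_zoom_scan(fig2_species, z, noise_free_model).scan
            )
            for z in (3, 4)
        ]
        rel = abs(
            obs[0].neutral_monoisotopic - obs[1].neutral_monoisotopic
        ) / obs[0].neutral_monoisotopic
        assert rel < 5e-6
        assert abs(obs[0].nmd - obs[1].nmd) < 0.005
        assert abs(obs[0].nis - obs[1].nis) < 0.005

    def test_average_mass_truncation_bias_is_small_for_large_peptides(
        self, noise_free_model
    ):
        """The 3% cutoff drops the faint heavy tail of the envelope, so the
        intensity-weighted average sits slightly below the full-distribution
        average; the deficit stays within tens of ppm up to ~8 kDa."""
        rng = np.random.default_rng(5)
        from cysmap.simulate import random_species

        for _ in range(3):
            sp = random_species(rng, 3000.0, 8200.0)
            truth = record_from_species("x", sp)
            z = max(2, int(round(truth.monoisotopic_mass / 900)))
            obs = observation_from_scan(
                simulate_zoom_scan(sp, z, noise_free_model).scan
            )
            err = obs.neutral_average - truth.average_mass
            assert err <= 1e-6  # truncation can only lower the average
            assert abs(err) / truth.average_mass * 1e6 < 40.0


class TestRunProcessing:
    def test_extraction_counts_and_order(self, run_entries, tmp_path, noise_free_model):
        path, _ = simulate_run(
            run_entries, noise_free_model, path=tmp_path / "run.mzxml"
        )
        scans = extract_zoom_scans(path)
        assert len(scans) == 3  # surveys are not zoom scans
        assert [s.retention_time for s in scans] == sorted(
            s.retention_time for s in scans
        )

    def test_process_run_recovers_all_species(self, run_entries, tmp_path):
        path, sims = simulate_run(
            run_entries, AcquisitionModel(seed=8), path=tmp_path / "run.mzxml"
        )
        observations, failures = process_run(path)
        assert not failures
        assert len(observations) == 3
        for obs, sim in zip(observations, sims):
            assert obs.charge == sim.charge
            rel = abs(
                obs.neutral_monoisotopic - sim.truth.monoisotopic_mass
            ) / sim.truth.monoisotopic_mass
            assert rel < 5e-6

    def test_unreadable_file_is_fatal(self, tmp_path):
        from cysmap.zoomscan import RunError

        bad = tmp_path / "run.mzxml"
        bad.write_text("not xml at all")
        with pytest.raises(RunError):
            process_run(bad)

    def test_unknown_extension_rejected(self, tmp_path):
        from cysmap.zoomscan import RunError

        p = tmp_path / "run.raw"
        p.write_text("")
        with pytest.raises(RunError):
            extract_zoom_scans(p)


class TestClustering:
    def obs(self, mono, rt, tic=1000.0, charge=2):
        from cysmap.zoomscan import PeptideObservation

        return PeptideObservation(
            neutral_monoisotopic=mono,
            neutral_average=mono + 1.0,
            charge=charge,
            nis=0.6,
            nmd=0.5,
            scan_id=f"{mono}@{rt}",
            retention_time=rt,
            tic=tic,
            n_isotopomers=5,
            spacing_rmsd=0.0,
        )

    def test_close_observations_merge(self):
        a = self.obs(2000.0, 100.0)
        b = self.obs(2000.0 + 2000.0 * 1e-6, 110.0)  # 1 ppm, 10 s
        records = cluster_observations([a, b])
        assert len(records) == 1
        assert records[0].n_scans == 2

    def test_distant_masses_stay_separate(self):
        a = self.obs(2000.0, 100.0)
        b = self.obs(2000.0 * (1 + 50e-6), 100.0)  # 50 ppm apart
        assert len(cluster_observations([a, b])) == 2

    def test_distant_rt_stay_separate(self):
        a = self.obs(2000.0, 100.0)
        b = self.obs(2000.0, 400.0)
        assert len(cluster_observations([a, b])) == 2

    def test_consensus_is_tic_weighted(self):
        a = self.obs(2000.000, 100.0, tic=3000.0)
        b = self.obs(2000.002, 105.0, tic=1000.0)
        rec = cluster_observations([a, b])[0]
        assert rec.monoisotopic_mass == pytest.approx(2000.0005, abs=1e-6)

    def test_planted_run_multiple_charge_states(self, tmp_path):
        rng = np.random.default_rng(77)
        from cysmap.simulate import random_species

        entries = []
        for i in range(8):
            sp = random_species(rng, 1500.0, 6000.0)
            mono = monoisotopic_mass(composition_of(sp))
            z = max(2, int(round(mono / 900.0)))
            entries.append(
                RunEntry(
                    species=sp,
                    label=f"sp{i}",
                    charges=(z, z + 1, z + 2),
                    retention_time=50.0 * (i + 1),
                )
            )
        path, _ = simulate_run(
            entries, AcquisitionModel(seed=13), path=tmp_path / "run.mzxml"
        )
        observations, failures = process_run(path)
        assert not failures and len(observations) == 24
        records = cluster_observations(observations)
        assert len(records) == 8
        assert all(len(r.charge_states) == 3 for r in records)
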