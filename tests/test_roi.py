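import numpy as np
import pytest

from roifuse.raw_io import RunData, Scan
from roifuse.roi import (
    ROI,
    ROIParams,
    build_rois,
    correct_baseline,
    filter_adducts,
    filter_contaminants,
    filter_isotopes,
    recommend_threshold,
)


def make_run(scan_centroids, dt=0.1):
    """scan_centroids: list of [(mz, intensity), ...] per scan."""
    scans = []
    for i, cents in enumerate(scan_centroids):
        if cents:
            mz, inten = zip(*cents)
        else:
            mz, inten = (), ()
        scans.append(Scan(time=i * dt, mz=np.array(mz), intensity=np.array(inten)))
    return RunData(scans=scans, group_id="g", replicate_id="r")


def make_roi(intensities, mz=100.0, dt=1.0, start=0):
    y = np.asarray(intensities, dtype=float)
    idx = np.arange(start, start + len(y))
    return ROI(mz_center=mz, times=idx * dt, intensities=y, scan_indices=idx)


class TestBuildRois:
    def test_two_scan_trace_admitted(self):
        run = make_run([[(100.0, 1e5)], [(100.0, 1e5)]])
        rois = build_rois(run, ROIParams(intensity_threshold=5e4, mz_error=0.01, min_roi_size=2))
        assert len(rois) == 1
        assert len(rois[0]) == 2
        assert rois[0].mz_center == pytest.approx(100.0)

    def test_all_below_threshold(self):
        run = make_run([[(100.0, 1e5)], [(100.0, 1e5)]])
        rois = build_rois(run, ROIParams(intensity_threshold=2e5, mz_error=0.01, min_roi_size=2))
        assert rois == []

    def test_close_masses_stay_disjoint(self):
        cents = [(100.000, 1e5), (100.020, 1e5)]
        run = make_run([cents] * 4)
        rois = build_rois(run, ROIParams(intensity_threshold=5e4, mz_error=0.01, min_roi_size=2))
        assert len(rois) == 2
        assert all(len(r) == 4 for r in rois)
        assert rois[0].mz_spread == 0.0

    def test_short_traces_discarded(self):
        run = make_run([[(100.0, 1e5)], [], [], [(200.0, 1e5)]])
        rois = build_rois(run, ROIParams(intensity_threshold=5e4, mz_error=0.01, min_roi_size=2))
        assert rois == []

    def test_gap_tolerance(self):
        frames = [[(100.0, 1e5)], [], [(100.0, 1e5)]]
        run = make_run(frames)
        params_tol = ROIParams(intensity_threshold=5e4, mz_error=0.01, min_roi_size=2, max_gap=1)
        rois = build_rois(run, params_tol)
        assert len(rois) == 1 and len(rois[0]) == 2
        # the missing scan stays a gap: only 2 members, non-adjacent indices
        assert list(rois[0].scan_indices) == [0, 2]
        params_strict = ROIParams(intensity_threshold=5e4, mz_error=0.01, min_roi_size=2, max_gap=0)
        assert build_rois(run, params_strict) == []

    def test_each_centroid_in_at_most_one_roi(self):
        rng = np.random.default_rng(5)
        frames = []
        for _ in range(6):
            mzs = np.sort(rng.uniform(100, 110, 8))
            frames.append([(m, 1e5) for m in mzs])
        run = make_run(frames)
        rois = build_rois(run, ROIParams(intensity_threshold=5e4, mz_error=0.05, min_roi_size=1))
        seen = set()
        for r in rois:
            for s, m in zip(r.scan_indices, r.mz_values):
                key = (int(s), float(m))
                assert key not in seen
                seen.add(key)
        total = sum(len(s.mz) for s in run.scans)
        assert len(seen) == total

    def test_within_scan_order_irrelevant(self):
        cents = [(100.0, 1e5), (100.5, 2e5), (101.0, 5e4)]
        run_fwd = make_run([cents] * 3)
        run_rev = make_run([list(reversed(cents))] * 3)
        p = ROIParams(intensity_threshold=1e4, mz_error=0.01, min_roi_size=2)
        a = build_rois(run_fwd, p)
        b = build_rois(run_rev, p)
        assert [r.mz_center for r in a] == [r.mz_center for r in b]

    def test_matches_brute_force_on_tiny_runs(self):
        # exhaustive oracle: cluster centroids by m/z gaps > tolerance,
        # then apply size/gap rules per cluster
        rng = np.random.default_rng(11)
        p = ROIParams(intensity_threshold=10.0, mz_error=0.01, min_roi_size=2, max_gap=0)
        for _ in range(20):
            base_mzs = np.sort(rng.uniform(100, 101, 3))
            # guarantee separability between groups
            base_mzs = 100 + np.arange(3) * 0.5 + rng.uniform(0, 0.002, 3)
            frames = []
            present = rng.random((5, 3)) < 0.7
            for i in range(5):
                frames.append(
                    [(base_mzs[j], 100.0) for j in range(3) if present[i, j]]
                )
            run = make_run(frames)
            rois = build_rois(run, p)
            expected = []
            for j in range(3):
                scans_present = np.nonzero(present[:, j])[0]
                # split into consecutive stretches (max_gap 0)
                stretch = []
                for s in scans_present:
                    if stretch and s != stretch[-1] + 1:
                        if len(stretch) >= p.min_roi_size:
                            expected.append((round(base_mzs[j], 4), tuple(stretch)))
                        stretch = []
                    stretch.append(s)
                if len(stretch) >= p.min_roi_size:
                    expected.append((round(base_mzs[j], 4), tuple(stretch)))
            got = sorted(
                (round(r.mz_center, 4), tuple(int(s) for s in r.scan_indices)) for r in rois
            )
            assert got == sorted(expected)


class TestRecommendThreshold:
    def test_single_run_fraction(self):
        run = make_run([[(100.0, 1e6)], [(100.0, 5e5)]])
        assert recommend_threshold([run], 0.05) == pytest.approx(5e4)

    def test_zero_fraction(self):
        run = make_run([[(100.0, 1e6)]])
        assert recommend_threshold([run], 0.0) == 0.0

    def test_lowest_bpc_wins(self):
        r1 = make_run([[(100.0, 1e6)]])
        r2 = make_run([[(100.0, 2e6)]])
        assert recommend_threshold([r1, r2], 0.10) == pytest.approx(1e5)

    def test_fraction_out_of_range(self):
        run = make_run([[(100.0, 1e6)]])
        with pytest.raises(ValueError):
            recommend_threshold([run], 1.5)


class TestBaseline:
    def test_constant_trace_zeroed(self):
        roi = make_roi([100.0] * 30)
        out = correct_baseline(roi, window=10)
        assert np.allclose(out.intensities, 0.0)

    def test_gaussian_on_offset_recovered(self):
        t = np.arange(101)
        clean = 1000 * np.exp(-0.5 * ((t - 50) / 4.0) ** 2)
        roi = make_roi(clean + 100.0)
        out = correct_baseline(roi, window=20)
        assert out.intensities.max() == pytest.approx(1000.0, rel=0.05)
        assert np.all(out.intensities[:20] < 50)
        assert int(np.argmax(out.intensities)) == 50

    def test_all_zero_unchanged(self):
        roi = make_roi([0.0] * 20)
        out = correct_baseline(roi, window=5)
        assert np.allclose(out.intensities, 0.0)

    def test_short_roi_uses_global_minimum(self):
        roi = make_roi([5.0, 7.0, 6.0])
        out = correct_baseline(roi, window=10)
        assert np.allclose(out.intensities, [0.0, 2.0, 1.0])


def co_eluting_pair(mz_lo, h_lo, mz_hi, h_hi, n=21, sigma=3.0):
    t = np.arange(n, dtype=float)
    shape = np.exp(-0.5 * ((t - n // 2) / sigma) ** 2)
    a = ROI(mz_center=mz_lo, times=t, intensities=h_lo * shape, scan_indices=np.arange(n))
    b = ROI(mz_center=mz_hi, times=t, intensities=h_hi * shape, scan_indices=np.arange(n))
    return a, b


class TestTraceFilters:
    def test_isotope_partner_removed(self):
        mono, iso = co_eluting_pair(200.0000, 1e6, 201.0034, 2e5)
        kept, removed = filter_isotopes([mono, iso], mz_error=0.01, corr_min=0.9)
        assert removed == [iso]
        assert kept == [mono]

    def test_single_roi_untouched(self):
        roi, _ = co_eluting_pair(200.0, 1e6, 300.0, 1e5)
        kept, removed = filter_isotopes([roi])
        assert kept == [roi] and removed == []

    def test_non_isotope_spacing_kept(self):
        # 0.5 Da apart: close to, but measurably off, the z=2 spacing
        # (0.50168 Da) at high mass accuracy
        a, b = co_eluting_pair(200.0, 1e6, 200.5, 2e5)
        kept, removed = filter_isotopes([a, b], mz_error=0.001)
        assert len(kept) == 2 and removed == []

    def test_kept_and_removed_partition_input(self):
        a, b = co_eluting_pair(200.0000, 1e6, 201.0034, 2e5)
        c, _ = co_eluting_pair(350.0, 5e5, 999.0, 1.0)
        kept, removed = filter_isotopes([a, b, c], mz_error=0.01)
        assert sorted(map(id, kept + removed)) == sorted(map(id, [a, b, c]))
        assert not set(map(id, kept)) & set(map(id, removed))

    def test_sodium_adduct_removed(self):
        mh, na = co_eluting_pair(300.1000, 1e6, 322.0819, 2e5)
        kept, removed = filter_adducts([mh, na], polarity="positive", mz_error=0.01)
        assert removed == [na]

    def test_empty_adduct_table_is_identity(self):
        mh, na = co_eluting_pair(300.1000, 1e6, 322.0819, 2e5)
        kept, removed = filter_adducts([mh, na], polarity="positive", adduct_table={})
        assert kept == [mh, na] and removed == []

    def test_persistent_contaminant_removed(self):
        n = 100
        t = np.arange(n, dtype=float)
        background = ROI(mz_center=150.0, times=t[:95], intensities=np.full(95, 1e4),
                         scan_indices=np.arange(95))
        kept, removed = filter_contaminants(
            [background], [150.0], mz_error=0.01, run_fraction=0.8, n_scans_total=n
        )
        assert removed == [background]

    def test_empty_contaminant_list_is_identity(self):
        roi, _ = co_eluting_pair(200.0, 1e6, 300.0, 1e5)
        kept, removed = filter_contaminants([roi], [])
        assert kept == [roi] and removed == []

    def test_transient_trace_survives_contaminant_filter(self):
        t = np.arange(10, dtype=float)
        short = ROI(mz_center=150.0, times=t, intensities=np.full(10, 1e5),
                    scan_indices=np.arange(10))
        kept, removed = filter_contaminants([short], [150.0], n_scans_total=100)
        assert kept == [short]
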