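"""Fingerprint matrix construction, QC statistics and the legacy format."""

import itertools

import numpy as np
import pandas as pd
import pytest

import specfx
from specfx import (CommonPeakMatrix, PeakTable, dispersion_stats,
                    fingerprint_similarity, linearity_screen, match_common_peaks,
                    pairwise_similarity, read_legacy_fingerprint, read_peak_table,
                    relative_to_is, write_legacy_fingerprint, write_peak_table)
from specfx.errors import AmbiguousMatchError, PeakTableParseError, SpecfxError
from specfx.synthetic import SyntheticSpec, gen_peak_tables, gen_spectrum_effect


def _table(sample, rts, areas, mode="positive", ids=None):
    ids = ids or [f"p{i}" for i in range(len(rts))]
    return PeakTable(sample=sample, peaks=pd.DataFrame(
        {"peak_id": ids, "rt_min": rts, "area": areas, "mode": mode}))


def _matrix(areas, rts=None, is_peak=None, mode="positive"):
    areas = pd.DataFrame(areas)
    areas.columns = [f"P{i + 1}" for i in range(areas.shape[1])]
    rts = rts or list(range(1, areas.shape[1] + 1))
    meta = pd.DataFrame({"rt_min": rts, "mode": mode}, index=areas.columns)
    return CommonPeakMatrix(areas=areas, peak_meta=meta, is_peak=is_peak)


class TestPeakTableIO:
    def test_round_trip(self, tmp_path):
        t = _table("S1", [1.0, 2.5, 7.25], [100.0, 5.5, 42.0])
        path = tmp_path / "s1.csv"
        write_peak_table(t, path)
        back = read_peak_table(path)
        assert back.sample == "S1"
        pd.testing.assert_frame_equal(back.peaks, t.peaks)

    def test_negative_area_cites_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample,peak_id,rt_min,area,mode\n"
                        "S1,p0,1.0,10,positive\nS1,p1,2.0,-5,positive\n")
        with pytest.raises(PeakTableParseError, match="line 3"):
            read_peak_table(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample,peak_id,rt_min,mode\nS1,p0,1.0,positive\n")
        with pytest.raises(PeakTableParseError, match="area"):
            read_peak_table(path)

    def test_non_numeric_rt(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample,peak_id,rt_min,area,mode\nS1,p0,oops,10,positive\n")
        with pytest.raises(PeakTableParseError, match="rt_min"):
            read_peak_table(path)


class TestMatching:
    def test_self_copy_keeps_all_peaks_and_areas(self):
        t1 = _table("A", [1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        t2 = _table("B", [1.0, 2.0, 3.0], [11.0, 21.0, 31.0])
        m = match_common_peaks([t1, t2], rt_tolerance=0.2)
        assert m.peak_ids == ["P1", "P2", "P3"]
        np.testing.assert_array_equal(m.areas.loc["A"], [10, 20, 30])
        np.testing.assert_array_equal(m.areas.loc["B"], [11, 21, 31])

    def test_offset_within_tolerance_matches_nearest_rt_assignment(self, rng):
        rts = np.sort(rng.uniform(1, 30, 8))
        rts = rts[np.concatenate(([True], np.diff(rts) > 1.0))]  # well separated
        tol = 0.3
        offset = 0.4 * tol
        t1 = _table("A", rts, rng.uniform(1, 10, len(rts)))
        t2 = _table("B", rts + offset, rng.uniform(1, 10, len(rts)))
        m = match_common_peaks([t1, t2], rt_tolerance=tol)
        assert len(m.peak_ids) == len(rts)
        # brute-force nearest-RT bipartite assignment over all permutations
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(len(rts))):
            cost = sum(abs(rts[i] - (rts + offset)[perm[i]]) for i in range(len(rts)))
            if cost < best_cost:
                best, best_cost = perm, cost
        assert best == tuple(range(len(rts)))  # oracle: identity pairing
        for k, pid in enumerate(m.peak_ids):
            assert m.rt.loc["A", pid] == pytest.approx(rts[k])
            assert m.rt.loc["B", pid] == pytest.approx(rts[k] + offset)

    def test_peak_absent_in_one_batch_is_excluded_not_fatal(self):
        t1 = _table("A", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        t2 = _table("B", [1.0, 3.0], [1.0, 3.0])
        m = match_common_peaks([t1, t2], rt_tolerance=0.2)
        assert len(m.peak_ids) == 2
        assert len(m.match_report["excluded"]) == 1
        assert m.match_report["excluded"][0]["present_in"] == ["A"]

    def test_ambiguous_match_names_batch(self):
        t1 = _table("A", [1.0, 1.05], [1.0, 2.0])
        t2 = _table("B", [1.02], [1.5])
        with pytest.raises(AmbiguousMatchError, match="'A'"):
            match_common_peaks([t1, t2], rt_tolerance=0.2)

    def test_batch_order_invariance(self):
        spec = SyntheticSpec(n_batches=5, n_peaks=12, n_active=3, seed=9)
        matrix, _, _ = gen_spectrum_effect(spec)
        tables = gen_peak_tables(matrix, seed=1, rt_jitter_sd=0.01)
        m1 = match_common_peaks(tables, rt_tolerance=0.2)
        m2 = match_common_peaks(tables[::-1], rt_tolerance=0.2)
        pd.testing.assert_frame_equal(m1.areas.sort_index(), m2.areas.sort_index())

    def test_study_shaped_run_yields_seventy_common_peaks(self, default_dataset):
        matrix, _, _ = default_dataset
        tables = gen_peak_tables(matrix, seed=4, rt_jitter_sd=0.01)
        m = match_common_peaks(tables, rt_tolerance=0.2,
                               is_peak_id=matrix.is_peak)
        assert len(m.peak_ids) == 70
        assert m.is_peak is not None


class TestRelativeMetrics:
    def test_is_peak_ratios_are_one(self, default_dataset):
        matrix, _, _ = default_dataset
        rel = relative_to_is(matrix)
        np.testing.assert_allclose(rel.rrt[matrix.is_peak], 1.0)
        np.testing.assert_allclose(rel.rpa[matrix.is_peak], 1.0)
        assert dispersion_stats(rel.rrt[matrix.is_peak], "cv") == 0.0

    def test_rrt_is_direct_rt_ratio(self):
        m = _matrix([[5.0, 7.0], [6.0, 8.0]], rts=[5.0, 10.0], is_peak="P1")
        rel = relative_to_is(m)
        np.testing.assert_allclose(rel.rrt["P2"], 2.0)

    def test_rpa_invariant_to_batch_scaling(self):
        areas = pd.DataFrame([[2.0, 4.0, 8.0], [1.0, 3.0, 9.0]])
        m1 = _matrix(areas, is_peak="P1")
        scaled = areas.copy()
        scaled.iloc[0] *= 7.0
        m2 = _matrix(scaled, is_peak="P1")
        pd.testing.assert_frame_equal(relative_to_is(m1).rpa, relative_to_is(m2).rpa)

    def test_zero_is_area_names_batch(self):
        m = _matrix([[0.0, 1.0], [1.0, 1.0]], is_peak="P1")
        m.areas.index = ["S1", "S2"]
        m.rt = None
        with pytest.raises(SpecfxError, match="S1"):
            relative_to_is(m)


class TestDispersion:
    def test_hand_case(self):
        assert dispersion_stats([1, 2, 3]) == pytest.approx(50.0)

    def test_constant_series_zero(self):
        assert dispersion_stats([4.2] * 5) == 0.0

    def test_scale_invariance(self, rng):
        x = rng.uniform(1, 5, 10)
        assert dispersion_stats(x) == pytest.approx(dispersion_stats(3.7 * x))

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -1.0]])
    def test_errors(self, bad):
        with pytest.raises(SpecfxError):
            dispersion_stats(bad)


class TestLinearityScreen:
    def test_exact_line_retained(self):
        dil = [2.0, 4.0, 8.0, 16.0]
        calib = pd.DataFrame({"P1": [0.5 * 1 / d + 0.1 for d in dil]}, index=dil)
        report = linearity_screen(calib)
        assert report.retained == ["P1"] and report.dropped == []
        assert report.stats.loc["P1", "r2"] == pytest.approx(1.0)
        assert report.stats.loc["P1", "slope"] == pytest.approx(0.5)

    def test_curved_series_matches_closed_form_r2(self):
        dil = np.array([2.0, 4.0, 8.0, 16.0, 32.0, 64.0])
        x = 1.0 / dil
        y = x ** 0.4
        calib = pd.DataFrame({"P1": y}, index=dil)
        report = linearity_screen(calib, r2_threshold=0.99)
        # closed-form OLS R^2 = squared Pearson correlation
        r2_oracle = float(np.corrcoef(x, y)[0, 1] ** 2)
        assert report.stats.loc["P1", "r2"] == pytest.approx(r2_oracle, abs=1e-12)
        assert report.dropped == ["P1"]

    def test_partition_invariant(self, default_dataset):
        matrix, _, _ = default_dataset
        calib = specfx.gen_calibration(matrix, failing_peaks={"P5", "P9"}, seed=1)
        report = linearity_screen(calib)
        assert set(report.retained) | set(report.dropped) == set(matrix.peak_ids)
        assert set(report.retained) & set(report.dropped) == set()
        assert (report.stats.loc[report.retained, "r2"] >= report.threshold).all()

    def test_degenerate_series_rejected(self):
        calib = pd.DataFrame({"P1": [1.0, 1.0, 1.0]}, index=[2.0, 2.0, 2.0])
        with pytest.raises(SpecfxError):
            linearity_screen(calib)


class TestSimilarity:
    def test_batch_equal_to_reference(self):
        m = _matrix([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        np.testing.assert_allclose(fingerprint_similarity(m), 1.0)

    def test_orthogonal_batches(self):
        m = _matrix([[1.0, 0.0], [0.0, 1.0]])
        sims = pairwise_similarity(m)
        assert sims.iloc[0, 1] == pytest.approx(0.0)

    def test_positive_rescaling_gives_one(self):
        m = _matrix([[1.0, 2.0, 3.0], [3.0, 6.0, 9.0]])
        np.testing.assert_allclose(fingerprint_similarity(m), 1.0, atol=1e-12)

    def test_bounded_on_synthetic(self, default_dataset):
        matrix, _, _ = default_dataset
        sims = fingerprint_similarity(matrix)
        assert ((sims >= -1.0) & (sims <= 1.0)).all()

    def test_zero_norm_rejected(self):
        m = _matrix([[0.0, 0.0], [1.0, 2.0]])
        with pytest.raises(SpecfxError, match="zero-norm"):
            fingerprint_similarity(m)


class TestLegacyFormat:
    def test_round_trip(self, tmp_path, default_dataset):
        matrix, _, _ = default_dataset
        path = tmp_path / "legacy.txt"
        write_legacy_fingerprint(matrix, None, path)
        b1, b2 = read_legacy_fingerprint(path)
        mean_area = matrix.areas.mean(axis=0)
        np.testing.assert_array_equal(b1["rt_min"],
                                      matrix.peak_meta["rt_min"].to_numpy(float))
        np.testing.assert_array_equal(b1["intensity"], mean_area.to_numpy(float))
        np.testing.assert_array_equal(b2["area"],
                                      mean_area.to_numpy(float)[
                                          np.argsort(matrix.peak_meta["rt_min"],
                                                     kind="stable")])

    def test_block2_sorted_by_rt(self, tmp_path, default_dataset):
        matrix, _, _ = default_dataset
        path = tmp_path / "legacy.txt"
        write_legacy_fingerprint(matrix, None, path)
        _, b2 = read_legacy_fingerprint(path)
        assert (np.diff(b2["rt_min"]) >= 0).all()

    def test_empty_matrix_writes_nothing(self, tmp_path):
        m = _matrix([[1.0], [2.0]])
        m.areas = m.areas.iloc[:, :0]
        m.peak_meta = m.peak_meta.iloc[:0]
        path = tmp_path / "legacy.txt"
        with pytest.raises(SpecfxError, match="empty"):
            write_legacy_fingerprint(m, None, path)
        assert not path.exists()

    def test_single_byte_encoding(self, tmp_path, default_dataset):
        matrix, _, _ = default_dataset
        path = tmp_path / "legacy.txt"
        write_legacy_fingerprint(matrix, None, path)
        raw = path.read_bytes()
        raw.decode("latin-1")  # must be single-byte decodable
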