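"""IO, detection filtering and TMT bridge normalization."""

import numpy as np
import pandas as pd
import pytest

from rerhythm.matrix import (
    AbundanceMatrix,
    bridge_normalize,
    filter_transcript_series,
    read_matrix,
    write_matrix,
)

from conftest import make_matrix


class TestIO:
    def test_round_trip_identity(self, toy_matrix, tmp_path):
        mp, sp = tmp_path / "m.tsv", tmp_path / "s.tsv"
        write_matrix(toy_matrix, mp, sp)
        back = read_matrix(mp, sp)
        pd.testing.assert_frame_equal(back.values, toy_matrix.values)
        assert list(back.samples.index) == list(toy_matrix.samples.index)

    def test_missing_metadata_sample_named(self, toy_matrix, tmp_path):
        mp, sp = tmp_path / "m.tsv", tmp_path / "s.tsv"
        write_matrix(toy_matrix, mp, sp)
        meta = pd.read_csv(sp, sep="\t")
        dropped = meta["sample_id"].iloc[3]
        meta.drop(index=3).to_csv(sp, sep="\t", index=False)
        with pytest.raises(ValueError, match=dropped):
            read_matrix(mp, sp)

    def test_non_numeric_cell_coordinates(self, toy_matrix, tmp_path):
        mp, sp = tmp_path / "m.tsv", tmp_path / "s.tsv"
        write_matrix(toy_matrix, mp, sp)
        lines = mp.read_text().splitlines()  # corrupt one data cell
        parts = lines[1].split("\t")
        parts[1] = "not_a_number"
        lines[1] = "\t".join(parts)
        mp.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="not_a_number|non-numeric"):
            read_matrix(mp, sp)

    def test_negative_values_rejected(self, grid8x3):
        with pytest.raises(ValueError, match="negative"):
            make_matrix(-np.ones((1, len(grid8x3))), grid8x3)


class TestFilter:
    def _matrix(self, rows, times):
        return make_matrix(np.asarray(rows, dtype=float), times)

    def test_boundary_rules(self):
        times = np.repeat(np.arange(0, 24, 3.0), 6)  # 48 samples
        total_49 = np.zeros(48)
        total_49[:48] = 49 / 48  # detected everywhere, total 49 -> dropped
        total_50_det_32 = np.zeros(48)
        total_50_det_32[:32] = 50 / 32  # total exactly 50, detected exactly 32 -> kept
        det_31 = np.zeros(48)
        det_31[:31] = 10  # total 310 but detected in 31 < 32 -> dropped
        m = self._matrix([total_49, total_50_det_32, det_31], times)
        kept, report = filter_transcript_series(m)
        assert list(kept.series_ids) == ["s1"]
        assert report.n_input == 3 and report.n_kept == 1
        assert report.n_dropped_low_abundance == 1
        assert report.n_dropped_low_detection == 1

    def test_fails_both_counted_once_as_low_abundance(self):
        times = np.repeat(np.arange(0, 24, 3.0), 6)
        weak = np.zeros(48)
        weak[:5] = 1.0  # total 5 (<50) and detected 5 (<32)
        m = self._matrix([weak], times)
        _, report = filter_transcript_series(m)
        assert report.n_dropped_low_abundance == 1
        assert report.n_dropped_low_detection == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        times = np.repeat(np.arange(0, 24, 3.0), 6)
        vals = rng.poisson(2.0, size=(500, 48)).astype(float)
        m = self._matrix(vals, times)
        kept, report = filter_transcript_series(m)
        expected = [
            i for i in range(500)
            if vals[i].sum() >= 50 and (vals[i] > 0).sum() >= 32
        ]
        assert list(kept.series_ids) == [f"s{i}" for i in expected]
        assert report.n_kept == len(expected)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        times = np.repeat(np.arange(0, 24, 3.0), 6)
        m = self._matrix(rng.poisson(3.0, size=(200, 48)).astype(float), times)
        once, _ = filter_transcript_series(m)
        twice, report = filter_transcript_series(once)
        assert report.n_kept == report.n_input
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_min_detected_above_sample_count_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="min_detected"):
            filter_transcript_series(toy_matrix, min_detected=100)


def _plex(values, bridge_cols, plex_id, times=None, tag=""):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    times = np.arange(n) % 8 * 3.0 if times is None else times
    m = make_matrix(values, times, compartment="TE", plex=plex_id)
    sample_ids = [f"p{plex_id}{tag}_{c}" for c in m.values.columns]
    vals = m.values.copy()
    vals.columns = sample_ids
    samples = m.samples.copy()
    samples.index = pd.Index(sample_ids, name="sample_id")
    samples["is_bridge"] = [i in bridge_cols for i in range(n)]
    return AbundanceMatrix(vals, samples)


class TestBridgeNormalize:
    def test_unit_bridges_leave_values_unchanged(self):
        vals = np.array([[2.0, 4.0, 1.0, 1.0], [3.0, 9.0, 1.0, 1.0]])
        plex = _plex(vals, bridge_cols=[2, 3], plex_id=0)
        out = bridge_normalize([plex])
        np.testing.assert_allclose(out.values.to_numpy(), vals[:, :2])

    def test_scaled_plex_outputs_equal(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(1, 10, size=(6, 6))
        a = _plex(base, bridge_cols=[4, 5], plex_id=0)
        b = _plex(base * 2.0, bridge_cols=[4, 5], plex_id=1, tag="b")
        out = bridge_normalize([a, b])
        block_a = out.values.iloc[:, :4].to_numpy()
        block_b = out.values.iloc[:, 4:].to_numpy()
        np.testing.assert_allclose(block_a, block_b)

    def test_plex_scaling_changes_output_only_by_series_factor(self):
        rng = np.random.default_rng(5)
        plexes = [
            _plex(rng.uniform(1, 10, size=(6, 6)), [4, 5], i, tag=f"t{i}")
            for i in range(3)
        ]
        ref = bridge_normalize(plexes).values
        scaled = [p if i != 1 else AbundanceMatrix(p.values * 7.0, p.samples)
                  for i, p in enumerate(plexes)]
        out = bridge_normalize(scaled).values
        ratio = (out / ref).to_numpy()
        # per-series constant factor: no column-to-column variation
        assert np.allclose(ratio, ratio[:, [0]])

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(6)
        plexes = [
            _plex(rng.uniform(0.5, 20, size=(8, 5)), [3, 4], i, tag=f"x{i}")
            for i in range(3)
        ]
        out = bridge_normalize(plexes)
        # independent per-series loop over the same definition
        for sid in out.series_ids:
            bmeans = []
            for p in plexes:
                is_b = p.samples["is_bridge"].to_numpy()
                bmeans.append(p.values.loc[sid, is_b].mean())
            anchor = np.mean(bmeans)
            for p, bm in zip(plexes, bmeans):
                is_b = p.samples["is_bridge"].to_numpy()
                for col in p.values.columns[~is_b]:
                    expected = p.values.loc[sid, col] / bm * anchor
                    assert out.values.loc[sid, col] == pytest.approx(expected)

    def test_zero_bridge_mean_series_dropped(self):
        vals = np.array([[2.0, 4.0, 1.0, 1.0], [3.0, 9.0, 0.0, 0.0]])
        plex = _plex(vals, bridge_cols=[2, 3], plex_id=0)
        out = bridge_normalize([plex])
        assert list(out.series_ids) == ["s0"]

    def test_plex_without_bridge_errors(self):
        plex = _plex(np.ones((2, 4)), bridge_cols=[], plex_id=0)
        with pytest.raises(ValueError, match="bridge"):
            bridge_normalize([plex])

    def test_concatenates_on_shared_series_sorted(self):
        a = _plex(np.ones((3, 4)) * 2, [2, 3], 0, tag="a")
        b = _plex(np.ones((2, 4)) * 3, [2, 3], 1, tag="b")
        b.values.index = pd.Index(["s2", "s0"], name="series_id")
        out = bridge_normalize([a, b])
        assert list(out.series_ids) == ["s0", "s2"]
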