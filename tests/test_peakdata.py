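"""Peak-list data model, I/O, tracking and residue-selection rules."""

import math
import warnings

import pytest

from titrakit import (
    Condition,
    Conformer,
    GroundTruth,
    Peak,
    PeakList,
    Site,
    TitrationSeries,
    filter_residues,
    gen_ph_series,
    read_peaklist,
    track_peaks,
    write_peaklist,
)
from titrakit.peakdata import PeakListError, parse_assignment


class TestParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Q62N-H", (62, "Q", Site.BACKBONE, Conformer.NAT)),
            ("K63*N-H", (63, "K", Site.BACKBONE, Conformer.ALT)),
            ("G47+N-H", (47, "G", Site.BACKBONE, Conformer.ADDITIONAL)),
            ("Q62NE2-HE21", (62, "Q", Site.SIDECHAIN_E21, Conformer.NAT)),
            ("Q62NE2-HE22", (62, "Q", Site.SIDECHAIN_E22, Conformer.NAT)),
            ("GLN62N-H", (62, "GLN", Site.BACKBONE, Conformer.NAT)),
        ],
    )
    def test_assignment_strings(self, text, expected):
        assert parse_assignment(text) == expected

    def test_sparky_row(self, tmp_path):
        p = tmp_path / "a.list"
        p.write_text(
            "      Assignment         w1         w2   Data Height\n"
            "         Q62N-H    121.300      8.950       1.0e6\n"
        )
        pl = read_peaklist(p, format="sparky", condition=Condition(pH=6.8))
        (peak,) = pl.peaks
        assert peak.residue_index == 62
        assert peak.site is Site.BACKBONE
        assert peak.conformer is Conformer.NAT
        assert peak.shift_H == pytest.approx(8.95)
        assert peak.shift_N == pytest.approx(121.3)
        assert peak.intensity == pytest.approx(1.0e6)

    def test_alt_conformer_suffix(self, tmp_path):
        p = tmp_path / "a.list"
        p.write_text("K63*N-H 120.1 8.2 5e5\n")
        pl = read_peaklist(p, format="sparky")
        assert pl.peaks[0].conformer is Conformer.ALT

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.list"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            pl = read_peaklist(p, format="sparky")
        assert len(pl) == 0

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.list"
        p.write_text("Q62N-H 121.3 8.95 1e6\nnot-an-assignment x y\n")
        with pytest.raises(PeakListError, match="bad.list:2"):
            read_peaklist(p, format="sparky")

    def test_duplicate_key_rejected(self):
        peaks = [
            Peak(62, "Q", Site.BACKBONE, Conformer.NAT, 8.9, 121.0, 1.0),
            Peak(62, "Q", Site.BACKBONE, Conformer.NAT, 8.8, 121.5, 2.0),
        ]
        with pytest.raises(PeakListError, match="duplicate"):
            PeakList(peaks)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "sparky"])
    def test_write_read_preserves_fields(self, tmp_path, fmt):
        peaks = [
            Peak(62, "Q", Site.BACKBONE, Conformer.NAT, 8.951, 121.302, 123456.0),
            Peak(63, "K", Site.BACKBONE, Conformer.ALT, 8.203, 120.117, 7.5e5),
            Peak(62, "Q", Site.SIDECHAIN_E21, Conformer.NAT, 6.801, 112.45, 9e4),
        ]
        cond = Condition(pH=6.8, temperature=296.15)
        pl = PeakList(peaks, cond, "fixture")
        path = tmp_path / f"out.{fmt}"
        write_peaklist(pl, path, format=fmt)
        back = read_peaklist(path, format=fmt, condition=cond)
        digits = 3 if fmt == "sparky" else 12  # sparky prints 3 decimals
        for orig, rt in zip(pl, back):
            assert rt.key == orig.key
            assert rt.shift_H == pytest.approx(orig.shift_H, abs=10**-digits)
            assert rt.shift_N == pytest.approx(orig.shift_N, abs=10**-digits)

    def test_csv_roundtrip_carries_condition(self, tmp_path):
        pl = PeakList(
            [Peak(5, "V", Site.BACKBONE, Conformer.NAT, 8.0, 120.0, 1.0)],
            Condition(pH=7.2, temperature=298.15, protein_total=5e-5),
        )
        path = tmp_path / "a.csv"
        write_peaklist(pl, path)
        back = read_peaklist(path, format="csv")
        assert back.condition.pH == 7.2
        assert back.condition.temperature == 298.15
        assert back.condition.protein_total == 5e-5


def _series_from_positions(positions, intensities=None):
    """Build a pH series from {pH: [(res, H, N)]} dicts."""
    points = []
    for pH, rows in sorted(positions.items()):
        peaks = [
            Peak(r, "A", Site.BACKBONE, Conformer.NAT, h, n,
                 1.0 if intensities is None else intensities[r])
            for r, h, n in rows
        ]
        points.append(PeakList(peaks, Condition(pH=pH)))
    return TitrationSeries(points, varying="pH")


class TestTracking:
    def test_stationary_peaks_zero_displacement(self):
        rows = [(1, 8.0, 120.0), (2, 9.0, 125.0)]
        series = _series_from_positions({5.0: rows, 6.0: rows, 7.0: rows})
        trajs = track_peaks(series, max_jump=0.05)
        assert len(trajs) == 2
        for t in trajs.values():
            assert t.complete and len(t.points) == 3
            assert t.points[0].shift_H == t.points[-1].shift_H

    def test_linear_drift_fully_linked(self):
        # 0.01 ppm/step 1H drift, well under max_jump 0.05
        series = _series_from_positions(
            {5.0 + i: [(1, 8.0 + 0.01 * i, 120.0)] for i in range(5)}
        )
        trajs = track_peaks(series, max_jump=0.05, by_assignment=False)
        (t,) = trajs.values()
        assert t.complete and len(t.points) == 5

    def test_crossing_peaks_flagged_ambiguous(self):
        # two peaks converge to the same position: candidate distances tie
        series = _series_from_positions(
            {
                5.0: [(1, 8.00, 120.0), (2, 8.02, 120.0)],
                6.0: [(1, 8.01, 120.0), (2, 8.01, 120.0)],
            }
        )
        trajs = track_peaks(series, max_jump=0.05, by_assignment=False)
        assert all(not t.complete and t.ambiguous_at for t in trajs.values())

    def test_jump_beyond_max_refused(self):
        series = _series_from_positions(
            {5.0: [(1, 8.0, 120.0)], 6.0: [(1, 8.5, 120.0)]}
        )
        trajs = track_peaks(series, max_jump=0.05)
        (t,) = trajs.values()
        assert not t.complete and len(t.points) == 1

    def test_generator_ground_truth_recovered_without_mislinks(self):
        # noise sigma far below max_jump/5: every trajectory must follow its peak
        truth = GroundTruth(seed=3, sigma_H=0.0005, sigma_N=0.003)
        series = gen_ph_series(truth)
        trajs = track_peaks(series, max_jump=0.2)
        layout = truth.layout()
        for key, traj in trajs.items():
            if key[2] is not Conformer.NAT or not traj.complete:
                continue
            lay = layout[key[0]]
            th = truth.theta(7.6, key[0])
            expected_H = lay["base_H"] + th * lay["dd_limit"] * lay["dir"][0]
            assert traj.points[-1].shift_H == pytest.approx(expected_H, abs=0.005)


class TestFilterResidues:
    def test_all_clean_all_retained(self, ph_series_clean, truth):
        retained, excluded = filter_residues(ph_series_clean, require_alt=True, max_jump=0.2)
        assert retained == set(truth.residues)
        assert excluded == {}

    def test_overlapping_pair_both_excluded(self):
        truth = GroundTruth(seed=2, overlap_pairs=[(22, 23)])
        series = gen_ph_series(truth, noise=False)
        retained, excluded = filter_residues(series, max_jump=0.2)
        assert excluded.get(22) == "overlap"
        assert excluded.get(23) == "overlap"
        assert 22 not in retained and 23 not in retained

    def test_planted_design_retains_expected_27_of_40(self):
        # 40 residues; 13 removed: 2x2 overlaps, 4 lost signals, 5 without alt peaks
        residues = list(range(2, 42))
        truth = GroundTruth(
            seed=4,
            residues=residues,
            overlap_pairs=[(5, 9), (14, 20)],
            lost_residues=frozenset({11, 25, 31, 40}),
            no_alt_residues=frozenset({3, 17, 28, 33, 38}),
        )
        series = gen_ph_series(truth, noise=False)
        retained, excluded = filter_residues(series, require_alt=True, max_jump=0.2)
        assert len(excluded) == 13
        assert len(retained) == 27
        assert {5, 9, 14, 20} <= {r for r, why in excluded.items() if why == "overlap"}
        assert all(excluded[r] == "lost-signal" for r in (11, 25, 31, 40))
        assert all(excluded[r] == "no-alt-signal" for r in (3, 17, 28, 33, 38))

    def test_idempotent(self, ph_series_clean):
        first = filter_residues(ph_series_clean, require_alt=True, max_jump=0.2)
        second = filter_residues(ph_series_clean, require_alt=True, max_jump=0.2)
        assert first == second


class TestInvariants:
    def test_series_requires_monotone_condition(self):
        rows = [(1, 8.0, 120.0)]
        points = [
            PeakList([Peak(1, "A", Site.BACKBONE, Conformer.NAT, 8.0, 120.0, 1.0)],
                     Condition(pH=p))
            for p in (5.0, 7.0, 6.0)
        ]
        with pytest.raises(ValueError, match="monotone"):
            TitrationSeries(points, varying="pH")

    def test_peak_outside_amide_window_warns(self):
        with pytest.warns(UserWarning, match="amide region"):
            Peak(1, "A", Site.BACKBONE, Conformer.NAT, 3.0, 120.0, 1.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            Peak(1, "A", Site.BACKBONE, Conformer.NAT, 8.0, 120.0, -1.0)
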