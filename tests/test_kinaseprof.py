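import numpy as np
import pandas as pd
import pytest

from phenocopy.kinaseprof import (
    KinaseEvidence,
    coverage_summary,
    read_panel,
    read_surrogate_map,
    select_off_target_kinases,
    surrogate_overlay,
    write_panel,
    write_surrogate_map,
)
from phenocopy.simdata import generate_kinase_panel


def panel_of(rows):
    return pd.DataFrame(
        rows, columns=["kinase_id", "compound_id", "inhibition_2uM", "inhibition_200nM"]
    )


class TestSelectionRule:
    @pytest.mark.parametrize(
        "i2,i02,selected",
        [
            (95.0, 60.0, True),
            (95.0, 40.0, False),
            (90.0, 50.0, True),  # boundaries inclusive: "at least"
            (89.9, 99.0, False),
            (100.0, 49.9, False),
            (-20.0, 60.0, False),  # apparent activation fails the 2 uM cut
        ],
    )
    def test_thresholds(self, i2, i02, selected):
        panel = panel_of([("K1", "C", i2, i02)])
        got = select_off_target_kinases(panel, "C")
        assert (got == ["K1"]) is selected

    def test_missing_compound_rejected(self):
        panel = panel_of([("K1", "C", 95.0, 60.0)])
        with pytest.raises(ValueError, match="XX"):
            select_off_target_kinases(panel, "XX")

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"K{i}", "C", float(rng.uniform(-50, 110)), float(rng.uniform(-50, 110)))
            for i in range(200)
        ]
        panel = panel_of(rows)
        expected = sorted(k for k, _, a, b in rows if a >= 90 and b >= 50)
        assert select_off_target_kinases(panel, "C") == expected

    def test_idempotent_and_order_independent(self):
        rows = [("K2", "C", 95.0, 60.0), ("K1", "C", 91.0, 51.0), ("K3", "C", 10.0, 0.0)]
        a = select_off_target_kinases(panel_of(rows), "C")
        b = select_off_target_kinases(panel_of(rows[::-1]), "C")
        assert a == b == ["K1", "K2"]


class TestPlantedPanel:
    def test_selection_recovers_planted_hits_exactly(self):
        compounds = ["BI1", "Ex1"]
        panel, _, truth = generate_kinase_panel(
            50, compounds, {"BI1": 7, "Ex1": ["K01", "K02"]}, seed=4
        )
        for c in compounds:
            assert set(select_off_target_kinases(panel, c)) == set(truth[c])

    def test_zero_redundancy_markers_unique(self):
        _, surrogate, _ = generate_kinase_panel(
            30, ["C"], {"C": 3}, seed=1, markers_per_kinase=(1, 4), redundancy=0.0
        )
        seen = {}
        for kin, markers in surrogate.items():
            for m in markers:
                assert m not in seen, f"marker {m} shared by {kin} and {seen[m]}"
                seen[m] = kin

    def test_reproducible_under_seed(self):
        a = generate_kinase_panel(30, ["C"], {"C": 5}, seed=9)
        b = generate_kinase_panel(30, ["C"], {"C": 5}, seed=9)
        assert a[0].equals(b[0]) and a[1] == b[1] and a[2] == b[2]

    def test_overplanting_rejected(self):
        with pytest.raises(ValueError, match="plant"):
            generate_kinase_panel(5, ["C"], {"C": 9}, seed=0)


class TestOverlay:
    MAP = {
        "K1": frozenset({"M1", "M2", "M3", "M4"}),
        "K2": frozenset({"M4", "M9"}),
        "K3": frozenset(),
    }

    def test_marker_counting(self):
        evidence = surrogate_overlay(["K1"], self.MAP, {"M1", "M3", "ZZZ"})
        (ev,) = evidence
        assert ev.n_markers == 4 and ev.n_markers_regulated == 2
        assert ev.regulated_marker_ids == ("M1", "M3")
        assert not ev.ambiguous

    def test_shared_regulated_marker_flags_both(self):
        evidence = surrogate_overlay(["K1", "K2"], self.MAP, {"M4"})
        by_id = {ev.kinase_id: ev for ev in evidence}
        assert by_id["K1"].ambiguous and by_id["K2"].ambiguous

    def test_kinase_without_markers_reported(self):
        evidence = surrogate_overlay(["K3"], self.MAP, {"M1"})
        assert evidence[0].n_markers == 0 and not evidence[0].ambiguous

    def test_unexpressed_kinase_dropped(self):
        evidence = surrogate_overlay(["K1", "K2"], self.MAP, {"M4"}, expressed_kinases={"K1"})
        assert [ev.kinase_id for ev in evidence] == ["K1"]
        assert not evidence[0].ambiguous  # K2 no longer competes for M4


class TestCoverage:
    def _evidence(self, markers):
        return [
            KinaseEvidence("K1", True, len(markers), 0, (), False, tuple(markers))
        ]

    def test_printed_ratio_arithmetic(self):
        markers = [f"M{i}" for i in range(366)]
        regulated = set(markers[:84])
        summary = coverage_summary(self._evidence(markers), regulated)
        assert summary == {
            "n_markers_total": 366,
            "n_markers_regulated": 84,
            "pct_regulated": 22.9,
        }

    def test_no_markers_gives_null_percentage(self):
        summary = coverage_summary(self._evidence([]), {"M1"})
        assert summary["pct_regulated"] is None

    def test_full_coverage(self):
        markers = ["M1", "M2"]
        summary = coverage_summary(self._evidence(markers), set(markers))
        assert summary["pct_regulated"] == 100.0

    def test_distinct_markers_across_kinases(self):
        evidence = [
            KinaseEvidence("K1", True, 2, 0, (), False, ("M1", "M2")),
            KinaseEvidence("K2", True, 2, 0, (), False, ("M2", "M3")),
        ]
        summary = coverage_summary(evidence, {"M2"})
        assert summary["n_markers_total"] == 3
        assert summary["n_markers_regulated"] == 1
        assert summary["pct_regulated"] == 33.3


class TestPanelIO:
    def test_round_trip(self, tmp_path):
        panel, surrogate, _ = generate_kinase_panel(
            10, ["C"], {"C": 2}, seed=2, markers_per_kinase=(0, 3)
        )
        write_panel(panel, tmp_path / "p.csv")
        write_surrogate_map(surrogate, tmp_path / "m.tsv")
        assert read_panel(tmp_path / "p.csv").equals(panel)
        assert read_surrogate_map(tmp_path / "m.tsv") == surrogate

    def test_out_of_range_inhibition_rejected(self, tmp_path):
        panel = panel_of([("K1", "C", 150.0, 60.0)])
        write_panel(panel, tmp_path / "p.csv")
        with pytest.raises(ValueError, match="inhibition_2uM"):
            read_panel(tmp_path / "p.csv")

    def test_duplicate_records_rejected(self, tmp_path):
        panel = panel_of([("K1", "C", 95.0, 60.0), ("K1", "C", 90.0, 50.0)])
        write_panel(panel, tmp_path / "p.csv")
        with pytest.raises(ValueError, match="duplicate"):
            read_panel(tmp_path / "p.csv")
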