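"""Gating, autofluorescence-corrected MFI, fold change, floater counts."""

import numpy as np
import pandas as pd
import pytest

from spheromet import (
    GateConfig,
    MarkerResult,
    corrected_mfi,
    count_floaters,
    fold_change,
    gate_events,
    generate_cytometry_events,
)


@pytest.fixture(scope="module")
def grid():
    table, gt = generate_cytometry_events(
        10_000, 500.0, 300.0, dapi_positive_fraction=0.05,
        doublet_fraction=0.1, seed=42)
    return table, gt


def _cond(table, stained, treatment):
    return table[(table.stained == stained) & (table.treatment == treatment)]


class TestGating:
    def test_singlet_gate_removes_exactly_flagged_doublets(self, grid):
        table, gt = grid
        sub = _cond(table, True, "plasma").reset_index(drop=True)
        flags = _cond(gt.event_flags, True, "plasma").reset_index(drop=True)
        gated, counts = gate_events(sub)
        assert counts["input"] - counts["singlets"] == flags.doublet.sum() == 1000

    def test_dapi_negative_fraction(self, grid):
        table, _ = grid
        gated, counts = gate_events(_cond(table, True, "untreated"))
        frac = counts["dapi_negative"] / counts["singlets"]
        # 5% DAPI+ by construction; allow binomial tolerance
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_permissive_gate_is_identity(self):
        table, _ = generate_cytometry_events(500, 500.0, 0.0,
                                             dapi_positive_fraction=0.0,
                                             doublet_fraction=0.0, seed=1)
        sub = _cond(table, False, "untreated")
        gated, _ = gate_events(sub)
        assert gated.equals(sub)

    def test_gate_order_invariance(self, grid):
        """Singlet and DAPI gates act on independent annotations: applying
        them in either order selects the same event set."""
        table, _ = grid
        sub = _cond(table, True, "plasma")
        cfg = GateConfig()
        lo, hi = cfg.singlet_band
        ratio = sub["fsc_h"] / sub["fsc_a"]
        singlet_then_dapi = sub[(ratio >= lo) & (ratio <= hi)]
        singlet_then_dapi = singlet_then_dapi[
            singlet_then_dapi["dapi"] <= cfg.dapi_cutoff]
        dapi_then_singlet = sub[sub["dapi"] <= cfg.dapi_cutoff]
        r2 = dapi_then_singlet["fsc_h"] / dapi_then_singlet["fsc_a"]
        dapi_then_singlet = dapi_then_singlet[(r2 >= lo) & (r2 <= hi)]
        assert singlet_then_dapi.index.equals(dapi_then_singlet.index)

    def test_missing_channel_named(self):
        with pytest.raises(ValueError, match="ssc_a"):
            gate_events(pd.DataFrame({"fsc_a": [1.0], "fsc_h": [1.0],
                                      "dapi": [1.0]}))


class TestCorrectedMfi:
    def test_recovers_stain_mfi(self, grid):
        table, _ = grid
        for treatment in ("untreated", "plasma"):
            g_s, _ = gate_events(_cond(table, True, treatment))
            g_u, _ = gate_events(_cond(table, False, treatment))
            res = corrected_mfi(g_s, g_u, "pecy7")
            se = np.sqrt(g_s["pecy7"].var() / len(g_s)
                         + g_u["pecy7"].var() / len(g_u))
            assert abs(res.corrected_mfi - 500.0) < 3 * se

    def test_zero_stain_corrects_to_zero(self):
        table, _ = generate_cytometry_events(10_000, 0.0, 300.0, seed=2)
        g_s, _ = gate_events(_cond(table, True, "plasma"))
        g_u, _ = gate_events(_cond(table, False, "plasma"))
        res = corrected_mfi(g_s, g_u, "pecy7")
        se = np.sqrt(g_s["pecy7"].var() / len(g_s)
                     + g_u["pecy7"].var() / len(g_u))
        assert abs(res.corrected_mfi) < 3 * se

    def test_treatment_mismatch_rejected(self, grid):
        table, _ = grid
        g_s, _ = gate_events(_cond(table, True, "plasma"))
        g_u, _ = gate_events(_cond(table, False, "untreated"))
        with pytest.raises(ValueError, match="treatment"):
            corrected_mfi(g_s, g_u, "pecy7")

    def test_negative_corrected_reported_as_is(self):
        s = pd.DataFrame({"pecy7": [100.0, 120.0], "treatment": ["t", "t"]})
        u = pd.DataFrame({"pecy7": [300.0, 320.0], "treatment": ["t", "t"]})
        res = corrected_mfi(s, u, "pecy7")
        assert res.corrected_mfi == pytest.approx(-200.0)

    def test_geometric_mode(self):
        s = pd.DataFrame({"pecy7": [100.0, 400.0], "treatment": ["t", "t"]})
        u = pd.DataFrame({"pecy7": [50.0, 200.0], "treatment": ["t", "t"]})
        res = corrected_mfi(s, u, "pecy7", geometric=True)
        assert res.corrected_mfi == pytest.approx(200.0 - 100.0)


class TestFoldChange:
    def _res(self, corrected, marker="pecy7", treatment="x"):
        return MarkerResult(marker=marker, treatment=treatment,
                            mfi_stained=0.0, mfi_unstained_matched=0.0,
                            corrected_mfi=corrected)

    def test_self_ratio_is_one(self):
        fc = fold_change(self._res(500.0), self._res(500.0))
        assert fc.fold_change_vs_control == pytest.approx(1.0)

    def test_zero_treated_gives_zero(self):
        fc = fold_change(self._res(0.0), self._res(500.0))
        assert fc.fold_change_vs_control == 0.0

    def test_non_positive_control_missing(self):
        fc = fold_change(self._res(500.0), self._res(-10.0))
        assert fc.fold_change_vs_control is None

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValueError, match="marker"):
            fold_change(self._res(1.0, marker="pe"), self._res(1.0))

    def test_simulated_two_fold_upregulation(self):
        control_tab, _ = generate_cytometry_events(10_000, 500.0, 300.0, seed=3)
        treated_tab, _ = generate_cytometry_events(10_000, 1000.0, 300.0, seed=4)
        g = {}
        for name, tab, tr in (("cs", control_tab, "untreated"),
                              ("cu", control_tab, "untreated"),
                              ("ts", treated_tab, "plasma"),
                              ("tu", treated_tab, "plasma")):
            stained = name.endswith("s")
            g[name], _ = gate_events(_cond(tab, stained, tr))
        res_c = corrected_mfi(g["cs"], g["cu"], "pecy7")
        res_t = corrected_mfi(g["ts"], g["tu"], "pecy7")
        fc = fold_change(res_t, res_c)
        assert fc.fold_change_vs_control == pytest.approx(2.0, rel=0.05)


class TestFloaters:
    def test_constructed_counts_exact(self):
        table, _ = generate_cytometry_events(
            500, 500.0, 300.0, dapi_positive_fraction=0.8,
            doublet_fraction=0.0, seed=5)
        sub = _cond(table, False, "untreated")
        assert count_floaters(sub, 1000.0) == 400

    def test_empty_table(self):
        assert count_floaters(pd.DataFrame({"dapi": []}), 1000.0) == 0

    def test_monotone_in_cutoff(self):
        table, _ = generate_cytometry_events(300, 500.0, 300.0,
                                             dapi_positive_fraction=0.5, seed=6)
        sub = _cond(table, True, "plasma")
        counts = [count_floaters(sub, c) for c in (-1.0, 600.0, 1500.0, 1e5)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] == len(sub)  # cutoff below all debris
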