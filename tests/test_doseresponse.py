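"""Dose-response fits, band-intensity conversion, background correction,
ABP competition arithmetic."""

import numpy as np
import pandas as pd
import pytest

import slowbind as sb
from slowbind.doseresponse import BandTable, abp_inhibition_table


def logistic_table(ic50=2.7, hill=1.0, top=100.0, bottom=0.0,
                   x=(0.0, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        r = np.where(x > 0, (x / ic50) ** hill, 0.0)
    y = bottom + (top - bottom) / (1 + r)
    return sb.DoseResponseTable(x, y)


class TestFitIc50:
    def test_exact_recovery(self):
        fit = sb.fit_ic50(logistic_table())
        assert fit.flag is None
        assert fit.ic50 == pytest.approx(2.7, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_scale_invariance(self):
        t1 = logistic_table()
        t2 = sb.DoseResponseTable(t1.concentration, 7.3 * t1.response)
        f1, f2 = sb.fit_ic50(t1), sb.fit_ic50(t2)
        assert f1.ic50 == pytest.approx(f2.ic50, rel=1e-8)
        assert f1.hill == pytest.approx(f2.hill, rel=1e-8)

    def test_all_at_top_flagged_above_range(self):
        x = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0])
        fit = sb.fit_ic50(sb.DoseResponseTable(x, np.full(6, 100.0)), fix_top=100.0)
        assert fit.flag == "above_range"
        assert fit.ic50 is None

    def test_all_at_bottom_flagged_below_range(self):
        x = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0])
        y = np.array([2.0, 1.5, 1.8, 1.2, 1.9, 1.4])
        fit = sb.fit_ic50(sb.DoseResponseTable(x, y), fix_top=100.0)
        assert fit.flag == "below_range"

    def test_steady_state_noncompetitive_ic50_equals_Ki(self, scheme11):
        I = np.array([0.0, 5.0, 15.0, 45.0, 135.0, 405.0, 1215.0])
        v = np.array([sb.steady_rate(scheme11, 10.0, i, 1.0) for i in I])
        table = sb.DoseResponseTable(I, 100.0 * v / v[0])
        fit = sb.fit_ic50(table)
        assert fit.ic50 == pytest.approx(scheme11.Ki, rel=0.02)

    def test_needs_five_concentrations(self):
        with pytest.raises(ValueError):
            sb.fit_ic50(sb.DoseResponseTable(np.array([0.0, 1, 10, 100]),
                                             np.array([100.0, 80, 30, 5])))

    def test_preincubation_moves_apparent_ic50_toward_steady_state(self, scheme11):
        """Slow binding: with short incubation the apparent IC50 overshoots
        the steady-state value and decreases with preincubation time."""
        I = np.array([0.0, 5.0, 15.0, 45.0, 135.0, 405.0, 1215.0, 3645.0])
        t_grid = np.arange(0.0, 61.0, 1.0)
        ic50s = []
        for pre in (0.0, 60.0, 600.0):
            design = sb.AssayDesign(E0=1.0, S0=10.0, I_grid=tuple(I),
                                    t_grid=t_grid, preincubation_min=pre)
            resp = []
            for i in I:
                c = sb.ode_curve(scheme11, design, i)
                resp.append(c.signal_au[-1] - c.signal_au[0])
            resp = 100.0 * np.array(resp) / resp[0]
            ic50s.append(sb.fit_ic50(sb.DoseResponseTable(I, resp)).ic50)
        steady = sb.ic50_from_scheme(scheme11, 10.0)
        assert ic50s[0] > ic50s[1] > ic50s[2]
        assert ic50s[2] >= steady * 0.95


def band_df(rows):
    return pd.DataFrame(rows, columns=["condition", "inhibitor",
                                       "substrate_au", "product_au"])


class TestBands:
    def test_conversion_and_vehicle_normalization(self):
        # uninhibited conversion 75%, series {75, 60, 30, 10, 2}%
        rows = [("DMSO", 0.0, 25.0, 75.0), ("c1", 10.0, 40.0, 60.0),
                ("c2", 30.0, 70.0, 30.0), ("c3", 100.0, 90.0, 10.0),
                ("c4", 300.0, 98.0, 2.0)]
        table = sb.conversion_from_bands(BandTable(band_df(rows)))
        assert np.allclose(table.response, [100.0, 80.0, 40.0, 40 / 3, 8 / 3],
                           rtol=1e-12)

    def test_equal_bands_half_conversion(self):
        rows = [("DMSO", 0.0, 50.0, 50.0)]
        t = sb.conversion_from_bands(BandTable(band_df(rows)))
        assert t.provenance["vehicle_conversion"] == pytest.approx(0.5)

    def test_zero_product_zero_conversion(self):
        rows = [("DMSO", 0.0, 25.0, 75.0), ("c", 100.0, 50.0, 0.0)]
        t = sb.conversion_from_bands(BandTable(band_df(rows)))
        assert t.response[1] == 0.0

    def test_zero_total_lane_excluded(self):
        rows = [("DMSO", 0.0, 25.0, 75.0), ("dead", 10.0, 0.0, 0.0)]
        with pytest.warns(UserWarning, match="zero-intensity"):
            t = sb.conversion_from_bands(BandTable(band_df(rows)))
        assert t.concentration.size == 1

    def test_background_correction(self):
        obs = BandTable(band_df([("a", 0.0, 10.0, 100.0), ("b", 10.0, 10.0, 25.0)]))
        ko = BandTable(band_df([("a", 0.0, 10.0, 30.0), ("b", 10.0, 10.0, 40.0)]))
        with pytest.warns(UserWarning, match="clamped"):
            corr = sb.correct_background(obs, ko)
        assert corr.lanes["product_au"].tolist() == [70.0, 0.0]
        assert corr.log[0]["background"] == 30.0

    def test_background_zero_is_identity(self):
        obs = BandTable(band_df([("a", 0.0, 10.0, 100.0)]))
        ko = BandTable(band_df([("a", 0.0, 10.0, 0.0)]))
        corr = sb.correct_background(obs, ko)
        assert corr.lanes["product_au"].tolist() == [100.0]

    def test_unmatched_lanes_error(self):
        obs = BandTable(band_df([("a", 5.0, 10.0, 100.0)]))
        ko = BandTable(band_df([("a", 0.0, 10.0, 30.0)]))
        with pytest.raises(ValueError, match="5.0"):
            sb.correct_background(obs, ko)


class TestAbp:
    @pytest.mark.parametrize("band,expected", [(100.0, 0.0), (0.0, 100.0), (25.0, 75.0)])
    def test_percent_inhibition(self, band, expected):
        assert sb.abp_percent_inhibition(band, 100.0) == expected

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            sb.abp_percent_inhibition(10.0, 0.0)

    def test_matrix_form(self):
        df = pd.DataFrame({
            "compound": ["9", "9", "10", "10"],
            "concentration": [0.5, 0.5, 0.5, 0.5],
            "enzyme": ["GlpG", "AarA", "GlpG", "AarA"],
            "band_au": [5.0, 10.0, 2.0, 60.0],
            "dmso_au": [100.0, 100.0, 100.0, 100.0],
        })
        mat = abp_inhibition_table(df)
        assert mat.loc[("9", 0.5), "GlpG"] == 95.0
        assert mat.loc[("10", 0.5), "AarA"] == 40.0
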