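"""Standard curves, ChIP-qPCR enrichment, ddCt, beta-gal, pigment, folds."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hetprofile.assay_quant import (
    StandardCurve,
    beta_gal_activity,
    beta_gal_summary,
    chip_qpcr_enrichment,
    ddct_expression,
    fit_input_standard_curve,
    genotype_fold_changes,
    pigment_summary,
)
from hetprofile.errors import DataError, FailedCurveError


def _input_wells(fracs, cts, locus="tgt"):
    return pd.DataFrame(
        {
            "locus": locus,
            "role": "input_dilution",
            "dilution_fraction": fracs,
            "ct": cts,
            "replicate": range(1, len(fracs) + 1),
        }
    )


def _ip_wells(cts, locus="tgt"):
    return pd.DataFrame(
        {
            "locus": locus,
            "role": "ip",
            "dilution_fraction": np.nan,
            "ct": cts,
            "replicate": range(1, len(cts) + 1),
        }
    )


class TestStandardCurve:
    def test_perfect_ten_fold_series(self):
        curve = fit_input_standard_curve(
            _input_wells([1.0, 0.1, 0.01], [10.0, 13.3219, 16.6439])
        )
        assert curve.slope == pytest.approx(-3.3219, abs=1e-3)
        assert curve.base == pytest.approx(2.000, abs=1e-3)
        assert curve.efficiency == pytest.approx(1.0, abs=2e-3)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_fold_steps_give_same_slope_on_log10_axis(self):
        fracs = [1.0, 0.5, 0.25, 0.125]
        cts = [10.0, 11.0, 12.0, 13.0]  # one cycle per halving
        curve = fit_input_standard_curve(_input_wells(fracs, cts))
        assert curve.slope == pytest.approx(-1 / math.log10(2), abs=1e-9)

    def test_requires_three_distinct_dilutions(self):
        with pytest.raises(DataError, match=">=3 distinct"):
            fit_input_standard_curve(_input_wells([1.0, 0.1], [10.0, 13.3]))

    def test_non_negative_slope_flags_failed_curve(self):
        with pytest.raises(FailedCurveError):
            fit_input_standard_curve(_input_wells([1.0, 0.1, 0.01], [16.0, 13.0, 10.0]))

    def test_noisy_fits_match_closed_form_ols_oracle(self, rng):
        """Fitted slope/intercept equal the normal-equation solution."""
        fracs = np.array([1.0, 0.1, 0.01, 0.001])
        x = np.log10(fracs)
        for _ in range(100):
            ct = 12.0 - 3.3 * x + rng.normal(0, 0.15, 4)
            curve = fit_input_standard_curve(_input_wells(fracs, ct))
            sxx = ((x - x.mean()) ** 2).sum()
            slope = (((x - x.mean()) * (ct - ct.mean())).sum()) / sxx
            assert curve.slope == pytest.approx(slope, abs=1e-9)
            assert curve.intercept == pytest.approx(ct.mean() - slope * x.mean(), abs=1e-9)

    @pytest.mark.parametrize("frac", [1.0, 0.37, 0.01, 1e-4])
    def test_curve_inversion_round_trip(self, frac):
        curve = StandardCurve("tgt", -3.1, 12.0, 1.0, (10.0, 25.0))
        assert curve.efficacy_at(curve.ct_at(frac)) == pytest.approx(frac, rel=1e-9)


class TestEnrichment:
    def _curve(self, locus="tgt"):
        # perfect-efficiency curve: ct = 14 + (-1/log10 2) * log10(f)
        slope = -1 / math.log10(2)
        return StandardCurve(locus, slope, 14.0, 1.0, (14.0, 14.0 - slope * 3))

    def test_ip_ct_at_knot_returns_that_input_fraction(self):
        curve = self._curve()
        assert curve.efficacy_at(curve.ct_at(0.01)) == pytest.approx(0.01, rel=1e-9)

    def test_relative_enrichment_is_efficacy_ratio(self):
        ct_t = self._curve("tgt").ct_at(0.02)
        ct_c = self._curve("ctl").ct_at(0.01)
        res = chip_qpcr_enrichment(
            _ip_wells([ct_t], "tgt"),
            self._curve("tgt"),
            self._curve("ctl"),
            _ip_wells([ct_c], "ctl"),
        )
        assert res.relative_enrichment == pytest.approx(2.0, rel=1e-9)
        assert res.pulldown_efficacy == pytest.approx(0.02, rel=1e-9)

    def test_control_against_itself_is_exactly_one(self):
        curve = self._curve("ctl")
        wells = _ip_wells([curve.ct_at(0.01)] * 3, "ctl")
        res = chip_qpcr_enrichment(wells, curve, curve, wells)
        assert res.relative_enrichment == 1.0

    def test_out_of_range_ip_ct_flagged(self):
        curve = self._curve()
        res = chip_qpcr_enrichment(
            _ip_wells([40.0], "tgt"), curve, self._curve("ctl"),
            _ip_wells([curve.ct_at(0.01)], "ctl"),
        )
        assert res.out_of_range


class TestDdct:
    def _wells(self, rows):
        return pd.DataFrame(rows, columns=["sample", "locus", "ct", "replicate"])

    def test_reference_sample_fold_is_exactly_one(self):
        wells = self._wells(
            [
                ("ref", "piwi", 20.0, 1), ("ref", "RPL32", 15.0, 1),
                ("kd", "piwi", 21.0, 1), ("kd", "RPL32", 15.0, 1),
            ]
        )
        res = ddct_expression(wells, "piwi", "RPL32", "ref")
        assert res.fold("ref") == 1.0

    def test_one_extra_cycle_halves_expression(self):
        wells = self._wells(
            [
                ("ref", "piwi", 20.0, 1), ("ref", "RPL32", 15.0, 1),
                ("kd", "piwi", 21.0, 1), ("kd", "RPL32", 15.0, 1),
            ]
        )
        res = ddct_expression(wells, "piwi", "RPL32", "ref")
        assert res.fold("kd") == pytest.approx(0.5, abs=1e-12)

    def test_random_tables_match_power_formula_oracle(self, rng):
        rows = []
        truth = {}
        samples = [f"s{i}" for i in range(8)]
        dcts = {}
        for s in samples:
            ct_ctl = rng.uniform(14, 18)
            dct = rng.uniform(2, 8)
            rows += [(s, "tgt", ct_ctl + dct, 1), (s, "ctl", ct_ctl, 1)]
            dcts[s] = dct
        res = ddct_expression(self._wells(rows), "tgt", "ctl", "s0")
        for s in samples[1:]:
            expected = 2.0 ** (-(dcts[s] - dcts["s0"]))
            assert res.fold(s) == pytest.approx(expected, rel=1e-9)

    @given(shift=st.floats(-5, 5))
    def test_fold_invariant_under_common_ct_shift(self, shift):
        """Shifting both loci of one sample by a constant leaves fold alone."""
        base = [
            ("ref", "tgt", 20.0, 1), ("ref", "ctl", 15.0, 1),
            ("kd", "tgt", 22.0, 1), ("kd", "ctl", 15.5, 1),
        ]
        shifted = [
            (s, l, ct + (shift if s == "kd" else 0.0), r) for s, l, ct, r in base
        ]
        f0 = ddct_expression(self._wells(base), "tgt", "ctl", "ref").fold("kd")
        f1 = ddct_expression(self._wells(shifted), "tgt", "ctl", "ref").fold("kd")
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_missing_control_locus_rejected(self):
        wells = self._wells([("ref", "tgt", 20.0, 1)])
        with pytest.raises(DataError, match="missing"):
            ddct_expression(wells, "tgt", "ctl", "ref")


class TestBetaGal:
    def _series(self, times, ods):
        return pd.DataFrame({"time_min": times, "od574": ods})

    def test_exact_line_gives_one_six_hundredth(self):
        res = beta_gal_activity(self._series([0, 60, 120], [0.1, 0.2, 0.3]))
        assert res.activity == pytest.approx(1 / 600, rel=1e-9)
        assert not res.clamped

    def test_flat_series_gives_zero(self):
        res = beta_gal_activity(self._series([0, 60, 120], [0.2, 0.2, 0.2]))
        assert res.activity == pytest.approx(0.0, abs=1e-15)

    def test_negative_slope_clamped_and_flagged(self):
        res = beta_gal_activity(self._series([0, 60, 120], [0.3, 0.2, 0.1]))
        assert res.activity == 0.0
        assert res.clamped

    def test_degenerate_time_vector_rejected(self):
        with pytest.raises(DataError, match="time"):
            beta_gal_activity(self._series([10, 10, 10], [0.1, 0.2, 0.3]))

    def test_noisy_series_matches_closed_form_ols(self, rng):
        t = np.arange(0, 121, 15.0)
        od = 0.05 + 2e-3 * t + rng.normal(0, 0.01, len(t))
        res = beta_gal_activity(self._series(t, od))
        sxx = ((t - t.mean()) ** 2).sum()
        slope = ((t - t.mean()) * (od - od.mean())).sum() / sxx
        assert res.activity == pytest.approx(slope, abs=1e-12)

    @given(t0=st.floats(-100, 100), scale=st.floats(0.1, 10))
    def test_time_shift_invariance_and_od_scaling(self, t0, scale):
        t = np.array([0.0, 60.0, 120.0])
        od = np.array([0.1, 0.25, 0.4])
        base = beta_gal_activity(self._series(t, od)).activity
        shifted = beta_gal_activity(self._series(t + t0, od)).activity
        scaled = beta_gal_activity(self._series(t, od * scale)).activity
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9)

    def test_od_ceiling_restricts_linear_range(self):
        t = [0, 30, 60, 90, 120]
        od = [0.1, 0.6, 1.1, 1.6, 1.6]  # saturates past 1.5
        full = beta_gal_activity(self._series(t, od))
        trimmed = beta_gal_activity(self._series(t, od), od_ceiling=1.5)
        assert trimmed.n_points == 3
        assert trimmed.activity > full.activity


class TestPigmentAndFolds:
    def test_constant_class_mean_and_zero_sem(self):
        df = pd.DataFrame({"genotype_class": ["C"] * 3, "od480": [0.2, 0.2, 0.2]})
        out = pigment_summary(df)
        assert out.iloc[0]["mean"] == pytest.approx(0.2)
        assert out.iloc[0]["sem"] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_class_rejected(self):
        df = pd.DataFrame({"genotype_class": ["C", "M", "M"], "od480": [0.2, 0.3, 0.4]})
        with pytest.raises(DataError, match="fewer than 2"):
            pigment_summary(df)

    def test_mean_sem_match_explicit_formula(self, rng):
        vals = rng.uniform(0.1, 0.5, 12)
        df = pd.DataFrame({"genotype_class": "C", "od480": vals})
        out = pigment_summary(df)
        assert out.iloc[0]["mean"] == pytest.approx(vals.mean(), abs=1e-12)
        assert out.iloc[0]["sem"] == pytest.approx(
            vals.std(ddof=1) / math.sqrt(len(vals)), abs=1e-12
        )

    def test_per_fly_normalization(self):
        df = pd.DataFrame(
            {"genotype_class": ["C", "C"], "od480": [0.5, 0.5], "flies_per_sample": [5, 5]}
        )
        out = pigment_summary(df, per_fly=True)
        assert out.iloc[0]["mean"] == pytest.approx(0.1)

    def test_additive_suppression_pattern(self):
        summary = pd.DataFrame(
            {
                "genotype_class": ["C", "M", "Z", "M+Z"],
                "mean": [1.0, 2.0, 4.0, 6.0],
                "sem": [0.0] * 4,
                "n": [4] * 4,
            }
        )
        gs = genotype_fold_changes(summary, "C")
        assert [gs.fold(c) for c in ["C", "M", "Z", "M+Z"]] == [1.0, 2.0, 4.0, 6.0]

    def test_equal_classes_all_fold_one(self):
        summary = pd.DataFrame(
            {"genotype_class": ["C", "M"], "mean": [2.0, 2.0], "sem": [0.1, 0.1], "n": [4, 4]}
        )
        gs = genotype_fold_changes(summary, "C")
        assert gs.fold("M") == 1.0

    def test_zero_control_mean_rejected(self):
        summary = pd.DataFrame(
            {"genotype_class": ["C", "M"], "mean": [0.0, 2.0], "sem": [0.0, 0.1], "n": [4, 4]}
        )
        with pytest.raises(DataError, match="control"):
            genotype_fold_changes(summary, "C")

    def test_beta_gal_summary_per_replicate_slopes(self):
        rows = []
        for rep, slope in [(1, 1e-3), (2, 3e-3)]:
            for t in (0, 60, 120):
                rows.append({"genotype_class": "C", "replicate": rep,
                             "time_min": t, "od574": 0.05 + slope * t})
        out = beta_gal_summary(pd.DataFrame(rows))
        assert out.iloc[0]["mean"] == pytest.approx(2e-3, rel=1e-9)
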