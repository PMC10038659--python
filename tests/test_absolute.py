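"""PRM/SID absolute quantification and the iBAQ calibration curve."""

import numpy as np
import pandas as pd
import pytest

import eccquant as eq
from eccquant.absolute import _log_median
from eccquant.exceptions import DataError, FitError, QuantificationError


def _prm(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "condition", "accession", "peptide",
            "light_area", "heavy_area", "sample_tic",
        ],
    )


class TestTicNormalize:
    def test_equal_tics_give_unit_factors(self):
        table = _prm([
            ("s1", "WT", "P1", "AAAAAAA", 10.0, 10.0, 1e9),
            ("s2", "WT", "P1", "AAAAAAA", 10.0, 10.0, 1e9),
        ])
        _, factors = eq.tic_normalize(table)
        assert np.allclose(factors, 1.0)

    def test_factors_scale_ratios(self):
        table = _prm([
            ("s1", "WT", "P1", "AAAAAAA", 20.0, 10.0, 2e9),
            ("s2", "WT", "P1", "AAAAAAA", 20.0, 10.0, 1e9),
        ])
        out, factors = eq.tic_normalize(table)
        assert tuple(factors) == pytest.approx((0.75, 1.5))
        assert tuple(out["ratio"]) == pytest.approx((1.5, 3.0))

    def test_tic_weighted_mean_of_factors_is_one(self, rng):
        tics = rng.uniform(5e8, 5e9, size=8)
        table = _prm([
            (f"s{i}", "WT", "P1", "AAAAAAA", 1.0, 1.0, t)
            for i, t in enumerate(tics)
        ])
        _, factors = eq.tic_normalize(table)
        weighted = (factors.to_numpy() * tics).sum() / tics.sum()
        assert weighted == pytest.approx(1.0)

    def test_zero_tic_rejected(self):
        table = _prm([("s1", "WT", "P1", "AAAAAAA", 1.0, 1.0, 0.0)])
        with pytest.raises(DataError):
            eq.tic_normalize(table)


class TestPeptideFmolPerUg:
    @pytest.mark.parametrize(
        "light,heavy,spike,expected",
        [(10.0, 10.0, 10.0, 10.0), (20.0, 10.0, 10.0, 20.0), (0.0, 10.0, 10.0, 0.0)],
    )
    def test_arithmetic(self, light, heavy, spike, expected):
        assert eq.peptide_fmol_per_ug(light, heavy, spike) == pytest.approx(expected)

    def test_missing_heavy_signal_is_flagged_not_silent(self):
        with pytest.raises(QuantificationError):
            eq.peptide_fmol_per_ug(10.0, 0.0, 10.0)


class TestProteinConcentration:
    def test_worked_unit_chain_example(self):
        # ratio 2 at spike 10 fmol/ug and yield 64.5 ug/mg -> 1.29 umol/kg
        table = _prm([("s1", "EDL-WT", "Ryr1", "AAAAAAA", 2.0, 1.0, 1e9)])
        conc = eq.protein_concentration(table, spike_S=10.0, yield_Y=64.5)
        assert conc["mean_umol_per_kg"].iloc[0] == pytest.approx(1.29)
        assert bool(conc["detected"].iloc[0])

    def test_median_robust_to_outlier_peptide(self):
        table = _prm([
            ("s1", "WT", "P1", "AAAAAAA", r, 1.0, 1e9) for r in (1.0, 2.0, 100.0)
        ])
        conc = eq.protein_concentration(table, spike_S=10.0, yield_Y=64.5)
        assert conc["mean_umol_per_kg"].iloc[0] == pytest.approx(2 * 10 * 64.5e-3)

    def test_not_detected_when_no_heavy_signal(self):
        table = _prm([("s1", "WT", "P1", "AAAAAAA", 5.0, 0.0, 1e9)])
        conc = eq.protein_concentration(table)
        assert not bool(conc["detected"].iloc[0])
        assert np.isnan(conc["mean_umol_per_kg"].iloc[0])
        assert conc["n_samples"].iloc[0] == 0

    def test_mean_and_sd_across_samples(self):
        table = _prm([
            ("s1", "WT", "P1", "AAAAAAA", 1.0, 1.0, 1e9),
            ("s2", "WT", "P1", "AAAAAAA", 3.0, 1.0, 1e9),
        ])
        conc = eq.protein_concentration(table, spike_S=10.0, yield_Y=100.0)
        # per-sample values 1.0 and 3.0 umol/kg
        assert conc["mean_umol_per_kg"].iloc[0] == pytest.approx(2.0)
        assert conc["sd_umol_per_kg"].iloc[0] == pytest.approx(np.std([1, 3], ddof=1))
        assert conc["n_samples"].iloc[0] == 2

    def test_log_median_even_count_is_geometric_mean_of_middles(self):
        assert _log_median(np.array([1.0, 4.0])) == pytest.approx(2.0)
        assert _log_median(np.array([1.0, 2.0, 8.0, 100.0])) == pytest.approx(4.0)
        assert _log_median(np.array([0.0, 4.0])) == 0.0


class TestCalibration:
    def test_perfectly_collinear_anchors(self):
        anchors = [(x, 2.0 * x - 3.0) for x in (1.0, 2.0, 3.0, 4.0)]
        model = eq.fit_calibration(anchors)
        assert model.r_squared == pytest.approx(1.0)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(-3.0)
        assert model.domain == (1.0, 4.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = np.array([2.0, 5.0, 8.0, 11.0])
        y = x - 3.0 + rng.normal(0, 0.2, size=4)
        model = eq.fit_calibration(np.column_stack([x, y]))
        # independent solve of the normal equations
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert model.slope == pytest.approx(slope)
        assert model.intercept == pytest.approx(intercept)

    def test_zero_spread_anchors_rejected(self):
        with pytest.raises(FitError):
            eq.fit_calibration([(1.0, 2.0), (1.0, 3.0)])

    def test_extrapolate_at_anchor_of_perfect_fit(self):
        anchors = [(1.0, -2.0), (5.0, 2.0)]  # y = x - 3
        model = eq.fit_calibration(anchors)
        result = eq.extrapolate(model, 5.0)
        assert result.umol_per_kg == pytest.approx(2.0**2.0)
        assert result.in_domain

    def test_extrapolate_hand_arithmetic(self):
        model = eq.CalibrationModel(slope=1.0, intercept=-3.0, r_squared=1.0,
                                    domain=(0.0, 20.0))
        assert eq.extrapolate(model, 10.0).umol_per_kg == pytest.approx(128.0)

    def test_out_of_domain_is_flagged(self):
        model = eq.CalibrationModel(slope=1.0, intercept=0.0, r_squared=1.0,
                                    domain=(5.0, 10.0))
        result = eq.extrapolate(model, 2.0)
        assert not result.in_domain
        assert result.umol_per_kg == pytest.approx(4.0)

    def test_noisy_anchor_r_squared_stays_high(self, rng):
        """With sigma=0.25 log2 scatter around a unit-slope line spanning a
        wide iBAQ range, the fitted correlation should stay near 1."""
        hits = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            x = np.linspace(8, 20, 8)
            y = x - 3 + local.normal(0, 0.25, size=8)
            if eq.fit_calibration(np.column_stack([x, y])).r_squared >= 0.95:
                hits += 1
        assert hits >= 18
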