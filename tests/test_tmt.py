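"""TMT reporter processing, moderated-t statistics and significance filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import eccquant as eq
from eccquant.exceptions import ConsistencyError, DataError, DesignError
from eccquant.proteins import ProteinDB, ProteinRecord
from eccquant.tmt import (
    TMT10_CHANNELS,
    ChannelDesign,
    ModerationHyperparams,
    estimate_hyperparams,
)

CH = list(TMT10_CHANNELS)
DESIGN = ChannelDesign(labels=("WT",) * 5 + ("dHT",) * 5)


def _psm(rows, channels=("126", "127N")):
    df = pd.DataFrame(
        [(acc, pep) for acc, pep, *_ in rows], columns=["accession", "peptide"]
    )
    for j, ch in enumerate(channels):
        df[ch] = [r[2 + j] for r in rows]
    return df


class TestCorrectReporters:
    def test_identity_matrix_is_noop(self):
        table = _psm([("P1", "AAAAAAA", 100.0, 50.0)])
        out, clipped = eq.correct_reporters(table, np.eye(2), channels=("126", "127N"))
        pd.testing.assert_frame_equal(out, table)
        assert clipped == 0

    def test_two_channel_leakage_matches_hand_inverse(self):
        # 5% symmetric leakage; hand inverse of [[.95,.05],[.05,.95]]
        impurity = np.array([[0.95, 0.05], [0.05, 0.95]])
        table = _psm([("P1", "AAAAAAA", 100.0, 0.0)])
        out, _ = eq.correct_reporters(table, impurity, channels=("126", "127N"))
        det = 0.95**2 - 0.05**2
        expected = (0.95 * 100 / det, 0.0)  # second entry clipped from negative
        assert out["126"].iloc[0] == pytest.approx(expected[0])
        assert out["127N"].iloc[0] == 0.0

    def test_round_trip_remixing_recovers_observed(self, rng):
        impurity = np.eye(10) * 0.92 + 0.008
        true = rng.uniform(10, 1000, size=(4, 10))
        observed = true @ impurity.T  # leak the true signals into neighbors
        table = pd.DataFrame({"accession": ["P1"] * 4, "peptide": ["AAAAAAA"] * 4})
        table[CH] = observed
        corrected, clipped = eq.correct_reporters(table, impurity)
        assert clipped == 0
        assert np.allclose(corrected[CH].to_numpy(), true)
        remixed = corrected[CH].to_numpy() @ impurity.T
        assert np.allclose(remixed, observed)

    def test_singular_matrix_rejected(self):
        table = _psm([("P1", "AAAAAAA", 1.0, 1.0)])
        with pytest.raises(DataError):
            eq.correct_reporters(table, np.ones((2, 2)), channels=("126", "127N"))


class TestNormalizeChannels:
    def test_equal_totals_give_unit_factors(self):
        table = _psm([("P1", "AAAAAAA", 100.0, 100.0)])
        _, factors = eq.normalize_channels(table, channels=("126", "127N"))
        assert np.allclose(factors, 1.0)

    def test_factors_and_post_totals(self):
        table = _psm([("P1", "AAAAAAA", 200.0, 100.0)])
        out, factors = eq.normalize_channels(table, channels=("126", "127N"))
        assert tuple(factors) == pytest.approx((0.75, 1.5))
        assert out["126"].sum() == pytest.approx(150.0)
        assert out["127N"].sum() == pytest.approx(150.0)

    def test_grand_total_conserved(self, rng):
        table = pd.DataFrame({"accession": ["P"] * 6, "peptide": ["AAAAAAA"] * 6})
        table[CH] = rng.uniform(1, 100, size=(6, 10))
        out, _ = eq.normalize_channels(table)
        assert out[CH].to_numpy().sum() == pytest.approx(table[CH].to_numpy().sum())

    def test_zero_total_channel_rejected(self):
        table = _psm([("P1", "AAAAAAA", 100.0, 0.0)])
        with pytest.raises(DataError):
            eq.normalize_channels(table, channels=("126", "127N"))


class TestRollup:
    DB = ProteinDB([
        ProteinRecord("P1", "", "AAAAAAAKCCCCCCC"),
        ProteinRecord("P2", "", "DDDDDDD"),
    ])

    def test_single_psm_passthrough(self):
        table = pd.DataFrame({"accession": ["P1"], "peptide": ["AAAAAAAK"]})
        table[CH] = [np.arange(10.0)]
        quants = eq.rollup(table, self.DB)
        assert np.allclose(quants.loc["P1", CH], np.arange(10.0))
        assert quants.loc["P1", "n_peptides"] == 1

    def test_summation_and_peptide_count(self):
        table = pd.DataFrame(
            {"accession": ["P1", "P1"], "peptide": ["AAAAAAAK", "CCCCCCC"]}
        )
        table[CH] = [[10.0] * 10, [1.0] * 10]
        quants = eq.rollup(table, self.DB)
        assert np.allclose(quants.loc["P1", CH], 11.0)
        assert quants.loc["P1", "n_peptides"] == 2
        # iBAQ: total intensity 110 over 2 observable peptides
        assert quants.loc["P1", "ibaq"] == pytest.approx(55.0)

    def test_row_order_invariance(self, rng):
        table = pd.DataFrame(
            {"accession": ["P1", "P2", "P1"], "peptide": ["AAAAAAAK", "DDDDDDD", "CCCCCCC"]}
        )
        table[CH] = rng.uniform(1, 10, size=(3, 10))
        shuffled = table.sample(frac=1, random_state=5).reset_index(drop=True)
        pd.testing.assert_frame_equal(eq.rollup(table, self.DB), eq.rollup(shuffled, self.DB))

    def test_unknown_accession_rejected(self):
        table = pd.DataFrame({"accession": ["GHOST"], "peptide": ["AAAAAAA"]})
        table[CH] = [[1.0] * 10]
        with pytest.raises(ConsistencyError):
            eq.rollup(table, self.DB)


def _toy_quants(rng, n=20):
    """Protein table with heteroscedastic log-normal channel intensities."""
    sigmas = rng.uniform(0.05, 0.5, size=n)
    base = rng.uniform(8, 15, size=n)
    L = base[:, None] + rng.normal(0, sigmas[:, None], size=(n, 10))
    quants = pd.DataFrame(2.0**L, columns=CH,
                          index=[f"P{i}" for i in range(n)])
    quants["n_peptides"] = 3
    return quants


class TestModeratedT:
    def test_d0_to_zero_limit_is_ordinary_pooled_t(self, rng):
        quants = _toy_quants(rng)
        hp = ModerationHyperparams(d0=1e-9, s0_sq=1.0)
        results, _ = eq.moderated_t(quants, DESIGN, hyperparams=hp)
        L = np.log2(quants[CH].to_numpy())
        t_ref, p_ref = stats.ttest_ind(L[:, 5:], L[:, :5], axis=1, equal_var=True)
        assert np.allclose(results["t_moderated"], t_ref, rtol=1e-6)
        assert np.allclose(results["p_value"], p_ref, rtol=1e-4)

    def test_d0_infinite_limit_uses_common_variance(self, rng):
        quants = _toy_quants(rng)
        s0 = 0.04
        hp = ModerationHyperparams(d0=np.inf, s0_sq=s0)
        results, _ = eq.moderated_t(quants, DESIGN, hyperparams=hp)
        L = np.log2(quants[CH].to_numpy())
        delta = L[:, 5:].mean(axis=1) - L[:, :5].mean(axis=1)
        t_ref = delta / np.sqrt(s0 * (1 / 5 + 1 / 5))
        assert np.allclose(results["t_moderated"], t_ref)
        assert np.allclose(results["p_value"], 2 * stats.norm.sf(np.abs(t_ref)))

    def test_matches_posterior_formula_transcription(self, rng):
        """Direct transcription of the shrinkage formulas, recomputed
        independently of the implementation's internals."""
        quants = _toy_quants(rng)
        results, hp = eq.moderated_t(quants, DESIGN)
        L = np.log2(quants[CH].to_numpy())
        g1, g2 = L[:, :5], L[:, 5:]
        delta = g2.mean(axis=1) - g1.mean(axis=1)
        s2 = (g1.var(axis=1, ddof=1) * 4 + g2.var(axis=1, ddof=1) * 4) / 8
        s2_post = (hp.d0 * hp.s0_sq + 8 * s2) / (hp.d0 + 8)
        t_ref = delta / np.sqrt(s2_post * 0.4)
        p_ref = 2 * stats.t.sf(np.abs(t_ref), hp.d0 + 8)
        assert np.allclose(results["t_moderated"], t_ref)
        assert np.allclose(results["p_value"], p_ref)
        assert np.allclose(results["ratio"], 2.0**delta)

    def test_scale_equivariance(self, rng):
        quants = _toy_quants(rng)
        scaled = quants.copy()
        scaled[CH] = scaled[CH] * 37.5
        r1, hp1 = eq.moderated_t(quants, DESIGN)
        r2, hp2 = eq.moderated_t(scaled, DESIGN, hyperparams=hp1)
        for col in ("ratio", "t_moderated", "p_value"):
            assert np.allclose(r1[col], r2[col])

    def test_hyperparameter_recovery_from_known_prior(self, rng):
        """Variances drawn from a scaled-inverse-chi-square prior should be
        matched by the moment estimator within a loose tolerance."""
        d0_true, s0_true, d = 8.0, 0.05, 8
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=4000)
        s2 = sigma2 * rng.chisquare(d, size=4000) / d
        hp = estimate_hyperparams(s2, d)
        assert hp.d0 == pytest.approx(d0_true, rel=0.3)
        assert hp.s0_sq == pytest.approx(s0_true, rel=0.1)

    def test_small_design_rejected(self, rng):
        quants = _toy_quants(rng)
        design = ChannelDesign(labels=("WT",) + ("dHT",) * 9)
        with pytest.raises(DesignError):
            eq.moderated_t(quants, design)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert eq.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_worked_step_up(self):
        assert eq.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, p_values):
        p = np.array(p_values)
        q = eq.bh_adjust(p)
        m = p.size
        # brute force: q_i = min over p_(j) >= p_i of p_(j) * m / rank(j)
        order = np.sort(p)
        expected = np.empty(m)
        for i, pi in enumerate(p):
            candidates = [
                min(1.0, order[j] * m / (j + 1))
                for j in range(m)
                if order[j] >= pi
            ]
            expected[i] = min(candidates)
        assert np.allclose(q, expected)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
    def test_monotone_in_p(self, p_values):
        p = np.array(p_values)
        q = eq.bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            eq.bh_adjust([0.5, 1.5])


class TestFilterSignificant:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["ratio", "q_value", "n_peptides"]
        ).assign(log2fc=lambda d: np.log2(d["ratio"]))

    def test_strongly_downregulated_channel_protein_kept(self):
        # ratio 0.40, q=3.97e-5, 5 peptides: the canonical kept-down row
        results = self._results([(0.40, 3.97e-5, 5)])
        kept, up, down = eq.filter_significant(results)
        assert len(kept) == 1 and down == 1 and up == 0

    def test_unchanged_protein_removed_despite_tiny_q(self):
        results = self._results([(1.00, 1e-9, 10)])
        kept, *_ = eq.filter_significant(results)
        assert kept.empty

    def test_boundary_toy_matches_exhaustive_rule(self):
        rows = [
            (0.79, 0.01, 3),   # kept: |0.79-1| = 0.21 >= 0.2
            (0.81, 0.01, 3),   # removed: fold change too small
            (1.25, 0.01, 3),   # kept
            (1.30, 0.05, 3),   # removed: q not < 0.05
            (0.40, 0.001, 1),  # removed: single peptide
            (1.50, 0.049, 2),  # kept
        ]
        results = self._results(rows)
        kept, up, down = eq.filter_significant(results)
        expected = {
            i for i, (r, q, n) in enumerate(rows)
            if q < 0.05 and abs(r - 1) >= 0.2 and n >= 2
        }
        assert set(kept.index) == expected == {0, 2, 5}
        assert up == 2 and down == 1
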