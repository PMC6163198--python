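import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cilioprior.de import (
    DeThresholds, ExpressionDataset, ModeratedTTest, apply_thresholds, bh_adjust,
    concordant_probes, estimate_variance_prior, fit_moderated_t, trigamma_inverse,
)
from conftest import make_dataset


def bh_brute_force(p):
    """Literal step-up definition: q_(i) = min_{j >= i} m * p_(j) / j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


class TestModeratedFit:
    def test_matches_independent_reference_on_frozen_fixture(self, limma_fixture, limma_oracle):
        """The shrinkage fit reproduces the reference empirical-Bayes pipeline
        (prior df/scale, moderated t, p) to near machine precision."""
        res = fit_moderated_t(limma_fixture)
        assert res.d0 == pytest.approx(2.542642628, rel=1e-8)
        assert res.s0_sq == pytest.approx(0.05517432911, rel=1e-8)
        tab = res.table.loc[limma_oracle.index]
        np.testing.assert_allclose(tab["logFC"], limma_oracle["logFC"], rtol=1e-9)
        np.testing.assert_allclose(tab["t"], limma_oracle["t"], rtol=1e-9)
        np.testing.assert_allclose(tab["p"], limma_oracle["p"], rtol=1e-8)

    def test_plain_mode_equals_pooled_two_sample_t(self, limma_fixture):
        res = fit_moderated_t(limma_fixture, shrink=False)
        x = limma_fixture.matrix.to_numpy()
        t_ref, p_ref = stats.ttest_ind(x[:, 4:], x[:, :4], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(res.table["p"], p_ref, rtol=1e-12)

    def test_group_label_swap_negates_effect_and_statistic(self, limma_fixture):
        res = fit_moderated_t(limma_fixture)
        swapped = ExpressionDataset(
            matrix=limma_fixture.matrix,
            groups=limma_fixture.groups.map({"FTE": "HGSOC", "HGSOC": "FTE"}),
            name="swapped",
        )
        res_sw = fit_moderated_t(swapped)
        np.testing.assert_allclose(res_sw.table["logFC"], -res.table["logFC"], rtol=1e-12)
        np.testing.assert_allclose(res_sw.table["t"], -res.table["t"], rtol=1e-12)
        np.testing.assert_allclose(res_sw.table["p"], res.table["p"], rtol=1e-12)

    def test_underdispersed_variances_fall_back_to_full_shrinkage(self):
        # identical per-probe variances cannot support a finite prior df
        rng = np.random.default_rng(5)
        n1 = n2 = 4
        base = rng.normal(size=n1 + n2)
        mat = np.tile(base, (40, 1)) + rng.normal(0, 1e-3, size=(40, n1 + n2)) * 0
        mat = np.vstack([base + 0.001 * i for i in range(40)])  # same spread every row
        samples = [f"F{i}" for i in range(n1)] + [f"H{i}" for i in range(n2)]
        ds = ExpressionDataset(
            pd.DataFrame(mat, index=[f"P{i}" for i in range(40)], columns=samples),
            pd.Series(["FTE"] * n1 + ["HGSOC"] * n2, index=samples), "flat")
        res = fit_moderated_t(ds)
        assert np.isinf(res.d0)
        np.testing.assert_allclose(res.table["s2_post"], res.s0_sq, rtol=1e-12)

    def test_zero_variance_probe_excluded(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng, n_probes=20)
        ds.matrix.iloc[0] = 3.0  # constant row
        res = fit_moderated_t(ds)
        assert res.excluded_probes == ["P0000"]
        assert "P0000" not in res.table.index

    def test_too_few_probes_instructs_plain_mode(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng, n_probes=1)
        with pytest.raises(ValueError, match="plain-t"):
            fit_moderated_t(ds)

    def test_summary_reports_prior_and_design(self, limma_fixture):
        text = fit_moderated_t(limma_fixture).summary()
        assert "Prior df" in text and "FTE: 4" in text and "HGSOC: 5" in text


class TestCalibrationAndRecovery:
    def test_null_type_one_error_near_nominal(self):
        """With no group difference, p < 0.05 should occur for ~5% of probes
        (within 3 Monte-Carlo standard errors at 2000 probes)."""
        rng = np.random.default_rng(20260919)
        ds = make_dataset(rng, n_probes=2000, n1=10, n2=10, d0=4.0, s0_sq=0.05)
        res = fit_moderated_t(ds)
        frac = float((res.table["p"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < 3 * se

    def test_prior_parameters_recovered_by_moment_matching(self):
        rng = np.random.default_rng(20260919)
        ds = make_dataset(rng, n_probes=2000, n1=10, n2=10, d0=4.0, s0_sq=0.05)
        res = fit_moderated_t(ds)
        assert abs(res.d0 - 4.0) / 4.0 < 0.25
        assert abs(res.s0_sq - 0.05) / 0.05 < 0.25

    def test_planted_de_recovered_with_fdr_control(self):
        """Planted |logFC| = 2 in 5% of probes: sensitivity >= 0.9 and
        observed false-discovery proportion <= 0.10 at default thresholds."""
        rng = np.random.default_rng(42)
        n_probes, n_de = 2000, 100
        de_idx = rng.choice(n_probes, size=n_de, replace=False)
        ds = make_dataset(rng, n_probes=n_probes, n1=10, n2=10, de_idx=de_idx, effect=2.0)
        res = fit_moderated_t(ds)
        sig = apply_thresholds(res.table, DeThresholds())
        planted = {f"P{i:04d}" for i in de_idx}
        retained = set(sig.index)
        sensitivity = len(retained & planted) / n_de
        fdp = len(retained - planted) / max(len(retained), 1)
        assert sensitivity >= 0.9
        assert fdp <= 0.10

    def test_retained_count_nondecreasing_in_effect_size(self):
        counts = []
        for effect in (0.5, 1.0, 1.5, 2.0, 3.0):
            rng = np.random.default_rng(99)  # same noise realization each time
            de_idx = np.arange(100)
            ds = make_dataset(rng, n_probes=1000, n1=10, n2=10, de_idx=de_idx, effect=effect)
            sig = apply_thresholds(fit_moderated_t(ds).table, DeThresholds())
            counts.append(len(sig))
        assert counts == sorted(counts)


class TestTrigammaInverse:
    @pytest.mark.parametrize("y", [0.05, 0.5, 2.0, 25.0, 400.0])
    def test_round_trip(self, y):
        from scipy.special import polygamma
        assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-6)


class TestBhAdjust:
    def test_hand_worked_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=100))
    def test_agrees_with_literal_step_up_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), rtol=1e-12, atol=1e-15)


class TestThresholdsAndConcordance:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["logFC", "q"],
                            index=[f"P{i}" for i in range(len(rows))])

    def test_strict_inequalities_on_both_cutoffs(self):
        tab = self._table([(1.01, 0.049), (2.0, 0.05), (1.0, 0.01), (-1.2, 0.02)])
        sig = apply_thresholds(tab, DeThresholds())
        assert list(sig.index) == ["P0", "P3"]
        assert list(sig["direction"]) == [1, -1]

    def test_concordance_requires_shared_probe_and_same_sign(self):
        a = self._table([(2.0, 0.01), (1.5, 0.01), (-1.5, 0.01)])
        a = apply_thresholds(a, DeThresholds())
        b = pd.DataFrame({"logFC": [1.8, -1.5], "q": [0.02, 0.01]}, index=["P0", "P1"])
        b = apply_thresholds(b, DeThresholds())
        conc = concordant_probes(a, b)
        assert list(conc.index) == ["P0"]  # P1 flips sign, P2 absent from b
        assert set(conc.columns) >= {"logFC_a", "logFC_b", "q_a", "q_b", "direction"}
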