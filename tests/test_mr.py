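import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cismr.mr import (
    MRError,
    MRModel,
    bonferroni_adjust,
    cochrans_q,
    ivw_correlated,
    leave_one_out,
    mr_egger_correlated,
    weighted_median,
)
from cismr.sumstats import HarmonizedSet, LDMatrix
from conftest import random_harmonized_set


def textbook_ivw(bx, by, se_y):
    """Independent-instrument IVW oracle: precision-weighted ratio average."""
    w = 1.0 / se_y**2
    beta = float((w * bx * by).sum() / (w * bx * bx).sum())
    se = float(1.0 / np.sqrt((w * bx * bx).sum()))
    return beta, se


def gls_oracle(X, y, omega):
    """Normal-equations GLS oracle: (X' O^-1 X)^-1 X' O^-1 y and covariance."""
    oinv = np.linalg.inv(omega)
    xtx = X.T @ oinv @ X
    coef = np.linalg.solve(xtx, X.T @ oinv @ y)
    return coef, np.linalg.inv(xtx)


class TestIVW:
    def test_single_instrument_is_wald_ratio(self):
        h = HarmonizedSet.from_arrays(["rs1"], np.array([1.0]),
                                      np.array([0.0]), np.array([0.06]),
                                      np.array([0.03]))
        est = ivw_correlated(h)
        assert est.method == "wald_ratio"
        assert est.beta == pytest.approx(0.06)
        assert est.se == pytest.approx(0.03)
        assert est.hr == pytest.approx(1.062, abs=5e-4)

    def test_two_instrument_closed_form(self, k2_independent_set):
        est = ivw_correlated(k2_independent_set)
        assert est.beta == pytest.approx(0.061176, abs=1e-5)
        assert est.se == pytest.approx(0.019403, abs=1e-5)  # phi = 1 here
        assert est.q_stat == pytest.approx(0.0588, abs=2e-4)
        assert est.phi == 1.0

    def test_identity_rho_matches_textbook_oracle(self, rng):
        for _ in range(50):
            h = random_harmonized_set(rng)
            est = ivw_correlated(h)
            beta, se_fixed = textbook_ivw(h.bx, h.by, h.se_y)
            assert est.beta == pytest.approx(beta, abs=1e-12)
            assert est.se == pytest.approx(
                se_fixed * np.sqrt(est.phi), rel=1e-12
            )

    def test_correlated_matches_gls_oracle(self, rng):
        for _ in range(20):
            h = random_harmonized_set(rng, correlated=True)
            omega = np.outer(h.se_y, h.se_y) * h.ld.rho
            coef, cov = gls_oracle(h.bx[:, None], h.by, omega)
            est = ivw_correlated(h)
            assert est.beta == pytest.approx(float(coef[0]), abs=1e-10)
            assert est.se == pytest.approx(
                float(np.sqrt(est.phi * cov[0, 0])), rel=1e-10
            )

    def test_empty_set_raises(self, k2_independent_set):
        import pandas as pd
        h = k2_independent_set
        empty = HarmonizedSet(h.table.iloc[:0], LDMatrix.identity([]),
                              pd.DataFrame(columns=["variant_id", "status",
                                                    "reason"]))
        with pytest.raises(MRError):
            ivw_correlated(empty)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 1000))
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        h = random_harmonized_set(rng)
        est = ivw_correlated(h)
        h2 = HarmonizedSet.from_arrays(h.variant_ids, h.bx * c, h.se_x,
                                       h.by, h.se_y, h.ld)
        est2 = ivw_correlated(h2)
        assert est2.beta == pytest.approx(est.beta / c, rel=1e-9)
        assert est2.ci_low == pytest.approx(est.ci_low / c, rel=1e-9)
        assert est2.ci_high == pytest.approx(est.ci_high / c, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), j=st.integers(0, 11))
    def test_allele_flip_invariance(self, seed, j):
        rng = np.random.default_rng(seed)
        h = random_harmonized_set(rng, correlated=True)
        j = j % h.k
        flip_id = h.variant_ids[j]
        sign = np.ones(h.k)
        sign[j] = -1.0
        h2 = HarmonizedSet.from_arrays(
            h.variant_ids, h.bx * sign, h.se_x, h.by * sign, h.se_y,
            h.ld.flip_signs([flip_id]),
        )
        for a, b in [(ivw_correlated(h), ivw_correlated(h2))]:
            assert b.beta == pytest.approx(a.beta, rel=1e-9, abs=1e-12)
            assert b.se == pytest.approx(a.se, rel=1e-9)
        if h.k >= 3:
            s1, i1 = mr_egger_correlated(h)
            s2, i2 = mr_egger_correlated(h2)
            assert s2.beta == pytest.approx(s1.beta, rel=1e-9, abs=1e-12)
            assert i2.beta == pytest.approx(i1.beta, rel=1e-9, abs=1e-12)


class TestEgger:
    def test_exact_linear_relation_recovered(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        by = 0.02 + 0.5 * bx
        h = HarmonizedSet.from_arrays(
            [f"rs{i}" for i in range(4)], bx, np.zeros(4), by,
            np.full(4, 0.01),
        )
        slope, intercept = mr_egger_correlated(h)
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.beta == pytest.approx(0.02, abs=1e-10)
        assert slope.q_stat == pytest.approx(0.0, abs=1e-8)

    def test_matches_gls_oracle_with_orientation(self, rng):
        for _ in range(20):
            h = random_harmonized_set(rng, k=5, correlated=True)
            sign = np.where(h.bx < 0, -1.0, 1.0)
            bx, by = h.bx * sign, h.by * sign
            rho = sign[:, None] * h.ld.rho * sign[None, :]
            omega = np.outer(h.se_y, h.se_y) * rho
            X = np.column_stack([np.ones(5), bx])
            coef, cov = gls_oracle(X, by, omega)
            slope, intercept = mr_egger_correlated(h)
            assert slope.beta == pytest.approx(float(coef[1]), abs=1e-10)
            assert intercept.beta == pytest.approx(float(coef[0]), abs=1e-10)
            assert slope.se == pytest.approx(
                float(np.sqrt(slope.phi * cov[1, 1])), rel=1e-9
            )

    def test_requires_three_instruments(self, k2_independent_set):
        with pytest.raises(MRError, match="insufficient"):
            mr_egger_correlated(k2_independent_set)


class TestWeightedMedian:
    def make(self, theta, weights_sey):
        k = len(theta)
        bx = np.ones(k)
        by = np.asarray(theta, float)
        return HarmonizedSet.from_arrays(
            [f"rs{i}" for i in range(k)], bx, np.full(k, 1e-6), by,
            np.asarray(weights_sey, float),
        )

    def test_equal_weights_is_plain_median(self):
        h = self.make([0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_hand_computed_interpolation(self):
        # weights (0.25, 0.25, 0.5) via se_y = 1/sqrt(w)
        se_y = 1.0 / np.sqrt(np.array([0.25, 0.25, 0.5]))
        h = self.make([0.1, 0.2, 0.3], se_y)
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.23333, abs=1e-4)

    def test_degenerate_identical_ratios(self):
        bx = np.array([0.5, 1.0, 2.0, 0.25])
        by = 0.07 * bx
        h = HarmonizedSet.from_arrays(
            [f"rs{i}" for i in range(4)], bx, np.full(4, 1e-4), by,
            np.full(4, 0.01),
        )
        est = weighted_median(h, n_boot=200, seed=3)
        assert est.beta == pytest.approx(0.07, abs=1e-10)
        assert est.se < 0.05

    def test_forces_identity_correlation(self, rng, caplog):
        h = random_harmonized_set(rng, k=4, correlated=True)
        with caplog.at_level("WARNING"):
            weighted_median(h, n_boot=10, seed=0)
        assert "independent" in caplog.text

    def test_bootstrap_deterministic_given_seed(self, rng):
        h = random_harmonized_set(rng, k=5)
        a = weighted_median(h, n_boot=100, seed=7)
        b = weighted_median(h, n_boot=100, seed=7)
        assert a.se == b.se


class TestCochransQ:
    def test_zero_for_identical_ratios(self):
        bx = np.array([0.5, 1.0, 2.0])
        by = 0.06 * bx
        h = HarmonizedSet.from_arrays(["a", "b", "c"], bx, np.zeros(3), by,
                                      np.full(3, 0.01))
        q, p = cochrans_q(h, 0.06)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_ivw_example(self, k2_independent_set):
        est = ivw_correlated(k2_independent_set)
        q, p = cochrans_q(k2_independent_set, est.beta)
        assert q == pytest.approx(0.0588, abs=2e-4)

    def test_outlier_inflates_q(self):
        bx = np.ones(5)
        by = np.full(5, 0.06)
        se_y = np.full(5, 0.01)
        by[2] += 10 * se_y[2]  # 10-sigma outlier
        h = HarmonizedSet.from_arrays([f"rs{i}" for i in range(5)], bx,
                                      np.zeros(5), by, se_y)
        est = ivw_correlated(h)
        q, p = cochrans_q(h, est.beta)
        assert p < 0.05

    def test_single_instrument_returns_none(self, caplog):
        h = HarmonizedSet.from_arrays(["rs1"], np.array([1.0]),
                                      np.array([0.0]), np.array([0.05]),
                                      np.array([0.01]))
        with caplog.at_level("WARNING"):
            assert cochrans_q(h, 0.05) is None


class TestLeaveOneOut:
    def test_two_instruments_give_wald_ratios(self, k2_independent_set):
        loo = leave_one_out(k2_independent_set)
        assert [e.method for e in loo] == ["wald_ratio", "wald_ratio"]
        # excluding rs1 leaves rs2: 0.02/0.25
        assert loo[0].beta == pytest.approx(0.08)
        assert loo[1].beta == pytest.approx(0.06)

    def test_homogeneous_set_stays_near_truth(self, rng):
        theta = 0.06
        k = 10
        bx = rng.uniform(0.2, 0.6, k)
        se_y = np.full(k, 0.01)
        by = theta * bx + rng.normal(0, se_y)
        h = HarmonizedSet.from_arrays([f"rs{i}" for i in range(k)], bx,
                                      np.zeros(k), by, se_y)
        for est in leave_one_out(h):
            assert abs(est.beta - theta) < 3 * est.se

    def test_single_outlier_identified(self):
        bx = np.ones(6)
        by = np.full(6, 0.05)
        by[4] = 0.5
        h = HarmonizedSet.from_arrays([f"rs{i}" for i in range(6)], bx,
                                      np.zeros(6), by, np.full(6, 0.01))
        loo = leave_one_out(h)
        betas = np.array([e.beta for e in loo])
        # the fit excluding the outlier is the only clean one
        assert betas[4] == pytest.approx(0.05, abs=1e-10)
        assert all(b > 0.1 for b in np.delete(betas, 4))


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.009, 4, 0.036),
        (0.5, 4, 1.0),
        (0.0125, 4, 0.05),
    ])
    def test_adjustment(self, p, m, expected):
        assert bonferroni_adjust([p], m)[0] == pytest.approx(expected)

    def test_boundary_not_significant_by_strict_test(self):
        adj = bonferroni_adjust([0.0125], 4)[0]
        assert not adj < 0.05

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.0], 4)
        with pytest.raises(ValueError):
            bonferroni_adjust([1.1], 4)


class TestModelResults:
    def test_fit_and_summary(self, rng):
        h = random_harmonized_set(rng, k=6)
        res = MRModel(h, correlated=False).fit(
            methods=("ivw", "egger", "weighted_median"), n_boot=50, seed=0
        )
        assert set(res.estimates) == {"ivw", "egger_slope",
                                      "egger_intercept", "weighted_median"}
        text = res.summary()
        assert "Cochran's Q" in text and "ivw" in text
        loo = res.leave_one_out()
        assert len(loo) == 6
        assert res.to_frame().shape[0] == 4

    def test_insufficient_instruments_recorded_not_raised(self,
                                                          k2_independent_set):
        res = MRModel(k2_independent_set).fit(methods=("ivw", "egger"))
        assert "egger" in res.errors
        assert res.ivw is not None

    def test_use_t_widens_small_sample_ci(self, rng):
        h = random_harmonized_set(rng, k=4)
        n_ci = MRModel(h).fit(methods=("ivw",)).ivw
        t_ci = MRModel(h, use_t=True).fit(methods=("ivw",)).ivw
        assert (t_ci.ci_high - t_ci.ci_low) > (n_ci.ci_high - n_ci.ci_low)

    def test_from_tables_roundtrip(self, tmp_path, rng):
        from cismr import synthetic
        from cismr.sumstats import write_ld_matrix, write_sumstats

        spec = synthetic.scenario("IL6ST_decode", seed=3, theta=0.1)
        exposure, ld, truth = synthetic.generate_exposure_gwas(spec)
        outcome = synthetic.generate_outcome_gwas(truth, spec)
        write_sumstats(exposure, tmp_path / "exp.tsv")
        write_sumstats(outcome, tmp_path / "out.tsv")
        write_ld_matrix(ld, tmp_path / "ld.tsv")
        model = MRModel.from_tables(tmp_path / "exp.tsv",
                                    tmp_path / "out.tsv",
                                    tmp_path / "ld.tsv")
        res = model.fit(methods=("ivw",))
        assert res.ivw is not None and res.ivw.k_snps == 19
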