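"""Estimator correctness: oracles, equivalences, error handling."""

import numpy as np
import pandas as pd
import pytest

from edumr import (
    EstimationRequest,
    additive_smm,
    mva_adjusted,
    tsls,
    wald_ratio,
    within_family_tsls,
)
from edumr.exceptions import DataError, DegenerateInstrumentError, RankDeficiencyError

from conftest import wald_oracle


def simple_iv_frame(n=1000, seed=0, beta=0.5, confounded=False):
    rng = np.random.default_rng(seed)
    z = rng.integers(0, 2, size=n).astype(float)
    u = rng.normal(size=n)
    x = 10 + 1.5 * z + (u if confounded else 0) + rng.normal(size=n)
    y = 2 + beta * x + (u if confounded else 0) + rng.normal(size=n)
    return pd.DataFrame({"y": y, "x": x, "z": z})


def req(**kw):
    d = dict(outcome="y", exposure="x", instruments=("z",), covariates=(), cluster_col=None)
    d.update(kw)
    return EstimationRequest(**d)


class TestMva:
    def test_noiseless_regression_exact(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": 2.0 * np.arange(10.0)})
        est = mva_adjusted(df, req())  # no instruments needed
        assert est.beta == pytest.approx(2.0, abs=1e-12)

    def test_constant_weights_do_not_change_estimate(self):
        df = simple_iv_frame(seed=1)
        df["w"] = 3.7
        a = mva_adjusted(df, req())
        b = mva_adjusted(df, req(weight_col="w"))
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_collinear_covariates_rejected_with_names(self):
        df = simple_iv_frame(seed=2)
        df["x2"] = 2 * df["x"]
        with pytest.raises(RankDeficiencyError):
            mva_adjusted(df, req(covariates=("x2",)))

    def test_confounding_biases_mva_but_not_iv(self):
        df = simple_iv_frame(n=30_000, seed=3, confounded=True)
        m = mva_adjusted(df, req())
        t = tsls(df, req())
        assert abs(m.beta - 0.5) > 3 * m.se  # biased away from truth
        assert abs(t.beta - 0.5) < 3 * t.se


class TestTsls:
    def test_equals_wald_ratio_oracle(self):
        df = simple_iv_frame(seed=4)
        est = tsls(df, req())
        assert est.beta == pytest.approx(wald_oracle(df, "y", "x", "z"), rel=1e-10)

    def test_perfect_instrument_equals_ols(self):
        df = simple_iv_frame(seed=5)
        df["zx"] = df["x"]
        iv = tsls(df, req(instruments=("zx",)))
        ols = mva_adjusted(df, req())
        assert iv.beta == pytest.approx(ols.beta, rel=1e-10)

    def test_matches_statsmodels_iv2sls(self):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        df = simple_iv_frame(n=2000, seed=6)
        df["c"] = np.random.default_rng(7).normal(size=len(df))
        est = tsls(df, req(covariates=("c",)))
        X = np.column_stack([df["x"], df["c"], np.ones(len(df))])
        Z = np.column_stack([df["z"], df["c"], np.ones(len(df))])
        ref = IV2SLS(df["y"].to_numpy(), X, instrument=Z).fit()
        assert est.beta == pytest.approx(ref.params[0], rel=1e-8)

    def test_constant_instrument_rejected(self):
        df = simple_iv_frame(seed=8)
        df["z0"] = 1.0
        with pytest.raises(DegenerateInstrumentError):
            tsls(df, req(instruments=("z0",)))

    def test_orthogonal_covariate_changes_little(self):
        df = simple_iv_frame(n=50_000, seed=9)
        df["noise_cov"] = np.random.default_rng(10).normal(size=len(df))
        a = tsls(df, req())
        b = tsls(df, req(covariates=("noise_cov",)))
        assert abs(a.beta - b.beta) < 0.01 * a.se

    def test_first_stage_f_attached(self):
        est = tsls(simple_iv_frame(seed=11), req())
        assert est.first_stage_f is not None and est.first_stage_f > 10


class TestAdditiveSmm:
    def test_wald_arithmetic_on_group_means(self):
        # groups (Z=1): Xbar=12, Ybar=0.30; (Z=0): Xbar=11, Ybar=0.35 -> psi = -0.05
        rows = []
        for z, xbar, ybar in [(1, 12.0, 0.30), (0, 11.0, 0.35)]:
            for i in range(20):
                rows.append({"z": z, "x": xbar + (i % 2 - 0.5), "y": ybar + (i % 2 - 0.5) * 0.1})
        df = pd.DataFrame(rows)
        est = additive_smm(df, req(scale="binary"))
        assert est.beta == pytest.approx(wald_oracle(df, "y", "x", "z"), rel=1e-10)

    def test_continuous_passthrough_equals_tsls(self):
        df = simple_iv_frame(seed=12)
        a = additive_smm(df, req())
        b = tsls(df, req())
        assert a.beta == pytest.approx(b.beta, rel=1e-10)

    def test_covariate_case_equals_tsls(self):
        df = simple_iv_frame(n=3000, seed=13)
        df["c"] = np.random.default_rng(14).normal(size=len(df))
        a = additive_smm(df, req(covariates=("c",)))
        b = tsls(df, req(covariates=("c",)))
        assert a.beta == pytest.approx(b.beta, rel=1e-8)

    def test_overidentified_runs_and_is_close_to_single(self):
        rng = np.random.default_rng(15)
        n = 20_000
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        x = 12 + 0.8 * z1 + 0.5 * z2 + rng.normal(size=n)
        p = np.clip(0.3 - 0.02 * (x - 12), 0, 1)
        y = (rng.uniform(size=n) < p).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "z1": z1, "z2": z2})
        est = additive_smm(df, req(instruments=("z1", "z2"), scale="binary"))
        assert est.beta == pytest.approx(-0.02, abs=3 * est.se)

    def test_risk_difference_reported_x100(self):
        df = simple_iv_frame(seed=16)
        est = additive_smm(df, req(scale="binary"))
        assert est.beta_display == pytest.approx(100 * est.beta)


class TestWaldRatio:
    def test_simple_ratio(self):
        assert wald_ratio(0.5, 0.1, 1.0, 0.05).beta == pytest.approx(0.5)

    def test_delta_method_limit_zero_first_stage_se(self):
        est = wald_ratio(0.5, 0.1, 1.0, 0.0)
        assert est.se == pytest.approx(0.1)

    def test_constructed_inverse(self):
        est = wald_ratio(-0.37 * 1.45, 0.02, 1.45, 0.03)
        assert est.beta == pytest.approx(-0.37)

    def test_zero_first_stage_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.5, 0.1, 0.0, 0.05)


class TestWithinFamily:
    @staticmethod
    def sib_frame(n_fam=4000, seed=0, dynastic=0.0, beta=0.5):
        rng = np.random.default_rng(seed)
        fam_score = rng.normal(size=n_fam)  # parental/dynastic component
        rows = []
        for k in range(2):
            z = fam_score[:, None].ravel() + rng.normal(size=n_fam)  # sib genotype
            x = 10 + 0.8 * z + rng.normal(size=n_fam)
            y = 2 + beta * x + dynastic * fam_score + rng.normal(size=n_fam)
            rows.append(pd.DataFrame({"family_id": np.arange(n_fam), "y": y, "x": x, "z": z}))
        return pd.concat(rows, ignore_index=True)

    def test_dynastic_bias_removed_within_family(self):
        df = self.sib_frame(seed=1, dynastic=1.0)
        pop = tsls(df, req())
        wf = within_family_tsls(df, req())
        assert abs(pop.beta - 0.5) > 3 * pop.se
        assert abs(wf.beta - 0.5) < 3 * wf.se

    def test_agrees_with_population_when_no_dynastic_effect(self):
        df = self.sib_frame(seed=2, dynastic=0.0)
        pop = tsls(df, req())
        wf = within_family_tsls(df, req())
        se = np.hypot(pop.se, wf.se)
        assert abs(pop.beta - wf.beta) < 3 * se

    def test_identical_siblings_degenerate(self):
        df = self.sib_frame(n_fam=50, seed=3)
        df["z"] = df.groupby("family_id")["z"].transform("mean")  # no within-fam variation
        with pytest.raises(DegenerateInstrumentError):
            within_family_tsls(df, req())


def test_missing_columns_raise_data_error():
    with pytest.raises(DataError):
        tsls(pd.DataFrame({"y": [1.0, 2.0]}), req())
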