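"""Binning rules and the per-bin Poisson/NB2 selection battery."""

import numpy as np
import pandas as pd
import pytest

from slcm import (
    CountDistributionSpec,
    MeasurementModelSelector,
    bin_and_dedupe,
    empirical_dispersion_summary,
    fit_bin_glm,
    marginal_kld,
    pearson_statistic,
    sample_count,
    select_measurement_model,
)
from slcm.measurement import BinFit


class TestBinning:
    def test_bin_codes(self):
        df = pd.DataFrame({
            "id": [1, 2, 3], "age_months": [18.0, 21.0, 69.0],
            "count": [1, 1, 1], "exposure": [50, 50, 50],
        })
        out = bin_and_dedupe(df, rng=np.random.default_rng(0))
        assert sorted(out.table["bin_t"]) == [0.0, 3.0, 51.0]

    def test_exposure_floor(self):
        df = pd.DataFrame({
            "id": range(6), "age_months": [20.0] * 6,
            "count": [1] * 6, "exposure": [24, 24, 30, 40, 25, 100],
        })
        out = bin_and_dedupe(df, rng=np.random.default_rng(0))
        assert len(out.table) == 4
        assert out.n_rejected_exposure == 2

    def test_within_bin_dedup_is_random_but_single(self):
        df = pd.DataFrame({
            "id": [7, 7], "age_months": [19.0, 20.5],
            "count": [3, 9], "exposure": [50, 60],
        })
        picks = set()
        for seed in range(20):
            out = bin_and_dedupe(df, rng=np.random.default_rng(seed))
            assert len(out.table) == 1
            assert out.table["bin_t"].iloc[0] == 0.0
            picks.add(int(out.table["count"].iloc[0]))
        assert picks == {3, 9}  # both records get picked under some seed

    def test_age_out_of_range_rejected_with_warning(self, caplog):
        df = pd.DataFrame({
            "id": [1, 2], "age_months": [17.0, 30.0],
            "count": [1, 1], "exposure": [50, 50],
        })
        with caplog.at_level("WARNING"):
            out = bin_and_dedupe(df, rng=np.random.default_rng(0))
        assert len(out.table) == 1
        assert out.n_rejected_age == 1
        assert any("age" in rec.message for rec in caplog.records)


class TestEmpiricalDispersion:
    def test_flags_from_arithmetic(self):
        df = pd.DataFrame({
            "id": range(6),
            "bin_t": [0.0] * 3 + [3.0] * 3,
            "count": [2, 2, 2, 0, 0, 12],
            "exposure": [50] * 6,
        })
        from slcm.measurement import BinnedData

        summ = empirical_dispersion_summary(BinnedData(df))
        under = summ[summ.bin_t == 0.0].iloc[0]
        over = summ[summ.bin_t == 3.0].iloc[0]
        assert under["mean"] == 2 and under["variance"] == 0 and under["flag"] == "underdispersed"
        assert over["mean"] == 4 and over["variance"] == 48 and over["flag"] == "overdispersed"

    def test_simulated_nb2_bin_flags_overdispersion(self):
        rng = np.random.default_rng(5)
        y = sample_count(5.0, CountDistributionSpec("nb2", 1.0), rng, size=500)
        df = pd.DataFrame({"id": range(500), "bin_t": 0.0, "count": y, "exposure": 100})
        from slcm.measurement import BinnedData

        summ = empirical_dispersion_summary(BinnedData(df))
        assert summ["flag"].iloc[0] == "overdispersed"


class TestBinGLM:
    def test_saturated_single_record(self):
        df = pd.DataFrame({"id": [1], "bin_t": [0.0], "count": [4], "exposure": [200]})
        fit = fit_bin_glm(df, "poisson")
        assert fit.intercept == pytest.approx(np.log(4 / 200), abs=1e-8)

    def test_poisson_matches_independent_irls(self, toy_bin):
        fit = fit_bin_glm(toy_bin, "poisson")
        # independent Newton-scoring oracle for the offset-only intercept
        y = toy_bin["count"].to_numpy(float)
        u = toy_bin["exposure"].to_numpy(float)
        a = 0.0
        for _ in range(50):
            mu = u * np.exp(a)
            step = (y - mu).sum() / mu.sum()
            a += step
            if abs(step) < 1e-12:
                break
        assert fit.intercept == pytest.approx(a, abs=1e-8)

    def test_nb2_dispersion_recovery(self):
        rng = np.random.default_rng(11)
        n = 2000
        u = rng.integers(25, 300, size=n)
        mu = u * np.exp(-3.0)
        y = np.array([sample_count(m, CountDistributionSpec("nb2", 0.5), rng) for m in mu])
        df = pd.DataFrame({"id": range(n), "bin_t": 0.0, "count": y, "exposure": u})
        fit = fit_bin_glm(df, "nb2")
        assert fit.converged
        # MLE SE of phi is not returned; 3x a conservative SE bound
        assert abs(fit.dispersion - 0.5) < 0.15

    def test_all_zero_counts_degenerate(self):
        df = pd.DataFrame({"id": range(5), "bin_t": 0.0, "count": 0, "exposure": 50})
        with pytest.warns(UserWarning, match="unidentified"):
            fit = fit_bin_glm(df, "nb2")
        assert fit.dispersion == 0.0

    def test_information_criterion_identities(self, toy_bin):
        for fam in ("poisson", "nb2"):
            fit = fit_bin_glm(toy_bin, fam)
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)
            assert fit.bic == pytest.approx(-2 * fit.loglik + fit.k * np.log(fit.n))
        assert fit_bin_glm(toy_bin, "nb2").k - fit_bin_glm(toy_bin, "poisson").k == 1


class TestPearson:
    def test_zero_for_perfect_fit(self):
        df = pd.DataFrame({"id": [1], "bin_t": [0.0], "count": [4], "exposure": [200]})
        fit = fit_bin_glm(df, "poisson")
        stat, df_ = pearson_statistic(fit, df)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df_ == 0

    def test_calibration_and_inflation(self):
        """Pearson/df near 1 under the true NB2 model; inflated when a
        Poisson model is fit to overdispersed counts (200 replications)."""
        rng = np.random.default_rng(3)
        n, phi = 1000, 1.0
        within, inflated = 0, 0
        reps = 200
        for _ in range(reps):
            u = rng.integers(25, 300, size=n)
            mu = u * np.exp(-3.5)
            lam = rng.gamma(1.0 / phi, phi * mu)
            y = rng.poisson(lam)
            df = pd.DataFrame({"id": range(n), "bin_t": 0.0, "count": y, "exposure": u})
            nb2 = fit_bin_glm(df, "nb2")
            ratio = nb2.pearson / nb2.df
            within += 0.85 <= ratio <= 1.15
            pois = fit_bin_glm(df, "poisson")
            inflated += (pois.pearson / pois.df) > 1.5
        assert within >= 0.90 * reps
        assert inflated >= 0.95 * reps


class TestKLD:
    def test_direct_summation_oracle(self):
        # two-point empirical pmf (half at 0, half at 2) against the
        # marginal of a fitted Poisson(mu=1): sum p*log(p/q) by hand
        fit = BinFit(bin_t=0.0, family="poisson", intercept=0.0, dispersion=None,
                     loglik=0.0, n=2, k=1, pearson=0.0, df=1, aic=0.0, bic=0.0, kld=0.0)
        records = pd.DataFrame({"count": [0, 2], "exposure": [1.0, 1.0]})
        kld = marginal_kld(fit, records)
        q0, q2 = np.exp(-1.0), np.exp(-1.0) / 2.0
        oracle = 0.5 * np.log(0.5 / q0) + 0.5 * np.log(0.5 / q2)
        assert kld == pytest.approx(oracle, abs=1e-12)

    def test_nonnegative(self, toy_bin):
        for fam in ("poisson", "nb2"):
            assert fit_bin_glm(toy_bin, fam).kld >= 0.0


class TestSelection:
    def test_nb2_data_recommends_nb2(self, dataset300):
        sel = MeasurementModelSelector(random_state=0).fit(dataset300)
        assert sel.recommendation_ == "nb2"
        assert sel.report_.detail["aic_wins_nb2"] > sel.report_.n_bins / 2

    def test_poisson_data_rarely_prefers_nb2(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(900):
            t = rng.choice(np.arange(0.0, 54.0, 3.0))
            u = int(rng.integers(25, 300))
            mu = u * np.exp(-4.0 + 0.02 * t)
            rows.append({"id": i, "age_months": 18 + t, "count": rng.poisson(mu), "exposure": u})
        sel = MeasurementModelSelector(random_state=0).fit(pd.DataFrame(rows))
        frac_nb2 = sel.report_.detail["aic_wins_nb2"] / sel.report_.n_bins
        assert frac_nb2 <= 0.35

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            select_measurement_model([])
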