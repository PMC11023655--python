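"""Phenotype derivation, standardisation and burden regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bwburden as b
from bwburden.assoc import BurdenFitError

from conftest import carrier_vector, phenotype_only_table


class TestDeriveOwnBw:
    def test_visit_mean(self):
        assert b.derive_own_bw([3.2, 3.4]).value_kg == pytest.approx(3.3)

    @pytest.mark.parametrize(
        "reports,multiple,reason",
        [
            ([2.0, 3.5], False, "discordant"),   # range > 1 kg
            ([0.9], False, "extreme"),           # < 1 kg
            ([7.0], False, "extreme"),           # upper bound inclusive
            ([3.3], True, "multiple_birth"),
            ([float("nan")], False, "invalid"),
        ],
    )
    def test_exclusions(self, reports, multiple, reason):
        out = b.derive_own_bw(reports, multiple)
        assert out.excluded and out.reason == reason

    def test_discordance_boundary_dialects(self):
        strict = b.PhenotypeDerivationRules()
        inclusive = b.PhenotypeDerivationRules(discordance_inclusive=True)
        assert not b.derive_own_bw([3.0, 4.0], rules=strict).excluded
        assert b.derive_own_bw([3.0, 4.0], rules=inclusive).excluded

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            b.derive_own_bw([])


class TestDeriveOffspringBw:
    def test_hospital_preferred(self):
        out = b.derive_offspring_bw([("hospital", 3.1), ("self", 3.6)])
        assert out.value_kg == pytest.approx(3.1)

    def test_self_only_mean(self):
        out = b.derive_offspring_bw([("self", 3.0), ("self", 3.2)])
        assert out.value_kg == pytest.approx(3.1)

    def test_extreme_hospital_record_excluded(self):
        out = b.derive_offspring_bw([("hospital", 0.8)])
        assert out.excluded and out.reason == "extreme"


class TestStandardize:
    def test_two_point(self):
        np.testing.assert_allclose(
            b.standardize([2.0, 4.0]), [-1 / np.sqrt(2), 1 / np.sqrt(2)]
        )

    def test_idempotent(self):
        x = np.array([1.0, 2.0, 5.0, -3.0])
        np.testing.assert_allclose(b.standardize(b.standardize(x)), b.standardize(x))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            b.standardize([3.0, 3.0, 3.0])


class TestFitBurden:
    def test_matches_normal_equations(self):
        """8-row toy fit equals the hand-solved least-squares solution."""
        ids = [f"S{i}" for i in range(8)]
        carrier = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        noise = np.array([0.3, -0.1, 0.2, -0.4, 0.1, -0.2, 0.15, -0.05])
        y = 2.0 * carrier + noise
        res = b.fit_burden(carrier_vector(carrier, ids), phenotype_only_table(y, ids))
        X = np.column_stack([np.ones(8), carrier])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.beta_sd == pytest.approx(beta[1], abs=1e-12)
        resid = y - X @ beta
        sigma2 = resid @ resid / (8 - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.se == pytest.approx(se, abs=1e-12)
        t = beta[1] / se
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), df=6), rel=1e-10)

    def test_orthogonal_carrier_near_null(self):
        rng = np.random.default_rng(3)
        n = 400
        ids = [f"S{i}" for i in range(n)]
        carrier = (rng.random(n) < 0.1).astype(int)
        y = rng.normal(size=n)
        res = b.fit_burden(carrier_vector(carrier, ids), phenotype_only_table(y, ids))
        assert abs(res.beta_sd) < 0.5
        assert res.p > 0.001

    def test_missing_carrier_complete_case(self):
        ids = [f"S{i}" for i in range(10)]
        status = np.array([-1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y = np.arange(10, dtype=float)
        res = b.fit_burden(carrier_vector(status, ids), phenotype_only_table(y, ids))
        assert res.n == 9
        assert res.n_carriers == 3

    def test_zero_variance_carrier_rejected(self):
        ids = [f"S{i}" for i in range(10)]
        with pytest.raises(BurdenFitError):
            b.fit_burden(
                carrier_vector(np.zeros(10, dtype=int), ids),
                phenotype_only_table(np.arange(10.0), ids),
            )

    def test_null_type_i_error_calibrated(self):
        """Under no planted effect, rejections at alpha=0.05 fall inside the
        exact binomial 95% interval (600 null genes)."""
        rng = np.random.default_rng(12)
        n, reps = 300, 600
        ids = [f"S{i}" for i in range(n)]
        rejections = 0
        for _ in range(reps):
            carrier = (rng.random(n) < 0.05).astype(int)
            if carrier.sum() == 0:
                carrier[0] = 1
            y = rng.normal(size=n)
            res = b.fit_burden(carrier_vector(carrier, ids), phenotype_only_table(y, ids))
            rejections += res.p < 0.05
        lo = stats.binom.ppf(0.025, reps, 0.05)
        hi = stats.binom.ppf(0.975, reps, 0.05)
        assert lo <= rejections <= hi

    def test_orthogonal_covariate_leaves_beta(self):
        rng = np.random.default_rng(4)
        n = 200
        ids = [f"S{i}" for i in range(n)]
        carrier = (rng.random(n) < 0.2).astype(int)
        y = 0.5 * carrier + rng.normal(size=n)
        base = b.fit_burden(carrier_vector(carrier, ids), phenotype_only_table(y, ids))
        cov = rng.normal(size=n)
        cov = cov - np.mean(cov)
        # orthogonalise against carrier and intercept
        X = np.column_stack([np.ones(n), carrier])
        cov = cov - X @ np.linalg.lstsq(X, cov, rcond=None)[0]
        df = pd.DataFrame({"phenotype": y, "z": cov}, index=ids)
        table = b.AnalysisTable(df, "fetal", ["z"])
        res = b.fit_burden(carrier_vector(carrier, ids), table)
        assert res.beta_sd == pytest.approx(base.beta_sd, abs=1e-10)


class TestSexStratified:
    def _setup(self, rng, beta_f=-1.0, beta_m=0.0, n=3000):
        ids = [f"S{i}" for i in range(n)]
        sex = pd.Series(np.where(rng.random(n) < 0.5, "F", "M"), index=ids)
        carrier = (rng.random(n) < 0.05).astype(int)
        beta = np.where(sex == "F", beta_f, beta_m)
        y = beta * carrier + rng.normal(size=n)
        return ids, sex, carrier, y

    def test_recovers_sex_specific_effects(self):
        rng = np.random.default_rng(21)
        ids, sex, carrier, y = self._setup(rng, beta_f=-1.7, beta_m=0.0, n=8000)
        table = phenotype_only_table(y, ids)
        res = b.sex_stratified_fit(carrier_vector(carrier, ids), table, sex)
        assert res["female"].beta_sd == pytest.approx(-1.7, abs=3 * res["female"].se)
        assert res["male"].beta_sd == pytest.approx(0.0, abs=3 * res["male"].se)

    def test_stratum_without_carriers_not_estimable(self):
        ids = [f"S{i}" for i in range(40)]
        sex = pd.Series(["F"] * 20 + ["M"] * 20, index=ids)
        carrier = np.array([1] * 3 + [0] * 37)  # all carriers female
        y = np.random.default_rng(0).normal(size=40)
        res = b.sex_stratified_fit(carrier_vector(carrier, ids),
                                   phenotype_only_table(y, ids), sex)
        assert res["female"] is not None
        assert res["male"] is None


class TestThresholds:
    def test_exome_wide_levels(self):
        assert b.bonferroni_threshold(16735 + 13684) == pytest.approx(1.64e-6, rel=5e-3)
        assert b.bonferroni_threshold(17745 + 13968) == pytest.approx(1.58e-6, rel=5e-3)
        assert b.bonferroni_threshold(1) == 0.05

    def test_strictly_decreasing(self):
        vals = [b.bonferroni_threshold(n) for n in (1, 10, 100, 1000)]
        assert all(a > bb for a, bb in zip(vals, vals[1:]))

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            b.bonferroni_threshold(0)


class TestBenjaminiHochberg:
    def test_single_value_unchanged(self):
        adj, rej = b.bh_adjust([0.04])
        assert adj[0] == pytest.approx(0.04)
        assert rej[0]

    def test_step_up_recursion(self):
        adj, _ = b.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        adj, rej = b.bh_adjust([1.0, 1.0, 1.0])
        assert (adj == 1.0).all() and not rej.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            b.bh_adjust([0.0, 0.5])
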