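import numpy as np
import pytest
from scipy import stats as sps

import mbscore as m
from mbscore.errors import ValidationError


@pytest.fixture(scope="module")
def scored(small_cohort, reference_model):
    cohort, _ = small_cohort
    return cohort, m.score_patients(reference_model, cohort)


class TestBCaInterval:
    def test_reduces_to_percentile_when_symmetric(self):
        """With z0 = 0 (median-unbiased replicates) and a = 0 (no jackknife)
        the BCa interval is exactly the percentile interval."""
        reps = np.linspace(-1.0, 1.0, 1001)  # symmetric around theta_hat = 0
        lo, hi = m.bca_interval(reps, 0.0, None)
        plo, phi = np.quantile(reps, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=1e-12)
        assert hi == pytest.approx(phi, abs=1e-12)

    def test_constant_replicates_degenerate(self):
        lo, hi = m.bca_interval(np.full(100, 0.7), 0.7, None)
        assert lo == hi == 0.7

    def test_all_nan_replicates(self):
        lo, hi = m.bca_interval(np.full(10, np.nan), 0.5, None)
        assert np.isnan(lo) and np.isnan(hi)

    def test_bias_correction_shifts_interval(self):
        """Replicates mostly above theta_hat pull the interval downward
        relative to the percentile interval (negative z0)."""
        rng = np.random.default_rng(1)
        reps = rng.normal(0.3, 1.0, 5000)
        lo, hi = m.bca_interval(reps, 0.0, None)
        plo, phi = np.quantile(reps, [0.025, 0.975])
        assert lo < plo and hi < phi

    def test_known_acceleration_example(self):
        """BCa on the sample mean with skewed data: interval is contained in
        the replicate range and covers the estimate."""
        rng = np.random.default_rng(2)
        x = rng.exponential(1.0, 60)
        theta = x.mean()
        reps = np.array(
            [x[rng.integers(0, 60, 60)].mean() for _ in range(2000)]
        )
        jack = np.array([np.delete(x, i).mean() for i in range(60)])
        lo, hi = m.bca_interval(reps, theta, jack)
        assert reps.min() <= lo < theta < hi <= reps.max()


class TestBootstrapKM:
    def test_summary_structure_and_bounds(self, scored):
        cohort, assign = scored
        summ = m.bootstrap_km(cohort, assign, R=200, seed=3)
        tab = summ.table()
        assert set(summ.tiers) == {"favourable", "intermediate", "adverse"}
        assert len(tab) == 3 * 2
        for _, row in tab.iterrows():
            if np.isnan(row["survival"]):
                continue
            assert 0.0 <= row["ci_lower"] <= row["survival"] + 1e-9
            assert row["survival"] - 1e-9 <= row["ci_upper"] <= 1.0
        assert all(0.0 <= p <= 1.0 for p in summ.cross_tier_p.values())

    def test_tiers_ordered_by_risk(self, scored):
        cohort, assign = scored
        summ = m.bootstrap_km(cohort, assign, R=200, seed=3)
        for h in (24.0, 36.0):
            s = summ.original[h]
            assert s["favourable"] > s["intermediate"] > s["adverse"]

    def test_seed_reproducibility(self, scored):
        cohort, assign = scored
        a = m.bootstrap_km(cohort, assign, R=150, seed=9).table()
        b = m.bootstrap_km(cohort, assign, R=150, seed=9).table()
        assert a.equals(b)
        c = m.bootstrap_km(cohort, assign, R=150, seed=10).table()
        assert not a.equals(c)

    def test_small_R_warns(self, scored):
        cohort, assign = scored
        with pytest.warns(UserWarning, match="unstable"):
            m.bootstrap_km(cohort, assign, R=50, seed=1)

    def test_single_tier_rejected(self, small_cohort):
        cohort, _ = small_cohort
        assign = m.RiskAssignment(
            patient_ids=cohort.patient_ids,
            scores=np.zeros(cohort.n, dtype=int),
            tiers=["favourable"] * cohort.n,
        )
        with pytest.raises(ValidationError, match="two tiers"):
            m.bootstrap_km(cohort, assign, R=150)


class TestCompareAUCBootstrap:
    def test_self_comparison_degenerate(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.normal(size=100)
        res = m.compare_auc_bootstrap(y, s, s, R=500, seed=4)
        assert res.delta == 0.0
        assert res.ci_lower == res.ci_upper == 0.0
        assert res.p_value == 1.0

    def test_antisymmetry(self, rng):
        y = rng.integers(0, 2, 120)
        y[:2] = [0, 1]
        a = y + rng.normal(0, 1.0, 120)
        b = rng.normal(size=120)
        r1 = m.compare_auc_bootstrap(y, a, b, R=400, seed=7)
        r2 = m.compare_auc_bootstrap(y, b, a, R=400, seed=7)
        assert r1.delta == pytest.approx(-r2.delta)
        assert r1.ci_lower == pytest.approx(-r2.ci_upper)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_clear_difference_detected(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        good = y + rng.normal(0, 0.6, n)
        noise = rng.normal(size=n)
        res = m.compare_auc_bootstrap(y, good, noise, R=1000, seed=5)
        assert res.delta > 0.2
        assert res.ci_lower > 0.0
        assert res.p_value == pytest.approx(1.0 / 1000)  # floored at 1/R

    def test_p_value_floor(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        s = y.astype(float)  # perfect
        res = m.compare_auc_bootstrap(y, s, rng.normal(size=60), R=200, seed=6)
        assert res.p_value >= 1.0 / 200

    def test_replicate_auc_identity(self, rng):
        """The vectorized row-wise AUC equals binary_auc row by row."""
        from mbscore.validate import _rowwise_auc

        for _ in range(20):
            n = int(rng.integers(10, 50))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n), 1)
            got = _rowwise_auc(y[None, :], s[None, :])[0]
            assert got == pytest.approx(m.binary_auc(y, s).auc, abs=1e-12)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValidationError):
            m.compare_auc_bootstrap([0, 1, 1], [0.1, 0.2], [0.1, 0.2, 0.3])


class TestFinalMultivariable:
    def test_recovers_generative_effects(self):
        """At n=800 the adverse-tier log HR and the age effect land near
        their generative values."""
        cohort, truth = m.simulate_cohort(m.SimulationConfig(n_patients=800, seed=21))
        comps = tuple(
            m.MBSComponent(gene=g, cutpoint=c, direction=d)
            for g, (c, d) in truth.cutpoint_map().items()
        )
        model = m.MBSModel(components=comps)
        assign = m.score_patients(model, cohort)
        res = m.final_multivariable(cohort, assign)
        beta = dict(zip(res.fit.names, res.fit.beta))
        assert beta["mbs_adverse"] > beta["mbs_intermediate"] > 0.0
        # expected adverse effect ~ E[beta * count | count >= 2] - 0 ~ 1.8
        assert 1.2 < beta["mbs_adverse"] < 2.6
        assert abs(beta["age"] - 0.03) < 0.02

    def test_ranking_sorted_by_wald(self, scored):
        cohort, assign = scored
        res = m.final_multivariable(cohort, assign)
        w = res.ranking["wald_chi2"].to_numpy()
        assert np.all(np.diff(w) <= 1e-12)
        assert set(res.ranking["covariate"]) == {
            "mbs_intermediate", "mbs_adverse", "age", "male", "ipssr_nonlow",
        }

    def test_empty_favourable_rejected(self, small_cohort):
        cohort, _ = small_cohort
        assign = m.RiskAssignment(
            patient_ids=cohort.patient_ids,
            scores=np.full(cohort.n, 2, dtype=int),
            tiers=["adverse"] * cohort.n,
        )
        with pytest.raises(ValidationError, match="favourable"):
            m.final_multivariable(cohort, assign)

    def test_monotone_tier_gets_profile_bound(self):
        """When no favourable-tier patient dies, the tier coefficients are
        monotone and a finite profile lower bound is reported."""
        cohort, truth = m.simulate_cohort(m.SimulationConfig(n_patients=150, seed=2))
        comps = tuple(
            m.MBSComponent(gene=g, cutpoint=c, direction=d)
            for g, (c, d) in truth.cutpoint_map().items()
        )
        assign = m.score_patients(m.MBSModel(components=comps), cohort)
        # censor every favourable-tier death to force the degenerate case
        fav = assign.tier_members("favourable")
        clin = []
        for r, is_fav in zip(cohort.clinical, fav):
            if is_fav and r.os_event == 1:
                r = m.ClinicalRecord(
                    patient_id=r.patient_id, os_time=r.os_time, os_event=0,
                    age=r.age, gender=r.gender, ipssr=r.ipssr,
                    group_label=r.group_label,
                )
            clin.append(r)
        cohort2 = m.Cohort(expression=cohort.expression, clinical=clin)
        with pytest.warns(UserWarning, match="monotone"):
            res = m.final_multivariable(cohort2, assign)
        flagged = [n for n, f in zip(res.fit.names, res.fit.monotone_flags) if f]
        assert flagged  # at least one tier indicator diverged
        for name in flagged:
            assert name in res.profile_lower
            assert res.profile_lower[name] < 15.0
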