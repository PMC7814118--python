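import numpy as np
import pytest

import mbscore as m
from mbscore.errors import UninformativeMarkerError, ValidationError

from _oracles import best_cutpoint_exhaustive, youden_at
from conftest import random_survival


def _marker_data(rng, n=60):
    """Expression weakly tied to death so the cutpoint is non-trivial."""
    v = rng.normal(size=n)
    t, d = random_survival(rng, n)
    # tilt: higher expression, earlier death
    order_v = np.argsort(v)
    order_t = np.argsort(-t)
    tilt = rng.random(n) < 0.4
    t2 = t.copy()
    t2[order_v[tilt]] = t[order_t[tilt]]
    return v, t2, d


class TestOptimalCutpoint:
    def test_matches_exhaustive_scan(self, rng):
        """Fast sort-based search agrees with the brute-force scan (metric
        value and tie-set membership) on 60 random datasets."""
        for _ in range(60):
            n = int(rng.integers(25, 80))
            v, t, d = _marker_data(rng, n)
            if d.sum() == 0:
                continue
            res = m.optimal_cutpoint(v, t, d, gene="G")
            best, cand = best_cutpoint_exhaustive(v, d, 0.10)
            assert res.metric_value == pytest.approx(best, abs=1e-10)
            assert any(res.cutpoint == pytest.approx(c, abs=1e-10) for c in cand)

    def test_perfect_separator(self, rng):
        n = 40
        d = np.array([1] * 20 + [0] * 20)
        v = d * 10.0 + rng.random(n)  # deaths all above 9, survivors below 1
        t = np.where(d == 1, rng.exponential(5.0, n), rng.exponential(50.0, n)) + 0.1
        res = m.optimal_cutpoint(v, t, d)
        assert res.metric_value == pytest.approx(1.0)
        assert 1.0 < res.cutpoint < 10.0
        assert res.direction == m.HIGH_IS_RISK

    def test_direction_flips_with_sign(self, rng):
        n = 40
        d = np.array([1] * 20 + [0] * 20)
        v = d * 10.0 + rng.random(n)
        t = np.where(d == 1, rng.exponential(5.0, n), rng.exponential(50.0, n)) + 0.1
        hi = m.optimal_cutpoint(v, t, d)
        lo = m.optimal_cutpoint(-v, t, d)
        assert hi.direction == m.HIGH_IS_RISK
        assert lo.direction == m.LOW_IS_RISK
        assert lo.cutpoint == pytest.approx(-hi.cutpoint)

    def test_monotone_transform_invariance(self, rng):
        """Youden depends only on the induced split, so any strictly
        increasing transform preserves the chosen split."""
        v, t, d = _marker_data(rng, 50)
        r1 = m.optimal_cutpoint(v, t, d)
        r2 = m.optimal_cutpoint(np.exp(v), t, d)
        np.testing.assert_array_equal(
            (v > r1.cutpoint), (np.exp(v) > r2.cutpoint)
        )
        assert r1.metric_value == pytest.approx(r2.metric_value)
        assert r1.direction == r2.direction

    def test_min_group_frac_respected(self, rng):
        for frac in (0.10, 0.25):
            v, t, d = _marker_data(rng, 60)
            res = m.optimal_cutpoint(v, t, d, min_group_frac=frac)
            assert min(res.n_high, res.n_low) >= int(np.floor(frac * 60))
            assert res.n_high + res.n_low == 60

    def test_concordance_metric(self, rng):
        v, t, d = _marker_data(rng, 50)
        res = m.optimal_cutpoint(v, t, d, metric="concordance")
        assert res.metric == "concordance"
        assert 0.5 <= res.metric_value <= 1.0

    def test_small_sample_and_no_events_rejected(self, rng):
        v = rng.normal(size=10)
        with pytest.raises(ValidationError, match="20"):
            m.optimal_cutpoint(v, np.ones(10), np.ones(10, dtype=int))
        v = rng.normal(size=30)
        with pytest.raises(ValidationError, match="events"):
            m.optimal_cutpoint(v, np.ones(30), np.zeros(30, dtype=int))

    def test_constant_marker_uninformative(self):
        t = np.arange(1.0, 31.0)
        d = np.ones(30, dtype=int)
        with pytest.raises(UninformativeMarkerError, match="constant"):
            m.optimal_cutpoint(np.full(30, 5.0), t, d)

    def test_tie_break_prefers_balance_then_smaller(self):
        """All labels identical in their metric: balanced split wins."""
        v = np.arange(40, dtype=float)
        d = np.array([1, 0] * 20)
        t = np.linspace(1, 40, 40)
        # alternating labels: Youden is maximized at several cuts; the pick
        # must be among the exhaustive-scan argmax set and admissible
        res = m.optimal_cutpoint(v, t, d)
        best, cand = best_cutpoint_exhaustive(v, d, 0.10)
        ok = [c for c in cand]
        assert any(res.cutpoint == pytest.approx(c) for c in ok)


@pytest.fixture(scope="module")
def screened(small_cohort):
    cohort, truth = small_cohort
    cuts = {
        g: m.optimal_cutpoint(
            cohort.expression.gene_values(g), cohort.times, cohort.events, gene=g
        )
        for g in cohort.expression.gene_ids
    }
    table = m.screen_genes(cohort, cohort.expression.gene_ids, cuts)
    return cohort, truth, table


class TestScreening:

    def test_two_stage_gating_contract(self, screened):
        _, _, table = screened
        f = table.frame
        # stage 2 never ran when stage 1 failed
        failed1 = f["uni_p"] > table.alpha
        assert f.loc[failed1, "multi_p"].isna().all()
        assert not f.loc[failed1, "selected"].any()
        # selected implies both stages passed
        sel = f["selected"]
        assert (f.loc[sel, "uni_p"] <= table.alpha).all()
        assert (f.loc[sel, "multi_p"] <= table.alpha).all()
        assert (f.loc[sel, "direction"].isin([m.HIGH_IS_RISK, m.LOW_IS_RISK])).all()

    def test_true_genes_recovered_at_n200(self, screened):
        """All five true genes pass screening in this signal-rich cohort."""
        _, truth, table = screened
        assert set(truth.genes) <= set(table.selected_genes)

    def test_missing_cutpoint_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValidationError, match="cutpoint"):
            m.screen_genes(cohort, ["PKM"], {})

    def test_tuple_cutpoints_accepted(self, small_cohort):
        cohort, truth = small_cohort
        cuts = {g: (c, d) for g, (c, d) in truth.cutpoint_map().items()}
        table = m.screen_genes(cohort, truth.genes, cuts)
        assert len(table.frame) == 5

    def test_build_and_model_consistency(self, screened):
        _, _, table = screened
        model = m.build_mbs(table)
        assert model.genes == table.selected_genes  # alphabetical both sides
        for comp in model.components:
            row = table.frame.loc[table.frame["gene"] == comp.gene].iloc[0]
            assert comp.cutpoint == row["cutpoint"]
            assert comp.direction == row["direction"]

    def test_build_with_nothing_selected(self, screened):
        _, _, table = screened
        empty = m.ScreeningTable(
            frame=table.frame.assign(selected=False),
            alpha=table.alpha,
            n_complete=table.n_complete,
            n_dropped=table.n_dropped,
        )
        with pytest.raises(ValidationError, match="no genes"):
            m.build_mbs(empty)


class TestScoring:
    def test_score_counts_risk_sides_exactly(self, small_cohort, reference_model):
        cohort, truth = small_cohort
        assign = m.score_patients(reference_model, cohort)
        np.testing.assert_array_equal(assign.scores, truth.risk_counts)

    def test_tier_mapping_exhaustive(self, small_cohort, reference_model):
        cohort, _ = small_cohort
        assign = m.score_patients(reference_model, cohort)
        for s, tier in zip(assign.scores, assign.tiers):
            expected = "favourable" if s == 0 else ("intermediate" if s == 1 else "adverse")
            assert tier == expected

    def test_monotonicity_in_risk_indicators(self, small_cohort, reference_model):
        """Pushing one gene across its cutpoint to the risky side can only
        increase the score by exactly 1."""
        cohort, truth = small_cohort
        base = m.score_patients(reference_model, cohort).scores
        comp = reference_model.components[0]
        frame = cohort.expression.frame.copy()
        v = frame.loc[comp.gene].to_numpy()
        risky = comp.as_cutpoint().risk_indicator(v).astype(bool)
        # move every non-risky patient across the cutpoint
        shift = 1.0 if comp.direction == m.HIGH_IS_RISK else -1.0
        v2 = np.where(risky, v, comp.cutpoint + shift * 0.5)
        frame.loc[comp.gene] = v2
        cohort2 = m.Cohort(
            expression=m.ExpressionMatrix(frame), clinical=cohort.clinical
        )
        bumped = m.score_patients(reference_model, cohort2).scores
        np.testing.assert_array_equal(bumped, base + (~risky).astype(int))

    def test_missing_model_gene_rejected(self, small_cohort):
        cohort, _ = small_cohort
        model = m.MBSModel(
            components=(
                m.MBSComponent("NOT_A_GENE", 1.0, m.HIGH_IS_RISK),
                m.MBSComponent("PKM", 1.0, m.HIGH_IS_RISK),
            )
        )
        with pytest.raises(ValidationError, match="NOT_A_GENE"):
            m.score_patients(model, cohort)

    def test_tier_table_percent_convention(self):
        """28/60/71 of 159 prints as 18/38/44 (largest tier absorbs the
        rounding residual so the column totals 100)."""
        ids = [f"P{i}" for i in range(159)]
        scores = np.array([0] * 28 + [1] * 60 + [2] * 71)
        tiers = ["favourable"] * 28 + ["intermediate"] * 60 + ["adverse"] * 71
        tab = m.tier_table(
            m.RiskAssignment(patient_ids=ids, scores=scores, tiers=tiers)
        )
        got = dict(zip(tab["tier"], tab["percent"]))
        assert got == {"favourable": 18, "intermediate": 38, "adverse": 44}
        assert tab["percent"].sum() == 100
        assert dict(zip(tab["tier"], tab["n"])) == {
            "favourable": 28, "intermediate": 60, "adverse": 71,
        }

    def test_tier_table_always_sums_to_100(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 200))
            scores = rng.integers(0, 5, n)
            tiers = [m.TierRule().tier(int(s)) for s in scores]
            tab = m.tier_table(
                m.RiskAssignment(
                    patient_ids=[str(i) for i in range(n)],
                    scores=scores,
                    tiers=tiers,
                )
            )
            assert tab["percent"].sum() == 100
            assert tab["n"].sum() == n
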