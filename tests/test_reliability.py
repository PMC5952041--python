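"""ICC, ANCOVA/EMM and partial-correlation behaviour.

The ICC and partial-correlation implementations are checked against
pingouin as an independent oracle; the implementations themselves are
built from the two-way ANOVA mean squares and residualization directly.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from smtract.phantom import simulate_group_table, simulate_rater_tables
from smtract.reliability import (
    ancova_gender,
    average_raters,
    group_report,
    icc_two_way,
    partial_correlation,
    reliability_report,
    validate_rater_table,
)


def _table(n=30, icc=0.8, seed=0, **kw):
    return simulate_rater_tables(n, icc, rng_seed=seed, **kw)


class TestICC:
    def test_perfect_agreement(self):
        tab = _table()
        tab2 = tab.copy()
        wide = tab2.pivot(index="subject", columns="rater", values="fa")
        tab2.loc[tab2.rater == 2, "fa"] = wide[1].to_numpy()  # rater2 := rater1
        assert np.isclose(icc_two_way(tab2, "fa").icc, 1.0)

    def test_constant_rater_offset_penalizes_agreement_only(self):
        """A large inter-rater bias lowers absolute agreement, not consistency."""
        tab = _table(n=40, icc=0.9, seed=3, metric_means={"fa": 0.25})
        tab.loc[tab.rater == 2, "fa"] += 0.2  # offset >> subject SD (0.025)
        agree = icc_two_way(tab, "fa", variant="agreement").icc
        consist = icc_two_way(tab, "fa", variant="consistency").icc
        assert agree < consist
        assert consist > 0.8
        # direct variance-component view: the offset sits in MSC only
        assert agree < 0.2

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        tab = _table(n=50, icc=0.9, seed=7)
        res = pg.intraclass_corr(
            data=tab, targets="subject", raters="rater", ratings="fa"
        ).set_index("Type")
        agree_key = "ICC2" if "ICC2" in res.index else "ICC(A,1)"
        consist_key = "ICC3" if "ICC3" in res.index else "ICC(C,1)"
        ours_a = icc_two_way(tab, "fa", variant="agreement")
        ours_c = icc_two_way(tab, "fa", variant="consistency")
        assert np.isclose(ours_a.icc, res.loc[agree_key, "ICC"], atol=1e-10)
        assert np.isclose(ours_c.icc, res.loc[consist_key, "ICC"], atol=1e-10)
        lo, hi = res.loc[agree_key, "CI95"]
        assert np.isclose(ours_a.ci95[0], lo, atol=5e-3)
        assert np.isclose(ours_a.ci95[1], hi, atol=5e-3)

    def test_affine_rescaling_invariance(self):
        tab = _table(n=40, icc=0.7, seed=9)
        r1 = icc_two_way(tab, "md").icc
        tab2 = tab.copy()
        tab2["md"] = tab2["md"] * 1e3 + 5.0
        assert np.isclose(icc_two_way(tab2, "md").icc, r1, atol=1e-12)

    def test_degenerate_between_subject_variance_flagged(self):
        tab = _table(n=20, icc=0.5, seed=1)
        tab["fa"] = np.tile([0.25, 0.26], 20)  # identical across subjects
        res = icc_two_way(tab, "fa")
        assert res.degenerate

    def test_ci_brackets_estimate(self):
        tab = _table(n=30, icc=0.6, seed=11)
        r = icc_two_way(tab, "rd")
        assert r.ci95[0] <= r.icc <= r.ci95[1]

    def test_malformed_table_rejected(self):
        tab = _table(n=10)
        with pytest.raises(ValueError, match="one row per rater"):
            validate_rater_table(pd.concat([tab, tab.iloc[:1]]))


class TestICCMonteCarlo:
    def test_recovery_and_coverage(self, icc_mc):
        """2000 reps at ICC 0.9, n=50: mean within 0.02, CI coverage ~95%."""
        estimates, covered = icc_mc
        assert abs(estimates.mean() - 0.9) < 0.02
        assert abs(covered.mean() - 0.95) < 0.02


class TestANCOVA:
    def test_emms_reduce_to_group_means_without_covariate_effects(self):
        rng = np.random.default_rng(4)
        n = 60
        gender = np.arange(n) % 2
        tab = pd.DataFrame(
            {
                "subject": np.arange(n),
                "fa": 0.25 + 0.01 * gender + rng.normal(0, 1e-6, n),
                "age": rng.normal(30, 10, n),
                "gender": gender,
                "etiv": rng.normal(1.4e6, 1e5, n),
            }
        )
        g = ancova_gender(tab, "fa")
        for lvl in (0, 1):
            grp = tab.loc[tab.gender == lvl, "fa"].mean()
            assert np.isclose(g.emm[lvl][0], grp, atol=1e-4)

    def test_forced_gender_effect_recovered(self):
        rng = np.random.default_rng(8)
        n = 40
        gender = np.arange(n) % 2
        tab = pd.DataFrame(
            {
                "subject": np.arange(n),
                "vol": 100.0 + 10.0 * gender + rng.normal(0, 1e-3, n),
                "age": rng.normal(30, 10, n),
                "gender": gender,
                "etiv": rng.normal(1.4e6, 1e5, n),
            }
        )
        g = ancova_gender(tab, "vol")
        assert np.isclose(g.emm[1][0] - g.emm[0][0], 10.0, atol=0.01)
        assert g.gender_p < 1e-6

    def test_published_summary_interval_arithmetic(self):
        """Printed group summaries reproduce under t(46) EMM arithmetic.

        With n = 50 and the gender+age+eTIV model (46 residual df), a total
        EMM of 129.971 mm^3 with SE 7.506 gives a 95% CI lower bound of
        114.862 -- and the total is the unweighted mean of the two gender
        EMMs (125.097, 134.844).
        """
        tcrit = st.t.ppf(0.975, 46)
        lower = 129.971 - tcrit * 7.506
        assert abs(lower - 114.862) < 5e-3
        assert abs((125.097 + 134.844) / 2 - 129.971) < 1e-3

    def test_rank_deficient_design_names_column(self):
        tab = simulate_group_table(30, rng_seed=2)
        tab["etiv"] = 3.0  # constant -> collinear with intercept
        with pytest.raises(ValueError, match="collinear"):
            ancova_gender(tab, "rd")

    def test_single_gender_rejected(self):
        tab = simulate_group_table(30, rng_seed=2)
        tab["gender"] = 1
        with pytest.raises(ValueError, match="gender"):
            ancova_gender(tab, "rd")

    def test_null_gender_type_I_error(self, ancova_null_mc):
        """1000 null reps: rejection rate 5% +/- 1.5%."""
        assert abs(ancova_null_mc.mean() - 0.05) < 0.015


class TestPartialCorrelation:
    def test_self_correlation_is_one(self):
        tab = simulate_group_table(40, rng_seed=5)
        tab["myage"] = tab["age"]
        r, p = partial_correlation(tab, "myage")
        assert np.isclose(r, 1.0)

    def test_control_signal_removed(self):
        """A metric equal to a control + noise has near-zero partial r."""
        rs = []
        for i in range(300):
            tab = simulate_group_table(50, rng_seed=40_000 + i)
            rng = np.random.default_rng(90_000 + i)
            tab["m"] = tab["etiv"] * 1e-6 + rng.normal(0, 0.01, len(tab))
            rs.append(partial_correlation(tab, "m")[0])
        assert abs(np.mean(rs)) < 0.05

    def test_no_controls_equals_pearson(self):
        tab = simulate_group_table(40, rng_seed=6, partial_r_age=0.5)
        r, _ = partial_correlation(tab, "rd", controls=())
        rp = st.pearsonr(tab["rd"], tab["age"]).statistic
        assert np.isclose(r, rp, atol=1e-12)

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        tab = simulate_group_table(50, rng_seed=3, partial_r_age=0.3)
        r, p = partial_correlation(tab, "rd")
        res = pg.partial_corr(data=tab, x="rd", y="age", covar=["gender", "etiv"])
        assert np.isclose(r, float(res["r"].iloc[0]), atol=1e-10)
        assert np.isclose(p, float(res.filter(like="p").iloc[0, 0]), atol=1e-10)

    def test_constant_residuals_rejected(self):
        tab = simulate_group_table(30, rng_seed=7)
        tab["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(tab, "flat")

    def test_recovery_and_power(self, partial_mc):
        """2000 reps at true partial r = 0.30, n = 50: mean within 0.02."""
        est, reject = partial_mc
        assert abs(est.mean() - 0.30) < 0.02
        # at this effect size the test rejects well above the 5% null rate,
        # consistent with a borderline-significant single-study detection
        assert 0.3 < reject.mean() < 0.9


class TestReports:
    def test_reliability_report_covers_all_metrics(self):
        tab = _table(n=20, icc=0.8, seed=12)
        rep = reliability_report(tab)
        assert len(rep) == 9
        assert ((rep["ci_lo"] <= rep["icc"]) & (rep["icc"] <= rep["ci_hi"])).all()

    def test_rater_averaging_precedes_group_stats(self):
        tab = _table(n=20, icc=0.8, seed=13)
        avg = average_raters(tab)
        assert len(avg) == 20
        wide = tab.pivot(index="subject", columns="rater", values="fa")
        assert np.allclose(avg["fa"], wide.mean(axis=1))
        rep = group_report(avg)
        assert set(rep["metric"]) == set(
            c for c in avg.columns if c not in ("subject", "age", "gender", "etiv")
        )
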