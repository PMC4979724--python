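import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from clinezone import (
    ClineData,
    ClineModelSpec,
    ClineParams,
    MCMCSettings,
    cline_loglik,
    constrained_fit,
    fit_cline_ml,
    reciprocal_constraint_test,
    stratified_subsample_analysis,
)
from clinezone.datasets import (
    constraint_test_inputs,
    credibility_interval_inputs,
    historical_cline_data,
    population_table,
    subsampling_mapping,
    transect_positions,
)
from clinezone.hypothesis_tests import ConstraintTestResult

DEC = ClineModelSpec(tails="none", orientation="decreasing")
FAST = MCMCSettings(burnin=1500, generations=10_000, thin=20, chains=2)


class TestConstrainedFit:
    def test_nonbinding_constraint_leaves_likelihood_unchanged(self):
        d = historical_cline_data()
        uncon = fit_cline_ml(d, DEC, seed=0)
        con = constrained_fit(
            d, DEC, {"center": (200.0, 300.0)}, method="ml"
        )
        res = reciprocal_constraint_test(uncon, con)
        assert res.two_llr == pytest.approx(0.0, abs=1e-4)
        # k drops by one for the constrained parameter, so a non-binding
        # constraint improves AIC by exactly 2
        assert con.k == uncon.k - 1
        assert res.delta_aic == pytest.approx(2.0, abs=1e-4)

    def test_width_constraint_pins_to_interval_edge(self):
        # constraining the historical width to the recent credibility
        # interval forces the fit to the interval's lower edge
        d = historical_cline_data()
        interval = credibility_interval_inputs("recent", "none")["width"]
        con = constrained_fit(d, DEC, {"width": interval}, method="ml")
        assert con.params.width == pytest.approx(interval[0], rel=1e-4)
        # 1-D profile oracle: optimise the center at the pinned width
        prof = minimize_scalar(
            lambda c: -cline_loglik(
                d, ClineParams(center=c, width=interval[0]), DEC
            ),
            bounds=(0.0, 400.0), method="bounded",
        )
        assert con.lnl_max == pytest.approx(-prof.fun, abs=1e-4)
        uncon = fit_cline_ml(d, DEC, seed=0)
        assert con.lnl_max < uncon.lnl_max - 20.0

    def test_degenerate_interval_fixes_parameter(self):
        d = historical_cline_data()
        con = constrained_fit(d, DEC, {"width": (15.0, 15.0)}, method="ml")
        assert con.params.width == 15.0

    def test_interval_outside_prior_support_rejected(self):
        d = historical_cline_data()
        with pytest.raises(ValueError, match="outside the prior support"):
            constrained_fit(d, DEC, {"width": (-5.0, 10.0)}, method="ml")

    def test_mismatched_data_rejected(self):
        d = historical_cline_data()
        other = ClineData(["a", "b"], [0, 100], [1.0, 0.0], [5, 5])
        uncon = fit_cline_ml(other, DEC, seed=0)
        con = constrained_fit(d, DEC, {"center": (250.0, 260.0)},
                              method="ml")
        with pytest.raises(ValueError, match="same underlying data"):
            reciprocal_constraint_test(uncon, con)

    def test_shrinking_interval_never_improves_likelihood(self):
        d = historical_cline_data()
        lnls = []
        for hi in (400.0, 300.0, 250.0):
            con = constrained_fit(d, DEC, {"width": (200.0, hi)},
                                  method="ml")
            lnls.append(con.lnl_max)
        assert lnls[0] >= lnls[1] - 1e-6 >= lnls[2] - 2e-6


class TestPublishedArithmetic:
    def test_reproduces_published_constraint_statistics(self):
        # frozen printed 2LLR and delta-AIC for the width-constrained
        # analyses of each model/constraint row, in table order
        expected_width = [
            (-52.650, -50.650), (-52.655, -50.655), (-44.834, -42.834),
            (-44.839, -42.839), (-487.030, -485.030), (-487.114, -485.114),
            (-137.256, -135.256), (-137.283, -135.283),
        ]
        tbl = constraint_test_inputs()
        width_rows = tbl[tbl["constrained"] == "width"].reset_index(drop=True)
        for i, (two_llr, d_aic) in enumerate(expected_width):
            row = width_rows.loc[i]
            res = ConstraintTestResult(
                constrained_params=("width",),
                lnl_uncon=row["lnl_uncon"], aic_uncon=row["aic_uncon"],
                lnl_con=row["lnl_con"], aic_con=row["aic_con"],
            )
            assert res.two_llr == pytest.approx(two_llr, abs=2.5e-3)
            assert res.delta_aic == pytest.approx(d_aic, abs=2.5e-3)

    def test_center_and_both_rows_follow_the_same_identities(self):
        tbl = constraint_test_inputs()
        for row in tbl.itertuples():
            res = ConstraintTestResult(
                constrained_params=(row.constrained,),
                lnl_uncon=row.lnl_uncon, aic_uncon=row.aic_uncon,
                lnl_con=row.lnl_con, aic_con=row.aic_con,
            )
            assert res.two_llr == pytest.approx(
                2 * (row.lnl_con - row.lnl_uncon), abs=1e-9
            )
            assert res.delta_aic == pytest.approx(
                row.aic_uncon - row.aic_con, abs=1e-9
            )

    def test_identity_case(self):
        res = ConstraintTestResult(("center",), -3.0, 10.0, -3.0, 8.0)
        assert res.two_llr == 0.0
        assert res.delta_aic == 2.0


def _h_table(era_positions, n_of, p_of, jitter=0.0, seed=0):
    """Synthesise a per-individual h table with given population means."""
    rng = np.random.default_rng(seed)
    rows = []
    for pop, x in era_positions.items():
        n = n_of[pop]
        base = p_of(x)
        h = np.clip(base + jitter * rng.standard_normal(n), 0, 1)
        for i in range(n):
            rows.append({"individual": f"{pop}_{i}", "population": pop,
                         "h": h[i]})
    return pd.DataFrame(rows)


def _published_design():
    tbl = population_table()
    n_of = dict(zip(tbl["population_id"], tbl["n"]))
    hist_x = transect_positions("historical")
    recent_x = transect_positions("recent")
    return n_of, hist_x, recent_x


class TestStratifiedSubsampling:
    def test_matched_totals_follow_design_arithmetic(self):
        # per-pair N matching with the proximate east anchor (L) gives the
        # published era totals 77 (H6 = J) and 73 (H6 = K); the
        # pure-parental anchor (M, N = 5) gives 69 and 65
        n_of, hist_x, recent_x = _published_design()

        def q(x):
            return float(np.clip(1 - (x / 300.0), 0, 1))

        hist_h = _h_table(hist_x, n_of, q, seed=1)
        recent_h = _h_table(recent_x, n_of, q, seed=2)
        fast = MCMCSettings(burnin=300, generations=1500, thin=30, chains=1)

        expected = {
            ("proximate", "J"): 77, ("proximate", "K"): 73,
            ("pure_parental", "J"): 69, ("pure_parental", "K"): 65,
        }
        for (anchor, h6), total in expected.items():
            mapping = subsampling_mapping(anchor)
            mapping["H6"] = [h6]
            s = stratified_subsample_analysis(
                hist_h, hist_x, recent_h, recent_x, mapping,
                reps=1, seed=0, settings=fast,
            )
            assert s.replicates.loc[0, "matched_n"] == total

    def test_identical_eras_show_no_significant_differences(self):
        n_of, hist_x, recent_x = _published_design()
        truth = ClineParams(center=250.0, width=30.0)
        from clinezone import cline_mu

        def q(x):
            return float(cline_mu(x, truth, DEC))

        hist_h = _h_table(hist_x, n_of, q, jitter=0.05, seed=3)
        # identical dataset presented as the recent era at the same sites
        recent_h = hist_h.copy()
        mapping = {p: [p] for p in hist_x}
        s = stratified_subsample_analysis(
            hist_h, hist_x, recent_h, hist_x, mapping,
            reps=3, seed=4, settings=FAST,
        )
        assert all(v == 0 for v in s.tallies.values())

    def test_known_width_increase_detected(self):
        n_of, hist_x, recent_x = _published_design()
        narrow = ClineParams(center=250.0, width=15.0)
        wide = ClineParams(center=250.0, width=200.0)
        from clinezone import cline_mu

        hist_h = _h_table(
            hist_x, n_of, lambda x: float(cline_mu(x, narrow, DEC)), seed=5
        )
        recent_h = _h_table(
            recent_x, n_of, lambda x: float(cline_mu(x, wide, DEC)), seed=6
        )
        s = stratified_subsample_analysis(
            hist_h, hist_x, recent_h, recent_x,
            subsampling_mapping("pure_parental"),
            reps=3, seed=7, settings=FAST,
        )
        assert s.tallies["recent_sig_wider"] == 3
        assert s.tallies["recent_sig_narrower"] == 0
        assert (
            s.ranges["recent_width"][0]
            <= s.means["recent_width"]
            <= s.ranges["recent_width"][1]
        )

    def test_same_seed_reproduces_replicates(self):
        n_of, hist_x, recent_x = _published_design()
        hist_h = _h_table(hist_x, n_of, lambda x: 0.7, jitter=0.1, seed=8)
        recent_h = _h_table(recent_x, n_of, lambda x: 0.6, jitter=0.1, seed=9)
        fast = MCMCSettings(burnin=300, generations=2000, thin=20, chains=1)
        kw = dict(reps=2, seed=11, settings=fast)
        s1 = stratified_subsample_analysis(
            hist_h, hist_x, recent_h, recent_x,
            subsampling_mapping("proximate"), **kw,
        )
        s2 = stratified_subsample_analysis(
            hist_h, hist_x, recent_h, recent_x,
            subsampling_mapping("proximate"), **kw,
        )
        pd.testing.assert_frame_equal(s1.replicates, s2.replicates)
        assert s1.tallies == s2.tallies

    def test_empty_candidate_set_rejected(self):
        n_of, hist_x, recent_x = _published_design()
        hist_h = _h_table(hist_x, n_of, lambda x: 0.5, seed=1)
        recent_h = _h_table(recent_x, n_of, lambda x: 0.5, seed=1)
        mapping = subsampling_mapping("proximate")
        mapping["H3"] = []
        with pytest.raises(ValueError, match="empty candidate"):
            stratified_subsample_analysis(
                hist_h, hist_x, recent_h, recent_x, mapping, reps=1, seed=0
            )
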