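"""Incidence-table loading, Poisson likelihood, deviance, LR test."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msceapc import (
    IncidenceTable,
    PoissonLikelihood,
    convolved_hazard,
    deviance,
    lr_test,
    poisson_loglik,
    read_incidence_table,
    saturated_loglik,
)
from msceapc.synthetic import generate_incidence_table, make_py_schedule


def small_table(rows):
    df = pd.DataFrame(rows, columns=["age", "year", "cases", "py"])
    return IncidenceTable.from_dataframe(df)


class TestLoader:
    def test_cohort_exclusion_rule(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "age\tyear\tcases\tpy\n"
            "50\t2000\t1\t1000\n"   # cohort 1950: kept
            "30\t2000\t2\t1000\n"   # cohort 1970: excluded
            "20\t1975\t0\t1000\n"   # cohort 1955: kept
        )
        t = read_incidence_table(path)
        assert len(t) == 2
        assert t.n_excluded_cohort == 1
        assert set(t.data["cohort"]) == {1950, 1955}

    def test_zero_py_rows_dropped_with_count(self):
        t = small_table([(50, 2000, 0, 0.0), (51, 2000, 3, 500.0)])
        assert len(t) == 1
        assert t.n_dropped_zero_py == 1

    def test_duplicate_strata_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            small_table([(50, 2000, 1, 100.0), (50, 2000, 2, 100.0)])

    def test_cases_without_person_years_rejected(self):
        with pytest.raises(ValueError, match="zero person-years"):
            small_table([(50, 2000, 3, 0.0)])

    def test_comma_delimited_also_accepted(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("age,year,cases,py\n50,2000,1,1000\n")
        assert len(read_incidence_table(path)) == 1

    def test_roundtrip_write_read(self, tmp_path):
        t = small_table([(50, 2000, 1, 1000.0), (51, 2001, 2, 900.0)])
        p = tmp_path / "out.tsv"
        t.write(p)
        t2 = read_incidence_table(p)
        pd.testing.assert_frame_equal(t.data, t2.data)


class TestPoissonLoglik:
    def test_matches_reference_poisson_logpmf(self, flat_params):
        bp, tp = flat_params
        sched = make_py_schedule(range(1990, 1995), range(40, 60),
                                 base_py=5e4)
        table = generate_incidence_table(bp, tp, sched, seed=3)
        lik = PoissonLikelihood(table)
        lam = lik.expected(bp, tp)
        reference = stats.poisson.logpmf(table.cases, lam).sum()
        assert lik.loglik(bp, tp) == pytest.approx(reference, rel=1e-12)

    def test_all_zero_cases_gives_minus_total_mean(self):
        t = small_table([(50, 2000, 0, 1e4), (60, 2005, 0, 2e4)])
        lik = PoissonLikelihood(t)
        lam = np.array([1.3, 0.7])
        assert lik.loglik_from_lambda(lam) == pytest.approx(-lam.sum())

    def test_saturated_when_means_equal_counts(self):
        t = small_table([(50, 2000, 4, 1e4), (60, 2005, 0, 2e4),
                         (70, 2010, 11, 3e4)])
        lik = PoissonLikelihood(t)
        assert lik.loglik_from_lambda(t.cases.astype(float)) == pytest.approx(
            lik.saturated_loglik()
        )

    def test_zero_mean_with_observed_cases_is_impossible(self):
        t = small_table([(50, 2000, 2, 1e4)])
        lik = PoissonLikelihood(t)
        assert lik.loglik_from_lambda(np.array([0.0])) == -np.inf

    def test_invalid_parameters_surface_as_minus_inf(self, flat_params):
        bp, tp = flat_params
        t = small_table([(50, 2000, 2, 1e4)])
        lik = PoissonLikelihood(t)
        # promotion trend pushing g beyond alpha: beta <= 0
        bad_tp = tp.replace(g1=0.1, g2=0.0)
        assert lik.loglik(bp, bad_tp) == -np.inf


class TestDeviance:
    def test_zero_at_saturated_fit(self):
        t = small_table([(50, 2000, 4, 1e4), (60, 2005, 7, 2e4)])
        lik = PoissonLikelihood(t)
        d, df = lik.deviance_from_lambda(t.cases.astype(float), n_free=0)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_single_stratum_hand_value(self):
        t = small_table([(50, 2000, 3, 1e4)])
        lik = PoissonLikelihood(t)
        d, _ = lik.deviance_from_lambda(np.array([2.0]))
        assert d == pytest.approx(2.0 * (3.0 * np.log(1.5) - 1.0), rel=1e-12)

    def test_zero_count_term_is_twice_lambda(self):
        t = small_table([(50, 2000, 0, 1e4)])
        lik = PoissonLikelihood(t)
        d, _ = lik.deviance_from_lambda(np.array([0.8]))
        assert d == pytest.approx(1.6, rel=1e-12)

    def test_additive_under_proportional_stratum_split(self):
        """Splitting a stratum's person-years (cases and mean split
        proportionally) leaves the deviance unchanged."""
        whole = small_table([(50, 2000, 6, 3e4)])
        split = small_table([(50, 2000, 2, 1e4), (50, 2001, 4, 2e4)])
        d1, _ = PoissonLikelihood(whole).deviance_from_lambda(np.array([4.5]))
        d2, _ = PoissonLikelihood(split).deviance_from_lambda(
            np.array([1.5, 3.0])
        )
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_loglik_deviance_duality(self, flat_params):
        """loglik = saturated loglik - deviance/2 for any parameters, so
        the MLE and the deviance minimizer coincide."""
        bp, tp = flat_params
        sched = make_py_schedule(range(1990, 1993), range(50, 60), base_py=1e5)
        table = generate_incidence_table(bp, tp, sched, seed=5)
        lik = PoissonLikelihood(table)
        for scale in (0.5, 1.0, 2.0):
            bps = bp.replace(nu0=bp.nu0 * scale)
            d, _ = lik.deviance(bps, tp)
            assert lik.loglik(bps, tp) == pytest.approx(
                lik.saturated_loglik() - d / 2.0, rel=1e-12
            )

    def test_row_order_invariance(self, flat_params):
        bp, tp = flat_params
        sched = make_py_schedule(range(1990, 1993), range(50, 60), base_py=1e5)
        table = generate_incidence_table(bp, tp, sched, seed=6)
        shuffled = IncidenceTable.from_dataframe(
            table.data[["age", "year", "cases", "py"]]
            .sample(frac=1.0, random_state=0)
        )
        assert PoissonLikelihood(shuffled).loglik(bp, tp) == pytest.approx(
            PoissonLikelihood(table).loglik(bp, tp), rel=1e-12
        )


class TestPredictedCounts:
    def test_composition_identity_single_stratum(self, flat_params):
        """lambda for one stratum equals the convolution hazard at the
        stratum midpoint times its person-years."""
        bp, tp = flat_params
        t = small_table([(60, 1990, 0, 5e4)])
        lik = PoissonLikelihood(t, step=0.25)
        lam = lik.expected(bp, tp)
        href = convolved_hazard(60.5, lambda s: bp.nu0, bp)
        assert lam[0] == pytest.approx(href * 5e4, rel=5e-3)

    def test_pre_lag_strata_have_zero_mean(self, flat_params):
        bp, tp = flat_params
        t = small_table([(2, 1950, 0, 5e4)])
        lam = PoissonLikelihood(t).expected(bp, tp)
        assert lam[0] == 0.0


class TestLrTest:
    def test_zero_difference_gives_p_one(self):
        assert lr_test(10.0, 10.0, 1) == 1.0

    def test_canonical_chi2_quantile(self):
        assert lr_test(3.841, 0.0, 1) == pytest.approx(0.05, abs=5e-4)

    def test_two_df_tail(self):
        assert lr_test(19.81, 0.0, 2) < 5e-5

    def test_nesting_violation_rejected(self):
        with pytest.raises(ValueError, match="nesting"):
            lr_test(5.0, 8.0, 1)


def test_functional_wrappers_agree_with_evaluator(flat_params):
    bp, tp = flat_params
    sched = make_py_schedule(range(1990, 1992), range(50, 55), base_py=1e5)
    table = generate_incidence_table(bp, tp, sched, seed=9)
    lik = PoissonLikelihood(table)
    assert poisson_loglik(table, bp, tp) == lik.loglik(bp, tp)
    assert deviance(table, bp, tp) == lik.deviance(bp, tp)
    assert saturated_loglik(table) == lik.saturated_loglik()
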