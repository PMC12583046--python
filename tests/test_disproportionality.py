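"""2×2 tables, the four disproportionality algorithms and the signal rule."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import digamma

from ssfaers.disproportionality import (
    DEFAULT_GPS_PRIOR,
    ContingencyTable,
    GpsPrior,
    SignalCriteria,
    SignalMetrics,
    build_contingency,
    compute_ebgm,
    compute_ic,
    compute_metrics,
    compute_prr_chi2,
    compute_ror,
    contingency_tables,
    evaluate_signal,
    fit_gps_prior,
    marginal_loglik,
    volcano_stats,
)
from ssfaers.faers_io import DrugMention, ReportCase


def make_case(rid, drugs=(), reactions=(), age=70.0):
    return ReportCase(
        report_id=rid, case_id=rid, receipt_date=date(2024, 1, 1), age_years=age,
        drugs=[DrugMention(raw_name=d, role="PS") for d in drugs],
        reactions=list(reactions),
    )


class FakePair:
    """(a, E) pair standing in for a table in prior-fit simulations."""

    def __init__(self, a, e):
        self.a = a
        self._e = e

    @property
    def expected(self):
        return self._e


def simulate_pairs(prior, n, rng):
    e = rng.uniform(0.5, 10.0, size=n)
    comp = rng.random(n) < prior.w
    lam = np.where(
        comp,
        rng.gamma(prior.alpha1, 1.0 / prior.beta1, n),
        rng.gamma(prior.alpha2, 1.0 / prior.beta2, n),
    )
    a = rng.poisson(lam * e)
    return [FakePair(int(ai), float(ei)) for ai, ei in zip(a, e)]


class TestBuildContingency:
    def test_hand_counted_fixture(self):
        pt = "Serotonin syndrome"
        background = [
            make_case("1", ["DRUGX"], [pt]),
            make_case("2", ["DRUGX"], [pt]),
            make_case("3", ["DRUGX"], ["Nausea"]),
            make_case("4", ["OTHER"], [pt]),
            make_case("5", ["OTHER"], [pt]),
            make_case("6", ["OTHER"], ["Nausea"]),
            make_case("7", ["OTHER"], ["Rash"]),
            make_case("8", ["OTHER"], []),
        ]
        cohort = [c for c in background if pt in c.reactions]
        t = build_contingency(cohort, background, "DRUGX")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 2, 3)
        assert t.n == 8

    def test_absent_drug_non_evaluable(self):
        background = [make_case("1", ["OTHER"], ["Serotonin syndrome"])]
        t = build_contingency(background, background, "DRUGX")
        assert (t.a, t.b) == (0, 0) and not t.evaluable

    def test_repeated_mentions_count_once(self):
        case = make_case("1", ["DRUGX", "DRUGX"], ["Serotonin syndrome"])
        t = build_contingency([case], [case], "DRUGX")
        assert t.a == 1

    def test_batch_matches_per_drug(self):
        pt = "Serotonin syndrome"
        background = [
            make_case(str(i), [d], [pt] if i % 3 == 0 else ["Nausea"])
            for i, d in enumerate(["A", "B", "C", "A", "B", "A", "C", "B", "A"])
        ]
        cohort = [c for c in background if pt in c.reactions]
        batch = contingency_tables(cohort, background, ["A", "B", "C"])
        for t in batch:
            single = build_contingency(cohort, background, t.drug)
            assert (t.a, t.b, t.c, t.d) == (single.a, single.b, single.c, single.d)


class TestRor:
    def test_proportional_table_is_null(self):
        ror, lo, hi, corrected = compute_ror(ContingencyTable(5, 50, 10, 100))
        assert ror == pytest.approx(1.0)
        assert not corrected

    def test_hand_arithmetic(self):
        ror, lo, hi, _ = compute_ror(ContingencyTable(8, 92, 192, 9708))
        assert ror == pytest.approx(4.3967, abs=1e-3)
        assert lo == pytest.approx(2.105, abs=1e-3)

    def test_strong_signal_table(self):
        ror, *_ = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)

    def test_zero_cell_haldane_correction(self):
        ror, lo, hi, corrected = compute_ror(ContingencyTable(5, 0, 10, 100))
        assert corrected
        assert ror == pytest.approx((5.5 * 100.5) / (0.5 * 10.5))

    def test_a_zero_gives_missing(self):
        ror, lo, hi, _ = compute_ror(ContingencyTable(0, 10, 10, 100))
        assert math.isnan(ror) and math.isnan(lo)

    @given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500))
    @settings(derandomize=True, max_examples=100)
    def test_antisymmetry(self, a, b, c, d):
        ror, lo, hi, _ = compute_ror(ContingencyTable(a, b, c, d))
        swapped, s_lo, s_hi, _ = compute_ror(ContingencyTable(b, a, d, c))
        assert swapped == pytest.approx(1.0 / ror)
        assert s_lo == pytest.approx(1.0 / hi)


class TestPrrChi2:
    def test_hand_arithmetic(self):
        prr, chi2 = compute_prr_chi2(ContingencyTable(8, 92, 192, 9708))
        assert prr == pytest.approx(4.125, abs=1e-3)
        assert chi2 == pytest.approx(18.553, abs=1e-3)

    def test_small_table(self):
        prr, chi2 = compute_prr_chi2(ContingencyTable(5, 5, 5, 85))
        assert prr == pytest.approx(9.0, abs=1e-3)
        assert chi2 == pytest.approx(19.753, abs=1e-3)

    def test_independence(self):
        prr, chi2 = compute_prr_chi2(ContingencyTable(5, 50, 10, 100))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominator_missing(self):
        prr, chi2 = compute_prr_chi2(ContingencyTable(3, 7, 0, 100))
        assert math.isnan(prr)

    @given(st.integers(0, 300), st.integers(1, 300), st.integers(1, 300), st.integers(1, 300))
    @settings(derandomize=True, max_examples=100)
    def test_chi2_transposition_invariance(self, a, b, c, d):
        _, chi2 = compute_prr_chi2(ContingencyTable(a, b, c, d))
        t_transposed = ContingencyTable(a, c, b, d)
        if t_transposed.b + t_transposed.a and t_transposed.c:
            _, chi2_t = compute_prr_chi2(t_transposed)
            if not (math.isnan(chi2) or math.isnan(chi2_t)):
                assert chi2_t == pytest.approx(chi2, rel=1e-9)


class TestIc:
    def test_independence_is_zero(self):
        # margins give E = a = 4
        ic, _ = compute_ic(ContingencyTable(4, 96, 96, 2304))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        ic, ic_lo = compute_ic(ContingencyTable(8, 92, 192, 9708))
        assert ic == pytest.approx(1.7655, abs=1e-3)
        assert ic_lo == pytest.approx(0.5529, abs=1e-3)

    def test_zero_count(self):
        # a=0 with margins giving E = 1
        ic, _ = compute_ic(ContingencyTable(0, 50, 50, 2400))
        assert ic == pytest.approx(math.log2(0.5 / 1.5), abs=1e-9)

    @given(st.integers(0, 400), st.floats(0.5, 50.0))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing_in_a_at_fixed_e(self, a, e):
        ic1, _ = compute_ic(FakePair(a, e))
        ic2, _ = compute_ic(FakePair(a + 1, e))
        assert ic2 > ic1

    def test_converges_to_log2_rr(self):
        # scale a and E together at fixed RR = 3; IC -> log2(RR)
        errors = [
            abs(compute_ic(FakePair(3 * s, float(s)))[0] - math.log2(3.0))
            for s in (1, 10, 100, 1000)
        ]
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] < 1e-3


class TestEbgm:
    def test_single_component_digamma_closed_form(self):
        # w=1, Gamma(2,4) prior, a=6, margins giving E=2 -> posterior Gamma(8,6)
        t = ContingencyTable(6, 94, 94, 4806)
        assert t.expected == pytest.approx(2.0)
        ebgm, _ = compute_ebgm(t, GpsPrior(w=1.0, alpha1=2.0, beta1=4.0))
        assert ebgm == pytest.approx(math.exp(digamma(8) - math.log(6)), abs=1e-10)
        ebgm0, _ = compute_ebgm(t, GpsPrior(w=0.0, alpha2=2.0, beta2=4.0))
        assert ebgm0 == pytest.approx(ebgm, abs=1e-10)

    def test_geometric_below_arithmetic_mean(self):
        t = ContingencyTable(6, 94, 94, 4806)
        ebgm, _ = compute_ebgm(t, GpsPrior(w=1.0, alpha1=2.0, beta1=4.0))
        assert ebgm <= 8.0 / 6.0

    def test_matches_quadrature_oracle(self):
        # default prior, a=5, margins giving E=1
        t = ContingencyTable(5, 95, 95, 9805)
        assert t.expected == pytest.approx(1.0)
        ebgm, eb05 = compute_ebgm(t)
        prior = DEFAULT_GPS_PRIOR
        # independent oracle: dense-grid quadrature over the posterior mixture
        a, e = t.a, t.expected
        m1 = stats.nbinom.pmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
        m2 = stats.nbinom.pmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
        q = prior.w * m1 / (prior.w * m1 + (1 - prior.w) * m2)
        grid = np.linspace(1e-9, 60.0, 1_000_001)
        pdf = q * stats.gamma.pdf(grid, prior.alpha1 + a, scale=1 / (prior.beta1 + e)) + (
            1 - q
        ) * stats.gamma.pdf(grid, prior.alpha2 + a, scale=1 / (prior.beta2 + e))
        pdf /= np.trapezoid(pdf, grid)
        oracle_ebgm = math.exp(np.trapezoid(pdf * np.log(grid), grid))
        cdf = np.cumsum(pdf) * (grid[1] - grid[0])
        oracle_eb05 = grid[np.searchsorted(cdf, 0.05)]
        assert ebgm == pytest.approx(oracle_ebgm, abs=1e-4)
        assert eb05 == pytest.approx(oracle_eb05, abs=1e-3)
        assert eb05 <= ebgm

    @given(st.integers(4, 200), st.floats(1.0, 20.0))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_shrinkage_between_one_and_rr(self, a, e):
        # only high-disproportionality tables: RR > 3
        if a / e <= 3.0:
            a = int(math.ceil(3.5 * e)) + 1
        t = FakePair(a, e)
        ebgm, eb05 = compute_ebgm(t, DEFAULT_GPS_PRIOR)
        rr = a / e
        assert 1.0 < ebgm < rr
        prior = DEFAULT_GPS_PRIOR
        m1 = stats.nbinom.pmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
        m2 = stats.nbinom.pmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
        q = prior.w * m1 / (prior.w * m1 + (1 - prior.w) * m2)
        post_mean = q * (prior.alpha1 + a) / (prior.beta1 + e) + (1 - q) * (
            prior.alpha2 + a
        ) / (prior.beta2 + e)
        assert ebgm <= post_mean + 1e-12


class TestFitGpsPrior:
    def test_recovers_generating_prior_likelihood(self):
        rng = np.random.default_rng(1234)
        train = simulate_pairs(DEFAULT_GPS_PRIOR, 5000, rng)
        held_out = simulate_pairs(DEFAULT_GPS_PRIOR, 5000, rng)
        fitted = fit_gps_prior(train)
        ll_fit = marginal_loglik(fitted, held_out) / len(held_out)
        ll_gen = marginal_loglik(DEFAULT_GPS_PRIOR, held_out) / len(held_out)
        assert abs(ll_fit - ll_gen) / abs(ll_gen) < 0.01

    def test_single_component_data_matches_single_component_likelihood(self):
        # the two-gamma ML fit is weight-unidentifiable on one-component data,
        # so the identifiable check is distribution equivalence on held-out data
        rng = np.random.default_rng(99)
        single = GpsPrior(w=1 - 1e-6, alpha1=2.0, beta1=4.0, alpha2=0.2, beta2=0.1)
        train = simulate_pairs(single, 3000, rng)
        held_out = simulate_pairs(single, 3000, rng)
        fitted = fit_gps_prior(train)
        ll_fit = marginal_loglik(fitted, held_out) / len(held_out)
        ll_gen = marginal_loglik(single, held_out) / len(held_out)
        assert abs(ll_fit - ll_gen) / abs(ll_gen) < 0.01

    def test_all_zero_counts_falls_back_to_default(self):
        pairs = [FakePair(0, 1.0) for _ in range(100)]
        assert fit_gps_prior(pairs) == DEFAULT_GPS_PRIOR

    def test_too_few_tables_is_error(self):
        with pytest.raises(ValueError, match="default prior"):
            fit_gps_prior([FakePair(1, 1.0)] * 10)


class TestSignalRule:
    def test_fixture_table_signals(self):
        m = compute_metrics(ContingencyTable(8, 92, 192, 9708))
        assert m.a == 8
        assert m.ror_lo == pytest.approx(2.105, abs=1e-3)
        assert m.prr == pytest.approx(4.125, abs=1e-3)
        assert m.chi2 == pytest.approx(18.553, abs=1e-3)
        assert m.ic_lo == pytest.approx(0.5529, abs=1e-3)
        assert m.is_signal

    def test_a_below_three_vetoes(self):
        strong = SignalMetrics(a=2, ror_lo=5.0, prr=10.0, chi2=50.0, ic_lo=2.0)
        assert not evaluate_signal(strong)

    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 1000), st.floats(-5, 5))
    @settings(derandomize=True, max_examples=50)
    def test_veto_holds_for_any_other_metrics(self, ror_lo, prr, chi2, ic_lo):
        m = SignalMetrics(a=2, ror_lo=ror_lo, prr=prr, chi2=chi2, ic_lo=ic_lo)
        assert not evaluate_signal(m)

    def test_proportional_table_not_a_signal(self):
        m = compute_metrics(ContingencyTable(5, 50, 10, 100))
        assert m.prr == pytest.approx(1.0)
        assert not m.is_signal

    def test_missing_metrics_fail(self):
        m = SignalMetrics(a=5)  # all metrics NaN
        assert not evaluate_signal(m)

    def test_strict_mode_requires_eb05(self):
        m = compute_metrics(ContingencyTable(8, 92, 192, 9708))
        strict = SignalCriteria(strict_ebgm=True)
        assert evaluate_signal(m, strict) == (m.eb05 > 2.0)


class TestVolcano:
    def test_fisher_mode_table_has_p_one(self):
        df = volcano_stats([ContingencyTable(1, 9, 9, 81, drug="x")])
        assert df.loc[0, "fisher_p"] == pytest.approx(1.0)

    def test_fisher_matches_scipy_convention(self):
        t = ContingencyTable(8, 92, 192, 9708, drug="x")
        df = volcano_stats([t])
        _, p = stats.fisher_exact([[8, 92], [192, 9708]])
        assert df.loc[0, "fisher_p"] == pytest.approx(float(p), rel=1e-12)

    def test_bonferroni_multiplication_and_cap(self):
        tables = [ContingencyTable(5, 5, 5, 85, drug=f"d{i}") for i in range(4)]
        df = volcano_stats(tables)
        assert (df["p_adj"] == np.minimum(1.0, 4 * df["fisher_p"])).all()

    def test_null_calibration_of_ror_lower_bound(self):
        # true rate ratio 1 with Poisson-like sampling: lower bound exceeds 1
        # in at most 5% of tables (plus 3 sigma Monte-Carlo slack)
        rng = np.random.default_rng(7)
        n_drug, n_other, p = 200, 9800, 0.02
        reps = 10_000
        a = rng.binomial(n_drug, p, reps)
        c = rng.binomial(n_other, p, reps)
        exceed = 0
        for ai, ci in zip(a, c):
            _, lo, _, _ = compute_ror(
                ContingencyTable(int(ai), n_drug - int(ai), int(ci), n_other - int(ci))
            )
            if not math.isnan(lo) and lo > 1.0:
                exceed += 1
        assert exceed / reps <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)
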