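"""One-way (tornado) and probabilistic sensitivity analyses."""

import dataclasses

import numpy as np
import pytest

from perioecon import (
    DistributionSpec,
    arm_expected_values,
    incremental_analysis,
    run_one_way_dsa,
    run_psa,
    sample_distribution,
)
from perioecon.config import load_config, parse_dsa_rows, parse_psa_specs
from perioecon.config import basecase_path


@pytest.fixture(scope="module")
def doc():
    return load_config(basecase_path())


@pytest.fixture(scope="module")
def psa_specs(doc):
    return parse_psa_specs(doc)


class TestDistributions:
    def test_degenerate_triangular(self):
        spec = DistributionSpec("triangular", minimum=5.0, mode=5.0, maximum=5.0)
        rng = np.random.default_rng(0)
        assert sample_distribution(spec, rng) == 5.0

    def test_lognormal_median_matches_table_rr(self):
        # median of exp(N(0.96, 0.27)) is e^0.96 ~ 2.611, close to the
        # published sensitivity base risk ratio of 2.60 for current smokers
        spec = DistributionSpec("lognormal_rr", log_mean=0.96, log_sd=0.27)
        rng = np.random.default_rng(11)
        draws = sample_distribution(spec, rng, size=100_000)
        assert np.median(draws) == pytest.approx(np.exp(0.96), rel=0.01)
        assert np.median(draws) == pytest.approx(2.60, rel=0.02)

    def test_triangular_mean_closed_form(self):
        spec = DistributionSpec("triangular", minimum=185.86, mode=227.41, maximum=525.59)
        rng = np.random.default_rng(12)
        draws = sample_distribution(spec, rng, size=100_000)
        expected = (185.86 + 227.41 + 525.59) / 3
        assert draws.mean() == pytest.approx(expected, rel=0.005)
        assert spec.mean == pytest.approx(expected)

    def test_uniform_mean_closed_form(self):
        spec = DistributionSpec("uniform", minimum=0.03, maximum=0.07)
        rng = np.random.default_rng(13)
        draws = sample_distribution(spec, rng, size=100_000)
        assert draws.mean() == pytest.approx(0.05, abs=1e-4)

    def test_log_geometric_mean_recovers_log_mean(self):
        spec = DistributionSpec("lognormal_rr", log_mean=0.14, log_sd=0.28)
        rng = np.random.default_rng(14)
        draws = sample_distribution(spec, rng, size=100_000)
        assert np.log(draws).mean() == pytest.approx(0.14, abs=0.005)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("triangular", minimum=2.0, mode=1.0, maximum=3.0)
        with pytest.raises(ValueError):
            DistributionSpec("uniform", minimum=1.0, maximum=1.0)
        with pytest.raises(ValueError):
            DistributionSpec("lognormal_rr", log_mean=0.1, log_sd=-0.1)
        with pytest.raises(ValueError):
            DistributionSpec("weibull")


class TestOneWayDSA:
    def test_inert_parameter_has_zero_spread(self, basecase):
        # the untreated-periodontitis utility never enters the trajectory
        rows = [{"param": "u_periodontitis", "min": 0.67, "base": 0.76, "max": 0.89}]
        res = run_one_way_dsa(basecase, rows, include_implant_scenario=False)
        assert res[0].spread == 0.0

    def test_discount_rate_monotonicity(self, basecase):
        rows = [{"param": "discount_rate", "min": 0.03, "base": 0.05, "max": 0.07}]
        res = run_one_way_dsa(basecase, rows, include_implant_scenario=False)[0]
        # all-positive rewards: totals shrink as the rate grows, in each arm
        lo, hi = res.outcomes["low"], res.outcomes["high"]
        base_inputs = basecase.to_model_inputs()
        for arm in ("SCT", "NO_SCT"):
            c_lo = arm_expected_values(
                base_inputs.with_overrides({"discount_rate": 0.03}), arm
            )
            c_hi = arm_expected_values(
                base_inputs.with_overrides({"discount_rate": 0.07}), arm
            )
            assert c_hi.expected_cost < c_lo.expected_cost
            assert c_hi.expected_effect < c_lo.expected_effect

    def test_sct_cost_at_maximum_flips_dominance(self, basecase):
        # at zero discount the base case is dominant; pricing the therapy at
        # its maximum turns it into a positive-cost trade-off
        ps = dataclasses.replace(basecase, discount_rate=0.0)
        rows = [{"param": "cost_sct", "min": 185.86, "base": 227.41, "max": 525.59}]
        res = run_one_way_dsa(ps, rows, include_implant_scenario=False)[0]
        assert res.outcomes["base"]["classification_cea"] == "DOMINANT"
        assert res.outcomes["high"]["classification_cea"] == "TRADEOFF_NE"
        assert res.outcomes["high"]["delta_cost"] > 0
        assert res.outcomes["high"]["delta_effect_cea"] > 0

    def test_unknown_parameter_errors(self, basecase):
        with pytest.raises(KeyError):
            run_one_way_dsa(basecase, [{"param": "nope", "min": 0, "base": 0, "max": 1}])

    def test_full_table_tornado_ordering(self, basecase, doc):
        res = run_one_way_dsa(basecase, parse_dsa_rows(doc))
        spreads = [r.spread for r in res]
        assert spreads == sorted(spreads, reverse=True)
        # the implant scenario row is appended
        assert any(r.parameter == "rehab_mode" for r in res)


class TestPSA:
    def test_all_fixed_specs_collapse_to_deterministic(self, basecase):
        base = basecase.to_model_inputs()
        specs = {
            "cost_sct": DistributionSpec("fixed", value=base.cost_sct),
            "discount_rate": DistributionSpec("fixed", value=base.discount_rate),
        }
        samples = run_psa(basecase, specs, iterations=5, seed=1)
        for arm in ("SCT", "NO_SCT"):
            det = arm_expected_values(base, arm)
            assert (samples.costs[arm] == det.expected_cost).all()
            assert (samples.effects[arm] == det.expected_effect).all()
            assert (samples.qalys[arm] == det.expected_qaly).all()

    def test_same_seed_reproduces_bitwise(self, basecase, psa_specs):
        a = run_psa(basecase, psa_specs, iterations=40, seed=7)
        b = run_psa(basecase, psa_specs, iterations=40, seed=7)
        for arm in ("SCT", "NO_SCT"):
            assert (a.costs[arm] == b.costs[arm]).all()
            assert (a.qalys[arm] == b.qalys[arm]).all()

    def test_shared_draws_across_arms(self, basecase, psa_specs):
        # both arms see the same draw: with identical quit probabilities and
        # no SCT cost the arms coincide iteration by iteration
        ps = basecase.to_model_inputs()
        same = ps.with_overrides({"p_quit_sct": 0.07, "cost_sct": 0.0})
        specs = {k: v for k, v in psa_specs.items() if k not in ("p_quit_sct", "cost_sct")}
        samples = run_psa(same, specs, iterations=30, seed=3)
        assert samples.costs["SCT"] == pytest.approx(samples.costs["NO_SCT"], abs=1e-9)

    def test_rejection_guard_trips_on_misspecified_distributions(self, basecase):
        specs = {
            "rr_current": DistributionSpec("uniform", minimum=400.0, maximum=500.0),
        }
        with pytest.raises(RuntimeError, match="invalid parameter draws"):
            run_psa(basecase, specs, iterations=1, seed=0)

    def test_paper_scale_moments(self, basecase, psa_specs):
        # with 1000 iterations, each sampled parameter's mean sits within
        # 3 standard errors of its analytic distribution mean; checked on
        # the cost of therapy via the recorded arm costs
        samples = run_psa(basecase, psa_specs, iterations=1000, seed=2021)
        base = basecase.to_model_inputs()
        # SCT-arm minus NO_SCT-arm cost differs by exactly the drawn SCT cost
        # when everything else is shared -- not true in general, so check the
        # moment on direct draws instead:
        rng = np.random.default_rng(99)
        for name in ("cost_sct", "discount_rate", "rr_current"):
            spec = psa_specs[name]
            draws = sample_distribution(spec, rng, size=1000)
            se = draws.std(ddof=1) / np.sqrt(len(draws))
            assert abs(draws.mean() - spec.mean) < 3 * se

    def test_incrementals_feed_economics(self, basecase, psa_specs):
        samples = run_psa(basecase, psa_specs, iterations=50, seed=5)
        de, dc = samples.deltas("effect")
        assert de.shape == dc.shape == (50,)
        assert np.isfinite(de).all() and np.isfinite(dc).all()
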