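import numpy as np
import pytest

from pscea import config
from pscea.cea import WTP_3X_GDP, inhb
from pscea.errors import ConfigurationError, InvalidParameterError
from pscea.sensitivity import (
    PSASample,
    SensitivitySpec,
    ce_plane_quadrants,
    ceac,
    draw_parameters,
    one_way,
    run_psa,
)


def spec(id="p", target="test_set_cost", base=155.0, low=78.0, high=310.0,
         sd=93.0, distribution="gamma", **kw):
    return SensitivitySpec(id=id, target=target, base=base, low=low, high=high,
                           sd=sd, distribution=distribution, **kw)


def sample(draw, dc, de):
    return PSASample(draw, {}, cost1=dc, effect1=de, cost0=0.0, effect0=0.0)


class TestSpecValidation:
    def test_range_must_bracket_base(self):
        with pytest.raises(InvalidParameterError):
            spec(base=50.0)

    def test_unknown_target_rejected(self):
        with pytest.raises(ConfigurationError):
            spec(target="market_share")

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ConfigurationError):
            spec(distribution="lognormal")

    def test_dose_specs_key_on_drug(self):
        s = spec(target="dose", drug="oxaliplatin", base=138, low=110, high=166,
                 sd=28, distribution="normal")
        assert s.key == ("dose", "oxaliplatin")


class TestOneWay:
    def test_degenerate_range_reproduces_base_inhb(self, model):
        s = spec(base=155.0, low=155.0, high=155.0)
        table = one_way([s], model, WTP_3X_GDP)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.inhb_low == row.inhb_high == pytest.approx(row.inhb_base)

    def test_comparator_drug_cost_moves_inhb_monotonically(self, model):
        s = spec(id="soraf_cost", target="monthly_drug_cost", arm="sorafenib",
                 base=3777, low=3021, high=4532, sd=1126)
        row = one_way([s], model, WTP_3X_GDP).iloc[0]
        # pricier comparator always favours the intervention
        assert row.inhb_low < row.inhb_base < row.inhb_high

    def test_rows_sorted_by_tornado_width(self, model, params):
        table = one_way(config.sensitivity_specs(params), model, WTP_3X_GDP)
        widths = table["width"].to_numpy()
        assert np.all(np.diff(widths) <= 1e-15)
        assert set(table["parameter"]) == {s.id for s in config.sensitivity_specs(params)}

    def test_endpoints_match_direct_model_reevaluation(self, model):
        # brute-force recomputation: perturb the input by hand and compare
        s = spec(id="tests", target="test_set_cost", base=155, low=78, high=310)
        row = one_way([s], model, WTP_3X_GDP).iloc[0]
        for side, value in (("inhb_low", 78.0), ("inhb_high", 310.0)):
            out = model.evaluate({("test_set_cost", None): value})
            assert getattr(row, side) == pytest.approx(
                inhb(out.icer.delta_effect, out.icer.delta_cost, WTP_3X_GDP)
            )

    def test_tornado_endpoints_bracket_base_for_monotone_parameter(self, model):
        s = spec(id="ae", target="ae_cost_multiplier", base=1.0, low=0.5, high=2.0,
                 sd=0.2)
        row = one_way([s], model, WTP_3X_GDP).iloc[0]
        assert min(row.inhb_low, row.inhb_high) <= row.inhb_base <= max(row.inhb_low, row.inhb_high)


class TestDrawParameters:
    def test_gamma_moment_matching(self):
        # mean 1865, sd 373 -> shape 25, scale 74.6; sample mean within 1%
        s = spec(id="cost", target="monthly_drug_cost", arm="folfox4",
                 base=1865.0, low=1492.0, high=2238.0, sd=373.0)
        draws = np.array([v[s.key] for v in draw_parameters([s], 123, n_draws=10**5)])
        assert draws.mean() == pytest.approx(1865.0, rel=0.01)
        assert draws.std() == pytest.approx(373.0, rel=0.02)

    def test_truncated_normal_utility_stays_in_unit_interval(self):
        s = spec(id="u", target="utility_pfs", base=0.76, low=0.61, high=0.91,
                 sd=0.152, distribution="normal")
        draws = np.array([v[s.key] for v in draw_parameters([s], 7, n_draws=5000)])
        assert np.all((draws >= 0.0) & (draws <= 1.0))

    def test_same_seed_same_vectors(self):
        specs = [
            spec(id="a"),
            spec(id="u", target="utility_pd", base=0.68, low=0.54, high=0.82,
                 sd=0.136, distribution="normal"),
        ]
        assert draw_parameters(specs, 99, 50) == draw_parameters(specs, 99, 50)

    def test_zero_sd_gives_constant_draws(self):
        s = spec(sd=0.0)
        draws = draw_parameters([s], 1, 20)
        assert all(v[s.key] == 155.0 for v in draws)

    def test_one_way_only_specs_excluded(self):
        s = spec(id="disc", target="discount_rate", base=0.05, low=0.0, high=0.08,
                 sd=0.0, distribution="none")
        assert draw_parameters([s], 1, 5) == [{}] * 5


class TestRunPsa:
    def test_zero_sd_psa_equals_deterministic_base_case(self, model, params):
        # degenerate draws pin every parameter at its tabulated base value, so
        # each sample must equal the deterministic run at that same vector
        # (the tabulated bases carry the published roundings, e.g. $1865/month,
        # so the reference is the model evaluated at those values)
        specs = [
            SensitivitySpec(id=s.id, target=s.target, base=s.base, low=s.low,
                            high=s.high, sd=0.0, distribution=s.distribution,
                            arm=s.arm, drug=s.drug)
            for s in config.sensitivity_specs(params)
        ]
        sampled = [s for s in specs if s.distribution != "none"]
        base = model.evaluate({s.key: s.base for s in sampled})
        samples = run_psa(model, specs, master_seed=5, n_draws=10)
        for s in samples:
            assert s.cost1 == base.intervention.discounted["total"]
            assert s.effect1 == base.intervention.qaly
            assert s.cost0 == base.comparator.discounted["total"]
            assert s.effect0 == base.comparator.qaly

    def test_seeded_reproducibility(self, model, params):
        specs = config.sensitivity_specs(params)
        a = run_psa(model, specs, master_seed=17, n_draws=40)
        b = run_psa(model, specs, master_seed=17, n_draws=40)
        assert [s.params for s in a] == [s.params for s in b]
        assert [(s.cost1, s.effect0) for s in a] == [(s.cost1, s.effect0) for s in b]

    def test_single_cost_parameter_propagates_its_sd(self, model):
        # only the comparator's monthly drug cost varies; the sd of delta_cost
        # should be the input sd scaled by discounted PFS person-months
        s = spec(id="soraf_cost", target="monthly_drug_cost", arm="sorafenib",
                 base=3777.0, low=3021.0, high=4532.0, sd=1126.0)
        n = 400
        samples = run_psa(model, [s], master_seed=21, n_draws=n)
        drawn = np.array([smp.params[s.key] for smp in samples])
        costs0 = np.array([smp.cost0 for smp in samples])
        person_months = np.polyfit(drawn, costs0, 1)[0]
        observed_sd = costs0.std(ddof=1)
        expected_sd = person_months * drawn.std(ddof=1)
        assert observed_sd == pytest.approx(expected_sd, rel=0.02)
        # and the intervention arm is untouched by a comparator-only draw
        assert np.ptp([smp.cost1 for smp in samples]) == 0.0

    def test_invalid_draw_count(self, model):
        with pytest.raises(InvalidParameterError):
            run_psa(model, [], master_seed=1, n_draws=0)


class TestCePlane:
    def test_all_dominant(self):
        shares = ce_plane_quadrants([sample(i, -1.0, 1.0) for i in range(5)])
        assert shares["dominant"] == 1.0

    def test_hand_built_enumeration(self):
        pts = (
            [(-10, 0.1)] * 3      # dominant
            + [(10, -0.1)]        # dominated
            + [(10, 0.1)] * 4     # NE trade-off
            + [(-10, -0.1)] * 2   # SW trade-off
        )
        shares = ce_plane_quadrants([sample(i, dc, de) for i, (dc, de) in enumerate(pts)])
        assert shares == {"dominant": 0.3, "dominated": 0.1, "ne": 0.4, "sw": 0.2}

    def test_boundary_points_are_never_dominant(self):
        shares = ce_plane_quadrants([sample(0, 0.0, 1.0), sample(1, -1.0, 0.0)])
        assert shares["dominant"] == 0.0
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_shares_partition_unity_for_random_input(self):
        rng = np.random.default_rng(0)
        pts = [sample(i, dc, de) for i, (dc, de) in
               enumerate(zip(rng.normal(0, 1e3, 500), rng.normal(0, 0.1, 500)))]
        assert sum(ce_plane_quadrants(pts).values()) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            ce_plane_quadrants([])


class TestCeac:
    def test_all_dominant_accepts_everywhere(self):
        pts = [sample(i, -1.0, 1.0) for i in range(4)]
        assert np.all(ceac(pts, [1e2, 1e4, 1e6]) == 1.0)

    def test_hand_built_half_split(self):
        pts = [sample(0, 1000.0, 0.1), sample(1, 3000.0, 0.1)]
        assert ceac(pts, [20000.0])[0] == 0.5

    def test_lambda_limits_match_quadrant_probabilities(self):
        rng = np.random.default_rng(3)
        pts = [sample(i, dc, de) for i, (dc, de) in
               enumerate(zip(rng.normal(500, 2e3, 400), rng.normal(0.01, 0.05, 400)))]
        p_low = ceac(pts, [1e-9])[0]
        p_high = ceac(pts, [1e15])[0]
        de = np.array([p.delta_effect for p in pts])
        dc = np.array([p.delta_cost for p in pts])
        assert p_low == pytest.approx((dc < 0).mean())
        assert p_high == pytest.approx((de > 0).mean())

    def test_consistency_with_inhb_share(self, model, params):
        samples = run_psa(model, config.sensitivity_specs(params), master_seed=2, n_draws=60)
        lam = WTP_3X_GDP
        share = np.mean([inhb(s.delta_effect, s.delta_cost, lam) > 0 for s in samples])
        assert ceac(samples, [lam])[0] == pytest.approx(share)

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            ceac([sample(0, -1, 1)], [])
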