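"""Synthetic survey generator: determinism, moments, parameter recovery."""

import dataclasses
import hashlib

import numpy as np
import pytest

from cumrisk.cumulative import cumulative_exposure_series
from cumrisk.exposure import ExposureMatrix, concentration_table
from cumrisk.synthetic import (
    FoodSpec,
    Injection,
    OccurrenceSpec,
    SyntheticConfig,
    default_config,
    generate_consumption,
    generate_occurrence,
    generate_population,
    generate_survey,
    ground_truth_cumulative,
)
from cumrisk.workflow import endpoint_tables as build_endpoints


def survey_digest(survey) -> str:
    h = hashlib.sha256()
    for i in survey.individuals:
        h.update(f"{i.id},{i.age},{i.gender},{i.body_weight!r};".encode())
    for c in survey.consumption:
        h.update(f"{c.individual},{c.day},{c.food},{c.amount!r};".encode())
    for o in survey.occurrence:
        h.update(f"{o.food},{o.chemical},{o.value!r},{o.loq},{o.detected};".encode())
    return h.hexdigest()


class TestPopulation:
    def test_empty(self):
        assert generate_population(default_config(seed=0, n_individuals=0)) == []

    def test_same_seed_identical(self):
        cfg = default_config(seed=5, n_individuals=50)
        assert survey_digest(generate_survey(cfg)) == survey_digest(generate_survey(cfg))

    def test_different_seed_differs(self):
        a = generate_survey(default_config(seed=5, n_individuals=50))
        b = generate_survey(default_config(seed=6, n_individuals=50))
        assert survey_digest(a) != survey_digest(b)

    def test_body_weight_means_within_3_se(self):
        cfg = default_config(seed=1, n_individuals=1000)
        pop = generate_population(cfg)
        for gender, (mean, sd) in cfg.bw_params.items():
            weights = np.array([p.body_weight for p in pop if p.gender == gender])
            se = sd / np.sqrt(len(weights))
            # truncation at 35 kg shifts the mean by < 0.01 kg at these params
            assert abs(weights.mean() - mean) < 3 * se
            assert weights.min() >= 35.0

    def test_ages_within_range_and_gender_split(self):
        cfg = default_config(seed=2, n_individuals=2000)
        pop = generate_population(cfg)
        ages = [p.age for p in pop]
        assert min(ages) >= 25 and max(ages) <= 74
        f = np.mean([p.gender == "female" for p in pop])
        assert abs(f - cfg.female_fraction) < 3 * np.sqrt(0.25 / len(pop))


class TestConsumption:
    def base_cfg(self, **food_kwargs):
        food = FoodSpec("f", "g", "other", **food_kwargs)
        return SyntheticConfig(n_individuals=300, seed=3, foods=(food,))

    def test_zero_consumer_probability(self):
        cfg = self.base_cfg(consumer_prob=0.0, mean_amount=100.0, sigma_log=0.5)
        assert generate_consumption(generate_population(cfg), cfg) == []

    def test_degenerate_lognormal(self):
        cfg = self.base_cfg(consumer_prob=1.0, mean_amount=100.0, sigma_log=1e-9)
        recs = generate_consumption(generate_population(cfg), cfg)
        assert len(recs) == 600  # everyone, both days
        assert all(abs(r.amount - 100.0) < 1e-3 for r in recs)

    def test_mean_amount_converges_to_lognormal_moment(self):
        cfg = SyntheticConfig(
            n_individuals=5000,
            seed=4,
            foods=(FoodSpec("f", "g", "other", 1.0, 150.0, 0.6),),
        )
        recs = generate_consumption(generate_population(cfg), cfg)
        amounts = np.array([r.amount for r in recs])
        cv = np.sqrt(np.exp(0.6**2) - 1)
        se = 150.0 * cv / np.sqrt(len(amounts))
        assert abs(amounts.mean() - 150.0) < 3 * se


class TestOccurrence:
    def occ_cfg(self, nd_prob, n_samples=400):
        spec = OccurrenceSpec("f", "Pb", 10.0, 0.5, nd_prob, 1.0, n_samples)
        return SyntheticConfig(n_individuals=0, seed=5, occurrence=(spec,))

    def test_all_nondetect(self):
        recs = generate_occurrence(self.occ_cfg(1.0))
        assert all(not r.detected for r in recs)

    def test_all_detected(self):
        recs = generate_occurrence(self.occ_cfg(0.0))
        assert all(r.detected for r in recs)

    def test_lb_mean_matches_censoring_identity(self):
        recs = generate_occurrence(self.occ_cfg(0.3, n_samples=20000))
        lb = np.array([r.value if r.detected else 0.0 for r in recs])
        expected = 0.7 * 10.0
        se = lb.std(ddof=1) / np.sqrt(len(lb))
        assert abs(lb.mean() - expected) < 3 * se


def _pipeline_estimate(cfg, rpf):
    survey = generate_survey(cfg)
    conc = concentration_table(survey.occurrence, survey.food_categories)
    matrix = ExposureMatrix.compute(survey.individuals, survey.consumption, conc)
    return survey, cumulative_exposure_series(matrix.entries, rpf)


def _conc_sampling_sd(cfg, rpf):
    """Analytic SD of the ground-truth prediction due to finite occurrence
    sampling (the pipeline plugs in sample mean concentrations)."""
    from cumrisk.speciation import default_rules
    from cumrisk.synthetic import _mean_inverse_bw, _species_weight

    rules = default_rules()
    cats = {f.food_id: f.category for f in cfg.foods}
    cons = {
        f.food_id: f.consumer_prob * np.exp(f.mu_log + f.sigma_log**2 / 2) / 1000.0
        for f in cfg.foods
    }
    e_inv = sum(
        p * _mean_inverse_bw(*cfg.bw_params[g])
        for g, p in [("female", cfg.female_fraction), ("male", 1 - cfg.female_fraction)]
    )
    var = 0.0
    for spec in cfg.occurrence:
        w = cons[spec.food_id] * _species_weight(spec, cats[spec.food_id], rpf, rules) * e_inv
        m1 = (1 - spec.nd_prob) * np.exp(spec.mu_log + spec.sigma_log**2 / 2)
        m2 = (1 - spec.nd_prob) * np.exp(2 * spec.mu_log + 2 * spec.sigma_log**2)
        var += w**2 * (m2 - m1**2) / spec.n_samples
    return np.sqrt(var)


class TestGroundTruth:
    def test_single_food_fixed_parameters_hand_computed(self):
        cfg = SyntheticConfig(
            n_individuals=10,
            seed=0,
            bw_params={"female": (70.0, 0.5), "male": (70.0, 0.5)},
            foods=(FoodSpec("f", "g", "other", 0.5, 200.0, 0.3),),
            occurrence=(OccurrenceSpec("f", "Pb", 50.0, 0.4, 0.0, 1.0),),
        )
        rpf = build_endpoints(("neuro6",))["neuro6"][0]
        gt = ground_truth_cumulative(cfg, rpf)["population"]
        # 0.5 consumer x 200 g x 50 µg/kg x RPF(Pb)=1 / 70 kg
        # (near-degenerate weight spread: E[1/W] deviates from 1/70 by ~5e-5)
        assert gt == pytest.approx(0.5 * 0.2 * 50.0 / 70.0, rel=1e-3)

    def test_doubling_concentrations_doubles_expectation(self):
        cfg = default_config(seed=0, n_individuals=10)
        doubled = dataclasses.replace(
            cfg,
            occurrence=tuple(
                dataclasses.replace(o, mean_conc=2 * o.mean_conc) for o in cfg.occurrence
            ),
        )
        rpf = build_endpoints(("neuro6",))["neuro6"][0]
        a = ground_truth_cumulative(cfg, rpf)["population"]
        b = ground_truth_cumulative(doubled, rpf)["population"]
        assert b == pytest.approx(2 * a, rel=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pipeline_recovers_expectation_at_n_2000(self, seed):
        """End-to-end parameter recovery within 3 SE across seeds."""
        cfg = default_config(seed=seed, n_individuals=2000)
        cfg = dataclasses.replace(
            cfg,
            occurrence=tuple(
                dataclasses.replace(o, n_samples=2000) for o in cfg.occurrence
            ),
        )
        rpf = build_endpoints(("neuro6",))["neuro6"][0]
        gt = ground_truth_cumulative(cfg, rpf)["population"]
        _, cum = _pipeline_estimate(cfg, rpf)
        se = np.sqrt(cum.std(ddof=1) ** 2 / len(cum) + _conc_sampling_sd(cfg, rpf) ** 2)
        assert abs(cum.mean() - gt) < 3 * se


class TestInjection:
    def test_injected_factor_shifts_group_mean_and_is_detected(self):
        from cumrisk.compare import GroupDef, compare_groups

        factor = 1.5
        cfg = default_config(
            seed=9,
            n_individuals=1200,
            effect_injections=(Injection("boosted women", factor, gender="female"),),
        )
        cfg = dataclasses.replace(
            cfg,
            occurrence=tuple(dataclasses.replace(o, n_samples=500) for o in cfg.occurrence),
        )
        rpf, hbgvs = build_endpoints(("neuro6",))["neuro6"]
        gt = ground_truth_cumulative(cfg, rpf)
        survey, cum = _pipeline_estimate(cfg, rpf)
        women = frozenset(i.id for i in survey.individuals if i.gender == "female")
        men = frozenset(i.id for i in survey.individuals if i.gender == "male")
        mask = cum.index.get_level_values("individual").isin(women)
        se = cum[mask].std(ddof=1) / np.sqrt(mask.sum()) + _conc_sampling_sd(cfg, rpf) * factor
        assert abs(cum[mask].mean() - gt["boosted women"]) < 3 * se
        conc = concentration_table(survey.occurrence, survey.food_categories)
        matrix = ExposureMatrix.compute(survey.individuals, survey.consumption, conc)
        (res,) = compare_groups(
            matrix,
            [(GroupDef("women", women), GroupDef("men", men))],
            {"neuro6": (rpf, hbgvs)},
        )
        assert res.p_value < 1e-6 and res.mean_a > res.mean_b


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            FoodSpec("f", "g", "other", 1.2, 100.0, 0.5)

    def test_bad_bw_params_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(bw_params={"female": (30.0, 5.0), "male": (84.5, 13.5)})
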