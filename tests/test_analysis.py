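"""Scenario runs, extreme conditions, both sensitivity semantics."""

import numpy as np
import pytest

from chemrisk import (
    Scenario,
    bounded_prior_sensitivity,
    extreme_condition_test,
    generate_random_model,
    nine_scenarios,
    query_posterior,
    rank_sensitivities,
    run_scenario,
    state_flip_sensitivity,
)
from chemrisk.analysis import perturb_prior
from chemrisk.attack_model import ORGANISATION_PROFILES, TARGET_PROFILES
from chemrisk.errors import ConfigurationError


class TestRunScenario:
    def test_equals_direct_posterior_query(self, illustrative_model):
        sc = nine_scenarios()[0]
        post = run_scenario(
            illustrative_model, Scenario(sc["name"], sc["evidence"], ("J", "K"))
        )
        direct = query_posterior(illustrative_model, ["J", "K"], sc["evidence"])
        assert np.allclose(post["J"], direct["J"])
        assert np.allclose(post["K"], direct["K"])

    def test_empty_evidence_returns_priors(self, illustrative_model):
        post = run_scenario(
            illustrative_model, Scenario("baseline", {}, ("26",))
        )
        assert np.allclose(post["26"], [0.4, 0.6])

    def test_evidence_is_echoed_for_audit(self, illustrative_model):
        sc = nine_scenarios()[4]
        post = run_scenario(
            illustrative_model, Scenario(sc["name"], sc["evidence"], ("J",))
        )
        assert post.evidence == sc["evidence"]

    def test_failed_attack_shifts_casualties_to_minor(self, illustrative_model):
        baseline = query_posterior(illustrative_model, ["K"])
        failed = run_scenario(
            illustrative_model, Scenario("failed", {"J": "No"}, ("K",))
        )
        assert failed.probability("K", "Minor") > baseline.probability(
            "K", "Minor"
        )

    def test_government_attack_by_weak_organisation_fails_most(
        self, illustrative_model
    ):
        failures = {}
        for sc in nine_scenarios():
            post = run_scenario(
                illustrative_model, Scenario(sc["name"], sc["evidence"], ("J",))
            )
            failures[sc["name"]] = post.probability("J", "No")
        assert max(failures, key=failures.get) == "Scenario 5"


class TestExtremeConditions:
    def test_directions_and_evidence_echo(self, illustrative_model):
        report = extreme_condition_test(illustrative_model)
        assert report["worst_evidence"]["26"] == "No"
        assert report["best_evidence"]["26"] == "Yes"
        assert report["checks"]["success_more_likely_when_worst"]
        assert report["checks"]["major_casualties_more_likely_when_worst"]
        assert not report["degenerate"]

    def test_missing_root_is_a_configuration_error(self, xy_net):
        with pytest.raises(ConfigurationError):
            extreme_condition_test(xy_net)


class TestStateFlipSensitivity:
    def test_security_check_dominates_prevention_measures(
        self, illustrative_model
    ):
        effects = {
            node: max(
                r.effect
                for r in state_flip_sensitivity(illustrative_model, node, "K")
            )
            for node in ("25", "26", "27", "28")
        }
        assert max(effects, key=effects.get) == "26"

    def test_disconnected_input_zero_effect(self):
        from chemrisk import (
            BayesianNetwork,
            ConditionalProbabilityTable,
            DiscreteVariable,
        )

        variables = {
            "X": DiscreteVariable("X", "X", ("a", "b")),
            "Y": DiscreteVariable("Y", "Y", ("u", "v")),
        }
        cpts = {
            "X": ConditionalProbabilityTable("X", (), np.array([0.3, 0.7])),
            "Y": ConditionalProbabilityTable("Y", (), np.array([0.8, 0.2])),
        }
        net = BayesianNetwork(variables, set(), cpts)
        results = state_flip_sensitivity(net, "X", "Y")
        assert all(r.effect < 1e-12 for r in results)

    def test_binary_flip_is_symmetric(self, illustrative_model):
        results = state_flip_sensitivity(illustrative_model, "26", "K")
        assert len(results) == 2
        assert results[0].effect == pytest.approx(results[1].effect, abs=1e-12)


class TestBoundedPriorSensitivity:
    def test_zero_delta_zero_effect(self, illustrative_model):
        r = bounded_prior_sensitivity(illustrative_model, "26", "Yes", 0.0, "K")
        assert r.effect == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_node_chain(self, xy_net):
        # P(X=a): 0.6 -> 0.66, so P(Y=u) = 0.66*0.9 + 0.34*0.2 = 0.662
        r = bounded_prior_sensitivity(xy_net, "X", "a", 0.1, "Y")
        assert r.baseline[0] == pytest.approx(0.62, abs=1e-12)
        assert r.perturbed[0] == pytest.approx(0.662, abs=1e-12)

    def test_larger_delta_larger_effect(self, illustrative_model):
        small = bounded_prior_sensitivity(illustrative_model, "26", "Yes", 0.1, "K")
        large = bounded_prior_sensitivity(illustrative_model, "26", "Yes", 0.2, "K")
        assert large.effect >= small.effect

    def test_perturbation_preserves_normalization(self, illustrative_model):
        for delta in (0.1, 0.2, -0.2):
            net, flags = perturb_prior(illustrative_model, "26", "Yes", delta)
            assert net.cpts["26"].table.sum() == pytest.approx(1.0, abs=1e-9)
            assert flags == []

    def test_overshoot_is_clipped_and_flagged(self, illustrative_model):
        net, flags = perturb_prior(illustrative_model, "23", "Downwind", 0.5)
        assert "clipped" in flags
        assert net.cpts["23"].table.sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_root_rejected(self, illustrative_model):
        with pytest.raises(ConfigurationError):
            bounded_prior_sensitivity(illustrative_model, "J", "Yes", 0.1, "K")


class TestRankSensitivities:
    def test_deterministic_total_ordering(self, illustrative_model):
        a = rank_sensitivities(illustrative_model, "K", 0.1)
        b = rank_sensitivities(illustrative_model, "K", 0.1)
        assert [r.node for r in a] == [r.node for r in b]
        assert len(a) == 31
        effects = [r.effect for r in a]
        assert effects == sorted(effects, reverse=True)

    def test_top_node_attains_the_maximum(self, illustrative_model):
        ranked = rank_sensitivities(illustrative_model, "K", 0.1)
        top = ranked[0]
        direct = bounded_prior_sensitivity(
            illustrative_model, top.node, top.state, 0.1, "K"
        )
        assert top.effect == pytest.approx(direct.effect, abs=1e-12)


class TestDefenseRegimes:
    @pytest.mark.parametrize("target", sorted(TARGET_PROFILES))
    def test_more_measures_mean_fewer_successes(self, illustrative_model, target):
        """Published ordering: no measures > patrol+surveillance > all measures."""
        base = dict(ORGANISATION_PROFILES["Organisation 1"])
        base.update(TARGET_PROFILES[target])
        regimes = {
            "none": {"25": "Less than 2 times", "26": "No", "27": "Non-24 h",
                     "28": "No"},
            "patrol+surveillance": {"25": "More than 2 times", "26": "No",
                                    "27": "24 h", "28": "No"},
            "all": {"25": "More than 2 times", "26": "Yes", "27": "24 h",
                    "28": "Yes"},
        }
        p_yes = {}
        for name, measures in regimes.items():
            evidence = dict(base)
            evidence.update(measures)
            post = query_posterior(illustrative_model, ["J"], evidence)
            p_yes[name] = post.probability("J", "Yes")
        assert p_yes["none"] > p_yes["patrol+surveillance"] > p_yes["all"]
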