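"""Axiom-based partial validation of expert-built networks."""

import numpy as np
import pytest

from chemrisk import (
    Perturbation,
    check_axiom1,
    check_axiom2,
    check_axiom3,
    partial_validation_report,
    query_posterior,
)
from chemrisk.axioms import default_battery
from chemrisk.errors import ConfigurationError


class TestAxiom1:
    def test_security_check_nudge_moves_prevention_and_success(
        self, illustrative_model
    ):
        """Raising the security-check prior raises P(prevention=High) and
        P(attack fails), the direction a protective measure must act in."""
        for target, state in (("G", "High"), ("J", "No")):
            check = check_axiom1(illustrative_model, "26", "Yes", 0.125, target)
            assert check.verdict == "pass"
            var = illustrative_model.variables[target]
            baseline = query_posterior(illustrative_model, [target])[target]
            change = check.changes[0]
            assert change[var.state_index(state)] > 0

    def test_d_separated_nodes_pass_with_note(self):
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
        check = check_axiom1(net, "X", "a", 0.1, "Y")
        assert check.verdict == "pass-with-note"

    def test_zero_delta_is_a_vacuous_pass(self, xy_net):
        check = check_axiom1(xy_net, "X", "a", 0.0, "Y")
        assert check.verdict == "pass-with-note"

    def test_same_root_and_target_rejected(self, xy_net):
        with pytest.raises(ConfigurationError):
            check_axiom1(xy_net, "X", "a", 0.1, "X")


class TestAxiom2:
    def test_monotone_chain_passes(self, xy_net):
        check = check_axiom2(xy_net, "X", "a", [0.05, 0.10, 0.20], "Y")
        assert check.verdict == "pass"
        mags = [float(np.max(np.abs(c))) for c in check.changes]
        assert mags == sorted(mags)

    def test_mixed_sign_deltas_fail(self, xy_net):
        """Shrinking then growing the same prior state pushes the child
        posterior in opposite directions: recorded as an axiom violation."""
        check = check_axiom2(xy_net, "X", "a", [-0.2, 0.1, 0.2], "Y")
        assert check.verdict == "fail"
        assert any("flips" in line for line in check.trace)

    def test_uniform_degenerate_child_passes_with_note(self):
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
            "X": ConditionalProbabilityTable("X", (), np.array([0.5, 0.5])),
            "Y": ConditionalProbabilityTable(
                "Y", ("X",), np.full((2, 2), 0.5)
            ),
        }
        net = BayesianNetwork(variables, {("X", "Y")}, cpts)
        check = check_axiom2(net, "X", "a", [0.1, 0.2], "Y")
        assert check.verdict == "pass-with-note"

    def test_non_increasing_deltas_rejected(self, xy_net):
        with pytest.raises(ConfigurationError):
            check_axiom2(xy_net, "X", "a", [0.2, 0.1], "Y")


class TestAxiom3:
    def test_combined_protection_dominates_each_alone(self, illustrative_model):
        """Security-check and upwind-shift nudges each raise P(J=No); jointly
        they must raise it at least as much as either alone."""
        perts = [
            Perturbation("26", "Yes", 0.125),
            Perturbation("23", "Upwind", 2 / 3),
        ]
        check = check_axiom3(illustrative_model, perts, "J", "No")
        assert check.verdict == "pass"

    def test_single_perturbation_trivially_passes(self, xy_net):
        check = check_axiom3(xy_net, [Perturbation("X", "a", 0.1)], "Y", "u")
        assert check.verdict == "pass"

    def test_mixed_direction_perturbations_inapplicable(self, xy_net):
        perts = [
            Perturbation("X", "a", 0.1),
            Perturbation("X", "b", 0.1),
        ]
        check = check_axiom3(xy_net, perts, "Y", "u")
        assert check.verdict == "inapplicable"

    def test_d_separated_roots_add_independently(self):
        """With independent roots feeding one child, the combined effect on
        the child equals the sum of single effects plus the (tiny)
        interaction term; verified against direct enumeration."""
        from chemrisk import (
            BayesianNetwork,
            ConditionalProbabilityTable,
            DiscreteVariable,
            brute_force_posterior,
        )
        from chemrisk.analysis import perturb_prior

        variables = {
            "X": DiscreteVariable("X", "X", ("a", "b")),
            "Z": DiscreteVariable("Z", "Z", ("c", "d")),
            "Y": DiscreteVariable("Y", "Y", ("u", "v")),
        }
        cpts = {
            "X": ConditionalProbabilityTable("X", (), np.array([0.4, 0.6])),
            "Z": ConditionalProbabilityTable("Z", (), np.array([0.3, 0.7])),
            "Y": ConditionalProbabilityTable(
                "Y",
                ("X", "Z"),
                np.array(
                    [[[0.9, 0.1], [0.7, 0.3]], [[0.5, 0.5], [0.2, 0.8]]]
                ),
            ),
        }
        net = BayesianNetwork(
            variables, {("X", "Y"), ("Z", "Y")}, cpts
        )
        delta = 0.005  # small enough that the bilinear interaction term
        # (product of the two mass shifts) stays well below the tolerance
        perts = [Perturbation("X", "a", delta), Perturbation("Z", "c", delta)]
        check = check_axiom3(net, perts, "Y", "u")
        assert check.verdict == "pass"
        # oracle: apply both via enumeration and compare with single sums
        base = brute_force_posterior(net, ["Y"]).probability("Y", "u")
        net_x, _ = perturb_prior(net, "X", "a", delta)
        net_z, _ = perturb_prior(net, "Z", "c", delta)
        net_xz, _ = perturb_prior(net_x, "Z", "c", delta)
        ex = brute_force_posterior(net_x, ["Y"]).probability("Y", "u") - base
        ez = brute_force_posterior(net_z, ["Y"]).probability("Y", "u") - base
        exz = brute_force_posterior(net_xz, ["Y"]).probability("Y", "u") - base
        assert exz == pytest.approx(ex + ez, abs=1e-6)


class TestBattery:
    def test_default_battery_passes_on_illustrative_model(
        self, illustrative_model
    ):
        report = partial_validation_report(illustrative_model, default_battery())
        assert report["all_passed"]
        assert report["counts"]["fail"] == 0

    def test_checks_do_not_mutate_the_model(self, illustrative_model):
        before = {k: c.table.copy() for k, c in illustrative_model.cpts.items()}
        partial_validation_report(illustrative_model, default_battery())
        for k, arr in before.items():
            assert np.array_equal(arr, illustrative_model.cpts[k].table)

    def test_failing_entry_is_reported(self, xy_net):
        battery = [
            {"axiom": 2, "root": "X", "state": "a", "deltas": [-0.2, 0.2],
             "child_target": "Y"},
        ]
        report = partial_validation_report(xy_net, battery)
        assert not report["all_passed"]
        assert report["counts"]["fail"] == 1

    def test_empty_battery_rejected(self, xy_net):
        with pytest.raises(ConfigurationError):
            partial_validation_report(xy_net, [])
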