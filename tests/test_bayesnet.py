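"""Data model, exact inference, enumeration oracle, sampling, likelihood."""

import itertools
import math

import numpy as np
import pytest

from chemrisk import (
    BayesianNetwork,
    CaseTable,
    ConditionalProbabilityTable,
    DiscreteVariable,
    brute_force_posterior,
    forward_sample,
    generate_random_model,
    joint_probability,
    log_likelihood,
    query_posterior,
    validate_network,
)
from chemrisk.bayesnet import MISSING, log_likelihood_details
from chemrisk.errors import (
    IncompleteAssignmentError,
    ModelError,
    OracleTooLargeError,
    ZeroProbabilityEvidenceError,
)


def _net(variables, edges, cpts):
    return BayesianNetwork(variables, edges, cpts, check=False)


class TestValidateNetwork:
    def test_well_formed_net_yields_empty_report(self, xy_net):
        assert validate_network(xy_net) == []

    def test_unnormalized_row_is_named(self, xy_net):
        bad = xy_net.copy()
        bad.cpts["Y"] = ConditionalProbabilityTable(
            "Y", ("X",), np.array([[0.5, 0.6], [0.2, 0.8]]), check=False
        )
        report = validate_network(bad)
        assert len(report) == 1
        assert "'Y'" in report[0] and "1.1" in report[0]

    def test_two_cycle_is_reported(self):
        variables = {
            "X": DiscreteVariable("X", "X", ("a", "b")),
            "Y": DiscreteVariable("Y", "Y", ("a", "b")),
        }
        cpts = {
            "X": ConditionalProbabilityTable(
                "X", ("Y",), np.full((2, 2), 0.5), check=False
            ),
            "Y": ConditionalProbabilityTable(
                "Y", ("X",), np.full((2, 2), 0.5), check=False
            ),
        }
        net = _net(variables, {("X", "Y"), ("Y", "X")}, cpts)
        assert any("cycle" in v for v in validate_network(net))

    def test_duplicate_states_rejected(self):
        with pytest.raises(ModelError):
            DiscreteVariable("X", "X", ("a", "a"))

    def test_single_state_rejected(self):
        with pytest.raises(ModelError):
            DiscreteVariable("X", "X", ("a",))


class TestJointProbability:
    def test_single_root(self):
        variables = {"X": DiscreteVariable("X", "X", ("s1", "s2"))}
        cpts = {"X": ConditionalProbabilityTable("X", (), np.array([0.6, 0.4]))}
        net = BayesianNetwork(variables, set(), cpts)
        assert joint_probability(net, {"X": "s1"}) == pytest.approx(0.6)

    def test_chain_product(self, xy_net):
        assert joint_probability(xy_net, {"X": "a", "Y": "u"}) == pytest.approx(
            0.54
        )

    def test_full_assignments_sum_to_one(self):
        net = generate_random_model(5, seed=11)
        total = sum(
            joint_probability(net, dict(zip(net.variables, combo)))
            for combo in itertools.product(
                *(v.states for v in net.variables.values())
            )
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_incomplete_assignment_raises(self, xy_net):
        with pytest.raises(IncompleteAssignmentError):
            joint_probability(xy_net, {"X": "a"})


class TestQueryPosterior:
    def test_posterior_given_descendant(self, xy_net):
        post = query_posterior(xy_net, ["X"], {"Y": "u"})
        assert post.probability("X", "a") == pytest.approx(0.54 / 0.62, abs=1e-9)

    def test_no_evidence_root_posterior_is_prior(self, xy_net):
        post = query_posterior(xy_net, ["X"])
        assert np.allclose(post["X"], [0.6, 0.4])

    def test_zero_probability_evidence_raises(self):
        variables = {
            "X": DiscreteVariable("X", "X", ("a", "b")),
            "Y": DiscreteVariable("Y", "Y", ("u", "v")),
        }
        cpts = {
            "X": ConditionalProbabilityTable("X", (), np.array([1.0, 0.0])),
            "Y": ConditionalProbabilityTable(
                "Y", ("X",), np.array([[1.0, 0.0], [0.0, 1.0]])
            ),
        }
        net = BayesianNetwork(variables, {("X", "Y")}, cpts)
        with pytest.raises(ZeroProbabilityEvidenceError):
            query_posterior(net, ["X"], {"Y": "v"})

    def test_target_in_evidence_rejected(self, xy_net):
        with pytest.raises(ModelError):
            query_posterior(xy_net, ["Y"], {"Y": "u"})

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_on_random_nets(self, seed):
        net = generate_random_model(6, seed=seed)
        rng = np.random.default_rng(seed + 100)
        ids = list(net.variables)
        for trial in range(3):
            n_ev = int(rng.integers(0, 3))
            ev_vars = list(rng.choice(ids, size=n_ev, replace=False))
            evidence = {
                v: net.variables[v].states[
                    int(rng.integers(net.variables[v].cardinality))
                ]
                for v in ev_vars
            }
            targets = [v for v in ids if v not in evidence]
            try:
                ve = query_posterior(net, targets, evidence)
            except ZeroProbabilityEvidenceError:
                continue
            bf = brute_force_posterior(net, targets, evidence)
            for t in targets:
                assert np.max(np.abs(ve[t] - bf[t])) < 1e-9


class TestBruteForce:
    def test_deterministic_net_point_mass(self):
        variables = {
            "X": DiscreteVariable("X", "X", ("a", "b")),
            "Y": DiscreteVariable("Y", "Y", ("u", "v")),
        }
        cpts = {
            "X": ConditionalProbabilityTable("X", (), np.array([1.0, 0.0])),
            "Y": ConditionalProbabilityTable(
                "Y", ("X",), np.array([[0.0, 1.0], [1.0, 0.0]])
            ),
        }
        net = BayesianNetwork(variables, {("X", "Y")}, cpts)
        post = brute_force_posterior(net, ["Y"])
        assert np.allclose(post["Y"], [0.0, 1.0])

    def test_uniform_net_uniform_posteriors(self):
        variables = {
            "X": DiscreteVariable("X", "X", ("a", "b", "c")),
            "Y": DiscreteVariable("Y", "Y", ("u", "v")),
        }
        cpts = {
            "X": ConditionalProbabilityTable("X", (), np.full(3, 1 / 3)),
            "Y": ConditionalProbabilityTable(
                "Y", ("X",), np.full((3, 2), 0.5)
            ),
        }
        net = BayesianNetwork(variables, {("X", "Y")}, cpts)
        post = brute_force_posterior(net, ["X", "Y"])
        assert np.allclose(post["X"], 1 / 3)
        assert np.allclose(post["Y"], 0.5)

    def test_state_space_cap(self, xy_net):
        with pytest.raises(OracleTooLargeError):
            brute_force_posterior(xy_net, ["X"], cap=3)


class TestForwardSample:
    def test_root_marginal_within_binomial_bound(self):
        variables = {"X": DiscreteVariable("X", "X", ("s1", "s2"))}
        cpts = {"X": ConditionalProbabilityTable("X", (), np.array([0.6, 0.4]))}
        net = BayesianNetwork(variables, set(), cpts)
        cases = forward_sample(net, 10_000, seed=5)
        freq = sum(r[0] == "s1" for r in cases.records) / 10_000
        assert abs(freq - 0.6) < 0.015

    def test_deterministic_net_all_identical(self):
        variables = {
            "X": DiscreteVariable("X", "X", ("a", "b")),
            "Y": DiscreteVariable("Y", "Y", ("u", "v")),
        }
        cpts = {
            "X": ConditionalProbabilityTable("X", (), np.array([0.0, 1.0])),
            "Y": ConditionalProbabilityTable(
                "Y", ("X",), np.array([[1.0, 0.0], [0.0, 1.0]])
            ),
        }
        net = BayesianNetwork(variables, {("X", "Y")}, cpts)
        cases = forward_sample(net, 50, seed=1)
        assert set(cases.records) == {("b", "v")}

    def test_same_seed_reproduces(self):
        net = generate_random_model(5, seed=2)
        a = forward_sample(net, 200, seed=9)
        b = forward_sample(net, 200, seed=9)
        assert a.records == b.records

    def test_empirical_marginals_match_exact(self):
        net = generate_random_model(4, seed=13)
        n = 100_000
        cases = forward_sample(net, n, seed=3)
        for i, vid in enumerate(cases.columns):
            exact = query_posterior(net, [vid])[vid]
            states = net.variables[vid].states
            for j, s in enumerate(states):
                p = exact[j]
                freq = sum(r[i] == s for r in cases.records) / n
                assert abs(freq - p) < 4 * math.sqrt(p * (1 - p) / n) + 1e-12


class TestLogLikelihood:
    def test_complete_record(self, xy_net):
        cases = CaseTable(("X", "Y"), [("a", "u")])
        assert log_likelihood(xy_net, cases) == pytest.approx(math.log(0.54))

    def test_missing_value_marginalized(self, xy_net):
        cases = CaseTable(("X", "Y"), [(MISSING, "u")])
        assert log_likelihood(xy_net, cases) == pytest.approx(math.log(0.62))

    def test_empty_table_zero(self, xy_net):
        assert log_likelihood(xy_net, CaseTable(("X", "Y"), [])) == 0.0

    def test_impossible_record_reported(self):
        variables = {"X": DiscreteVariable("X", "X", ("a", "b"))}
        cpts = {"X": ConditionalProbabilityTable("X", (), np.array([1.0, 0.0]))}
        net = BayesianNetwork(variables, set(), cpts)
        cases = CaseTable(("X",), [("a",), ("b",)])
        total, offenders = log_likelihood_details(net, cases)
        assert total == -math.inf
        assert offenders == [1]


class TestCaseTableIO:
    def test_csv_round_trip_with_missing(self, tmp_path, xy_net):
        cases = CaseTable(("X", "Y"), [("a", MISSING), (MISSING, "v")])
        path = tmp_path / "cases.csv"
        cases.to_csv(path)
        assert CaseTable.from_csv(path).records == cases.records

    def test_na_token_read_as_missing(self, tmp_path):
        path = tmp_path / "cases.csv"
        path.write_text("X,Y\na,NA\n,v\n")
        cases = CaseTable.from_csv(path)
        assert cases.records == [("a", MISSING), (MISSING, "v")]

    def test_illegal_state_rejected(self, xy_net):
        cases = CaseTable(("X",), [("zzz",)])
        with pytest.raises(ModelError):
            cases.validate_against(xy_net)
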