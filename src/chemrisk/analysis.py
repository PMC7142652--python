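"""Scenario, extreme-condition and sensitivity analysis over a network.

Two distinct sensitivity semantics are provided and deliberately kept
apart:

* :func:`state_flip_sensitivity` conditions an input node on each of its
  states as hard evidence and compares the target posteriors — the
  "switch a measure on/off" reading.
* :func:`bounded_prior_sensitivity` perturbs a root prior multiplicatively
  by a bounded fraction (10%, 20%, ...) with proportional co-variation of
  the remaining states — the "resources move a prior a little" reading.

Effect size is the L-infinity distance between target distributions (the
largest single-state probability change); total variation is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayesnet import (
    BayesianNetwork,
    ConditionalProbabilityTable,
    PosteriorTable,
    query_posterior,
)
from .errors import ConfigurationError, ZeroProbabilityEvidenceError
from .attack_model import EXTREME_BEST, EXTREME_WORST, PARENT_IDS

__all__ = [
    "Scenario",
    "SensitivityResult",
    "run_scenario",
    "extreme_condition_test",
    "state_flip_sensitivity",
    "bounded_prior_sensitivity",
    "rank_sensitivities",
    "perturb_prior",
]

DEFAULT_TARGETS = ("E", "G", "H", "I", "J", "K")


@dataclass
class Scenario:
    """A named partial evidence assignment plus query targets."""

    name: str
    evidence: dict[str, str]
    targets: tuple[str, ...] = DEFAULT_TARGETS
    description: str = ""

    def __post_init__(self) -> None:
        if not self.targets:
            raise ConfigurationError("scenario needs at least one target")


@dataclass
class SensitivityResult:
    """Outcome of one perturbation: baseline vs perturbed target posterior."""

    node: str
    state: str
    size: "float | str"
    target: str
    baseline: np.ndarray
    perturbed: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def effect(self) -> float:
        """L-infinity distance between baseline and perturbed distributions."""
        return float(np.max(np.abs(self.perturbed - self.baseline)))

    @property
    def total_variation(self) -> float:
        return 0.5 * float(np.abs(self.perturbed - self.baseline).sum())


def run_scenario(net: BayesianNetwork, scenario: Scenario) -> PosteriorTable:
    """Posteriors of the scenario's targets given its evidence.

    A thin, audited wrapper over :func:`query_posterior`: the returned table
    echoes the evidence, and zero-probability evidence is reported with the
    scenario's name.
    """
    targets = tuple(t for t in scenario.targets if t not in scenario.evidence)
    if not targets:
        raise ConfigurationError(
            f"{scenario.name}: every target is fixed by the evidence"
        )
    try:
        return query_posterior(net, targets, scenario.evidence)
    except ZeroProbabilityEvidenceError as exc:
        raise ZeroProbabilityEvidenceError(
            f"{scenario.name}: {exc}"
        ) from None


def extreme_condition_test(
    net: BayesianNetwork,
    targets: tuple[str, ...] = ("G", "H", "I", "J", "K"),
) -> dict:
    """Worst-case vs best-case root assignments, with direction checks.

    Sets all 31 roots to their most attack-favourable states, then to their
    least favourable ones, and reports the posteriors of the child targets.
    The report records whether attack success and major casualties are more
    probable under the worst condition, as they must be for any sensibly
    oriented model.
    """
    for node in PARENT_IDS:
        if node not in net.variables:
            raise ConfigurationError(
                f"model is missing extreme-condition node {node!r}"
            )
    targets = tuple(t for t in targets if t in net.variables)
    worst = query_posterior(net, targets, EXTREME_WORST)
    best = query_posterior(net, targets, EXTREME_BEST)
    checks = {}
    if "J" in targets:
        checks["success_more_likely_when_worst"] = (
            worst.probability("J", "Yes") > best.probability("J", "Yes")
        )
    if "K" in targets:
        checks["major_casualties_more_likely_when_worst"] = (
            worst.probability("K", "Major") > best.probability("K", "Major")
        )
    return {
        "worst_evidence": dict(EXTREME_WORST),
        "best_evidence": dict(EXTREME_BEST),
        "worst": worst,
        "best": best,
        "checks": checks,
        "degenerate": bool(
            checks
            and all(
                np.allclose(worst[t], best[t]) for t in targets
            )
        ),
    }


def state_flip_sensitivity(
    net: BayesianNetwork, input_node: str, target: str
) -> list[SensitivityResult]:
    """Condition ``input_node`` on each of its states; compare target posteriors.

    One result per ordered state pair (reference state, flipped state); for
    a binary node this is the yes-vs-no comparison in both directions.
    """
    if input_node == target:
        raise ConfigurationError("input node and target must differ")
    states = net.variables[input_node].states
    post = {
        s: query_posterior(net, [target], {input_node: s})[target]
        for s in states
    }
    results = []
    for ref in states:
        for flip in states:
            if ref == flip:
                continue
            results.append(
                SensitivityResult(
                    node=input_node,
                    state=flip,
                    size=f"{ref}->{flip}",
                    target=target,
                    baseline=post[ref],
                    perturbed=post[flip],
                )
            )
    return results


def perturb_prior(
    net: BayesianNetwork, root_node: str, state: str, delta: float
) -> tuple[BayesianNetwork, list[str]]:
    """Multiplicative prior perturbation with proportional co-variation.

    The named state's mass becomes p*(1+delta); the other states share the
    remainder in their original proportions.  If the perturbed mass leaves
    [0, 1] it is clipped and the result flagged.
    """
    cpt = net.cpts[root_node]
    if cpt.parents:
        raise ConfigurationError(f"{root_node!r} is not a root node")
    var = net.variables[root_node]
    idx = var.state_index(state)
    p = float(cpt.table[idx])
    flags: list[str] = []
    new_p = p * (1.0 + delta)
    if new_p > 1.0 or new_p < 0.0:
        new_p = min(1.0, max(0.0, new_p))
        flags.append("clipped")
    rest = 1.0 - p
    vec = cpt.table.copy()
    if rest > 0:
        vec *= (1.0 - new_p) / rest
    else:
        vec[:] = (1.0 - new_p) / (var.cardinality - 1)
    vec[idx] = new_p
    perturbed = net.copy()
    perturbed.cpts[root_node] = ConditionalProbabilityTable(root_node, (), vec)
    return perturbed, flags


def bounded_prior_sensitivity(
    net: BayesianNetwork,
    root_node: str,
    state: str,
    delta: float,
    target: str,
) -> SensitivityResult:
    """Effect on ``target`` of a bounded (e.g. 10%/20%) prior change."""
    baseline = query_posterior(net, [target])[target]
    perturbed_net, flags = perturb_prior(net, root_node, state, delta)
    perturbed = query_posterior(perturbed_net, [target])[target]
    return SensitivityResult(
        node=root_node,
        state=state,
        size=delta,
        target=target,
        baseline=baseline,
        perturbed=perturbed,
        flags=flags,
    )


def rank_sensitivities(
    net: BayesianNetwork,
    target: str,
    delta: float,
    roots: "tuple[str, ...] | None" = None,
) -> list[SensitivityResult]:
    """Rank all root nodes by their largest single-state effect on ``target``.

    For each root the most attack-relevant perturbation over its states is
    taken (max effect over states); the list is sorted by descending effect
    with a deterministic tie-break by node id.
    """
    if target not in net.variables:
        raise ConfigurationError(f"unknown target {target!r}")
    if roots is None:
        roots = tuple(
            v for v in net.variables if not net.cpts[v].parents and v != target
        )
    best: list[SensitivityResult] = []
    for node in roots:
        per_state = [
            bounded_prior_sensitivity(net, node, s, delta, target)
            for s in net.variables[node].states
        ]
        best.append(max(per_state, key=lambda r: r.effect))
    return sorted(best, key=lambda r: (-r.effect, r.node))
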