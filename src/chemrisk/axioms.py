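"""Partial model validation by three directional-consistency axioms.

An expert-built network whose CPTs cannot be checked against held-out data
can still be screened for basic causal sanity:

1. Nudging a root prior must move the posterior of a downstream node, in
   the direction implied by conditioning on the nudged state (no change is
   acceptable only when the nodes are d-separated).
2. Larger nudges of the same root state must move the child posterior in a
   consistent direction with non-decreasing magnitude.
3. The joint impact of several same-direction nudges must be at least as
   large as the impact of any proper subset of them (super-additivity of
   combined influences).

Checks are pure — they work on copies and never mutate the input model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import perturb_prior
from .bayesnet import BayesianNetwork, query_posterior
from .errors import ConfigurationError

__all__ = [
    "AxiomCheck",
    "Perturbation",
    "check_axiom1",
    "check_axiom2",
    "check_axiom3",
    "partial_validation_report",
]

#: below this, a posterior change counts as "no change"
NO_CHANGE_TOL = 1e-12
#: slack for axiom-3 magnitude comparisons (floating-point pipelines)
SUPERADD_TOL = 1e-9


@dataclass(frozen=True)
class Perturbation:
    """One root-prior nudge: raise P(root = state) by the fraction delta."""

    root: str
    state: str
    delta: float


@dataclass
class AxiomCheck:
    """Verdict and full trace of one axiom evaluation."""

    axiom: int
    nodes: dict
    perturbations: list
    changes: list
    verdict: str  # "pass" | "pass-with-note" | "fail" | "inapplicable"
    trace: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.verdict in ("pass", "pass-with-note")


def _direction_probe(
    net: BayesianNetwork, root: str, state: str, target: str
) -> np.ndarray:
    """Sign pattern of the influence of ``root=state`` on ``target``.

    Mixture identity: raising P(root=state) with proportional co-variation
    moves the target posterior along P(target | root=state) - P(target |
    root != state), so conditioning gives the implied direction per state.
    """
    on = query_posterior(net, [target], {root: state})[target]
    prior = query_posterior(net, [target])[target]
    return np.sign(np.where(np.abs(on - prior) < NO_CHANGE_TOL, 0.0, on - prior))


def _posterior_change(
    net: BayesianNetwork,
    perturbations: "list[Perturbation]",
    target: str,
) -> tuple[np.ndarray, list[str]]:
    """Target-posterior change vector after applying perturbations jointly."""
    baseline = query_posterior(net, [target])[target]
    perturbed_net = net
    flags: list[str] = []
    for p in perturbations:
        perturbed_net, f = perturb_prior(perturbed_net, p.root, p.state, p.delta)
        flags.extend(f"{p.root}: {msg}" for msg in f)
    after = query_posterior(perturbed_net, [target])[target]
    return after - baseline, flags


def check_axiom1(
    net: BayesianNetwork,
    root: str,
    state: str,
    delta: float,
    child_target: str,
) -> AxiomCheck:
    """A prior nudge must move the downstream posterior consistently."""
    if root == child_target:
        raise ConfigurationError("root and target must differ")
    if net.cpts[root].parents:
        raise ConfigurationError(f"{root!r} is not a prior (root) node")
    probe = _direction_probe(net, root, state, child_target)
    change, flags = _posterior_change(
        net, [Perturbation(root, state, delta)], child_target
    )
    trace = [f"direction probe: {probe.tolist()}", f"change: {change.tolist()}"]
    trace.extend(flags)
    moved = np.abs(change) > NO_CHANGE_TOL
    if delta == 0 or not moved.any():
        if probe.any():
            verdict = "fail" if delta != 0 else "pass-with-note"
            if delta == 0:
                trace.append("zero perturbation: vacuous pass")
            else:
                trace.append("connected nodes but no posterior movement")
        else:
            verdict = "pass-with-note"
            trace.append("no movement and flat probe: d-separated nodes")
    else:
        consistent = np.all(
            (np.sign(change) == probe) | ~moved
        )
        verdict = "pass" if consistent else "fail"
        if not consistent:
            trace.append("posterior moved against the conditioning direction")
    return AxiomCheck(
        axiom=1,
        nodes={"root": root, "state": state, "target": child_target},
        perturbations=[Perturbation(root, state, delta)],
        changes=[change],
        verdict=verdict,
        trace=trace,
    )


def check_axiom2(
    net: BayesianNetwork,
    root: str,
    state: str,
    deltas: "list[float]",
    child_target: str,
) -> AxiomCheck:
    """Growing nudges must act in one direction with growing magnitude."""
    if len(deltas) < 2 or any(
        b <= a for a, b in zip(deltas, deltas[1:])
    ):
        raise ConfigurationError("deltas must be a strictly increasing list of >=2")
    changes = []
    trace = []
    for d in deltas:
        change, flags = _posterior_change(
            net, [Perturbation(root, state, d)], child_target
        )
        changes.append(change)
        trace.append(f"delta={d}: change {change.tolist()}")
        trace.extend(flags)
    mags = [float(np.max(np.abs(c))) for c in changes]
    if all(m <= NO_CHANGE_TOL for m in mags):
        return AxiomCheck(
            2,
            {"root": root, "state": state, "target": child_target},
            [Perturbation(root, state, d) for d in deltas],
            changes,
            "pass-with-note",
            trace + ["no effect at any delta (independent or degenerate)"],
        )
    signs = [np.sign(np.where(np.abs(c) < NO_CHANGE_TOL, 0.0, c)) for c in changes]
    ref = next(s for s, m in zip(signs, mags) if m > NO_CHANGE_TOL)
    same_sign = all(
        np.all((s == ref) | (s == 0)) for s in signs
    )
    monotone = all(
        b >= a - SUPERADD_TOL for a, b in zip(mags, mags[1:])
    )
    verdict = "pass" if (same_sign and monotone) else "fail"
    if not same_sign:
        trace.append("effect direction flips across deltas")
    if not monotone:
        trace.append("effect magnitude decreases for a larger delta")
    return AxiomCheck(
        2,
        {"root": root, "state": state, "target": child_target},
        [Perturbation(root, state, d) for d in deltas],
        changes,
        verdict,
        trace,
    )


def check_axiom3(
    net: BayesianNetwork,
    perturbations: "list[Perturbation]",
    child_target: str,
    target_state: str,
) -> AxiomCheck:
    """Combined same-direction nudges must dominate every proper subset.

    The effect is the signed change of P(child_target = target_state).  All
    perturbations must individually move it in the same direction — the
    axiom is inapplicable (reported, not failed) otherwise.
    """
    var = net.variables[child_target]
    sidx = var.state_index(target_state)
    trace: list[str] = []
    singles = []
    for p in perturbations:
        change, flags = _posterior_change(net, [p], child_target)
        singles.append(float(change[sidx]))
        trace.append(f"{p.root}={p.state} delta={p.delta}: {change[sidx]:+.3e}")
        trace.extend(flags)
    active = [s for s in singles if abs(s) > NO_CHANGE_TOL]
    if active and (min(active) < 0 < max(active)):
        return AxiomCheck(
            3,
            {"target": child_target, "state": target_state},
            list(perturbations),
            singles,
            "inapplicable",
            trace + ["perturbations act in mixed directions on the target"],
        )
    # combined and all proper subsets
    n = len(perturbations)
    effects: dict[tuple[int, ...], float] = {}
    for mask in range(1, 2**n):
        subset = tuple(i for i in range(n) if mask & (1 << i))
        change, _ = _posterior_change(
            net, [perturbations[i] for i in subset], child_target
        )
        effects[subset] = float(change[sidx])
    full = tuple(range(n))
    combined = effects[full]
    ok = all(
        abs(combined) >= abs(eff) - SUPERADD_TOL
        for subset, eff in effects.items()
        if subset != full
    )
    trace.append(f"combined: {combined:+.3e}")
    return AxiomCheck(
        3,
        {"target": child_target, "state": target_state},
        list(perturbations),
        [effects[k] for k in sorted(effects)],
        "pass" if ok else "fail",
        trace,
    )


def partial_validation_report(
    net: BayesianNetwork, battery: "list[dict]"
) -> dict:
    """Run a configured battery of axiom checks and aggregate verdicts.

    Each battery entry is a dict with an ``axiom`` key (1, 2 or 3) and the
    keyword arguments of the corresponding check.  CPTs are snapshotted and
    compared afterwards to guarantee the checks were pure.
    """
    if not battery:
        raise ConfigurationError("validation battery is empty")
    before = {k: c.table.copy() for k, c in net.cpts.items()}
    checks: list[AxiomCheck] = []
    for entry in battery:
        entry = dict(entry)
        axiom = entry.pop("axiom")
        if axiom == 1:
            checks.append(check_axiom1(net, **entry))
        elif axiom == 2:
            checks.append(check_axiom2(net, **entry))
        elif axiom == 3:
            perts = [Perturbation(**p) for p in entry.pop("perturbations")]
            checks.append(check_axiom3(net, perts, **entry))
        else:
            raise ConfigurationError(f"unknown axiom {axiom!r}")
    for k, arr in before.items():
        if not np.array_equal(arr, net.cpts[k].table):
            raise RuntimeError(f"axiom check mutated CPT of {k!r}")
    counts = {
        v: sum(1 for c in checks if c.verdict == v)
        for v in ("pass", "pass-with-note", "fail", "inapplicable")
    }
    return {
        "checks": checks,
        "counts": counts,
        "all_passed": counts["fail"] == 0,
    }


def default_battery() -> "list[dict]":
    """The packaged regression battery for the illustrative attack model.

    Mirrors the published walk-through: nudging the security-check prior up
    (axiom 1 on police prevention and on attack success, axiom 2 over
    growing nudges) and combining it with an upwind-shift of the wind
    direction (axiom 3 on attack failure).
    """
    return [
        {"axiom": 1, "root": "26", "state": "Yes", "delta": 0.125,
         "child_target": "G"},
        {"axiom": 1, "root": "26", "state": "Yes", "delta": 0.125,
         "child_target": "J"},
        {"axiom": 2, "root": "26", "state": "Yes",
         "deltas": [0.05, 0.10, 0.20], "child_target": "J"},
        {"axiom": 3, "perturbations": [
            {"root": "26", "state": "Yes", "delta": 0.125},
            {"root": "23", "state": "Upwind", "delta": 2 / 3},
        ], "child_target": "J", "target_state": "No"},
    ]
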