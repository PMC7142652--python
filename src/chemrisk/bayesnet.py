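"""Discrete Bayesian networks: data model, exact inference, sampling.

The network is a DAG of :class:`DiscreteVariable` nodes, each carrying one
:class:`ConditionalProbabilityTable` (a prior when the parent list is empty).
Posterior queries run variable elimination with a min-fill ordering;
:func:`brute_force_posterior` provides the independent enumeration oracle
against which elimination is checked.  Probabilities are handled in linear
space — the networks this package targets are small (tens of nodes, a
handful of states each), so log-space machinery is unnecessary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    IncompleteAssignmentError,
    ModelError,
    OracleTooLargeError,
    ZeroProbabilityEvidenceError,
)

__all__ = [
    "DiscreteVariable",
    "ConditionalProbabilityTable",
    "BayesianNetwork",
    "CaseTable",
    "PosteriorTable",
    "validate_network",
    "joint_probability",
    "query_posterior",
    "brute_force_posterior",
    "forward_sample",
    "log_likelihood",
]

#: CaseTable missing-value marker used in memory.
MISSING = None

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class DiscreteVariable:
    """A named node with an ordered, finite list of state labels.

    State identity is by exact (case-sensitive) label string; the order given
    here fixes the order of every probability vector for this variable.
    """

    id: str
    label: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ModelError(f"variable {self.id!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise ModelError(f"variable {self.id!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ModelError(
                f"{state!r} is not a state of variable {self.id!r} "
                f"(states: {list(self.states)})"
            ) from None


class ConditionalProbabilityTable:
    """P(child | parents) as a dense array.

    ``table`` has shape ``(*parent_cardinalities, child_cardinality)``; a
    prior (no parents) is a 1-D vector.  Rows are addressed by tuples of
    parent state *labels* in the CPT's parent order.
    """

    def __init__(
        self,
        child: str,
        parents: tuple[str, ...],
        table: np.ndarray,
        *,
        check: bool = True,
    ) -> None:
        self.child = child
        self.parents = tuple(parents)
        self.table = np.asarray(table, dtype=float)
        if self.table.ndim != len(self.parents) + 1:
            raise ModelError(
                f"CPT for {child!r}: table rank {self.table.ndim} does not "
                f"match {len(self.parents)} parents"
            )
        if check:
            errs = self.check_rows()
            if errs:
                raise ModelError("; ".join(errs))

    def check_rows(self) -> list[str]:
        """Return human-readable violations (range / normalization)."""
        errs: list[str] = []
        if np.any(self.table < -_NORM_TOL) or np.any(self.table > 1 + _NORM_TOL):
            errs.append(f"CPT for {self.child!r} has entries outside [0, 1]")
        sums = self.table.sum(axis=-1)
        bad = np.argwhere(np.abs(sums - 1.0) > _NORM_TOL)
        for idx in bad[:10]:
            errs.append(
                f"CPT row {tuple(int(i) for i in idx)} of {self.child!r} "
                f"sums to {float(sums[tuple(idx)]):.6g}, not 1"
            )
        return errs

    @classmethod
    def from_rows(
        cls,
        child: str,
        parents: tuple[str, ...],
        rows: dict[tuple[str, ...], "np.ndarray | list[float]"],
        variables: dict[str, DiscreteVariable],
        *,
        check: bool = True,
    ) -> "ConditionalProbabilityTable":
        """Build from a mapping of parent-label tuples to probability vectors."""
        child_var = variables[child]
        shape = tuple(variables[p].cardinality for p in parents) + (
            child_var.cardinality,
        )
        table = np.full(shape, np.nan)
        expected = itertools.product(*(variables[p].states for p in parents))
        expected_set = set(expected)
        for combo, vec in rows.items():
            combo = tuple(combo)
            if combo not in expected_set:
                raise ModelError(
                    f"CPT for {child!r}: unknown parent combination {combo!r}"
                )
            idx = tuple(
                variables[p].state_index(s) for p, s in zip(parents, combo)
            )
            table[idx] = np.asarray(vec, dtype=float)
        if np.isnan(table).any():
            missing = sorted(expected_set - {tuple(c) for c in rows})
            raise ModelError(
                f"CPT for {child!r}: missing rows for {missing[:5]!r}"
            )
        return cls(child, parents, table, check=check)

    def rows(
        self, variables: dict[str, DiscreteVariable]
    ) -> dict[tuple[str, ...], np.ndarray]:
        """Inverse of :meth:`from_rows`."""
        out: dict[tuple[str, ...], np.ndarray] = {}
        for combo in itertools.product(*(variables[p].states for p in self.parents)):
            idx = tuple(
                variables[p].state_index(s) for p, s in zip(self.parents, combo)
            )
            out[combo] = self.table[idx]
        return out

    def row(
        self, combo: tuple[str, ...], variables: dict[str, DiscreteVariable]
    ) -> np.ndarray:
        idx = tuple(
            variables[p].state_index(s) for p, s in zip(self.parents, combo)
        )
        return self.table[idx]

    def copy(self) -> "ConditionalProbabilityTable":
        return ConditionalProbabilityTable(
            self.child, self.parents, self.table.copy(), check=False
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ConditionalProbabilityTable)
            and self.child == other.child
            and self.parents == other.parents
            and self.table.shape == other.table.shape
            and np.array_equal(self.table, other.table)
        )


class BayesianNetwork:
    """A DAG of discrete variables plus one CPT per variable."""

    def __init__(
        self,
        variables: "list[DiscreteVariable] | dict[str, DiscreteVariable]",
        edges: "set[tuple[str, str]] | list[tuple[str, str]]",
        cpts: dict[str, ConditionalProbabilityTable],
        *,
        check: bool = True,
    ) -> None:
        if isinstance(variables, dict):
            self.variables = dict(variables)
        else:
            self.variables = {v.id: v for v in variables}
        self.edges = {(str(a), str(b)) for a, b in edges}
        self.cpts = dict(cpts)
        if check:
            report = validate_network(self)
            if report:
                raise ModelError("; ".join(report))

    def parents(self, var_id: str) -> tuple[str, ...]:
        cpt = self.cpts.get(var_id)
        if cpt is not None:
            return cpt.parents
        return tuple(sorted(a for a, b in self.edges if b == var_id))

    def children(self, var_id: str) -> tuple[str, ...]:
        return tuple(sorted(b for a, b in self.edges if a == var_id))

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list[str]:
        try:
            return list(nx.lexicographical_topological_sort(self.graph()))
        except nx.NetworkXUnfeasible:
            raise ModelError(
                "graph has a cycle; no topological order exists"
            ) from None

    def copy(self) -> "BayesianNetwork":
        return BayesianNetwork(
            dict(self.variables),
            set(self.edges),
            {k: c.copy() for k, c in self.cpts.items()},
            check=False,
        )

    def validate_evidence(self, evidence: dict[str, str]) -> None:
        for var_id, state in evidence.items():
            if var_id not in self.variables:
                raise ModelError(f"evidence names unknown variable {var_id!r}")
            self.variables[var_id].state_index(state)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BayesianNetwork)
            and self.variables == other.variables
            and self.edges == other.edges
            and self.cpts == other.cpts
        )


@dataclass
class CaseTable:
    """Records of (possibly missing) state labels, one column per variable.

    Missing entries are ``None`` in memory.  On disk the table is a UTF-8
    comma-delimited CSV whose first row holds the variable ids; a missing
    value is written as an empty field, and both empty fields and the literal
    string ``NA`` are read back as missing.
    """

    columns: tuple[str, ...]
    records: list[tuple]

    def __post_init__(self) -> None:
        self.columns = tuple(self.columns)
        self.records = [tuple(r) for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def validate_against(self, net: BayesianNetwork) -> None:
        for col in self.columns:
            if col not in net.variables:
                raise ModelError(f"case column {col!r} is not a model variable")
        for i, rec in enumerate(self.records):
            for col, val in zip(self.columns, rec):
                if val is not MISSING:
                    try:
                        net.variables[col].state_index(val)
                    except ModelError as exc:
                        raise ModelError(f"record {i}: {exc}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [[v if v is not MISSING else "" for v in r] for r in self.records],
            columns=list(self.columns),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CaseTable":
        records = []
        for row in df.itertuples(index=False):
            records.append(
                tuple(
                    MISSING if (pd.isna(v) or v in ("", "NA")) else str(v)
                    for v in row
                )
            )
        return cls(tuple(str(c) for c in df.columns), records)

    @classmethod
    def from_csv(cls, path) -> "CaseTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls.from_dataframe(df)


@dataclass
class PosteriorTable:
    """Marginal posterior vectors, one per queried variable."""

    marginals: dict[str, np.ndarray]
    states: dict[str, tuple[str, ...]]
    evidence: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, var_id: str) -> np.ndarray:
        return self.marginals[var_id]

    def probability(self, var_id: str, state: str) -> float:
        return float(self.marginals[var_id][self.states[var_id].index(state)])

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            v: {s: float(p) for s, p in zip(self.states[v], vec)}
            for v, vec in self.marginals.items()
        }


# ---------------------------------------------------------------------------
# validation


def validate_network(net: BayesianNetwork) -> list[str]:
    """Check all structural invariants; return a list of violations.

    An empty list means the network is well-formed.  Violations are reported,
    never raised, so a partially built model can be inspected.
    """
    report: list[str] = []
    for a, b in sorted(net.edges):
        for end in (a, b):
            if end not in net.variables:
                report.append(f"edge ({a},{b}) references unknown variable {end!r}")
    g = nx.DiGraph()
    g.add_nodes_from(net.variables)
    g.add_edges_from(
        (a, b) for a, b in net.edges if a in net.variables and b in net.variables
    )
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        report.append(f"graph contains a directed cycle: {cycle}")
    for var_id in sorted(net.variables):
        cpt = net.cpts.get(var_id)
        if cpt is None:
            report.append(f"variable {var_id!r} has no CPT")
            continue
        graph_parents = tuple(sorted(a for a, b in net.edges if b == var_id))
        if tuple(sorted(cpt.parents)) != graph_parents:
            report.append(
                f"CPT parents {list(cpt.parents)} of {var_id!r} differ from "
                f"graph parents {list(graph_parents)}"
            )
            continue
        expected = tuple(
            net.variables[p].cardinality
            for p in cpt.parents
            if p in net.variables
        ) + (net.variables[var_id].cardinality,)
        if cpt.table.shape != expected:
            report.append(
                f"CPT of {var_id!r} has shape {cpt.table.shape}, expected {expected}"
            )
            continue
        report.extend(cpt.check_rows())
    for var_id in sorted(net.cpts):
        if var_id not in net.variables:
            report.append(f"CPT present for unknown variable {var_id!r}")
    return report


# ---------------------------------------------------------------------------
# factors and variable elimination


class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray) -> None:
        self.vars = vars
        self.values = values


def _multiply(f1: _Factor, f2: _Factor) -> _Factor:
    out_vars = f1.vars + tuple(v for v in f2.vars if v not in f1.vars)
    sl1 = [slice(None) if v in f1.vars else np.newaxis for v in out_vars]
    a1 = f1.values[tuple(sl1)] if len(out_vars) > len(f1.vars) else f1.values
    # f2 axes may be permuted relative to out_vars
    perm = [f2.vars.index(v) for v in out_vars if v in f2.vars]
    a2 = np.transpose(f2.values, perm)
    sl2 = [slice(None) if v in f2.vars else np.newaxis for v in out_vars]
    a2 = a2[tuple(sl2)]
    return _Factor(out_vars, a1 * a2)


def _sum_out(f: _Factor, var: str) -> _Factor:
    axis = f.vars.index(var)
    return _Factor(
        f.vars[:axis] + f.vars[axis + 1 :], f.values.sum(axis=axis)
    )


def _restrict(f: _Factor, var: str, idx: int) -> _Factor:
    axis = f.vars.index(var)
    sl = [slice(None)] * f.values.ndim
    sl[axis] = idx
    return _Factor(f.vars[:axis] + f.vars[axis + 1 :], f.values[tuple(sl)])


def _min_fill_order(
    factors: list[_Factor], eliminate: set[str]
) -> list[str]:
    """Min-fill elimination order with a deterministic tie-break by id."""
    all_vars = {v for f in factors for v in f.vars}
    neighbors: dict[str, set[str]] = {v: set() for v in all_vars}
    for f in factors:
        scope = set(f.vars)
        for v in scope:
            neighbors[v] |= scope - {v}
    order: list[str] = []
    remaining = set(eliminate)
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nb_list = sorted(neighbors[v])
            fill = 0
            for i, u in enumerate(nb_list):
                for w in nb_list[i + 1 :]:
                    if w not in neighbors[u]:
                        fill += 1
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        assert best is not None
        order.append(best)
        remaining.discard(best)
        nb = set(neighbors[best])
        for u in nb:
            neighbors[u] |= nb - {u}
            neighbors[u].discard(best)
        del neighbors[best]
    return order


def _eliminate(
    net: BayesianNetwork,
    keep: tuple[str, ...],
    evidence: dict[str, str],
) -> _Factor:
    """Unnormalized factor over ``keep`` given evidence (VE core).

    The factor's total mass is P(evidence).
    """
    net.validate_evidence(evidence)
    ev_idx = {
        v: net.variables[v].state_index(s) for v, s in evidence.items()
    }
    factors: list[_Factor] = []
    for var_id, cpt in net.cpts.items():
        f = _Factor(cpt.parents + (cpt.child,), cpt.table)
        for v in f.vars:
            if v in ev_idx:
                f = _restrict(f, v, ev_idx[v])
        factors.append(f)
    eliminate = set(net.variables) - set(keep) - set(evidence)
    for var in _min_fill_order(factors, eliminate):
        bucket = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        prod = bucket[0]
        for f in bucket[1:]:
            prod = _multiply(prod, f)
        factors.append(_sum_out(prod, var))
    result = _Factor((), np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    # put axes in `keep` order
    if keep:
        perm = [result.vars.index(v) for v in keep]
        result = _Factor(tuple(keep), np.transpose(result.values, perm))
    return result


def joint_marginal(
    net: BayesianNetwork,
    targets: tuple[str, ...],
    evidence: dict[str, str] | None = None,
) -> np.ndarray:
    """Exact joint posterior array over ``targets`` given evidence."""
    evidence = dict(evidence or {})
    f = _eliminate(net, tuple(targets), evidence)
    z = float(f.values.sum())
    if z <= 0.0:
        raise ZeroProbabilityEvidenceError(
            f"evidence {evidence!r} has probability 0 under the model"
        )
    return f.values / z


def evidence_probability(
    net: BayesianNetwork, evidence: dict[str, str]
) -> float:
    """P(evidence), the normalizer of any posterior query."""
    f = _eliminate(net, (), dict(evidence))
    return float(f.values)


def query_posterior(
    net: BayesianNetwork,
    targets: "list[str] | tuple[str, ...]",
    evidence: dict[str, str] | None = None,
) -> PosteriorTable:
    """Exact marginal posteriors of ``targets`` by variable elimination."""
    evidence = dict(evidence or {})
    targets = tuple(targets)
    overlap = set(targets) & set(evidence)
    if overlap:
        raise ModelError(f"targets {sorted(overlap)} also appear in evidence")
    for t in targets:
        if t not in net.variables:
            raise ModelError(f"unknown target variable {t!r}")
    marginals: dict[str, np.ndarray] = {}
    for t in targets:
        marginals[t] = joint_marginal(net, (t,), evidence)
    return PosteriorTable(
        marginals,
        {t: net.variables[t].states for t in targets},
        evidence,
    )


# ---------------------------------------------------------------------------
# enumeration oracle


def joint_probability(
    net: BayesianNetwork, full_assignment: dict[str, str]
) -> float:
    """Chain-rule probability of one complete assignment."""
    missing = set(net.variables) - set(full_assignment)
    if missing:
        raise IncompleteAssignmentError(
            f"assignment misses variables {sorted(missing)}"
        )
    p = 1.0
    for var_id, cpt in net.cpts.items():
        idx = tuple(
            net.variables[v].state_index(full_assignment[v]) for v in cpt.parents
        ) + (net.variables[var_id].state_index(full_assignment[var_id]),)
        p *= float(cpt.table[idx])
    return p


def brute_force_posterior(
    net: BayesianNetwork,
    targets: "list[str] | tuple[str, ...]",
    evidence: dict[str, str] | None = None,
    *,
    cap: int = 10**7,
) -> PosteriorTable:
    """Posteriors by explicit summation over every completion (test oracle)."""
    evidence = dict(evidence or {})
    net.validate_evidence(evidence)
    targets = tuple(targets)
    size = 1
    for v in net.variables.values():
        size *= v.cardinality
    if size > cap:
        raise OracleTooLargeError(
            f"joint state space {size} exceeds oracle cap {cap}"
        )
    free = [v for v in net.variables if v not in evidence]
    sums = {
        t: np.zeros(net.variables[t].cardinality) for t in targets
    }
    z = 0.0
    for combo in itertools.product(*(net.variables[v].states for v in free)):
        assignment = dict(evidence)
        assignment.update(dict(zip(free, combo)))
        p = joint_probability(net, assignment)
        z += p
        for t in targets:
            sums[t][net.variables[t].state_index(assignment[t])] += p
    if z <= 0.0:
        raise ZeroProbabilityEvidenceError(
            f"evidence {evidence!r} has probability 0 under the model"
        )
    return PosteriorTable(
        {t: sums[t] / z for t in targets},
        {t: net.variables[t].states for t in targets},
        evidence,
    )


# ---------------------------------------------------------------------------
# sampling and likelihood


def forward_sample(
    net: BayesianNetwork, n: int, seed: "int | np.random.Generator"
) -> CaseTable:
    """Draw ``n`` complete records by ancestral sampling in topological order."""
    if n < 1:
        raise ModelError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    order = net.topological_order()
    samples: dict[str, np.ndarray] = {}
    for var_id in order:
        cpt = net.cpts[var_id]
        card = net.variables[var_id].cardinality
        if not cpt.parents:
            samples[var_id] = rng.choice(card, size=n, p=cpt.table)
            continue
        # flat index into parent rows, then inverse-CDF draw per record
        flat = np.zeros(n, dtype=np.int64)
        for p in cpt.parents:
            flat = flat * net.variables[p].cardinality + samples[p]
        rows = cpt.table.reshape(-1, card)[flat]  # (n, card)
        cdf = np.cumsum(rows, axis=1)
        u = rng.random(n)
        samples[var_id] = np.minimum(
            (u[:, None] >= cdf).sum(axis=1), card - 1
        )
    columns = tuple(order)
    state_lists = [net.variables[v].states for v in columns]
    records = [
        tuple(state_lists[j][samples[v][i]] for j, v in enumerate(columns))
        for i in range(n)
    ]
    return CaseTable(columns, records)


def group_records(
    cases: CaseTable,
) -> list[tuple[tuple, int]]:
    """Collapse a case table into (unique record, multiplicity) pairs."""
    counts: dict[tuple, int] = {}
    for rec in cases.records:
        counts[rec] = counts.get(rec, 0) + 1
    return sorted(counts.items(), key=lambda kv: tuple(map(str, kv[0])))


def log_likelihood(
    net: BayesianNetwork, cases: CaseTable
) -> float:
    """Sum of log marginal probabilities of the observed entries.

    Missing entries are marginalized by exact inference.  A record whose
    observed values have probability 0 contributes ``-inf``; the offending
    record indices are attached to the returned float via
    :func:`log_likelihood_details` when needed.
    """
    total, _ = log_likelihood_details(net, cases)
    return total


def log_likelihood_details(
    net: BayesianNetwork, cases: CaseTable
) -> tuple[float, list[int]]:
    """As :func:`log_likelihood` but also return zero-probability record indices."""
    cases.validate_against(net)
    logp_by_record: dict[tuple, float] = {}
    for rec, _ in group_records(cases):
        evidence = {
            c: v for c, v in zip(cases.columns, rec) if v is not MISSING
        }
        p = evidence_probability(net, evidence) if evidence else 1.0
        logp_by_record[rec] = math.log(p) if p > 0 else -math.inf
    total = 0.0
    offenders: list[int] = []
    for i, rec in enumerate(cases.records):
        lp = logp_by_record[rec]
        if lp == -math.inf:
            offenders.append(i)
        total += lp
    return total, offenders
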