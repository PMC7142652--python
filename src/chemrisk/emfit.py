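"""EM parameter learning for a fixed-structure discrete network.

Case tables may have missing entries (assumed missing at random).  The
E-step distributes each record's unit of evidence over the cells of every
CPT family in proportion to the exact posterior given the record's observed
values; the M-step renormalizes the accumulated expected counts with a
Dirichlet pseudocount alpha per cell.  With alpha > 0 the iteration ascends
the posterior-penalized likelihood, which keeps sparse parent combinations
away from zero rows; convergence is declared on the observed-data
log-likelihood.

Records are grouped by identical value patterns before the E-step, so the
per-iteration inference cost scales with the number of *distinct* records,
not the sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bayesnet import (
    MISSING,
    BayesianNetwork,
    CaseTable,
    ConditionalProbabilityTable,
    group_records,
    joint_marginal,
)
from .errors import (
    InsufficientDataError,
    StructureMismatchError,
    ZeroProbabilityRecordError,
)

__all__ = [
    "EMConfig",
    "EMTrace",
    "expected_counts",
    "m_step",
    "em_fit",
    "parameter_recovery_report",
]


@dataclass
class EMConfig:
    """Settings for :func:`em_fit`.

    alpha is the Laplace-style pseudocount added to every CPT cell in the
    M-step; tolerance is the absolute change in observed-data log-likelihood
    below which the iteration stops.
    """

    max_iterations: int = 500
    tolerance: float = 1e-6
    alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class EMTrace:
    """Per-iteration observed-data log-likelihoods and convergence flags."""

    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0


def expected_counts(
    net: BayesianNetwork, record: tuple, columns: "tuple[str, ...]"
) -> dict[str, np.ndarray]:
    """E-step contribution of one record: expected count per CPT cell.

    For every family the increments sum to 1 (one record distributes one
    observation over the family's cells).
    """
    grouped = _grouped_expected_counts(
        net, [(tuple(record), 1)], columns
    )
    return grouped


def _family_scatter(
    net: BayesianNetwork,
    counts: dict[str, np.ndarray],
    evidence: dict[str, str],
    weight: float,
    posterior_over,  # callable (vars tuple) -> ndarray
) -> None:
    """Add one (weighted) record's expected counts for every family."""
    for child, cpt in net.cpts.items():
        family = cpt.parents + (child,)
        free = tuple(v for v in family if v not in evidence)
        if not free:
            idx = tuple(
                net.variables[v].state_index(evidence[v]) for v in family
            )
            counts[child][idx] += weight
            continue
        post = posterior_over(free)  # array over free vars, in order
        # scatter into the family array with observed indices fixed
        idx: list = []
        free_pos = {v: i for i, v in enumerate(free)}
        # build an index expression: observed -> int, free -> slice
        expr = tuple(
            net.variables[v].state_index(evidence[v])
            if v in evidence
            else slice(None)
            for v in family
        )
        # post axes follow `free` order which matches family order filtered
        counts[child][expr] += weight * post


def _grouped_expected_counts(
    net: BayesianNetwork,
    grouped: "list[tuple[tuple, int]]",
    columns: "tuple[str, ...]",
    *,
    joint_cap: int = 200_000,
) -> dict[str, np.ndarray]:
    """Expected counts for pre-grouped records; also used by em_fit."""
    counts = {
        child: np.zeros(cpt.table.shape) for child, cpt in net.cpts.items()
    }
    for record, weight in grouped:
        evidence = {
            c: v for c, v in zip(columns, record) if v is not MISSING
        }
        hidden = tuple(
            v for v in net.topological_order() if v not in evidence
        )
        hidden_size = 1
        for v in hidden:
            hidden_size *= net.variables[v].cardinality
        if hidden and hidden_size <= joint_cap:
            # one inference per record: joint over all hidden variables,
            # families then marginalize from it
            try:
                joint = joint_marginal(net, hidden, evidence)
            except Exception as exc:
                raise ZeroProbabilityRecordError(
                    f"record {record!r} impossible under current parameters"
                ) from exc
            hpos = {v: i for i, v in enumerate(hidden)}

            def posterior_over(free, _joint=joint, _hpos=hpos):
                axes = tuple(
                    i for i in range(_joint.ndim)
                    if hidden[i] not in free
                )
                marg = _joint.sum(axis=axes) if axes else _joint
                kept = tuple(v for v in hidden if v in free)
                perm = [kept.index(v) for v in free]
                return np.transpose(marg, perm)

        else:

            def posterior_over(free, _ev=evidence):
                try:
                    return joint_marginal(net, free, _ev)
                except Exception as exc:
                    raise ZeroProbabilityRecordError(
                        f"record impossible under current parameters"
                    ) from exc

        _family_scatter(net, counts, evidence, weight, posterior_over)
    return counts


def m_step(
    counts: dict[str, np.ndarray],
    alpha: float,
    net: BayesianNetwork,
) -> dict[str, ConditionalProbabilityTable]:
    """Renormalize (counts + alpha) over child states into new CPTs.

    With alpha = 0 an all-zero row (unseen parent combination) falls back to
    a uniform row.
    """
    new_cpts: dict[str, ConditionalProbabilityTable] = {}
    for child, arr in counts.items():
        smoothed = arr + alpha
        sums = smoothed.sum(axis=-1, keepdims=True)
        card = arr.shape[-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            table = np.where(sums > 0, smoothed / np.where(sums > 0, sums, 1.0),
                             1.0 / card)
        new_cpts[child] = ConditionalProbabilityTable(
            child, net.cpts[child].parents, table, check=False
        )
    return new_cpts


def _initial_cpts(
    net: BayesianNetwork, seed: int
) -> dict[str, ConditionalProbabilityTable]:
    """Uniform rows with seeded Dirichlet(5) jitter to break symmetry."""
    rng = np.random.default_rng(seed)
    cpts = {}
    for child, cpt in net.cpts.items():
        card = cpt.table.shape[-1]
        n_rows = int(np.prod(cpt.table.shape[:-1], dtype=np.int64)) if cpt.parents else 1
        rows = rng.dirichlet([5.0] * card, size=n_rows)
        table = rows.reshape(cpt.table.shape)
        cpts[child] = ConditionalProbabilityTable(
            child, cpt.parents, table, check=False
        )
    return cpts


def em_fit(
    structure: BayesianNetwork,
    cases: CaseTable,
    config: EMConfig | None = None,
) -> tuple[BayesianNetwork, EMTrace]:
    """Fit CPTs of a fixed structure from (possibly incomplete) cases.

    The incoming network supplies variables, edges and CPT shapes only; its
    probability values are ignored and re-initialized from ``config.seed``.
    Variables absent from the case table are treated as entirely hidden.
    """
    config = config or EMConfig()
    if len(cases) == 0:
        raise InsufficientDataError("cannot fit from an empty case table")
    cases.validate_against(structure)
    net = BayesianNetwork(
        dict(structure.variables),
        set(structure.edges),
        _initial_cpts(structure, config.seed),
        check=False,
    )
    # hide variables not present as columns
    missing_cols = tuple(
        v for v in structure.variables if v not in cases.columns
    )
    columns = cases.columns + missing_cols
    grouped = [
        (rec + (MISSING,) * len(missing_cols), w)
        for rec, w in group_records(cases)
    ]
    trace = EMTrace()
    prev_ll: float | None = None
    for it in range(1, config.max_iterations + 1):
        counts = _grouped_expected_counts(net, grouped, columns)
        # observed-data log-likelihood under the parameters just used
        ll = _grouped_log_likelihood(net, grouped, columns)
        trace.log_likelihoods.append(ll)
        trace.iterations = it
        net.cpts = m_step(counts, config.alpha, net)
        if prev_ll is not None and abs(ll - prev_ll) < config.tolerance:
            trace.converged = True
            break
        prev_ll = ll
    return net, trace


def _grouped_log_likelihood(
    net: BayesianNetwork,
    grouped: "list[tuple[tuple, int]]",
    columns: "tuple[str, ...]",
) -> float:
    from .bayesnet import evidence_probability

    total = 0.0
    for rec, w in grouped:
        evidence = {c: v for c, v in zip(columns, rec) if v is not MISSING}
        p = evidence_probability(net, evidence) if evidence else 1.0
        total += w * (math.log(p) if p > 0 else -math.inf)
    return total


def parameter_recovery_report(
    true_net: BayesianNetwork,
    fitted_net: BayesianNetwork,
    cases: CaseTable | None = None,
    min_support: int = 0,
) -> dict:
    """Per-CPT-row total-variation distance between two same-structure nets.

    ``support`` of a row counts records in ``cases`` whose parent values are
    all observed and match the row's parent combination; rows with support
    below ``min_support`` are excluded from the summary and counted
    separately.  TV distance per row is 0.5 * sum |p - q|.
    """
    if set(true_net.variables) != set(fitted_net.variables) or set(
        true_net.edges
    ) != set(fitted_net.edges):
        raise StructureMismatchError("networks do not share a structure")
    rows = []
    for child, t_cpt in true_net.cpts.items():
        f_cpt = fitted_net.cpts[child]
        if t_cpt.parents != f_cpt.parents:
            raise StructureMismatchError(
                f"CPT parent order differs for {child!r}"
            )
        t_rows = t_cpt.rows(true_net.variables)
        f_rows = f_cpt.rows(fitted_net.variables)
        for combo, p in t_rows.items():
            q = f_rows[combo]
            tv = 0.5 * float(np.abs(p - q).sum())
            support = _row_support(cases, t_cpt.parents, combo)
            rows.append(
                {"child": child, "parents": combo, "tv": tv, "support": support}
            )
    included = [
        r for r in rows if cases is None or r["support"] >= min_support
    ]
    excluded = len(rows) - len(included)
    tvs = [r["tv"] for r in included]
    return {
        "rows": rows,
        "included": len(included),
        "excluded_low_support": excluded,
        "mean_tv": float(np.mean(tvs)) if tvs else float("nan"),
        "max_tv": float(np.max(tvs)) if tvs else float("nan"),
    }


def _row_support(
    cases: CaseTable | None,
    parents: tuple[str, ...],
    combo: tuple[str, ...],
) -> int:
    if cases is None or not parents:
        n = len(cases) if cases is not None else 0
        return n
    pos = []
    for p in parents:
        if p not in cases.columns:
            return 0
        pos.append(cases.columns.index(p))
    count = 0
    for rec in cases.records:
        vals = tuple(rec[i] for i in pos)
        if vals == combo:
            count += 1
    return count
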