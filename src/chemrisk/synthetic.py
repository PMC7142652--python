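"""Synthetic case tables emulating discretized attack-incident records.

The study-scale dataset this generator stands in for is a table of 287
discretized historical incidents with appreciable missingness; the real
table is not redistributable, so everything here is forward-sampled from a
ground-truth network and masked with a configurable mechanism:

* ``mcar`` — every cell masked independently with the same rate (EM's
  ignorable-missingness assumption holds);
* ``mnar-severity`` — masking probability is doubled for records whose
  casualty outcome is Major, mimicking outcome-dependent reporting; useful
  for demonstrating EM bias, not for recovery tests.

No record is ever fully masked: a record that would lose every field is
re-drawn, keeping its log-likelihood finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayesnet import (
    MISSING,
    BayesianNetwork,
    CaseTable,
    ConditionalProbabilityTable,
    DiscreteVariable,
    forward_sample,
)
from .attack_model import build_default_structure
from .errors import ConfigurationError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_ground_truth_model",
    "generate_random_model",
    "generate_cases",
    "apply_missingness",
]

MECHANISMS = ("mcar", "mnar-severity")

#: default number of records, matching the study-scale case table
DEFAULT_N_CASES = 287
#: default fraction of masked cells
DEFAULT_MISSING_RATE = 0.1


@dataclass
class SyntheticConfig:
    """Generation settings; the seed is mandatory for reproducibility."""

    n: int = DEFAULT_N_CASES
    missing_rate: float = DEFAULT_MISSING_RATE
    mechanism: str = "mcar"
    seed: int = 0
    variables: "tuple[str, ...] | None" = None  # optional column subset

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}"
            )
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")


@dataclass
class GroundTruth:
    """A generating network plus a provenance note."""

    net: BayesianNetwork
    provenance: str


def generate_ground_truth_model(
    seed: int, concentration: float = 1.0
) -> GroundTruth:
    """Default 42-node structure with CPT rows drawn from Dirichlet(c).

    Large concentrations approach uniform rows; c = 1 gives flat-Dirichlet
    tables with substantial row-to-row variation.
    """
    if concentration <= 0:
        raise ConfigurationError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    net = build_default_structure()
    for var_id, cpt in net.cpts.items():
        card = cpt.table.shape[-1]
        n_rows = int(np.prod(cpt.table.shape[:-1], dtype=np.int64))
        rows = rng.dirichlet([concentration] * card, size=max(n_rows, 1))
        net.cpts[var_id] = ConditionalProbabilityTable(
            var_id, cpt.parents, rows.reshape(cpt.table.shape), check=False
        )
    return GroundTruth(net, f"seeded Dirichlet({concentration}) draw, seed={seed}")


def generate_random_model(
    n_nodes: int,
    seed: int,
    max_parents: int = 2,
    max_states: int = 3,
    concentration: float = 1.0,
) -> BayesianNetwork:
    """A random small DAG with Dirichlet CPTs, for recovery and oracle tests."""
    rng = np.random.default_rng(seed)
    ids = [f"X{i}" for i in range(n_nodes)]
    variables = {}
    for vid in ids:
        card = int(rng.integers(2, max_states + 1))
        variables[vid] = DiscreteVariable(
            vid, vid, tuple(f"s{j}" for j in range(card))
        )
    edges = set()
    parent_sets: dict[str, tuple[str, ...]] = {}
    for i, vid in enumerate(ids):
        k = int(rng.integers(0, min(i, max_parents) + 1))
        parents = tuple(
            ids[j] for j in sorted(rng.choice(i, size=k, replace=False))
        ) if k else ()
        parent_sets[vid] = parents
        edges |= {(p, vid) for p in parents}
    cpts = {}
    for vid in ids:
        parents = parent_sets[vid]
        card = variables[vid].cardinality
        shape = tuple(variables[p].cardinality for p in parents) + (card,)
        n_rows = int(np.prod(shape[:-1], dtype=np.int64))
        rows = rng.dirichlet([concentration] * card, size=max(n_rows, 1))
        cpts[vid] = ConditionalProbabilityTable(
            vid, parents, rows.reshape(shape), check=False
        )
    return BayesianNetwork(variables, edges, cpts)


def apply_missingness(
    cases: CaseTable,
    rate: float,
    mechanism: str = "mcar",
    seed: int = 0,
    severity_column: str = "K",
    severity_state: str = "Major",
) -> CaseTable:
    """Mask entries of a complete table per the chosen mechanism.

    Under ``mnar-severity`` the cell-masking probability is doubled for
    records whose ``severity_column`` equals ``severity_state`` (capped at
    1).  A record that would end up fully masked is re-drawn until at least
    one field survives.
    """
    if not 0 <= rate < 1:
        raise ConfigurationError("rate must be in [0, 1)")
    if mechanism not in MECHANISMS:
        raise ConfigurationError(f"unknown mechanism {mechanism!r}")
    if rate == 0:
        return CaseTable(cases.columns, list(cases.records))
    rng = np.random.default_rng(seed)
    k = len(cases.columns)
    sev_idx = (
        cases.columns.index(severity_column)
        if mechanism == "mnar-severity" and severity_column in cases.columns
        else None
    )
    records = []
    for rec in cases.records:
        p = rate
        if sev_idx is not None and rec[sev_idx] == severity_state:
            p = min(2 * rate, 1.0)
        while True:
            mask = rng.random(k) < p
            if not mask.all():
                break
        records.append(
            tuple(MISSING if m else v for v, m in zip(rec, mask))
        )
    return CaseTable(cases.columns, records)


def generate_cases(
    truth: "GroundTruth | BayesianNetwork", cfg: SyntheticConfig
) -> CaseTable:
    """Forward-sample n records from the truth and apply missingness."""
    net = truth.net if isinstance(truth, GroundTruth) else truth
    complete = forward_sample(net, cfg.n, cfg.seed)
    if cfg.variables is not None:
        keep = [complete.columns.index(v) for v in cfg.variables]
        complete = CaseTable(
            tuple(cfg.variables),
            [tuple(rec[i] for i in keep) for rec in complete.records],
        )
    # independent stream for the mask so n and rate decouple
    return apply_missingness(
        complete, cfg.missing_rate, cfg.mechanism, seed=cfg.seed + 1_000_003
    )
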