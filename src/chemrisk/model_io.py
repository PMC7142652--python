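"""YAML model files: variables, edges (with provenance), CPTs.

Schema (version 1)::

    schema_version: 1
    variables:
      - {id: X, label: ..., states: [a, b]}
    edges:
      - {from: X, to: Y, provenance: text-derived | default-assumption}
    cpts:
      - child: Y
        parents: [X]
        rows:
          - {given: [a], p: [0.9, 0.1]}

Probabilities are written at full double precision, so
``load_model(save_model(net))`` is an exact round trip.
"""

from __future__ import annotations

import numpy as np
import yaml

from .bayesnet import (
    BayesianNetwork,
    ConditionalProbabilityTable,
    DiscreteVariable,
    validate_network,
)
from .errors import ModelError

__all__ = ["load_model", "save_model", "model_to_dict", "model_from_dict"]

SCHEMA_VERSION = 1


def model_to_dict(net: BayesianNetwork) -> dict:
    provenance = getattr(net, "edge_provenance", {})
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "variables": [
            {"id": v.id, "label": v.label, "states": list(v.states)}
            for v in net.variables.values()
        ],
        "edges": [
            {
                "from": a,
                "to": b,
                **(
                    {"provenance": provenance[(a, b)]}
                    if (a, b) in provenance
                    else {}
                ),
            }
            for a, b in sorted(net.edges)
        ],
        "cpts": [],
    }
    for child in net.variables:
        cpt = net.cpts[child]
        rows = [
            {"given": list(combo), "p": [float(x) for x in vec]}
            for combo, vec in cpt.rows(net.variables).items()
        ]
        doc["cpts"].append(
            {"child": child, "parents": list(cpt.parents), "rows": rows}
        )
    return doc


def model_from_dict(doc: dict) -> BayesianNetwork:
    if not isinstance(doc, dict):
        raise ModelError("model document is not a mapping")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelError(f"unsupported schema_version {version!r}")
    try:
        variables = {
            str(v["id"]): DiscreteVariable(
                str(v["id"]), str(v.get("label", v["id"])),
                tuple(str(s) for s in v["states"]),
            )
            for v in doc["variables"]
        }
    except KeyError as exc:
        raise ModelError(f"variable entry missing key {exc}") from None
    edges = set()
    provenance = {}
    for e in doc.get("edges", []):
        edge = (str(e["from"]), str(e["to"]))
        edges.add(edge)
        if "provenance" in e:
            provenance[edge] = str(e["provenance"])
    cpts: dict[str, ConditionalProbabilityTable] = {}
    for entry in doc.get("cpts", []):
        child = str(entry["child"])
        if child not in variables:
            raise ModelError(f"CPT for unknown variable {child!r}")
        parents = tuple(str(p) for p in entry.get("parents", []))
        rows = {}
        for row in entry["rows"]:
            combo = tuple(str(s) for s in row.get("given", []))
            rows[combo] = [float(x) for x in row["p"]]
        cpts[child] = ConditionalProbabilityTable.from_rows(
            child, parents, rows, variables
        )
    missing = sorted(set(variables) - set(cpts))
    if missing:
        raise ModelError(f"model file omits CPTs for variables {missing}")
    net = BayesianNetwork(variables, edges, cpts, check=False)
    report = validate_network(net)
    if report:
        raise ModelError("invalid model file: " + "; ".join(report))
    if provenance:
        net.edge_provenance = provenance  # type: ignore[attr-defined]
    return net


def save_model(net: BayesianNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            model_to_dict(net), fh, sort_keys=False, default_flow_style=None
        )


def load_model(path) -> BayesianNetwork:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)
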