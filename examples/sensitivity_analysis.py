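"""Two sensitivity semantics: evidence flips and bounded prior changes.

Flipping a prevention measure on/off (hard evidence) measures its full
leverage; nudging its prior by 10-20% with proportional co-variation
measures what a realistic reallocation of resources buys.  Effects are
L-infinity distances between the casualty posteriors.
"""

from chemrisk import (
    build_illustrative_model,
    rank_sensitivities,
    state_flip_sensitivity,
)

net = build_illustrative_model()

print("Casualty sensitivity to switching each prevention measure (flip):")
labels = {"25": "Patrol", "26": "Security check", "27": "Surveillance",
          "28": "Police investigation"}
for node in ("25", "26", "27", "28"):
    effect = max(r.effect for r in state_flip_sensitivity(net, node, "K"))
    print(f"  {labels[node]:<22} effect={effect:.4f}")

print("\nTop root factors for casualties under a 10% prior change:")
for r in rank_sensitivities(net, "K", delta=0.1)[:8]:
    print(f"  node {r.node:>2} ({r.state}): effect={r.effect:.5f}")
print("\nSecurity check dominates the on/off comparison, while under small "
      "prior nudges the emergency-response timeliness nodes (29-31) edge "
      "ahead: casualties respond to response capability as much as to "
      "prevention once measures only move a little.")
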