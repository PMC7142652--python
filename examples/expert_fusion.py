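"""Fuse four experts' judgments about emergency-response ability.

Each expert hands in a probability vector over (High, Medium, Low) for one
combination of hospital/fire/police response timeliness; Dempster's rule
multiplies agreements and renormalizes away the conflict mass K.  The fused
vector becomes one row of node H's conditional probability table.
"""

from chemrisk import MassFunction, combine_all, decide_edge
from chemrisk.attack_model import EXPERT_CPT_PANELS_H

frame = ("High", "Medium", "Low")

print("Fused CPT rows for 'Ability of the emergency response':")
for combo, vectors in EXPERT_CPT_PANELS_H.items():
    panel = [MassFunction.from_vector(frame, v) for v in vectors]
    result = combine_all(panel)
    fused = ", ".join(f"{p:.3f}" for p in result.combined.as_vector())
    print(f"  {combo}: ({fused})   conflict K={result.conflict:.3f}")

# Edge elicitation: four experts rate the strength of the causal link
# between attack success and casualties on a (strong, weak) frame.  The
# edge is accepted when the combined 'strong' mass strictly exceeds 0.85.
panel = [MassFunction.from_vector(("strong", "weak"), (0.9, 0.1))] * 4
exists, weight = decide_edge(panel, threshold=0.85)
print(f"\nEdge decision: combined strong mass {weight:.5f} -> "
      f"edge {'accepted' if exists else 'rejected'}")
print("High conflict K is common: confident experts disagree on specifics, "
      "and the rule rewards the states they jointly support.")
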