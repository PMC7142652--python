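"""Partial validation of the network with three directional axioms.

Without held-out data, an expert-built model can still be screened: a prior
nudge must move downstream posteriors (axiom 1), consistently and
monotonically as the nudge grows (axiom 2), and combined protective nudges
must do at least as much as any subset (axiom 3).
"""

from chemrisk import build_illustrative_model, partial_validation_report
from chemrisk.axioms import default_battery

net = build_illustrative_model()
report = partial_validation_report(net, default_battery())

for check in report["checks"]:
    print(f"axiom {check.axiom} {check.nodes}: {check.verdict}")
    for line in check.trace[:2]:
        print(f"    {line}")
print(f"\nSummary: {report['counts']} -> "
      f"{'model passes' if report['all_passed'] else 'violations found'}")
print("The battery nudges the security-check prior (protective) and the "
      "wind-direction prior (upwind shifts hurt the attacker) and checks "
      "prevention ability and attack success respond in those directions.")
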