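"""Learn CPTs from synthetic incomplete case records and audit recovery.

A ground-truth network with Dirichlet-drawn CPTs forward-samples a case
table at study scale (287 records) and at a larger n; 10% of cells are
masked completely at random.  EM refits the CPTs from scratch, and the
recovery report measures per-row total-variation distance to the truth.
"""

from chemrisk import (
    EMConfig,
    SyntheticConfig,
    em_fit,
    generate_cases,
    generate_random_model,
    parameter_recovery_report,
)

truth = generate_random_model(6, seed=42)

for n in (287, 5000):
    cases = generate_cases(truth, SyntheticConfig(n=n, missing_rate=0.1, seed=7))
    fitted, trace = em_fit(truth, cases, EMConfig(seed=1))
    report = parameter_recovery_report(truth, fitted, cases, min_support=20)
    print(f"n={n}: EM {trace.iterations} iterations "
          f"(converged={trace.converged}), "
          f"final log-likelihood {trace.log_likelihoods[-1]:.1f}")
    print(f"       mean row TV {report['mean_tv']:.4f}, "
          f"max {report['max_tv']:.4f}, "
          f"{report['excluded_low_support']} low-support rows excluded")
print("\nTV distance is halved-L1 between true and fitted rows; it shrinks "
      "as the sample grows, and rows whose parent combinations rarely occur "
      "are reported but excluded from the summary.")
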