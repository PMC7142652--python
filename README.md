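# chemrisk

Probabilistic risk analysis of chemical terrorist attacks with a discrete
Bayesian network.

The package is for risk analysts and public-safety researchers who want to
model how the threat posed by a terrorist organisation, the weapon it can
field, the attractiveness and defences of an urban target, and the weather
combine into the probability of a successful attack and the severity of the
resulting casualties — and then interrogate that model with scenario,
sensitivity and validation machinery.

## The model

A Bayesian network factorizes a joint distribution over discrete variables
as

    P(X_1, ..., X_n) = prod_i P(X_i | Pa(X_i))

The packaged network has 31 root factors (organisation profile, weapon
type/dose/delivery, target demographics, weather, police prevention
measures, emergency-response timeliness) feeding 11 aggregate nodes through
42 directed edges, ending in `J` (whether the attack succeeds) and `K`
(casualty severity: Minor / Medium / Major).

Three estimation and analysis tools are built in:

* **Dempster–Shafer fusion** of expert judgments. Each expert supplies a
  basic probability assignment m(·) over a frame Θ with m(∅)=0 and
  Σ m(A)=1. Dempster's rule combines N experts by

      m(A) ∝ Σ_{A_1 ∩ ... ∩ A_N = A} m_1(A_1) ... m_N(A_N),

  renormalized by 1−K where the conflict K is the product mass on empty
  intersections. Used both to decide whether a causal edge exists (combined
  "strong" mass > 0.85) and to fuse elicited CPT rows.
* **EM parameter learning** from incomplete case tables: exact-inference
  E-step, pseudocount-smoothed M-step, monotone log-likelihood trace, and a
  total-variation recovery report against a known ground truth.
* **Exact inference** by variable elimination (min-fill ordering), checked
  everywhere against a brute-force enumeration oracle, plus ancestral
  sampling and a synthetic-case generator with MCAR / outcome-dependent
  (MNAR) missingness.

Because the study-scale CPTs behind the published analyses are not
available, the packaged model ships with documented *illustrative* CPTs: a
monotone severity-kernel construction (plus the one fully published family,
node H, reproduced by fusing the expert panels). Qualitative directions —
which measures matter most, which scenarios fail — are meaningful on this
model; exact published posteriors are not reproduced by design.

## Worked example

```python
from chemrisk import MassFunction, combine_all

frame = ("High", "Medium", "Low")
panel = [MassFunction.from_vector(frame, v) for v in
         [(0.3, 0.3, 0.4), (0.7, 0.2, 0.1), (0.4, 0.3, 0.3), (0.7, 0.2, 0.1)]]
result = combine_all(panel)
print([round(x, 3) for x in result.combined.as_vector()], round(result.conflict, 4))
```

prints

```
[0.925, 0.057, 0.019] 0.9364
```

— four experts who individually lean only weakly toward "High" emergency
response jointly support it with mass 0.925 once their agreements are
multiplied and the (large) conflict mass is renormalized away. This fused
vector is one CPT row of the emergency-response node.

Scenario analysis on the packaged model:

```python
from chemrisk import Scenario, build_illustrative_model, nine_scenarios, run_scenario

net = build_illustrative_model()
for sc in nine_scenarios()[:6]:
    post = run_scenario(net, Scenario(sc["name"], sc["evidence"], ("J",)))
    print(sc["name"], round(post.probability("J", "No"), 3))
```

```
Scenario 1 0.037
Scenario 2 0.138
Scenario 3 0.097
Scenario 4 0.618
Scenario 5 0.848
Scenario 6 0.793
```

Scenario 5 — the weakest organisation attacking the best-defended
(government) target — has the highest failure probability of the nine, the
defining qualitative pattern of the case study.

The `examples/` directory holds one short narrative script per capability
(expert fusion, scenario analysis, sensitivity analysis, EM recovery,
axiom validation); each prints the numbers it computes and a line on what
they mean. A thin CLI mirrors the library:

```sh
chemrisk infer --target J --evidence 26=Yes
chemrisk simulate --random-truth --seed 7 --n 287 --out cases.csv
chemrisk validate
```

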