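# cdpath

Learning pathways and learning progressions from cognitive diagnostic
assessment data.

Large-scale standardized tests usually report one score per student. For
personalising instruction that is not enough: two students with the same
reading score can have very different cognitive profiles. `cdpath` is a
pipeline for researchers and psychometricians who want to go from raw
dichotomous responses to an actionable map of *what* students have
mastered and *in which order* skills are typically acquired:

1. **Diagnose.** Fit a mixed cognitive diagnostic model (CDM) to a binary
   response matrix and a Q-matrix: every multi-attribute item is screened
   with an item-level Wald test against the saturated G-DINA model and
   assigned the best-fitting reduced family (DINA, DINO, ACDM, LLM, RRUM)
   or kept saturated; examinees are classified into knowledge states
   α = (α₁, …, α_K) ∈ {0,1}^K by maximum a posteriori estimation.
2. **Map pathways.** Tally the knowledge states, keep the most frequent
   ones, connect states that differ by mastery of exactly one attribute
   (first-order transitions s ⊂ t, |t| = |s|+1), and extract the dominant
   learning path — the source-to-sink chain carrying the most students.
3. **Build the progression.** Absorb rare states into the dominant ones
   by nearest-centroid assignment (Hamming distance), scale every state by
   the mean EAP ability of its students under a 2PL IRT model
   P(x=1|θ) = 1/(1+e^{−a(θ−b)}), and cut the θ scale into tiers.

A seeded synthetic-cohort generator reproduces the statistical structure
of a real provincial English-reading examination (its published 20-item ×
8-attribute Q-matrix, marginal mastery rates, and nested skill-acquisition
order), so the entire pipeline is testable without confidential data.

## Worked example

```python
import numpy as np
from cdpath import (
    reading_scenario, simulate_cohort, build_mixed_model, classify,
    tabulate_states, top_states, build_graph, dominant_path,
    assign_rare_states, fit_2pl, state_ability_table, set_levels,
)

# a 20,000-student cohort with the built-in exam design
scenario = reading_scenario(n=20_000, seed=1)
profiles, responses = simulate_cohort(scenario)

plan, fit = build_mixed_model(responses, scenario.q, alpha=0.05, seed=1)
cls = classify(fit, responses)

table = tabulate_states(cls)
retained, coverage = top_states(table, k=17)
graph = build_graph(retained, table.total_n)
path = dominant_path(graph)
print(" -> ".join(path))
print(f"top-17 coverage: {100 * coverage:.1f}%")

rare = {s: c for s, c in table.counts.items() if s not in retained}
mapping = assign_rare_states(rare, retained)
twopl = fit_2pl(responses)
ability = state_ability_table(cls.map_states, mapping, twopl.theta)
tiers = set_levels(ability, n_tiers=3)
print(tiers.rows.tail(3).to_string(index=False))
```

Output:

```
0000000 -> 0000010 -> 0100010 -> 0100011 -> 0110011 -> 0110111 -> 0111111 -> 1111111
top-17 coverage: 96.0%
  state  level    n  mean_theta  tier
0111111      6  690    0.706357     3
1011111      6  563    0.943650     3
1111111      7 4815    1.242175     3
```

Reading the output: the dominant path says students typically master A6
(information matching) first, then A2 (complex sentences), A7 (option
processing), A3 (inter-sentence relations), A5 (inference), A4
(organisation/rhetoric), and finally A1 (difficult vocabulary). The
progression table scales each knowledge state by the mean ability of its
students — here full mastery (`1111111`) sits at θ ≈ 1.24, at the top of
tier 3 — so every state gets both a micro-level position (which skills)
and a macro-level tier (how able).

The same run is available from the shell:

```bash
cdpath simulate --n 20000 --seed 1 --out resp.csv
cdpath run --data resp.csv --qmatrix q.csv --out-dir run1 --seed 1
```

`cdpath run` writes `fit.json`, `plan.json`, `classification.csv`,
`pathway.json`/`pathway.dot`, `progression.csv` and a `manifest.json`
that pins the config hash, so a rerun with the same inputs is
byte-identical.

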