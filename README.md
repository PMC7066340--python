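# mddvuln

Vulnerability stratification and compartmental dynamics of adolescent
major depressive disorder (MDD).

Adolescent MDD risk can be screened without clinical instruments by
combining subjective well-being (SWB, Satisfaction With Life Scale) with
the three Trait Meta-Mood Scale subscales — Attention (EQ-A), Clarity
(EQ-C) and Mood Repair (EQ-R).  `mddvuln` implements, for epidemiologists
and school-mental-health researchers, the full pipeline around that idea:

1. **Stratification** — each variable is discretised into three levels
   (low / adequate / high, sex-specific cut-offs for EQ-A and EQ-C); the
   3⁴ = 81 "superposed states" carry totals from 80 to 140 and map to
   three groups: high vulnerability *V1* (total < 100), low vulnerability
   *V2* (100–120) and complete mental health *M* (> 120).
2. **Parameter estimation** — cohort band counts and lifestyle tables
   (daily exercise and technology-use categories) become the eight
   parameters of the model below, following the published procedure for a
   227-adolescent cohort.
3. **Dynamics** — the three-compartment nonlinear ODE system in the
   fractions x = V1/N, y = V2/N, z = M/N,

       dx/dt = aμ − μx + εxy − αx
       dy/dt = bμ − μy − εxy + αx − δyz + βz
       dz/dt = cμ − μz + δyz − βz

   with entry probabilities (a, b, c), turnover rate μ, negative/positive
   peer-pressure contact rates ε and δ, exercise rate α (V1→V2) and
   technology rate β (M→V2) — all per day.  Trajectories, steady states
   and parameter sweeps are provided.
4. **Equilibrium & stability** — the equilibrium cubic in y (A = εδ),
   Vieta root-positivity screening, the z back-substitution
   z = cμ/(β+μ−δy), the Jacobian at the disease-free equilibrium (0, 0, 1)
   with closed-form eigenvalues −(μ+α), −μ, −(μ+β+δ), and both published
   reproduction-number variants side by side.
5. **Synthetic cohorts** — a deterministic 227-record reference cohort
   reproducing every published marginal count, plus a seeded generator for
   cohorts with configurable band structure, so the whole pipeline runs
   end-to-end without any external data.

## Worked example

```python
import mddvuln as m

cohort = m.reference_cohort()                 # 227 deterministic records
summary = m.summarize_cohort(cohort)
print(summary.band_counts)
# {'high_vuln': 88, 'low_vuln': 136, 'complete': 3}

report = m.estimate_all(summary)
print({k: round(v, 4) for k, v in report.params.to_dict().items()})
# {'mu': 0.0034, 'a': 0.3106, 'b': 0.4799, 'c': 0.0106,
#  'delta': 0.5, 'epsilon': 0.2, 'alpha': 0.6795, 'beta': 0.6943}

traj = m.integrate(report.params, m.STUDY_INITIAL_FRACTIONS)
print(traj.solver_meta["t_end"], traj.terminal)
# 4096.0 [2.03010308e-03 7.98938149e-01 1.21393739e-04]

stab = m.stability_analysis(report.params)
print(stab.eigenvalues, stab.stable)
# (-0.682961276737968, -0.00342, -1.1977367892156863) True
```

Reading the output: 88/136/3 of the 227 adolescents fall into the
high-vulnerability, low-vulnerability and complete-mental-health groups.
The estimated parameters match the published cohort analysis (e.g.
b = 0.4799, δ = 0.5, ε = 0.2; α and β differ from the published 0.6796 /
0.6941 only by its chained rounding, which
`EstimationConfig(chained_rounding=True)` emulates exactly).  Integrating
from the cohort's initial fractions (0.3876, 0.5991, 0.0132), the system
reaches a steady state by ~4100 days in which the low-vulnerability
fraction has grown to ≈ 0.80 while the other two shrink — and all three
eigenvalues at the disease-free equilibrium are negative, so (0, 0, 1) is
asymptotically stable.

The same workflow is available from the shell:

```sh
mddvuln synth --reference --out cohort.csv
mddvuln score cohort.csv --out-classification cls.csv --out-summary summary.json
mddvuln estimate summary.json --out params.json
mddvuln simulate params.json --out trajectory.csv
mddvuln equilibrium params.json --out stability.json
mddvuln run config.yaml        # full pipeline with a digest manifest
```

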