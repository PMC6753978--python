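# neutralfire

Neutral lattice models of groundcover community assembly in frequently burned
ecosystems, with a Fourier amplitude sensitivity test (FAST) of the model's
demographic and community-size parameters.

## The problem

Fire-dependent woodlands such as longleaf pine (*Pinus palustris*) savannas
hold extraordinary fine-scale plant diversity — dozens of groundcover species
within a square metre on uniform sandy soil. One candidate explanation is
neutral: frequent low-intensity fire kills individuals at random and
suppresses competitive exclusion, so community composition is governed by
stochastic birth, death, and immigration rather than niche differences.
`neutralfire` implements a pair of parsimonious autonomous-agent models built
on the demographic parameters of the unified neutral theory of biodiversity
(UNTB) to test that premise, for ecologists modelling fine-scale richness
dynamics under frequent-fire regimes.

## The model

A community is a lattice of 10 cm × 10 cm cells, each holding at most one
individual; fire is implicit in the rates. Each yearly time step:

1. **Mortality** — every individual dies independently with probability *m*
   (no density dependence), synchronously.
2. **Recruitment** — every now-empty cell gains a recruit with probability
   *b*. With probability *i* the recruit immigrates, drawn from the
   metacommunity relative frequencies; otherwise it comes from the local
   pool:
   - **non-spatial model**: the realized relative frequencies of the area's
     survivors;
   - **spatial model**: a parent among occupied cells within a Chebyshev
     radius of 5 cells (maximum reach √2 · 0.5 m = 0.71 m), chosen with
     probability ∝ exp(−d/λ), d the Euclidean center-to-center distance under
     periodic boundaries.

The metacommunity is a species frequency distribution tallied from mapped
plant censuses, optionally coarsened to 20/50/100/200-cm grains by
presence–absence. The target output is **normalized richness**
S(50)/S(1). First-order FAST indices measure the share of its variance
explained by each of five parameters: birth (0.2–0.6), mortality (0.2–0.6),
immigration (0.01–0.25), area (1–25 m²), and number of areas (1–30).

## Worked example

```python
import numpy as np
from neutralfire import (SimulationParams, generate_metacommunity, simulate,
                         FASTDesign, run_experiment)

# a right-skewed (log-series) metacommunity like a field census tally
meta = generate_metacommunity(123, 20.0, 7000, np.random.default_rng(7))

params = SimulationParams(birth=0.4, mortality=0.4, immigration=0.1,
                          area_m2=3.0, n_areas=5, model="spatial",
                          n_steps=50, seed=42)
traj = simulate(params, meta)
print(traj.richness_by_step[0], traj.richness_by_step[1],
      traj.richness_by_step[50], round(traj.normalized_richness, 3))
# 93 84 52 0.619

res = run_experiment(FASTDesign(samples_per_parameter=100),
                     {"sandhills": {10: meta}}, models=("nonspatial",),
                     replicate_seeds=(1,), max_area_m2=9.0)
for p, v in res[0].first_order.items():
    print(f"{p:<12} {100 * v:5.1f} %")
# birth          3.4 %
# mortality      0.6 %
# immigration   31.5 %
# area_m2        4.0 %
# n_areas       18.4 %
```

The five pooled communities lose about 38% of their initial richness over 50
years at these rates (normalized richness 0.62). The FAST run — 500
parameter combinations through the simulator — shows the signature result:
the direct effects of birth and mortality on richness are tiny (< 5% of
output variance), while immigration and the community-size parameters
dominate. Dispersal limitation, not demographic rates, controls simulated
fine-scale richness.

The same pipeline is scriptable from the shell:

```bash
neutralfire synth --preset eafb --seed 3 --out data/
neutralfire distributions --census data/census.csv --year 2012 --out dists/
neutralfire simulate --model spatial --meta data/metacommunity.csv \
    --birth 0.4 --mortality 0.4 --immigration 0.1 --steps 50 --seed 42 --out sim/
neutralfire fast --meta-dir dists/ --models nonspatial --scales 10 \
    --n-samples 100 --replicates 3 --seed 1 --out fast/
neutralfire experiment --config experiment.yaml
```

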