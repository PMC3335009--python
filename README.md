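# starpanel

Bayesian structured additive regression (STAR) for county-year panels of
standardized health-indicator rates — the disease-mapping setting in which
one asks how county-level determinants (here: primary-care-physician
availability and socioeconomic deprivation) relate to outcome rates over
time and across space, while accounting for spatial autocorrelation
between neighbouring counties and serial correlation within them.

## The models

For log-transformed standardized rates y_ct (county c, year t) the package
fits, by a block Gibbs sampler,

* a **varying-coefficient model** with time-varying covariate effects

      y_ct = α + x1_ct·β1_t + x2_ct·β2_t + f(t) + s_c + u_c + ε_ct

* and a **random-effects model** with county-specific covariate effects

      y_ct = α + x1_ct·b1_c + x2_ct·b2_c + f(t) + s_c + u_c + ε_ct

where β1, β2 carry second-order random-walk smoothness priors, b1, b2
exchangeable normal priors, f(t) is a Bayesian P-spline time smoother,
s_c a structured spatial effect with an intrinsic CAR (Markov random
field) prior on the county adjacency graph, u_c exchangeable county
noise, and every variance component an inverse-gamma (0.001, 0.001)
hyperprior. Reported summaries include posterior means with 95% credible
intervals, DIC = D(θ) + p_d, the structured share of spatial variance
ρ = σ²_str/(σ²_str + σ²_unstr), and an 80%-posterior-probability
classification of each county's spatial effect. Upstream, the package
also performs direct age-race rate standardization and one-factor
deprivation-index construction (loadings, Cronbach's alpha, variance
explained, standardized county scores), and it ships synthetic-data
generators that draw panels, adjacency graphs (GAL format), census tables
and stratified counts from the same generative models with known truth.

See `docs/methods.md` for assumptions, identifiability constraints,
sampler details and limitations.

## Worked example

```python
import numpy as np
import starpanel as sp
from starpanel.synthetic_data import (
    make_lattice_graph, default_true_parameters, simulate_panel,
)

graph = make_lattice_graph(6, 6, n_components=2, island_fraction=0.05, seed=7)
true = default_true_parameters(T=21, seed=7)      # beta1 declines 3.72 -> 2.45
panel, truth = simulate_panel(graph, true)

spec = sp.apply_constraints(sp.build_vcm(panel, graph))
draws = sp.gibbs_run(spec, sp.ChainConfig(iterations=4400, burn_in=400, thin=4, seed=1))
summary = sp.summarize(spec, draws)

print(summary.diagnostics)
b1 = draws.draws["beta1"]
lo, hi = np.percentile(b1, [2.5, 97.5], axis=0)
m = b1.mean(axis=0)
print(f"beta1 1988: {m[0]:.2f} (95% CI {lo[0]:.2f}, {hi[0]:.2f})")
print(f"beta1 2008: {m[-1]:.2f} (95% CI {lo[-1]:.2f}, {hi[-1]:.2f})")
```

prints

```
{'model_kind': 'VCM', 'D_theta': -92.96, 'p_d': 52.6, 'DIC': -40.36,
 'sigma2_str': 2.75, 'sigma2_str_ci': [1.23, 5.13],
 'sigma2_unstr': 0.46, 'sigma2_unstr_ci': [0.16, 1.06], 'rho': 0.86,
 'n_positive': 14, 'n_negative': 11, 'share_positive_pct': 38.9}
beta1 1988: 3.12 (95% CI -0.09, 5.87)
beta1 2008: 2.92 (95% CI -0.10, 5.68)
```

Reading the output: ρ = 0.86 says the spatially *structured* component
dominates total spatial variance — the panel was simulated with
σ²_str = 2.26 against σ²_unstr = 0.56, and the fit recovers that
signature (2.75 vs 0.46, both CIs covering truth). Fourteen of the 36
counties carry ≥ 80% posterior probability of an elevated rate given
their location. The time-varying availability effect is recovered with
wide intervals covering the declining truth: on a 36-county panel the
covariate's cross-sectional variation competes with the county effects,
so the effect is informed mostly by within-county changes over time.
`summary.counties` holds, per county, the structured-effect mean, its
positive posterior probability, the 80%-rule classification and a
quintile map bin ready for joining to any mapping tool.

The same pipeline is scriptable from the shell:

```sh
starpanel simulate --out demo --rows 6 --cols 6 --components 2 --seed 7
starpanel fit --panel demo/panel.csv --graph demo/graph.gal --out demo/vcm \
    --model vcm --iterations 22000 --burnin 2000 --thin 20 --seed 1
starpanel index --census demo/census.csv --out demo/scores.csv
starpanel standardize --counts demo/counts.csv \
    --standard demo/standard_population.csv --out demo/rates.csv
```

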