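# ergmotif

Significance testing of network motifs in biological networks with
exponential random graph models (ERGMs).

Molecular networks — directed gene-regulatory networks, undirected
protein–protein interaction (PPI) networks — are full of recurring
small subgraphs ("motifs"): the feed-forward loop (transitive triad,
030T in the triad-census naming), the bi-fan, the bi-parallel.  The
classical test compares a motif's count against degree-preserving
randomizations, one motif at a time, assuming independence.
`ergmotif` instead fits a model of the whole network,

    Pr(X = x) = (1/κ(θ)) · exp( Σ_A θ_A z_A(x) ),

whose statistics z_A include density, reciprocity, sinks/sources,
alternating k-stars, alternating k-two-paths and k-triangles with
decay λ, self-loops, and node-attribute effects (sender, receiver,
interaction, categorical matching).  A significantly positive θ_A
means configuration A is over-represented *given every other effect in
the model*.  Motifs that are not themselves model terms (bi-fan,
bi-parallel, the full triad census) are then tested against an
ensemble simulated from the fitted model — a null that already
accounts for density, degree skew, two-paths and transitive closure.

The package provides:

* a graph data model with edge-list / Pajek I/O, attribute tables
  (with NA-aware categorical matching), multi-edge/self-loop
  preprocessing, and confidence-score thresholding for weighted
  interaction data;
* all configuration statistics with exact local change statistics;
* a Metropolis–Hastings sampler with uniform-toggle and exact
  fixed-density swap proposals, no-reciprocity conditioning, and
  optional self-loop modelling;
* moment-equation (approximate maximum-likelihood) estimation with
  multi-run pooling, standard errors from the simulated Fisher
  information, and the |t| ≤ 0.3 convergence rule;
* simulation-based goodness-of-fit (degree, geodesic, shared-partner
  and triad-census distributions) and a Mahalanobis-distance grid
  search over the λ decay parameters;
* triad census (16 MAN classes), induced bi-fan/bi-parallel counting,
  and ensemble z-scores / empirical p-values;
* synthetic generators for regulatory-like and PPI-like networks, used
  throughout the test suite.

## Worked example

Fit a two-effect model to a sparse synthetic regulatory-like digraph
and test the bi-fan against the fitted ensemble:

```python
import numpy as np
from ergmotif import (EffectSpec, ModelSpec, EstimationSettings,
                      estimate, simulate_ensemble, SamplerSettings,
                      count_four_node_motif, motif_significance, BIFAN)
from ergmotif.synthetic import generate_from_model, plant_bifans

model = ModelSpec([EffectSpec("Arc"), EffectSpec("AltKTrianglesT")])
base = generate_from_model(model, np.array([-4.6, 1.0]), 100, seed=1)
net = plant_bifans(base, 3, seed=2)          # spike in 3 bi-fans

ests, runs = estimate(net, model, EstimationSettings(n_runs=3, seed=3))
for e in ests:
    flag = "*" if e.significant else " "
    print(f"{e.effect:16s} {e.theta:+.3f} ({e.ci95[0]:+.3f}, {e.ci95[1]:+.3f}){flag}")

theta = np.array([e.theta for e in ests])
ens = simulate_ensemble(model, theta, init=net, n_samples=100,
                        settings=SamplerSettings(seed=4), keep_networks=True)
obs = count_four_node_motif(net, BIFAN)
sims = [count_four_node_motif(s, BIFAN) for s in ens.networks]
z, p = motif_significance(obs, sims)
print(f"bifan: observed {obs}, ensemble mean {np.mean(sims):.2f}, "
      f"z = {z:.2f}, p = {p:.4f}")
```

Output from this exact script:

```
Arc              -4.469 (-4.677, -4.261)*
AltKTrianglesT   +0.734 (-0.504, +1.972) 
bifan: observed 3, ensemble mean 0.29, z = 5.67, p = 0.0099
```

Reading it: the density parameter is strongly negative (a sparse
network) and the transitive-closure estimate is positive but not
significant at this size (its interval straddles zero — one synthetic
network of 100 nodes carries limited information about closure), while
the bi-fan count sits above all 100 ensemble draws (upper-tail
empirical p = 1/101): the planted bi-fans are detected as
over-represented even under a null that models density and
transitivity.

A command-line interface mirrors the library —
`ergmotif fixture|estimate|simulate|gof|gridsearch|motifs`, each
driven by a flat `key = value` config file plus `--seed` and
`--output-dir`; see `ergmotif --help`.

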