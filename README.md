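# manifoldcost

A quantitative cost function for the topology of low-dimensional data
manifolds, with the supporting preprocessing (a chemometrics scaling suite,
a principal-component outlier classifier), a cost-guided backward
feature-selection algorithm, and synthetic benchmark generators.

## The problem

Reduced-order modeling, embedding-based visualization and regression on
latent coordinates all start the same way: a dataset **X** ∈ ℝ^(N×Q) is
projected onto a small number of manifold parameters **η** = [η₁, …, η_q]
(via PCA, t-SNE, UMAP, an autoencoder, …).  Whether anything useful can be
built on top of **η** depends on the *topology* of the projection with
respect to the dependent variables **φ** = [φ₁, …, φ_m] one cares about:

* **non-uniqueness** — regions where the projection folds over itself, so a
  single manifold location carries several different φ values; no regression
  can resolve this;
* **small feature sizes** — regions where φ changes steeply over a tiny
  patch of the manifold, which is hard to model and often a milder symptom
  of the same folding.

`manifoldcost` turns these two pathologies into a single number, so that
scalings, projection techniques, hyper-parameters and variable subsets can
be ranked instead of eyeballed.  It applies to manifolds of any
dimensionality and any user-selected dependent variables — including numeric
class labels (e.g. cluster identity in a 2D embedding of transcriptomics
data).

## The metric

For each dependent variable φ, with **η** min-max scaled to the unit box,
the kernel-smoothed *normalized variance* at bandwidth σ is

    N(σ) = Σₖ (φₖ − K(ηₖ, σ))² / Σₖ (φₖ − φ̄)² ,

where K(η, σ) is the Gaussian-kernel weighted average of φ with weights
wⱼ = exp(−‖ηⱼ − η‖²₂ / σ²).  N runs from ≈0 (structure fully resolved at
vanishing bandwidth) to ≈1 (smoothing at the manifold diameter erases all
structure).  Its scale-space derivative

    D(σ) = dN/dlog₁₀σ + lim_{σ→0} N(σ) ,     D̂ = D / max D

peaks at every length scale where φ varies; the rightmost peak σ_peak is the
largest feature size, and any mass at σ ≪ σ_peak signals non-uniqueness.
The per-variable cost integrates D̂ against a penalty anchored at σ_peak
(σ̃ = log₁₀σ):

    L_i = ∫ P(σ) D̂(σ) dσ̃ ,
    P(σ) = |σ̃ − σ̃_peak|^r + b (σ̃_max − σ̃_min)/(σ̃_peak − σ̃_min) ,

with defaults r = 1, b = 1 and σ ∈ logspace(−7, 3, 200).  Per-variable costs
are aggregated with a norm (L₁ by default): **lower L, better-behaved
manifold**.  The computation scales as O(mN²) per bandwidth.

## Worked example

Score the hand-constructable non-uniqueness benchmark: a 1D manifold with
φ = x, against the same manifold with 90 overlapping observations forced to
φ = 0:

```python
from manifoldcost import ManifoldCost
from manifoldcost.datasets import gen_overlap

for d in (0, 90):
    eta, phi = gen_overlap(d=d)
    model = ManifoldCost(r=1.0, b=1.0).fit(eta, phi)
    print(f"d={d}: L = {model.cost_:.2f}, "
          f"sigma_peak = {model.sigma_peaks_[0]:.2g}")
```

prints

```
d=0: L = 1.10, sigma_peak = 0.61
d=90: L = 2.11, sigma_peak = 0.61
```

The largest feature (the unit gradient, σ_peak ≈ 0.6) is identical in both
cases; the overlapping observations add a secondary rise in D̂ at
σ ≈ 5×10⁻⁴ — the distance between an overlap point and its nearest unique
neighbor — and the penalized integral nearly doubles.  The same estimator
composes with scikit-learn:
`CostGuidedFeatureSelector(n_components=2).fit(X, phi)` backward-eliminates
state variables to minimize the cost of the retained subset's PCA
projection.

The same pipeline is available from the shell:

```bash
manifoldcost toygen overlap --d 90 --out overlap90.csv
manifoldcost assess --embedding overlap90.csv --out report
manifoldcost rank-scalings --data data.csv --vars T,Y1 --dim 2 --out rank
```

`assess` writes a JSON cost report (with full provenance) plus the
N(σ)/D̂(σ) curves as TSV; `rank-scalings` loops all thirteen scalings
(None, Auto, Pareto, VAST, Range, ⟨0,1⟩, ⟨−1,1⟩, Level, Max, Poisson,
S1–S3) over a q-dimensional PCA projection and writes the ranked table.

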