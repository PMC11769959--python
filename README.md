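# metabolink

Network analysis of longitudinal metabolomics data by coupling pairwise PCA
with sparse Gaussian graphical models.

## The problem

NMR metabolomics of differentiating cell cultures yields a table of
estimated metabolite concentrations: one row per sample, one column per
metabolite, with each sample belonging to one stage of an ordered biological
progression (e.g. hESC → embryoid body → rosette → neural progenitor →
neuron). Two questions recur in such studies:

1. **Which metabolites move together?** Pairwise correlations are too dense
   to read at p ≈ 90 metabolites; what is wanted is the *conditional*
   dependence structure.
2. **Which metabolites characterize each stage transition?** A five-way
   classification is hard to read off a global ordination, but each
   *consecutive pair* of stages is a clean binary contrast.

This package answers both and overlays the answers. It is aimed at
metabolomics / systems-biology researchers working with stage- or
time-resolved concentration tables, but nothing in it is specific to NMR.

## Method

Let X be the n × p concentration matrix, column-standardized
(z-scores, population sd). Three ingredients:

**Sparse precision network.** The graphical lasso maximizes the penalized
Gaussian log-likelihood

```
log det Θ − tr(S Θ) − α Σ_{i≠j} |Θ_ij|
```

over positive-definite precision matrices Θ, where S is the empirical
covariance of the standardized data. A zero Θ_ij means metabolites i and j
are conditionally independent given all others; nonzero entries become
edges weighted by the partial correlation −Θ_ij/√(Θ_ii Θ_jj) (positive →
solid line, negative → dashed; thickness ∝ magnitude). The solver is a
from-scratch blockwise coordinate descent (Friedman-style, duality-gap
stopping); the full-dataset penalty is chosen by K-fold cross-validated
held-out log-likelihood, while per-transition fits use a fixed α = 0.9
because the small pair subsets are unstable under cross-validation.
Metabolites left with no edges are pruned from the drawn network.

**Transition PCA.** For each consecutive stage pair (a, b), PCA via SVD on
the pair's samples gives loadings with a deterministic sign convention. The
component maximizing the standardized between-stage score separation is
selected and oriented so stage b's samples score higher; each metabolite's
signed loading on that component then associates it with stage a (negative)
or stage b (positive), and |loading|, max-normalized within the pair, is
its score intensity in [0, 1].

**Overlay.** Each transition's sparse network is drawn over the full-data
background network (neutral grey, shared seeded layout across panels). Node
color = assigned stage, color intensity = score intensity, node size =
|Δ| where Δ is the stage-mean difference of normalized concentration over
the transition. Everything rendered is also exported as tables
(GraphML + CSV), so no number lives only in a figure.

A template pattern screen is included: a dash-separated profile such as
`1-2-3-4-5` (monotone increase) or `2-1-1-1-1` (elevated only in the first
stage) is correlated per metabolite against the stage-indexed levels
(Pearson r with t-distribution p-values).

Because the original study's NMR dataset is not publicly deposited, the
package ships a first-class synthetic-data module: multivariate Gaussian
draws from a planted sparse precision matrix (Erdős–Rényi support,
diagonally dominant), with persistent stage-mean shifts on planted marker
sets, so every pipeline claim is testable against recorded ground truth.

## Worked example

```python
from metabolink import (StageSequence, PipelineConfig, make_truth, plant_markers,
                        generate_dataset, run_all_transitions)

stages = StageSequence(["hESC", "EB", "Rosette", "hNPC", "Neuron"])
truth = make_truth(20, stages, density=0.08, seed=7)
truth = plant_markers(truth, ("EB", "Rosette"), ["M003", "M011", "M017"], shift=3.0)
data = generate_dataset(truth, n_rep=8, seed=70)

full, nets = run_all_transitions(data, stages, PipelineConfig(seed=0))
print(f"background: {len(full.network.nodes)} nodes, {full.network.n_edges} edges "
      f"(alpha = {full.alpha:.3f})")
net = nets[1]  # EB -> Rosette
top = sorted(net.node_attrs, key=lambda m: net.node_attrs[m]["score_intensity"],
             reverse=True)[:3]
for m in top:
    a = net.node_attrs[m]
    print(f"{m}: stage={a['assigned_stage']}  intensity={a['score_intensity']:.2f}  "
          f"delta={a['delta']:+.2f}")
```

prints

```
background: 14 nodes, 11 edges (alpha = 0.300)
M003: stage=Rosette  intensity=1.00  delta=+1.91
M010: stage=Rosette  intensity=0.99  delta=+0.32
M017: stage=Rosette  intensity=0.93  delta=+1.68
```

The background network keeps 14 of 20 metabolites (6 had no surviving
conditional dependencies at the cross-validated penalty α = 0.300). For the
EB → Rosette transition, two of the three planted markers (M003, M017) top
the intensity ranking, are assigned to the later stage, and show large
positive concentration deltas; M010 is a correlated neighbor pulled up by
the planted dependence structure.

The same pipeline is available from the shell:

```
metabolink synth --n-metabolites 40 --n-rep 6 --seed 1 --out sim
metabolink run --input sim.csv --stages hESC,EB,Rosette,hNPC,Neuron \
    --seed 1 --out results/
metabolink pattern --input sim.csv --stages hESC,EB,Rosette,hNPC,Neuron \
    --pattern 1-2-3-4-5 --out patterns.csv
```

`run` writes one background GraphML, one annotated GraphML + node/edge CSV
per transition, the heatmap and 3-D PCA scatter with their underlying
tables, and a provenance JSON (versions, seeds, penalties, config hash).

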