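# hillode

**Prior-informed, Hill-kinetics-structured neural ODEs for gene
regulatory dynamics.**

`hillode` learns a continuous dynamical model of gene expression from
sparse time-series (or pseudotime) trajectories and keeps the model
*explainable*: the trained parameters directly encode a gene regulatory
network (GRN) that can be extracted, scored against reference networks,
and interrogated with in silico perturbations.  It is aimed at
computational biologists who have (a) expression trajectories for tens
to hundreds of genes and (b) a putative regulator→target network (from
motif scans, ChIP data, or curation) and want a dynamical model that
both predicts expression and exposes which regulations it learned.

## The model

Expression g(t) ∈ [0,1]^n evolves as dg/dt = f(g) − g with fixed
unit-rate degradation.  The production field f is a neural network whose
activations mirror the Hill-Langmuir binding curve
H(P) = P^α/(κ^α + P^α):

    φ_Σ(x) = (x − 0.5)/(1 + |x − 0.5|)        φ_Π(x) = log(1 + φ_Σ(x))

    dĝ/dt = ReLU(υ) ⊙ [ W_∪ ( c_Σ(g) ⊕ c_Π(g) ) − g ]
    c_Σ(g) = W_Σ φ_Σ(g) + b_Σ                 (additive co-regulation)
    c_Π(g) = exp(W_Π φ_Π(g) + b_Π)            (multiplicative, log scale)

Per-gene multipliers ReLU(υ) let genes with no temporal variation be
represented exactly.  A prior network A (signed or existence-only)
enters as a soft constraint: the blended loss

    L = λ · MSE[g(t₁), solve(g(t₀))] + (1−λ) · (1/K) Σₖ MSE[(A−I)γₖ, f̂(γₖ)]

penalizes the learned field toward the linear prior field on K random
"ghost" expression vectors γₖ ∈ [0,1]^n, with λ tuned on a validation
split.  After training, the encoded GRN is read out in closed form as
the Jacobian of the field at the activation centre,
D = diag(ReLU(υ))(U_Σ W_Σ + U_Π diag(e^{b_Π}) W_Π), with no sensitivity
analysis.  Everything runs in numpy on one CPU; gradients through the
ODE solve are hand-derived (see `docs/methods.md`).

A built-in simulator generates signed ground-truth networks with random
Hill kinetics and noisy trajectories, so the entire pipeline can be
validated against known truth.

## Worked example

`examples/train_and_extract_network.py` simulates a 50-gene system,
trains with a 20%-corrupted prior, and scores the extracted network
(about a minute on one CPU):

```
validation MSE after training: 6.43e-04
edge-recovery AUC: 0.949  (corrupted prior alone: 0.894)
out-degree correlation: 0.848
C_max threshold 0.0993: TPR 0.85, TNR 0.98, sparsity 0.95
sign accuracy on true edges: 0.80
```

Reading the numbers: the trained model ranks true regulator→target
pairs above non-edges with AUC 0.949 — *above* the 0.894 achieved by
the corrupted prior it was trained with, so the model learned regulatory
structure from the data beyond what the prior encoded.  At the
balanced-accuracy-optimal threshold the binary network recovers 85% of
true edges while rejecting 98% of non-edges, and 80% of true edges carry
the correct activating/repressive sign in the extracted matrix.

Other entry points: `examples/simulate_benchmark_data.py` (the
simulator and its calibration), `examples/influence_analysis.py`
(perturbation influence scores, pathway permutation tests, regulator
log-fold changes), `examples/full_benchmark.py` (the full 350-gene
protocol; long-running).  A thin CLI wraps the same library calls:

```bash
hillode simulate --n-genes 100 --n-traj 160 --sigma 0.025 --corruption-level 0.1 --seed 1 --out sim/
hillode train --expr sim/trajectories.tsv --prior sim/prior_edges.tsv --out run/
hillode extract-grn --checkpoint run/model.npz --out edges.tsv
hillode evaluate --checkpoint run/model.npz --truth sim/truth_edges.tsv --out metrics.json
```

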