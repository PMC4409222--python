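# nide — robust Bayesian differential gene expression

`nide` identifies differentially expressed (DE) genes from microarray-style
expression matrices (bulk or single-cell log intensities / log ratios) when
the data contain outliers and only a handful of replicates per gene. Instead
of assuming Gaussian errors, it fits a Bayesian hierarchical model whose
errors follow a **normal/independent (N/I)** distribution — a scale mixture
of normals

    Y_isr = μ_is + ε_isr / √U_isr,   ε_isr | τ_εi ~ N(0, τ_εi⁻¹),
    U_isr ~ g(u; ν_i)

covering the normal, Student-t, slash, contaminated-normal and Laplace
families. Outlying replicates are absorbed by small latent scale factors
U_isr rather than inflating a gene's variance, so moderate shifts stay
detectable.

Group means carry a spike mixture prior over mean-equality patterns: for two
groups,

    μ_i ~ (1−p) N(μ_i1; 0, τ_μ12⁻¹) 1[μ_i1 = μ_i2]
        +   p   N(μ_i1; 0, τ_μ1⁻¹) N(μ_i2; 0, τ_μ2⁻¹) 1[μ_i1 ≠ μ_i2]

and for k ≤ 5 groups every set partition of the groups is a mixture
component (a gene is DE iff at least one pairwise equality fails — the
union–intersection rule). Inference is by a collapsed Metropolis-within-Gibbs
sampler (numba-compiled, reproducible from a seed); decisions use the
per-gene posterior DE probability π_i = P(not all means equal | data),
thresholded at κ, with Bayesian error rates

    bFDR = Σ(1−π_i)r_i / Σr_i,  bFPR = Σ(1−π_i)r_i / Σ(1−π_i),
    bTPR = Σπ_i r_i / Σπ_i,     r_i = 1(π_i > κ),

plus posterior-weighted ROC/AUC curves. A simulation-study module generates
the standard two-group heavy-tail benchmarks (contaminated-normal or t
errors, a stated fraction of genes shifted by δ in group 1) and scores
TPR/FPR/TDR/AUC against the known truth. See `docs/methods.md` for the full
model, sampler and design notes.

## Worked example

```python
import numpy as np
from nide import (ExpressionDataset, MCMCConfig, NIFamilySpec,
                  bayes_rates, de_probability, run_chains)

rng = np.random.default_rng(0)
n1, n2 = 8, 6
values = rng.normal(14.0, 1.0, size=(100, n1 + n2))
values[:5, :n1] += 3.0            # five genes shifted in group 1
data = ExpressionDataset(values, [f"g{i}" for i in range(100)],
                         ["treated", "control"],
                         np.array([0] * n1 + [1] * n2))

config = MCMCConfig(n_iter=4000, n_burnin=2000, n_chains=2, seed=1,
                    family=NIFamilySpec.t(5.0))
summary = de_probability(run_chains(data, config))
report = bayes_rates(summary, kappa=0.5)
print(f"called {report.n_called} genes at kappa=0.5, bFDR={report.bFDR:.4f}")
print("top posterior DE probabilities:", np.round(np.sort(summary.pi)[-6:], 3))
```

Output:

```
called 4 genes at kappa=0.5, bFDR=0.0134
top posterior DE probabilities: [0.436 0.476 0.955 0.992 1.    1.   ]
```

Four of the five shifted genes clear the κ = 0.5 threshold (the fifth sits
at π ≈ 0.48 — with 8 + 6 replicates one shifted gene can stay borderline);
`bFDR` is the posterior-expected fraction of false calls among the four
(≈ 1.3%), and the strongest null gene reaches only π ≈ 0.44.

The same analysis from the shell, with results, decisions at
κ ∈ {0.5, 0.7, 0.9, 0.95}, ROC points and a run manifest written as TSV/JSON:

```sh
nide fit --matrix expr.tsv --groups groups.tsv --family t \
         --iters 20000 --burnin 15000 --chains 2 --seed 1 --out results/
nide simulate --config study.yaml --out study_out/
nide check            # sampler self-test (prior-marginal preservation)
```

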