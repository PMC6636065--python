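# mplnmix

Model-based clustering of multivariate count data — RNA-seq gene expression
in particular — with finite mixtures of **multivariate Poisson-log normal
(MPLN)** distributions, estimated by a Markov chain Monte Carlo EM
(MCMC-EM) algorithm.

## Who this is for

Given a genes × samples matrix of read counts, the goal is to find groups of
co-expressed genes. Count data from sequencing experiments are overdispersed
and correlated across samples, which univariate Poisson or negative-binomial
mixtures cannot represent. The MPLN model keeps the discrete Poisson
observation layer but places a multivariate Gaussian on the latent log-means,
so each cluster carries a full covariance structure over samples.

## The model

For gene *i* and sample *j*, with fixed normalization offsets *s<sub>j</sub>*
(trimmed mean of M-values, TMM, by default):

```
Y_ij | θ_ij ~ Poisson( exp{ θ_ij + log s_j } )
(θ_i1, …, θ_id)′ ~ N_d( μ_g , Σ_g )          for a gene in cluster g
```

A *G*-component mixture attaches weights π<sub>g</sub>. Marginally
E(Y<sub>j</sub>) = exp{μ<sub>jg</sub> + ½σ<sub>jjg</sub>} =: m<sub>jg</sub> and
Var(Y<sub>j</sub>) = m<sub>jg</sub> + m<sub>jg</sub>²(e^{σ_jjg} − 1) ≥
E(Y<sub>j</sub>): overdispersion is built in.

Because the latent posterior f(θ<sub>ig</sub> | y<sub>i</sub>, μ<sub>g</sub>,
Σ<sub>g</sub>) has no closed form, the E-step is Monte Carlo: per gene and
component, MCMC chains (3 chains, half discarded as warmup) are drawn and
gated on split-chain R-hat < 1.1 and effective sample size > 100, with the
chain length increased by 100 and sampling redone when the gate fails.
Responsibilities and the closed-form M-step updates (π, μ, Σ) follow.  The
outer loop stops when the Heidelberger–Welch stationarity test accepts the
log-likelihood trace at α = 0.05.  The number of clusters is selected by
BIC (AIC, AIC3 and ICL are also reported), with the free-parameter count
K = (G−1) + Gd + Gd(d+1)/2.

## Worked example

Simulate a two-component dataset, then cluster it:

```bash
mplnmix simulate --scenario S2 --n 150 --seed 42 -o sim/
mplnmix fit sim/counts.csv --g-min 1 --g-max 3 --max-em-iter 15 --seed 7 -o run/
```

The fit prints the per-G criteria table and the selection:

```
 G  K       loglik         AIC         BIC        AIC3         ICL  converged  failed
 1 27 -4544.632167 9143.264333 9224.551486 9170.264333 9224.551486       True   False
 2 55 -4342.896293 8795.792586 8961.377527 8850.792586 8961.377527       True   False
 3 83 -4325.175085 8816.350170 9066.232899 8899.350170 9104.025544       True   False
chosen G (BIC): 2
```

BIC is minimized at G = 2, the generating number of clusters: the extra
component of G = 3 buys only ~18 log-likelihood units against a penalty
difference of ~105. ICL > BIC at G = 3 flags the uncertain assignments the
superfluous component creates, while at G ≤ 2 the responsibilities are
one-hot and ICL = BIC. `run/` then contains the
criteria table, per-G weights/means/covariances, the responsibility matrix
ẑ<sub>ig</sub>, MAP cluster labels (here matching the generating labels,
adjusted Rand index 1.0), per-cluster mean log-expression profiles and a
manifest with every seed needed to reproduce the run.

The same pipeline is available as a library:

```python
from mplnmix import RunConfig, run_clustering_range, load_counts
report, fits, offsets = run_clustering_range(load_counts("sim/counts.csv"),
                                             RunConfig(g_min=1, g_max=3,
                                                       master_seed=7))
print(report.best("BIC"))
```

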