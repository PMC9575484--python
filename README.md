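# rbpnet

Inference of RNA-binding-protein (RBP) regulatory networks from bulk
RNA-seq expression, with survival follow-up — the analysis style used to
study RBP–ncRNA regulation in acute myeloid leukemia cohorts.

## Scientific problem

RBPs control the post-transcriptional fate of coding and non-coding RNAs
(lncRNAs, snoRNAs, circRNA hosts). In a tumor cohort, an RBP that drives a
target's abundance leaves a statistical dependence between the two
expression profiles across patients — but that dependence is often
*nonlinear*, so Pearson correlation misses it. This package:

1. normalizes raw counts (log2 + quantile, or TMM + log2-CPM);
2. screens for genes upregulated in high-risk versus lower-risk patients
   (two-sided *t*-test plus fold-change gate);
3. tests every RBP–gene pair with the **unbiased distance correlation**,
   which detects linear and nonlinear dependence alike, and keeps edges
   passing a stringent dual threshold;
4. asks whether network genes carry prognostic signal (median-split
   log-rank test and univariate Cox regression on overall survival).

A negative-binomial synthetic-cohort generator with planted ground truth
(upregulated genes, regulatory edges of known functional form, hazard
effects) makes every stage testable end to end.

## Model

For a gene pair with expression vectors `x, y ∈ R^n` over `n` patients,
let `a_ij = |x_i − x_j|` and define the U-centered matrix

```
Ã_ij = a_ij − (1/(n−2)) Σ_k a_kj − (1/(n−2)) Σ_l a_il + (1/((n−1)(n−2))) Σ_kl a_kl ,   Ã_ii = 0 .
```

The unbiased distance covariance and correlation are

```
Cov_D(x, y) = (1/(n(n−3))) Σ_ij Ã_ij B̃_ij ,
R_D(x, y)   = Cov_D(x, y) / sqrt(Cov_D(x, x) · Cov_D(y, y)) ∈ [−1, 1] ,
```

with the conservative large-sample test `P = 1 − F_{χ²₁}(n·R_D + 1)`.
An edge RBP → target is kept when `P < 1e−6` and `R_D > 0.2` (both
configurable). Differential expression uses Student's *t* (high-risk vs
intermediate + low) with `p < 0.05` and `log2FC ≥ 1`. Survival uses the
cohort-median expression split for the log-rank test and the Cox partial
likelihood `h(t|z) = h₀(t)·exp(βz)` (Efron ties) for effect sizes.

## Worked example

```python
from rbpnet.synth import SimulationDesign, simulate_cohort
from rbpnet.normalize import log2_quantile_normalize
from rbpnet.de import de_screen, upregulated_ids
from rbpnet.dcor import pairwise_screen
from rbpnet.network import build_network
from rbpnet.survival import km_logrank, cox_univariate
from rbpnet.io import RunConfig

design = SimulationDesign(n_genes=500, rng_seed=7)   # 37/101/32 risk groups
expr, ann, genes, truth = simulate_cohort(design)
norm = log2_quantile_normalize(expr)

cfg = RunConfig()
up = upregulated_ids(de_screen(norm, ann, cfg))
rbps = [g for g in genes.genes_of_class("RBP") if g in set(up)]
net = build_network(pairwise_screen(norm, rbps, up), genes, cfg)
print(net.edges.head(3).to_string(index=False))

g = net.edges.target_id.iloc[0]
km = km_logrank(norm.values.loc[g], ann)
cox = cox_univariate(norm.values.loc[g], ann, cfg)
print(f"{g}: logrank p={km.p_value:.3g}  Cox HR={cox.hazard_ratio:.3f} "
      f"(95% CI {cox.ci_low:.3f}-{cox.ci_high:.3f})")
```

Output:

```
rbp_id target_id target_class   n      r_d        p_raw
RBP001    G00074       coding 170 0.536376 7.898419e-22
RBP001    G00246       coding 170 0.504453 1.227075e-20
RBP002    G00168       coding 170 0.545222 3.694322e-22
G00074: logrank p=0.645  Cox HR=1.008 (95% CI 0.850-1.197)
```

Three of five simulated RBPs pass the differential-expression gate and
the strongest planted edges survive the `P < 1e−6 ∧ R_D > 0.2` screen;
this particular target carries no planted hazard effect, and the survival
tests correctly find nothing.

The same pipeline is available from the command line:

```bash
rbpnet --seed 7 --out-dir out run-all --n-genes 500
```

which writes `counts.tsv`, `normalized.tsv`, `de_results.tsv`,
`network.edges.tsv`, `network.graphml`, `survival.tsv`, `summary.json`
and the ground-truth file, byte-identically for a fixed seed.

## Layout

- `src/rbpnet/io.py` — tabular formats, schemas, run configuration
- `src/rbpnet/normalize.py` — log2+quantile and TMM+log2-CPM
- `src/rbpnet/de.py` — risk-group differential expression
- `src/rbpnet/dcor.py` — unbiased distance correlation and pairwise screen
- `src/rbpnet/network.py` — edge filtering, degrees, summaries, GraphML
- `src/rbpnet/survival.py` — log-rank, Kaplan–Meier, univariate Cox
- `src/rbpnet/synth.py` — negative-binomial cohort generator with ground truth
- `src/rbpnet/cli.py` — stagewise and `run-all` command line

See `docs/methods.md` for model details, generator assumptions and
numerical choices.
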