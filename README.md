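# aadfe

Type-specific distributions of fitness effects (DFEs) for amino-acid
replacements: maximum-entropy fitting of deep-mutational-scanning (DMS)
quantiles and a tunable purifying-selection model of evolutionary
exchangeability.

## The problem

Substitution matrices and evolutionary comparisons say that some amino-acid
replacements (say Thr↔Ser) are far more acceptable than others — yet the
effect of any *single* replacement is notoriously context-dependent. These
views can be reconciled by looking at the whole distribution of fitness
effects for each of the 20×19 = 380 ordered replacement types, built by
pooling DMS assays on a common within-assay percentile-rank scale
(quantiles in (0, 1], 1 = fittest).

On that scale the type-specific DFE is well described by the
maximum-entropy distribution on [0, 1] with a fixed mean — a truncated
exponential:

```
p(x) = c e^{-λx},   c = λ / (1 − e^{-λ}),   x ∈ [0, 1],
```

with a single real shape parameter λ (λ > 0 ⇔ mean μ < 0.5, deleterious-
leaning; λ = 0 is uniform). The mean determines the whole shape:
μ(λ) = 1/λ − 1/(e^λ − 1), which is strictly decreasing, so λ can be
recovered from a sample mean by Newton inversion. Although mean quantiles
only span roughly 0.22–0.71, the exponential form amplifies modest mean
differences into large differences in the upper tail — a 0.4 vs 0.6 mean
gives a ≥3-fold difference in P(X > 0.9).

Modeling purifying selection as a stringency threshold q (replacements
with fitness quantile below q are rejected) gives the normalized
substitution rate, the type-specific analog of K_a/K_s:

```
K_λ/K_s(q) = (1 − e^{−2(1−q)(−λ)}) / (1 − e^{−2(−λ)}),
```

formally the Kimura fixation probability with scaled coefficient −2λ and
initial frequency 1 − q. As q → 1, K_λ/K_s ÷ (1 − q) → 2(−λ)/(1 − e^{2λ}):
benign-leaning types are linearly enriched, deleterious types
exponentially depleted. Harmonic-mean combination of the forward and
reverse rates over the 75 amino-acid pairs adjacent under the standard
genetic code predicts the relative-exchangeability index U (centered so
the 75 entries average 1).

A synthetic-data module generates DMS-like assay tables with known
ground-truth λ per type (and a misspecified "stability" regime with
interior-mode distributions), so the whole rank → fit → selection pipeline
is testable end to end without any downloads.

## Worked example

```python
import numpy as np
from aadfe import (fit_lambda_from_mean, tail_probability, k_ratio_limit,
                   pool_by_type, summarize_all, predict_U)
from aadfe.synthetic import (gen_lambda_matrix, SyntheticScenario,
                             gen_scenario_assays)

# a replacement type whose mean quantile is 0.62 (Arg->Lys-like)
m = fit_lambda_from_mean(0.62)
print(f"lambda = {m.lambda_:.4f}")
print(f"P(top 10%) = {tail_probability(m, 0.9):.4f}  (uniform: 0.1000)")
print(f"K/Ks enrichment as q->1: {k_ratio_limit(m.lambda_):.3f}")

# full synthetic pipeline: 5 assays x 7600 mutations, known lambda*
lm = gen_lambda_matrix(seed=42)
scenario = SyntheticScenario(lambda_star=lm, seed=42, n_assays=5,
                             muts_per_assay=7600)
dfes, long, dropped = pool_by_type(gen_scenario_assays(scenario))
reports, agg = summarize_all(dfes, seed=43)
star = np.array([lm.entries[(r.from_aa, r.to_aa)] for r in reports.itertuples()])
print(f"types: {agg['n_types']}, records: {agg['total_records']}")
print(f"corr(lambda*, lambda_hat) = {np.corrcoef(star, reports['lambda_hat'])[0,1]:.4f}")
print(f"split-half fit pass fraction = {agg['fit_pass_fraction']:.3f}")
for q in (0.5, 0.999):
    print(f"predicted U dynamic range at q={q}: {predict_U(lm, q).dynamic_range:.1f}")
```

prints

```
lambda = -1.4926
P(top 10%) = 0.1789  (uniform: 0.1000)
K/Ks enrichment as q->1: 3.144
types: 380, records: 38000
corr(lambda*, lambda_hat) = 0.9801
split-half fit pass fraction = 1.000
predicted U dynamic range at q=0.5: 46.4
predicted U dynamic range at q=0.999: 1599.4
```

A mean quantile of 0.62 corresponds to λ ≈ −1.49: such a replacement is
better than a random one only 62% of the time, but it is ~1.8× as likely as
a random one to land in the fittest decile, and accumulates ~3× faster
under stringent selection. On the synthetic data, fitted λ values track the
ground truth (r = 0.98 at ~100 observations/type, >0.99 at ~1000), the
split-half KS test retains the exponential law, and the predicted
exchangeability spread widens sharply as the stringency q → 1.

The same pipeline runs from the shell over a YAML config:

```
aadfe all config.yaml        # simulate (if configured) -> rank -> fit -> select
```

with subcommands `simulate`, `rank`, `fit`, `select` for individual stages.
Assay inputs are headered CSV/TSV files (`mutant,score`; the ProteinGym
v0.1 `mutant,DMS_score` dialect is a named preset).

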