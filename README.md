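# sigtie

Significant-tie backbone extraction for temporal networks.

Timestamped interaction data — face-to-face contacts from wearable sensors,
daily interbank loans, e-mail exchanges — mix structurally meaningful ties
with interactions that occur simply because both parties are very active.
`sigtie` filters a temporal network against a *temporal fitness null model*:
it keeps exactly those pairs of nodes that interact more often than their
individual activity levels can explain.  Because the null model is temporal,
it can also assign significance to higher-order temporal structure such as
triads of *simultaneous* interactions — something no filter defined on the
time-aggregated network can do.  It is aimed at researchers in network
science, computational epidemiology and computational social science who
need a principled, tunable backbone of a contact sequence.

## Model

The observation window of length *T* is split into τ = ⌊*T*/Δ⌋ intervals at
resolution Δ; each interval yields a binary snapshot in which pair (i, j) is
present if it interacted at least once.  The null model gives every node a
latent activity *a*ᵢ ∈ (0, 1] and lets every pair interact independently in
every interval with probability

&nbsp;&nbsp;&nbsp;&nbsp;*u*(*a*ᵢ, *a*ⱼ) = *a*ᵢ·*a*ⱼ,

so the aggregate count *m*ᵢⱼ is Binomial(τ, *a*ᵢ*a*ⱼ).  The activities are
estimated by maximum likelihood from all pair counts jointly, solving the
score equations

&nbsp;&nbsp;&nbsp;&nbsp;*H*ᵢ(**a**) = Σⱼ≠ᵢ (*m*ᵢⱼ − τ*a*ᵢ*a*ⱼ)/(1 − *a*ᵢ*a*ⱼ) = 0,&nbsp;&nbsp; i = 1…N,

with a configuration-model starting point.  Each interacting pair is then
tested against its binomial null: a tie is significant at level α when its
observed count exceeds the (1 − α)-percentile of Binomial(τ, *a*ᵢ\**a*ⱼ\*)
(equivalently P(X ≥ *m*ᵢⱼ) ≤ α; Bonferroni correction optional).  The
significant ties, with their temporally resolved interactions, form an
irreducible temporal backbone.  A triangle (i, j, k) co-occurs within one
interval with probability *v* = *u*ᵢⱼ*u*ⱼₖ*u*ᵢₖ, so simultaneous triads are
tested with the same binomial machinery.

Also included: the disparity-filter baseline (p = (1 − w/s)^(k−1)) on the
aggregate network and per snapshot (DP-R), a planted strong-tie benchmark
generator with ground truth, and backbone comparison metrics (Jaccard,
weighted cosine, intra-community fraction, ROC/AUC, weighted modularity).

## Worked example

```python
from sigtie import (SignificantTieFilter, SyntheticSpec,
                    detection_rates, generate_benchmark)

spec = SyntheticSpec(n_nodes=300, t_span=300, delta=10,
                     strong_fraction=0.2, seed=42)
result = generate_benchmark(spec)          # snapshots + known strong ties

model = SignificantTieFilter(alpha=1e-3).fit(result.snapshots)
backbone = model.backbone()
tested = {t.pair for t in model.tests_}
tpr, fpr, frac = detection_rates(backbone.pairs, result.strong_set, tested)

print(f"tau = {model.tau_}, tested pairs = {model.n_tested_}")
print(f"significant ties = {len(backbone.pairs)} ({frac:.3f} of tested)")
print(f"recovered strong ties: TPR = {tpr:.3f}, FPR = {fpr:.5f}")
```

prints

```
tau = 30, tested pairs = 34612
significant ties = 3286 (0.095 of tested)
recovered strong ties: TPR = 0.474, FPR = 0.00007
```

Of the ~34.6k interacting pairs, 20% carry planted extra interactions; at
α = 10⁻³ the filter flags 9.5% of pairs, essentially all of them truly
strong (7 false positives per 100k null pairs).  The strong ties it misses
join highly active nodes, whose boosted counts the null can still explain —
the flagged fraction is a conservative estimate of the strong fraction.
`model.backbone(alpha)` re-thresholds the stored tails at any other level
without re-fitting, and `model.triads()` tests simultaneous triangles.

A command-line interface mirrors the library
(`sigtie synth | binarize | estimate | filter | triads | baseline |
evaluate | pipeline`); `sigtie pipeline run.yaml` drives the whole analysis
from a config file and writes re-parseable TSV tables plus a JSON manifest.

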