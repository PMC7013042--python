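# scfc — rich-club organization and structure–function coupling of brain networks

`scfc` is a Python toolkit for a common analysis pattern in network
neuroscience: given paired **structural connectomes** (streamline counts
between parcellated brain regions, from diffusion tractography) and
**functional connectomes** (Pearson correlations between regional BOLD
time series) for subjects in several diagnostic groups — e.g. normal
controls (NC), mild cognitive impairment (MCI), and Alzheimer's disease
(AD) — quantify

1. **rich-club organization** of the structural network: hubs, and the
   normalized rich-club coefficient against degree-preserving nulls,
2. the partition of edges into **rich-club / feeder / local** classes and
   their densities,
3. per-subject **SC-FC coupling** — the correlation between Gaussianized
   structural weights and their functional counterparts, overall and per
   edge class, and
4. covariate-adjusted **group statistics** (ANCOVA with age / sex /
   education, Bonferroni-corrected contrasts, chi-square for sex, partial
   correlations with clinical scores).

Because the raw imaging data behind such studies are access-controlled,
the package ships a first-class **synthetic cohort generator** that plants
every effect the analysis is designed to detect — a nested rich club,
group-specific loss of feeder/local connections, tunable coupling
strength, and clinical scores tied to network summaries — so the entire
pipeline is testable end to end with known ground truth.

## The statistics at the core

For a binary undirected network, the **rich-club coefficient** at degree
threshold *k* is

&nbsp;&nbsp;&nbsp;&nbsp;Φ(k) = 2·E(S) / (|S|·(|S|−1)),&nbsp;&nbsp;S = {i : degree(i) > k},

the fraction of realized edges among nodes of degree > *k*. Since high
degrees alone force Φ upward, Φ is normalized by the mean coefficient of
degree-preserving surrogates (Maslov–Sneppen double-edge swaps):
Φ_norm(k) = Φ(k) / ⟨Φ_null(k)⟩. Values above 1 over a range of *k* indicate
rich-club organization beyond what the degree sequence implies.

Hubs are selected once, from the cohort-wide mean degree profile (top
fraction, or mean degree > k), and every present edge falls in exactly one
class: **rich-club** (hub–hub), **feeder** (hub–nonhub), **local**
(nonhub–nonhub). Class densities use the all-pairs denominator N(N−1)/2,
so they sum to network density.

**SC-FC coupling** for one subject is the Pearson correlation, over region
pairs with nonzero SC *and* nonzero FC, between the rank-based
inverse-normal (Blom) scores of the SC weights and the raw FC weights —
one value per subject per scope (all / rich-club / feeder / local), never
pooled across subjects.

Efficiency metrics (global, local, nodal) use hop-count shortest paths
with the 1/∞ = 0 convention.

## Worked example

```python
from scfc import (GeneratorConfig, generate_cohort, consensus_mean_degree,
                  select_hubs, cohort_coupling, ancova, chi_square_sex)
from scfc.richclub import cohort_classification
from scfc.pipeline import covariate_frame

cfg = GeneratorConfig(seed=7)          # 97 subjects, 246 regions, 43 planted hubs
cohort = generate_cohort(cfg)

mean_deg = consensus_mean_degree(cohort)
hubs = select_hubs(mean_deg, {"mode": "top_fraction", "fraction": 43/246})

density = cohort_classification(cohort, hubs)
coupling = cohort_coupling(cohort, hubs)
```

Running the full snippet (see `tests/` for the assembled version) prints:

```
cohort: 97 subjects (NC=38, MCI=40, AD=19)
hubs: 43 regions, consensus mean degree 8.59-18.22
mean edge-class proportions: rich_club=0.120, feeder=0.342, local=0.538
feeder density ANCOVA: F=52.43, p=7.13e-16, adjusted means NC=0.01072 MCI=0.00985 AD=0.00906
mean SC-FC coupling: NC=0.308, MCI=0.393, AD=0.498
sex chi-square: 7.820 (p=0.020)
```

Reading the numbers: the consensus hub set recovers the planted hubs; edge
classes split roughly 12% / 34% / 54%; the planted feeder-density
reduction (MCI and AD keep 90% and 85% of feeder edges) is detected by the
covariate-adjusted group test; and the mean recovered coupling per group
sits on the generative values 0.30 / 0.40 / 0.50.

A command-line interface wraps the same stages:

```bash
scfc simulate --seed 7 --out cohort/          # write a synthetic cohort
scfc run --seed 7 --out results/              # full pipeline, all tables
scfc report results/                          # summarize the stats tables
```

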