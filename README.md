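# metagc

Per-phylum GC-content analysis of classified shotgun-metagenome reads.

Prokaryotic genomes span roughly 15–75% G+C, and the cause of that spread
is contested: lineage-specific neutral processes (mutation bias, biased
gene conversion) predict that GC is a property of *phylogeny*, while
selection by the habitat predicts an *environmental* component that acts
on every resident lineage at once. `metagc` implements the analysis that
separates the two signals in metagenomic survey data, for microbiome and
microbial-ecology researchers working with taxonomically classified
shotgun reads:

1. **Per-phylum GC profiling.** Reads (length ≥ 100 bp, phylum-level
   classification confidence ≥ 0.80) are aggregated into a samples ×
   phyla matrix of mean GC (percent), with SDs and read counts;
   per-sample relative abundances come along for free.
2. **Silent-site GC (GC4).** From annotated coding intervals, third
   positions of 4-fold degenerate codons (boxes GCN, CGN, GGN, CTN, CCN,
   TCN, ACN, GTN under translation table 11) are extracted; their GC is
   immune to selection on amino-acid usage.
3. **Cross-phylum correlation screen.** For every pair of phyla,
   Spearman's ρ of their mean GC across samples (midranks; two-sided p
   from the t approximation t = ρ√((n−2)/(1−ρ²)), or exact permutation
   for small n). If phyla were independent, ~5% of pairs would reach
   p < 0.05 by chance; a shared environmental force produces an excess
   of significant positive correlations. Subsets (one environment /
   all-minus-one), an interquartile outlier filter, and the GC4 matrix
   provide the robustness reruns.
4. **Genus-set similarity.** Per-environment genus presence sets,
   compared with the Jaccard index |A∩B| / |A∪B|.
5. **Dominance/GC enrichment.** Gut samples are ranked by Actinobacteria
   abundance; the dominated subset (abundance ≥ 0.5, or top-q fraction)
   of size n is intersected with the top-K GC-rich samples per phylum
   (K = n) and the overlap k scored by the hypergeometric point mass
   P(X=k) = C(K,k)·C(N−K,n−k)/C(N,n), alongside its upper tail and a
   two-sided Mann–Whitney rank-sum comparison of the two groups' GC.

A synthetic community generator produces labeled read collections with
exactly the statistical structure these analyses assume — per-phylum
Normal GC profiles, an additive per-sample environment offset shared
across phyla, multinomial/Dirichlet abundances (including
Actinobacteria-dominated gut regimes), and coding reads built from
4-fold boxes — so every stage is testable end to end without external
data, with known ground truth.

## Worked example

```python
import numpy as np
from metagc import *
from metagc.synthetic_community import EnvironmentProfile, SyntheticConfig, default_phylum_profiles

cfg = SyntheticConfig(
    phyla=default_phylum_profiles(),
    environments=[EnvironmentProfile("human_gut", n_samples=40)],
    reads_per_sample=500,
    read_length=150,
    offset_sd=3.0,   # shared environmental GC pressure, SD in GC points
    seed=7,
)
collection = generate_collection(cfg)
screened, removed = screen_reads(collection.reads)
print(f"kept {len(screened)} of {len(collection.reads)} reads; removed {removed}")

gc = build_gc_matrix(screened, min_reads=10)
print(gc.mean.round(1).iloc[:3, :3])

results = spearman_matrix(gc)
summary = significance_summary(results)
print(f"mean fraction of significant partners: {summary.attrs['mean_fraction']:.2f} "
      f"(chance level {summary.attrs['alpha']})")
print(f"median rho: {np.median([r.rho for r in results]):.2f}")
```

prints

```
kept 18980 of 20000 reads; removed {'length': 0, 'confidence': 1020, 'unclassified': 0}
phylum           Actinobacteria  Bacteroidetes  Chlamydiae
sample_id
human_gut_s0000            62.6           43.7        40.4
human_gut_s0001            57.3           44.1        36.4
human_gut_s0002            62.7           45.6        40.6
mean fraction of significant partners: 1.00 (chance level 0.05)
median rho: 0.75
```

The screen removed the ~5% of reads whose synthetic classification
confidence fell below 0.80. The matrix shows each phylum near its
characteristic mean (Actinobacteria ~62%, Chlamydiae ~40%) with
sample-to-sample wobble; because a shared offset (SD 3 GC points) moves
all phyla together within each sample, every phylum pair is
significantly positively correlated — the mean significant-partner
fraction is 1.00 against the 0.05 chance level. Set `offset_sd=0.0` and
the fraction falls to ~0.05.

## Command line

```sh
metagc all --config run.yaml --out results/run1
```

runs simulate → screen → GC/GC4/IQR matrices → correlation subsets →
Jaccard → enrichment, writing TSVs plus `report.json`. Stage subcommands
(`simulate`, `screen`, `gc`, `gc4`, `correlate`, `jaccard`, `enrich`)
re-run any piece from its on-disk inputs; see `metagc --help`.

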