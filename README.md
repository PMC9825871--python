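# microassembly

Community-assembly and co-occurrence network analysis for soil microbiome
OTU tables, built around a two-region (arid vs. humid) field design.

Soil bacteria and fungi respond differently to aridity: bacterial communities
tend to assemble stochastically (dispersal and drift), fungal communities
deterministically (environmental filtering along the moisture gradient), and
their co-occurrence networks differ in complexity and in how they tolerate
species loss. `microassembly` packages the full analysis chain needed to ask
those questions of any sample × taxon count table, together with a synthetic
data generator with planted ground truth so that every inference stage has a
recovery test.

## What it computes

* **Diversity & ordination** — Shannon *H*, Pielou *J* = *H*/ln *S*,
  Bray–Curtis dissimilarity, PCoA, one-factor PERMANOVA (seeded,
  bit-reproducible permutations), rank-sum group comparison, and
  distance–decay regression of similarity (1 − BC) on great-circle distance.
* **Niche structure** — Levins breadth *B* = 1/Σ *p*², community breadth
  *B*com, asymmetric Levins overlap *O*ᵢₖ = Σ *p*ᵢ*p*ₖ / Σ *p*ᵢ², and the
  overlap-network mean degree.
* **Assembly inference** — Sloan's neutral community model: occurrence
  frequency predicted as 1 − Beta(*Nm·p*, *Nm*(1−*p*)).cdf(*d*), with *Nm*
  fitted by bounded least squares (`SloanNCM(...).fit()` returns an
  `NCMResults` with estimates, R², Wilson 95 % envelope and a `summary()`
  table); and the normalized stochasticity ratio (NST), which compares each
  within-group pair's dissimilarity with its expectation under a null model
  preserving per-sample richness and occurrence-frequency-proportional
  occupancy (50 % = stochastic/deterministic boundary).
* **Signed networks** — edges are Spearman correlations with |ρ| > 0.6 and
  Benjamini–Hochberg *q* < 0.01 across all tested pairs; per-node degree and
  harmonic closeness, greedy modularity, negative-link proportion, and
  robustness under random-extinction simulation (fraction of taxa retaining
  ≥ 1 link after removing half the nodes).
* **Driver ranking** — out-of-bag permutation importance from a bootstrap
  ensemble of regression trees relating climatic/edaphic covariates to
  community composition (single PCoA axis or eigenvalue-weighted across
  axes).

## Worked example

Generate a study-like dataset (26 arid + 21 humid sites × 3 replicates = 141
samples per marker) and fit the neutral model to the bacteria-like table:

```
$ microassembly simulate --seed 7 --out fixtures
$ microassembly ncm --table fixtures/bacteria_counts.tsv
Sloan neutral community model
=============================================
samples                        141
taxa fitted                    300
mean depth N               10000.0
detection limit d         6.93e-05
Nm (dispersal level)        952.27
m  (migration rate)        0.09523
R2                          0.9786
taxa above 95% CI            38.0%
taxa within 95% CI           59.7%
taxa below 95% CI             2.3%
```

The table was generated with migration rate *m* = 0.1 and reads/sample
*N* = 10 000; the fit recovers *m* ≈ 0.095 with R² ≈ 0.98 — occurrence
frequencies of this community are almost fully explained by neutral
dispersal. The stochasticity ratio agrees:

```
$ microassembly nst --table fixtures/fungi_counts.tsv \
      --metadata fixtures/metadata.tsv --n-null 100 --seed 1
{
  "nst_percent": { "arid": 58.3, "humid": 61.0 },
  "class": { "arid": "stochastic-dominated", "humid": "stochastic-dominated" }
}
```

(Within one region the fungi-like community spans only part of the aridity
gradient, so per-region NST sits closer to the boundary than the whole-
gradient contrast.) In the library, a per-region signed network:

```python
import microassembly as ma

mat = ma.read_community_table("fixtures/fungi_counts.tsv")
meta = ma.read_metadata("fixtures/metadata.tsv")
mat, meta = ma.align(mat, meta)
sub = mat.select_samples(meta.index[meta.region == "arid"]).drop_empty_taxa()
net = ma.build_network(sub, prevalence_min=1/3)
rob = ma.robustness(net, removal_fraction=0.5, n_repetitions=100, seed=1)
print(net.n_nodes, net.n_edges, ma.negative_link_proportion(net), rob.mean)
```

prints `49 1022 0.272 0.489`: 49 prevalent taxa, a dense gradient-driven
network with 27 % negative links, and on average 48.9 % of taxa keeping at
least one link when half the nodes are removed.

The full pipeline (diversity → decay → niche → NCM/NST → per-region
networks → drivers) runs from one YAML config:

```
$ microassembly run --config config.yaml --seed 1 --out results
```

writing every table, edge list (TSV + GraphML), a `summary.json`, and a
manifest that reproduces the run exactly.

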