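# phycosphere

Community-assembly analysis for host-associated microbiomes, built around
the question of how algal (or other host) strains assemble their microbiota:
does the host deterministically select *functions* while the *taxa* filling
those functions turn over stochastically?

The package provides, as a tested library plus thin analysis drivers:

- **Sloan neutral community model** — occurrence frequency vs. metacommunity
  relative abundance, `freq(p) = 1 − I_d(Nm·p, Nm·(1−p))` with `I` the
  regularized incomplete beta function; bounded least-squares estimation of
  the dispersal parameter `Nm`, R², taxon-bootstrap 95% CIs, and
  classification of taxa against the Wilson neutral envelope.
- **Co-occurrence networks** — Spearman correlation networks at the
  conventional thresholds (|ρ| ≥ 0.75, P ≤ 0.01), topology metrics
  (average degree 2E/N, density 2E/(N(N−1)), mean local clustering),
  robustness under random removal of half the nodes, vulnerability
  `V_i = (E_glob(G) − E_glob(G−i))/E_glob(G)` with `E_glob` the mean inverse
  shortest-path length, and high-weight (ρ > 0.9) edge extraction with
  family-pair grouping.
- **Permutation statistics** — ANOSIM, one-factor PERMANOVA and Mantel
  tests implemented from their definitions, with exhaustive enumeration for
  small designs and the unbiased p-value convention (1+b)/(1+m).
- **Diversity** — richness, Shannon, Pielou, root-inclusive Faith PD;
  Bray-Curtis and binary Jaccard; classical PCoA with negative eigenvalues
  reported, not silently corrected.
- **Core/accessory/specific partitioning** — exact UpSet-style intersection
  counts and per-group abundance shares under an explicit detection rule.
- **Synthetic-data generators** — a Moran-type neutral assembly simulator
  (the discrete process the Sloan model approximates) and a
  "function-first, taxonomy-stochastic" strain generator in which host
  strains share a deterministic functional-guild filter but recruit taxa
  within guilds by lottery. Both are seeded and give bit-identical output,
  so every analysis stage is testable against known ground truth without
  any sequencing data.

## Worked example

```python
import phycosphere as ph

# neutral assembly: 50 communities of 10,000 individuals, immigration 0.1
meta = ph.sample_metacommunity(n_taxa=500, shape=1.0, seed=0)
cfg = ph.NeutralSimConfig(N=10_000, m=0.1, n_samples=50, seed=1)
table = ph.simulate_local_communities(meta, cfg)
fit = ph.bootstrap_ncm(table, n_boot=1000, seed=2)
print(f"Nm = {fit.Nm:.0f} (95% CI {fit.ci_low:.0f}-{fit.ci_high:.0f}), "
      f"R^2 = {fit.r_squared:.3f}")
```

prints

```
Nm = 1089 (95% CI 1038-1141), R^2 = 0.920
```

i.e. the fit recovers the generator's dispersal parameter (`m·N = 1000`;
the exact stationary concentration of the discrete process is
`m(N−1)/(1−m) ≈ 1111` — see `docs/methods.md`) with a high coefficient of
determination, as expected for data that are neutral by construction.

The strain-level decoupling analysis runs the same way:

```python
ds = ph.generate_redundant_strains(seed=3)          # 6 strains, redundancy 8
groups = ds.metadata["group"].to_dict()
dec = ph.decoupling_analysis(ds.abundance, ds.function_table, groups,
                             n_perm=9999, seed=4)
```

On this dataset the taxonomic and functional views disagree exactly as the
redundancy mechanism predicts: median between-sample Bray-Curtis ≈ 0.74 on
taxa vs ≈ 0.10 on functions, strain separation ANOSIM R = 1.0 on taxa vs
≈ 0.04 on functions, and no significant Mantel correlation between the two
distance matrices (p ≈ 0.2).

## Analysis drivers and CLI

The numbered scripts under `analysis/` run the full study pipeline over
generated data and write tables under `results/`:

```sh
python analysis/01_simulate_communities.py 1   # seed
python analysis/02_diversity_ordination.py
python analysis/03_group_statistics.py 1
python analysis/04_network_stability.py 1
python analysis/05_neutral_model.py 1
python analysis/06_partition_core_taxa.py
python analysis/07_decoupling.py 1
```

The same stages are available on your own TSV tables through the `phycosphere`
command (`simulate`, `diversity`, `ordinate`, `compare`, `decouple`,
`network`, `ncm`, `partition`, and `run` for a YAML-configured full
pipeline).

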