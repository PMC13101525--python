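# Methods

This note documents the models implemented by `phycosphere`, the design
choices that were genuinely open, the synthetic-data generators' assumptions,
and known limitations.

## Neutral community model

### Model and fit

The Sloan formulation treats a focal taxon's relative abundance `x` in a
local community of size `N` as a drift-immigration balance around its
metacommunity relative abundance `p`, with stationary distribution
`Beta(Nm·p, Nm·(1−p))`. A taxon is scored detected when `x` exceeds a
detection limit `d`, so its predicted occurrence frequency across
communities is

    freq(p) = 1 − I_d(Nm·p, Nm·(1−p)),

with `I` the regularized incomplete beta function. `fit_ncm` computes, per
taxon, `p` (mean relative abundance across samples) and the observed
detection frequency (fraction of samples with count > 0), then estimates
`Nm` by bounded nonlinear least squares of predicted against observed
frequencies over taxa (untransformed, unbinned, unweighted). The search
minimizes SSE over `log Nm` with a 25-point log-spaced grid bracketing
followed by bounded scalar refinement (`xatol` 1e−10); bounds are
`Nm ∈ (10⁻³, 10·N]`. Fit quality is `R² = 1 − SS_resid/SS_total` on the
observed frequencies. Taxa never detected are excluded; at least 10
detected taxa are required.

`N` defaults to the mean per-sample total count, which is why relative-
abundance tables are rejected unless `N` is given explicitly — silent
total-sum scaling would destroy the information the model needs.

### Detection limit calibration

The model's sharp threshold at `d` stands in for a smooth sampling process:
with sequencing (or counting) depth `N`, a taxon at relative abundance `x`
is seen at least once with probability `1 − (1−x)^N`. Matching the step
function to this curve at its half-detection point gives

    1 − (1−d)^N = 1/2   ⇒   d = 1 − 2^(−1/N) ≈ ln 2 / N,

which is the package default. The conventional `d = 1/N` sits where the
true detection probability is already ≈ 0.63, and least-squares fits with
it systematically inflate `Nm` on count data (≈ +29% in noise-free
asymptotics at `N = 10⁴` with a 500-taxon lognormal metacommunity; the
ln 2 calibration reduces the asymptotic discrepancy to ≈ +3%). `d` remains
an explicit override for users who want the `1/N` convention, and every fit
records the `N` and `d` actually used.

### Bootstrap and envelope

Confidence intervals for `Nm` resample taxa — the regression's observation
units — with replacement (default 1,000 replicates) and take the 2.5/97.5
percentiles of the refitted estimates. The per-taxon neutral envelope is
the Wilson score interval at level `1−α` (default 95%) around the predicted
frequency given the number of samples; taxa are classified above / within /
below by where their observed frequency falls. Taxa with observed frequency
exactly 1 are classified "above" whenever the envelope's upper bound is
below 1, which is the standard behavior of envelope plots at saturation.

## Moran neutral simulator

`simulate_local_communities` realizes the discrete process the Sloan model
approximates. Each sample is an independent chain: the community starts as
`N` i.i.d. draws from the metacommunity, then undergoes `burn_in`
replacement events. Per event one uniformly chosen individual dies; with
probability `m` it is replaced by a metacommunity draw, otherwise by a copy
of a uniformly chosen surviving individual. Counts are recorded after the
burn-in; rows always sum to `N` exactly. The event loop is a numba kernel
fed with pre-generated random streams (immigrant identities are drawn only
for immigration events), and a pure-python mirror of the kernel is kept for
cross-checking; all randomness flows through a seeded generator, so output
is bit-identical per seed.

Two facts about this process matter for interpreting fits:

- **Exact stationary law.** With parent-independent immigration the
  stationary distribution of the counts is Dirichlet-multinomial with
  concentration `I = m(N−1)/(1−m)`; equivalently the latent frequency of a
  taxon is exactly `Beta(I·p, I·(1−p))`. `I → Nm` only in the small-`m`
  diffusion limit: at `m = 0.1` the exact concentration is ≈ 11% above
  `m·N`. A well-behaved estimator therefore converges on `I`, not on
  `m·N`, and narrow bootstrap intervals (±4–5% with 500 taxa) will often
  exclude the nominal product `m·N` while covering `I`'s fitted image.
  `effective_dispersal(N, m)` exposes the exact value. This is a property
  of the process, not an estimator defect; recovery experiments should
  compare against it when `m` is not small.
- **Burn-in.** The chain forgets its initial condition at rate ≈ `m` per
  generation (`N` events). The default `burn_in = 50·N` events (≈ 50
  generations) is ample for `m ≳ 0.1`; for smaller `m` scale it like
  `≈ 5·N/m` events. Recovery experiments in the test suite use that rule at
  `m = 0.01`.

Measured behavior (package's own experiments, seeded): at `N = 10⁴`,
`m = 0.1`, 500-taxon lognormal metacommunity, 50 samples, the fitted `Nm`
lands within ±15% of `m·N = 1000` in 20/20 seeds (the ln 2 calibration and
the `I > m·N` offset partially cancel), with `R² ≈ 0.92–0.94`.

## Function-first strain generator

`generate_redundant_strains` produces the "deterministic functions,
stochastic taxa" structure:

- **Host filter (deterministic).** One lognormal profile over `n_guilds`
  functional guilds (σ = `guild_shape`, default 1.0), shared by every
  strain. Guild function profiles are binary: guild *g* emits function
  *F_g* with weight 1 — the simplest mapping that produces the decoupling
  signal; the `GuildMap` type supports arbitrary weight profiles.
- **Taxon lottery (stochastic).** Each guild has `redundancy` candidate
  taxa. Every candidate carries a colonization propensity drawn once from
  `Beta(colonization_a, colonization_b)` (defaults 0.7, 0.9) and shared
  across strains, so some taxa are near-cosmopolitan (the core) and others
  sporadic. Each strain recruits each candidate independently with that
  probability — at least one per guild, so the functional filter is always
  satisfied — and weights recruits by `Gamma(lottery_alpha)` draws
  (default 0.5). Strains thus agree at the guild level while differing in
  which taxa carry each guild.
- **Per-sample noise.** Two independent lognormal processes: within-guild
  compositional jitter (σ = `noise_sigma`, default 0.9), renormalized
  inside each guild so it reshuffles taxa without moving guild totals; and
  per-taxon functional-rate fluctuations (σ = `rate_sigma`, default 0.25)
  whose lottery-weighted mean scales each guild's total. Because a guild's
  rate is an average over its recruited taxa, guild totals become more
  stable as realized redundancy grows — the portfolio (insurance) effect
  that makes between-strain functional distance non-increasing in
  redundancy. Counts are multinomial-resampled at `depth` (default 10,000),
  emulating sequencing-depth sampling.
- **Defaults as study conditions.** 6 strains × 12 samples (4 timepoints ×
  3 replicates), 40 guilds × redundancy 8 = 320 taxa, depth 10,000. The
  noise scales are set so the generator sits firmly in the regime the
  design encodes — functional variation much smaller than taxonomic
  variation and statistically independent of it. With them the default
  datasets show: median between-sample Bray-Curtis ≈ 0.73 on taxa vs
  ≈ 0.10 on functions; strain separation ANOSIM R ≈ 1.0 on taxa vs ≈ 0.04
  on functions; Mantel correlation between the two distance matrices
  non-significant; ≈ 10–15% of detected taxa core (present in all six
  strains, ≈ 20–30% of community abundance) and a few percent
  strain-specific at low abundance.

The function table is always the exact linear aggregation
`abundance @ W` of the realized counts (`attach_functions`), so functional
noise can never be fully independent of taxonomic noise — they share the
multinomial sampling layer and the guild-total fluctuations. The defaults
keep that shared component small relative to the lottery-plus-jitter
taxonomic signal; pushing `rate_sigma` up (or `depth` far down) moves the
generator out of the decoupled regime.

What the generator does **not** emulate: temporal dynamics (timepoints are
labels, not a succession process), covariance between taxa within a sample
beyond compositional constraints, taxon-specific detection bias, chimeras
or any sequence-level artifact. In particular, because samples are
conditionally independent given their strain, within-strain co-occurrence
networks built from these data are sparse and fragmented — there is no
engineered correlation structure for the network stage to find — so
network stability values on synthetic data are far below those of real
successional communities. Passing network tests therefore certify the
metrics (verified against closed forms, exhaustive enumeration and an
independent graph library), not any claim about realistic network topology.

## Diversity, ordination and permutation statistics

- Shannon uses natural logs; Pielou is `H/ln(richness)` with the
  convention 0 when richness < 2. Faith PD is root-inclusive (the path
  from each present leaf to the root is counted), matching the dominant
  amplicon-toolchain convention; a single-node tree contributes its own
  branch length.
- Bray-Curtis is abundance-based; Jaccard is computed on presence/absence
  (no abundance qualifier). A pair of all-zero samples has distance 0 with
  a logged warning. Tables are total-sum scaled before diversity and
  distance computation in the pipeline (explicit, configurable transform;
  never applied implicitly on read).
- PCoA Gower-centers `−d²/2` and eigendecomposes; axes are scaled by
  `√λ`, ordered by descending eigenvalue; negative eigenvalues are
  reported and their axes dropped, with no Cailliez/Lingoes correction —
  transparency over silent repair. Proportions explained are over the
  positive spectrum.
- ANOSIM ranks the off-diagonal distances with average ranks on ties;
  PERMANOVA is the one-factor pseudo-F with `SS_total = Σ d²/n`; both
  permute sample labels jointly over rows and columns. Mantel correlates
  off-diagonal vectors (Pearson or Spearman) under simultaneous
  row/column permutation of the second matrix, two-sided on |r|.
  Monte-Carlo p-values use `(1+b)/(1+m)` and can never be 0; when the
  number of distinct label arrangements is enumerable (n ≤ 10 and
  requested permutations cover it, or `n_perm="exact"`), the null is
  enumerated and the p-value is the exact tail fraction including the
  observed arrangement. Permutation counts default to 9,999.

## Co-occurrence networks

Taxa below a prevalence floor are dropped before correlation; constant
taxa are excluded with a warning and can never form edges. Spearman
p-values use the t-approximation, switching to exact permutation
enumeration below 10 samples where the approximation is poor. Edges
require `|ρ| ≥ r_threshold` (default 0.75) and `p ≤ p_threshold` (default
0.01); the sign is kept as an attribute and reports carry the
positive-edge fraction, so claims about positive-correlation dominance can
be checked rather than assumed. Correlation p-values are not
multiple-testing corrected by default (the thresholds are conventionally
applied raw); a BH option is available on the pipeline config.

Robustness is the mean, over seeded repetitions (default 100), of the
largest-connected-component fraction among survivors after removing
`⌊f·N⌋` uniformly chosen nodes (default f = 0.5). Isolated survivors count
as size-1 components; an edgeless graph therefore scores `1/survivors`,
not 0. Vulnerability uses global efficiency (mean inverse shortest-path
length over unordered pairs, 0 for disconnected pairs):
`V_i = (E_glob(G) − E_glob(G−i))/E_glob(G)`; `V_i` can be negative for
structurally redundant nodes, and the network's vulnerability is the
maximum. An edgeless graph has vulnerability 0 by convention (warned).

## Pipeline

`run_pipeline` executes configured stages in dependency order from a
single YAML-able config holding either input paths or generator
parameters (exactly one). Each stage's seed is derived as
`global_seed XOR sha256(stage_name)[:4] mod 2³¹−1`, so adding or removing
a stage never perturbs another stage's randomness, and the whole report is
bit-identical per config + seed. The report echoes every default actually
used (normalization, `N`, `d`, permutation counts) so unstated conventions
are auditable. The neutral-model stage fits the pooled sample set by
default with an option for per-group fits; which samples enter the fit is
a genuine analysis choice the config makes explicit. Group "presence" for
partitioning defaults to count > 0 in ≥ 1 sample of the group, pooling
replicates and timepoints; the threshold is configurable. Per-group
abundance shares are computed from group-mean relative abundances over
detected taxa, with taxa specific to *other* groups counted in the
accessory share so each group's three shares sum to 100%.

## Known limitations

- One-factor designs only for PERMANOVA/ANOSIM; no pairwise post-hoc
  tests, PERMDISP, or multi-factor models.
- The Mantel null permutes one matrix's rows/columns, which assumes
  exchangeable samples; block structure (e.g. repeated timepoints) is not
  accounted for.
- Vulnerability is O(N · BFS) per node and intended for networks up to a
  few hundred nodes.
- The exact-stationary discrepancy between `I` and `m·N` means bootstrap
  CIs from well-specified fits will not cover `m·N` at moderate `m`;
  compare against `effective_dispersal(N, m)` instead.
- No UniFrac, rarefaction curves, differential-abundance testing, or
  figure rendering; exports are TSV/JSON for external plotting.
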