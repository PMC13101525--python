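"""Synthetic community generator.

Two generators provide ground truth for the downstream analyses:

* :func:`simulate_local_communities` — a Moran-type neutral assembly
  process: local communities of fixed size N evolve by single-individual
  death events; the replacement comes from the regional metacommunity with
  probability m (immigration) and otherwise copies a uniformly chosen
  surviving local individual (drift). This is the discrete process whose
  drift-immigration balance the Sloan model approximates, so fitted Nm can
  be compared against the generator's parameters.

* :func:`generate_redundant_strains` — "function-first, taxonomy-
  stochastic" communities: every host strain imposes the same deterministic
  functional-guild composition, but within each guild the taxa that realize
  the function are drawn by a per-strain lottery. With high within-guild
  redundancy, strains diverge taxonomically while converging functionally —
  the decoupling signature the statistical stages are asked to detect.

All randomness flows through numpy Generators seeded explicitly; identical
seeds give bit-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .io import AbundanceTable, write_abundance_table, write_metadata


@dataclass
class Metacommunity:
    """Regional source pool: taxon ids and their relative abundances."""

    taxon_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if len(self.taxon_ids) != len(set(self.taxon_ids)):
            raise ValueError("duplicate taxon ids")
        if np.any(self.p <= 0):
            raise ValueError("metacommunity abundances must be positive")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("metacommunity abundances must sum to 1")


@dataclass
class NeutralSimConfig:
    """Parameters of the Moran neutral simulation.

    burn_in defaults to 50*N replacement events (about 50 generations),
    empirically sufficient for stationarity at moderate immigration; low-m
    runs should scale it like ~5N/m events (see docs/methods.md).
    """

    N: int
    m: float
    n_samples: int
    burn_in: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 < self.m <= 1:
            raise ValueError("m must lie in (0, 1]; m = 0 never equilibrates")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.burn_in is None:
            self.burn_in = 50 * self.N


@dataclass
class GuildMap:
    """taxon -> guild assignment and guild -> function weight profiles."""

    guild_of: dict[str, str]
    functions_of: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for g, funcs in self.functions_of.items():
            if not funcs:
                raise ValueError(f"guild {g!r} has no function weights")
        missing = {g for g in self.guild_of.values()} - set(self.functions_of)
        if missing:
            raise ValueError(f"guilds without function profiles: {sorted(missing)}")

    def redundancy(self, guild: str) -> int:
        return sum(1 for g in self.guild_of.values() if g == guild)

    def weight_matrix(self, taxon_ids, function_ids=None) -> pd.DataFrame:
        """Taxon x function weight matrix W (function table = abundance @ W)."""
        if function_ids is None:
            function_ids = sorted({f for fw in self.functions_of.values() for f in fw})
        w = pd.DataFrame(0.0, index=list(taxon_ids), columns=list(function_ids))
        for t in taxon_ids:
            if t not in self.guild_of:
                raise KeyError(f"taxon not in guild map: {t!r}")
            for f, wt in self.functions_of[self.guild_of[t]].items():
                w.loc[t, f] = wt
        return w


@dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth that produced them."""

    abundance: AbundanceTable
    function_table: AbundanceTable
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_abundance_table(self.abundance, outdir / "abundance.tsv")
        write_abundance_table(self.function_table, outdir / "functions.tsv")
        write_metadata(self.metadata, outdir / "metadata.tsv")
        truth = {k: v for k, v in self.truth.items() if k != "guild_map"}
        if "guild_map" in self.truth:
            gm = self.truth["guild_map"]
            truth["guild_of"] = gm.guild_of
            truth["functions_of"] = gm.functions_of
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, default=str) + "\n")


def sample_metacommunity(
    n_taxa: int, shape: float = 1.0, seed: int = 0
) -> Metacommunity:
    """Lognormal species-abundance metacommunity, sorted most-abundant first.

    ``shape`` is the lognormal sigma; larger values give stronger dominance
    (lower evenness).
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if shape <= 0:
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)
    raw = np.sort(rng.lognormal(mean=0.0, sigma=shape, size=n_taxa))[::-1]
    p = raw / raw.sum()
    width = len(str(n_taxa))
    ids = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    return Metacommunity(taxon_ids=ids, p=p)


@njit(cache=True)
def _moran_kernel(community, deaths, is_imm, imm_draws, copy_offsets, counts):
    """Sequential Moran events on an individual-label array.

    community[i] holds the taxon index of individual i. At event t,
    individual deaths[t] dies; if is_imm[t] it is replaced by the
    pre-drawn metacommunity immigrant imm_draws[t], otherwise by a copy of
    a surviving individual chosen via copy_offsets[t] (offset skips the
    dying slot). Final counts are accumulated into ``counts``.
    """
    n = community.shape[0]
    for t in range(deaths.shape[0]):
        i = deaths[t]
        if is_imm[t]:
            community[i] = imm_draws[t]
        else:
            j = copy_offsets[t]
            if j >= i:
                j += 1
            community[i] = community[j]
    for i in range(n):
        counts[community[i]] += 1


def _moran_python(community, deaths, is_imm, imm_draws, copy_offsets, counts):
    """Pure-python mirror of the kernel (cross-check oracle for tests)."""
    n = community.shape[0]
    for t in range(deaths.shape[0]):
        i = deaths[t]
        if is_imm[t]:
            community[i] = imm_draws[t]
        else:
            j = copy_offsets[t]
            if j >= i:
                j += 1
            community[i] = community[j]
    for i in range(n):
        counts[community[i]] += 1


def simulate_local_communities(
    meta: Metacommunity, cfg: NeutralSimConfig, _kernel=None
) -> AbundanceTable:
    """Simulate independent local communities under neutral assembly.

    Each sample starts as N independent draws from the metacommunity and
    undergoes cfg.burn_in Moran replacement events before its counts are
    recorded; every row therefore sums to N exactly.
    """
    kernel = _kernel or _moran_kernel
    rng = np.random.default_rng(cfg.seed)
    cum = np.cumsum(meta.p)
    cum[-1] = 1.0
    s = len(meta.p)
    n, burn = cfg.N, int(cfg.burn_in)
    table = np.zeros((cfg.n_samples, s), dtype=np.int64)
    for k in range(cfg.n_samples):
        community = np.searchsorted(cum, rng.random(n)).astype(np.int64)
        deaths = rng.integers(0, n, size=burn)
        is_imm = rng.random(burn) < cfg.m
        # immigrant identities are only drawn for immigration events
        imm_draws = np.zeros(burn, dtype=np.int64)
        imm_idx = np.flatnonzero(is_imm)
        imm_draws[imm_idx] = np.searchsorted(cum, rng.random(len(imm_idx)))
        copy_offsets = (
            rng.integers(0, n - 1, size=burn) if n > 1
            else np.zeros(burn, dtype=np.int64)
        )
        kernel(community, deaths, is_imm, imm_draws, copy_offsets, table[k])
    ids = [f"s{k + 1:03d}" for k in range(cfg.n_samples)]
    return AbundanceTable(pd.DataFrame(table, index=ids, columns=meta.taxon_ids))


def attach_functions(table: AbundanceTable, guilds: GuildMap) -> AbundanceTable:
    """Aggregate a taxon table to a function table via the guild map.

    Function abundance of a sample is the weight-matrix product of its
    taxon abundances; unmapped taxa are an error.
    """
    unmapped = [t for t in table.taxon_ids if t not in guilds.guild_of]
    if unmapped:
        raise KeyError(f"taxa missing from guild map: {unmapped}")
    w = guilds.weight_matrix(table.taxon_ids)
    func = table.data @ w
    return AbundanceTable(func)


def generate_redundant_strains(
    n_strains: int = 6,
    n_guilds: int = 40,
    redundancy: int = 8,
    samples_per_strain: int = 12,
    n_timepoints: int = 4,
    depth: int = 10_000,
    guild_shape: float = 1.0,
    lottery_alpha: float = 0.5,
    colonization_a: float = 0.7,
    colonization_b: float = 0.9,
    noise_sigma: float = 0.9,
    rate_sigma: float = 0.25,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate strain communities with deterministic functional filtering
    and stochastic taxon identity.

    Every strain receives the same guild-level target composition (a
    lognormal profile over guilds — the deterministic host filter). Within
    each guild of ``redundancy`` candidate taxa, each strain runs a taxon
    lottery: every candidate taxon carries a colonization propensity
    (Beta(colonization_a, colonization_b), shared across strains, so some
    taxa are near-cosmopolitan and others sporadic); the strain recruits
    each candidate independently with that probability (at least one per
    guild, so the functional filter is always satisfied) and weights the
    recruits by Gamma(lottery_alpha) draws. Strains therefore share a core
    of high-propensity taxa, differ in which mid-propensity taxa they
    recruit (accessory/specific taxa), yet realize identical guild-level
    composition. Guild function profiles are binary (one function per
    guild, weight 1).

    Each sample then receives two independent lognormal noise processes:

    * within-guild compositional jitter (sigma ``noise_sigma``) —
      per-taxon fluctuations renormalized inside each guild, so they
      shuffle which taxa carry a guild without moving the guild total
      (taxonomic noise);
    * per-taxon functional-rate fluctuations (sigma ``rate_sigma``) —
      each candidate taxon's realized contribution rate varies; a guild's
      total activity is the lottery-weighted mean of its members' rates,
      so guilds realized by more (more evenly weighted) taxa average the
      fluctuation away — a portfolio effect that makes function profiles
      more stable as redundancy rises while leaving taxonomic turnover
      untouched. Functional fluctuations are kept smaller than
      compositional ones (the study regime: conserved function, volatile
      taxonomy), so the guild-level component they share with the taxon
      table is negligible against the compositional signal.

    Finally counts are multinomial-resampled at ``depth`` (sequencing-depth
    sampling). Because the two noise processes are independent,
    between-sample functional distances carry no information about
    taxonomic distances beyond the shared sampling noise — taxonomically
    divergent, functionally convergent communities by construction.
    """
    for name, v in (("n_strains", n_strains), ("n_guilds", n_guilds),
                    ("redundancy", redundancy),
                    ("samples_per_strain", samples_per_strain)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    if samples_per_strain % n_timepoints:
        n_timepoints = 1
    rng = np.random.default_rng(seed)
    n_taxa = n_guilds * redundancy
    tw = len(str(n_taxa))
    taxa = [f"t{i + 1:0{tw}d}" for i in range(n_taxa)]
    guilds = [f"G{g + 1:03d}" for g in range(n_guilds)]
    guild_of = {taxa[g * redundancy + j]: guilds[g]
                for g in range(n_guilds) for j in range(redundancy)}
    functions_of = {g: {f"F{g[1:]}": 1.0} for g in guilds}
    gmap = GuildMap(guild_of=guild_of, functions_of=functions_of)

    # deterministic host filter: one guild profile shared by all strains
    gw = rng.lognormal(0.0, guild_shape, n_guilds)
    gw /= gw.sum()

    # taxon lottery: colonization mask + Gamma weights within each guild
    propensity = rng.beta(colonization_a, colonization_b,
                          (n_guilds, redundancy))
    lottery = np.zeros((n_strains, n_guilds, redundancy))
    for s in range(n_strains):
        for g in range(n_guilds):
            mask = rng.random(redundancy) < propensity[g]
            if not mask.any():
                mask[rng.integers(redundancy)] = True
            w = rng.gamma(lottery_alpha, 1.0, redundancy) * mask
            lottery[s, g] = w / w.sum()

    strains = [f"strain{s + 1}" for s in range(n_strains)]
    reps_per_tp = samples_per_strain // n_timepoints
    rows, meta_rows, ids = [], [], []
    for s, strain in enumerate(strains):
        for k in range(samples_per_strain):
            tp = k // reps_per_tp + 1
            rep = k % reps_per_tp + 1
            # taxonomic noise: jitter within-guild composition, guild-sum
            # preserving
            comp = lottery[s] * rng.lognormal(0.0, noise_sigma,
                                              (n_guilds, redundancy))
            comp /= comp.sum(axis=1, keepdims=True)
            # functional-rate noise: lottery-weighted mean of independent
            # per-taxon rate fluctuations (portfolio effect in redundancy)
            rates = rng.lognormal(0.0, rate_sigma, (n_guilds, redundancy))
            guild_totals = gw * (lottery[s] * rates).sum(axis=1)
            prof = (guild_totals[:, None] * comp).ravel()
            prof /= prof.sum()
            rows.append(rng.multinomial(depth, prof))
            ids.append(f"{strain}_T{tp}_R{rep}")
            meta_rows.append({"group": strain, "timepoint": f"T{tp}",
                              "replicate": f"R{rep}"})
    abundance = AbundanceTable(pd.DataFrame(np.array(rows), index=ids, columns=taxa))
    function_table = attach_functions(abundance, gmap)
    metadata = pd.DataFrame(meta_rows, index=ids)
    truth = {
        "m": None, "N": depth, "guild_map": gmap, "seed": seed,
        "n_strains": n_strains, "n_guilds": n_guilds,
        "redundancy": redundancy, "samples_per_strain": samples_per_strain,
        "n_timepoints": n_timepoints, "guild_shape": guild_shape,
        "lottery_alpha": lottery_alpha, "noise_sigma": noise_sigma,
        "rate_sigma": rate_sigma,
        "colonization_a": colonization_a, "colonization_b": colonization_b,
        "guild_weights": gw.tolist(),
    }
    return SyntheticDataset(abundance=abundance, function_table=function_table,
                            metadata=metadata, truth=truth)


def effective_dispersal(N: int, m: float) -> float:
    """Exact stationary concentration of the Moran immigration process.

    The stationary distribution of local counts is Dirichlet-multinomial
    with concentration I = m(N-1)/(1-m) (equal to Nm in the small-m,
    large-N diffusion limit that the Sloan model assumes).
    """
    if m >= 1.0:
        return float("inf")
    return m * (N - 1) / (1.0 - m)
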