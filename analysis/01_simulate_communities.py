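"""Generate the synthetic datasets every downstream analysis consumes.

Two artifacts are written under results/data/:

* ``neutral/`` — 50 local communities of 10,000 individuals assembled from
  a 500-taxon lognormal metacommunity under Moran drift-immigration
  dynamics (m = 0.1), the input for the neutral-model fit;
* ``strains/`` — six host strains sharing one functional-guild filter with
  within-guild redundancy 8 (12 samples each: 4 timepoints x 3
  replicates), the input for diversity, network, decoupling and
  partitioning analyses.
"""

import sys
from pathlib import Path

from phycosphere.synthetic import (
    NeutralSimConfig,
    generate_redundant_strains,
    sample_metacommunity,
    simulate_local_communities,
)
from phycosphere.io import write_abundance_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    neutral_dir = OUT / "neutral"
    neutral_dir.mkdir(parents=True, exist_ok=True)
    meta = sample_metacommunity(500, shape=1.0, seed=SEED)
    cfg = NeutralSimConfig(N=10_000, m=0.1, n_samples=50, seed=SEED + 1)
    table = simulate_local_communities(meta, cfg)
    write_abundance_table(table, neutral_dir / "abundance.tsv")
    print(f"neutral: {table.n_samples} samples x {table.n_taxa} taxa, "
          f"depth {int(table.values.sum(axis=1)[0])}, true Nm = "
          f"{cfg.m * cfg.N:.0f} -> {neutral_dir}")

    ds = generate_redundant_strains(seed=SEED + 2)
    ds.write(OUT / "strains")
    n_strains = ds.metadata["group"].nunique()
    print(f"strains: {n_strains} strains, {ds.abundance.n_samples} samples x "
          f"{ds.abundance.n_taxa} taxa, {ds.function_table.n_taxa} functions, "
          f"redundancy {ds.truth['redundancy']} -> {OUT / 'strains'}")


if __name__ == "__main__":
    main()
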