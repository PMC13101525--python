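"""ANOSIM and PERMANOVA between strains on taxonomic composition.

Quantifies how strongly strain identity structures the communities in both
Bray-Curtis (abundance) and Jaccard (membership) space; writes
results/stats/group_comparisons.json.
"""

import sys
from pathlib import Path

from phycosphere.diversity import beta_diversity
from phycosphere.io import read_abundance_table, read_metadata, to_relative, write_json
from phycosphere.multivariate import anosim, permanova

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    table = to_relative(read_abundance_table(ROOT / "data/strains/abundance.tsv"))
    groups = read_metadata(ROOT / "data/strains/metadata.tsv")["group"].to_dict()
    out = ROOT / "stats"
    out.mkdir(parents=True, exist_ok=True)

    results = {}
    for metric in ("bray_curtis", "jaccard"):
        dm = beta_diversity(table, metric)
        a = anosim(dm, groups, n_perm=9999, seed=SEED)
        p = permanova(dm, groups, n_perm=9999, seed=SEED)
        results[metric] = {"anosim": a.to_dict(), "permanova": p.to_dict()}
        print(f"{metric}: ANOSIM R = {a.statistic:.3f} (P = {a.p_value:.4f}); "
              f"PERMANOVA R^2 = {p.r_squared:.3f}, F = {p.statistic:.2f} "
              f"(P = {p.p_value:.4f})")
    write_json(results, out / "group_comparisons.json")


if __name__ == "__main__":
    main()
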