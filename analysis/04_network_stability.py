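"""Per-strain Spearman co-occurrence networks and stability metrics.

For each strain's 12 samples, builds the |rho| >= 0.75, P <= 0.01 network
over taxa detected in at least a third of the strain's samples, then
computes topology (degree, density, clustering), robustness to random
removal of half the nodes (100 repetitions), vulnerability (maximal
relative drop in global efficiency), the positive-edge fraction, and the
count of high-weight (rho > 0.9) edges. Writes edge lists and a summary
table under results/network/.
"""

import sys
from pathlib import Path

import pandas as pd

from phycosphere.io import (
    AbundanceTable, read_abundance_table, read_metadata, write_edge_list,
)
from phycosphere.network import (
    correlation_network, high_weight_edges, network_metrics,
    robustness, vulnerability,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    table = read_abundance_table(ROOT / "data/strains/abundance.tsv")
    metadata = read_metadata(ROOT / "data/strains/metadata.tsv")
    out = ROOT / "network"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for strain, samples in metadata.groupby("group").groups.items():
        sub = AbundanceTable(table.data.loc[list(samples)])
        net = correlation_network(sub, r_threshold=0.75, p_threshold=0.01,
                                  min_prevalence=1 / 3)
        write_edge_list(net, out / f"edges_{strain}.tsv")
        row = {"strain": strain, **network_metrics(net)}
        row["positive_edge_fraction"] = net.positive_edge_fraction()
        if net.n_edges:
            row["robustness"] = robustness(net, 0.5, n_reps=100, seed=SEED)
            vul = vulnerability(net)
            row["global_efficiency"] = vul["global_efficiency"]
            row["vulnerability"] = vul["vulnerability"]
        hw, _ = high_weight_edges(net, 0.9)
        row["n_high_weight_edges"] = len(hw)
        rows.append(row)

    summary = pd.DataFrame(rows).set_index("strain")
    summary.to_csv(out / "network_summary.tsv", sep="\t")
    print(summary.round(3).to_string())
    if "robustness" in summary:
        print(f"\nrobustness range {summary['robustness'].min():.2f}-"
              f"{summary['robustness'].max():.2f}; vulnerability range "
              f"{summary['vulnerability'].min():.3f}-"
              f"{summary['vulnerability'].max():.3f}")


if __name__ == "__main__":
    main()
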