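"""Alpha diversity and PCoA ordination of the strain communities.

Reads results/data/strains/, writes per-sample alpha diversity and
Bray-Curtis / Jaccard PCoA coordinates under results/diversity/, and
reports whether strains differ more in membership than in evenness.
"""

from pathlib import Path

import pandas as pd

from phycosphere.diversity import alpha_diversity, beta_diversity, pcoa
from phycosphere.io import read_abundance_table, read_metadata, to_relative

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = to_relative(read_abundance_table(ROOT / "data/strains/abundance.tsv"))
    metadata = read_metadata(ROOT / "data/strains/metadata.tsv")
    out = ROOT / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    alpha = alpha_diversity(table)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    by_strain = alpha.join(metadata["group"]).groupby("group").mean()
    print("mean alpha diversity per strain:")
    print(by_strain.round(3).to_string(), "\n")

    for metric in ("bray_curtis", "jaccard"):
        dm = beta_diversity(table, metric)
        ord_ = pcoa(dm)
        ord_.coordinates.to_csv(out / f"pcoa_{metric}.tsv", sep="\t")
        pd.DataFrame({
            "eigenvalue": ord_.eigenvalues,
            "proportion_explained": ord_.proportion_explained,
        }).to_csv(out / f"pcoa_{metric}_eigen.tsv", sep="\t", index=False)
        print(f"PCoA ({metric}): first two axes explain "
              f"{100 * ord_.proportion_explained[:2].sum():.1f}% "
              f"({ord_.negative_eigenvalues.size} negative eigenvalues dropped)")


if __name__ == "__main__":
    main()
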