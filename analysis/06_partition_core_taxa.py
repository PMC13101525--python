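"""Core / accessory / strain-specific partitioning of the strain dataset.

Counts taxa present in all six strains (core), in a strict subset
(accessory) or in exactly one strain (specific), their UpSet-style
intersection counts, and each class's share of community abundance.
Writes results/partition/.
"""

from pathlib import Path

from phycosphere.io import read_abundance_table, read_metadata, write_json
from phycosphere.partition import intersection_frame, partition_taxa

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_abundance_table(ROOT / "data/strains/abundance.tsv")
    groups = read_metadata(ROOT / "data/strains/metadata.tsv")["group"].to_dict()
    out = ROOT / "partition"
    out.mkdir(parents=True, exist_ok=True)

    part = partition_taxa(table, groups, min_samples=1)
    part.to_frame().to_csv(out / "taxon_partition.tsv", sep="\t", index=False)
    intersection_frame(part.intersection_counts).to_csv(
        out / "intersection_counts.tsv", sep="\t", index=False)
    write_json({"n_core": len(part.core),
                "n_accessory": len(part.accessory),
                "n_specific": {g: len(s) for g, s in part.specific.items()},
                "abundance_share": part.abundance_share},
               out / "summary.json")

    n_spec = sum(len(s) for s in part.specific.values())
    print(f"detected taxa: {len(part.detected)}; core: {len(part.core)}; "
          f"accessory: {len(part.accessory)}; strain-specific: {n_spec}")
    core_pct = [s["core_pct"] for s in part.abundance_share.values()]
    spec_pct = [s["specific_pct"] for s in part.abundance_share.values()]
    print(f"core abundance share per strain: "
          f"{min(core_pct):.1f}%-{max(core_pct):.1f}%; "
          f"specific share: {min(spec_pct):.1f}%-{max(spec_pct):.1f}%")


if __name__ == "__main__":
    main()
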