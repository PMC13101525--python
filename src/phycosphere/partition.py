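"""Core / accessory / group-specific taxon partitioning and UpSet-style
intersection counts.

A taxon is "present in group g" when it passes the detection rule (count
> 0 in at least k samples of the group, k = 1 by default, pooling
replicates and timepoints). Core taxa are present in all groups, specific
taxa in exactly one, accessory taxa in more than one but not all; the three
sets partition the detected taxa. Abundance shares per group use group-mean
relative abundances so results are in "% of each community" terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceTable, to_relative


@dataclass
class TaxonPartition:
    core: set[str]
    accessory: set[str]
    specific: dict[str, set[str]]
    presence_sets: dict[str, frozenset[str]]
    intersection_counts: dict[frozenset, int]
    abundance_share: dict[str, dict[str, float]]

    @property
    def detected(self) -> set[str]:
        return set(self.presence_sets)

    def to_frame(self) -> pd.DataFrame:
        """Per-taxon class and presence-set table (UpSet-compatible)."""
        rows = []
        spec_of = {t: g for g, ts in self.specific.items() for t in ts}
        for t in sorted(self.detected):
            if t in self.core:
                cls = "core"
            elif t in self.accessory:
                cls = "accessory"
            else:
                cls = f"specific:{spec_of[t]}"
            rows.append({"taxon": t, "class": cls,
                         "presence_set": "&".join(sorted(self.presence_sets[t]))})
        return pd.DataFrame(rows, columns=["taxon", "class", "presence_set"])


def _presence_sets(
    table: AbundanceTable, groups, min_samples: int
) -> tuple[dict[str, frozenset[str]], list[str]]:
    labels = np.asarray([groups[s] for s in table.sample_ids])
    group_names = sorted(set(labels))
    x = table.values > 0
    taxa = np.asarray(table.taxon_ids)
    present_in = {}
    for g in group_names:
        rows = labels == g
        if not rows.any():
            raise ValueError(f"empty group {g!r}")
        present_in[g] = x[rows].sum(axis=0) >= min_samples
    sets: dict[str, frozenset[str]] = {}
    for j, t in enumerate(taxa):
        s = frozenset(g for g in group_names if present_in[g][j])
        if s:
            sets[str(t)] = s
    return sets, group_names


def partition_taxa(
    table: AbundanceTable, groups, min_samples: int = 1
) -> TaxonPartition:
    """Partition detected taxa into core / accessory / group-specific sets.

    ``groups`` maps sample id -> group label; ``min_samples`` is the
    detection rule (count > 0 in at least that many samples of a group).
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    sets, group_names = _presence_sets(table, groups, min_samples)
    all_groups = frozenset(group_names)
    core = {t for t, s in sets.items() if s == all_groups}
    specific = {g: set() for g in group_names}
    for t, s in sets.items():
        if len(s) == 1 and s != all_groups:
            specific[next(iter(s))].add(t)
    spec_union = set().union(*specific.values()) if specific else set()
    accessory = set(sets) - core - spec_union

    counts: dict[frozenset, int] = {}
    for s in sets.values():
        counts[s] = counts.get(s, 0) + 1

    rel = to_relative(table)
    labels = np.asarray([groups[s] for s in table.sample_ids])
    taxa = np.asarray(table.taxon_ids)
    share: dict[str, dict[str, float]] = {}
    in_core = np.isin(taxa, list(core))
    in_acc = np.isin(taxa, list(accessory))
    for g in group_names:
        mean_rel = rel.values[labels == g].mean(axis=0)
        in_spec = np.isin(taxa, list(specific[g]))
        detected_mask = np.isin(taxa, list(sets))
        total = mean_rel[detected_mask].sum()
        if total == 0:
            share[g] = {"core_pct": 0.0, "accessory_pct": 0.0, "specific_pct": 0.0}
            continue
        other_spec = np.isin(taxa, list(spec_union - specific[g]))
        share[g] = {
            "core_pct": 100.0 * mean_rel[in_core].sum() / total,
            "accessory_pct": 100.0 * (mean_rel[in_acc].sum()
                                      + mean_rel[other_spec].sum()) / total,
            "specific_pct": 100.0 * mean_rel[in_spec].sum() / total,
        }
    return TaxonPartition(
        core=core, accessory=accessory, specific=specific,
        presence_sets=sets, intersection_counts=counts, abundance_share=share,
    )


def intersection_counts(
    table: AbundanceTable, groups, min_samples: int = 1
) -> dict[frozenset, int]:
    """Exact UpSet counts: for each non-empty group subset S, the number of
    taxa whose presence-set equals S; counts sum to the detected total."""
    sets, _ = _presence_sets(table, groups, min_samples)
    counts: dict[frozenset, int] = {}
    for s in sets.values():
        counts[s] = counts.get(s, 0) + 1
    return counts


def intersection_frame(counts: dict[frozenset, int]) -> pd.DataFrame:
    """UpSet-compatible TSV layout: one row per subset, groups joined by &."""
    rows = [
        {"groups": "&".join(sorted(s)), "degree": len(s), "count": c}
        for s, c in counts.items()
    ]
    return (
        pd.DataFrame(rows, columns=["groups", "degree", "count"])
        .sort_values(["degree", "groups"])
        .reset_index(drop=True)
    )
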