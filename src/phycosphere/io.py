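"""Readers and writers for the pipeline's standard artifacts.

All tabular interchange is TSV (samples as rows unless stated otherwise);
trees are Newick; result documents are JSON. Relative-abundance scaling is an
explicit transform (:func:`to_relative`), never applied implicitly on read,
because the neutral-model stage needs raw counts to estimate community size.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode


class ValidationError(ValueError):
    """Raised when an input artifact violates a format contract."""


@dataclass
class AbundanceTable:
    """Sample x taxon matrix of non-negative counts or relative abundances.

    ``data`` is a pandas DataFrame with sample ids as the index and taxon
    (or function) ids as columns. ``taxonomy`` optionally maps a taxon id to
    a lineage string (used for family-level annotation of networks).
    """

    data: pd.DataFrame
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        x = self.data.to_numpy(dtype=float)
        if np.isnan(x).any():
            i, j = np.argwhere(np.isnan(x))[0]
            raise ValidationError(
                f"NaN abundance at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if (x < 0).any():
            i, j = np.argwhere(x < 0)[0]
            raise ValidationError(
                f"negative abundance ({x[i, j]}) at sample "
                f"{self.data.index[i]!r}, taxon {self.data.columns[j]!r}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate taxon id {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scale each sample to relative abundances.

    All-zero samples are left all-zero rather than producing NaN.
    """
    x = table.values
    totals = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, x / totals, 0.0)
    return AbundanceTable(
        pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
        taxonomy=table.taxonomy,
    )


def read_abundance_table(
    path: str | Path, orientation: str = "rows-are-samples"
) -> AbundanceTable:
    """Read a TSV abundance table (header row, first column = ids).

    ``orientation`` is ``"rows-are-samples"`` or ``"rows-are-taxa"``; the
    latter is transposed on read so the in-memory table is always
    samples x taxa. Input row/column order is preserved.
    """
    if orientation not in ("rows-are-samples", "rows-are-taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric value in {path}: {exc}") from exc
    if orientation == "rows-are-taxa":
        df = df.T
    return AbundanceTable(df)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write samples-as-rows TSV; first column header is ``sample_id``."""
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV (first column = sample id)."""
    md = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    md.index = md.index.astype(str)
    if md.index.has_duplicates:
        dup = md.index[md.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id in metadata: {dup!r}")
    return md


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    md = metadata.copy()
    md.index.name = "sample_id"
    md.to_csv(path, sep="\t")


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths; leaf labels are taxon ids."""

    tree: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        tips = list(self.tree.tips())
        if not tips:  # degenerate single-node tree: the root is the leaf
            return [self.tree.name] if self.tree.name else []
        return [t.name for t in tips]

    @property
    def total_branch_length(self) -> float:
        return float(
            sum(n.length or 0.0 for n in self.tree.traverse(include_self=True))
        )


def read_newick(source: str | Path) -> PhyloTree:
    """Parse a single-tree Newick file (or literal Newick string).

    Branch lengths must be non-negative and leaf labels unique.
    """
    text = str(source)
    if not text.strip().endswith(";"):
        text = Path(source).read_text()
    try:
        tree = TreeNode.read(_io.StringIO(text))
    except Exception as exc:  # skbio raises several parser error types
        raise ValidationError(f"malformed Newick: {exc}") from exc
    names = [t.name for t in tree.tips()] or ([tree.name] if tree.name else [])
    if any(n is None for n in names):
        raise ValidationError("unlabeled leaf in tree")
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ValidationError(f"duplicate leaf label {dup!r}")
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length at {node.name!r}")
    return PhyloTree(tree)


def write_edge_list(net, path: str | Path) -> None:
    """Write a co-occurrence network as a TSV edge list.

    Columns: source, target, rho, p, sign (source < target lexicographically;
    family columns added when taxonomy annotation is present). An empty
    network yields a header-only file.
    """
    rows = []
    has_family = any("family" in d for _, d in net.graph.nodes(data=True))
    for u, v, d in net.graph.edges(data=True):
        a, b = sorted((str(u), str(v)))
        row = {
            "source": a,
            "target": b,
            "rho": d["rho"],
            "p": d["p"],
            "sign": "+" if d["rho"] >= 0 else "-",
        }
        if has_family:
            row["family_source"] = net.graph.nodes[a].get("family", "")
            row["family_target"] = net.graph.nodes[b].get("family", "")
        rows.append(row)
    cols = ["source", "target", "rho", "p", "sign"]
    if has_family:
        cols += ["family_source", "family_target"]
    df = pd.DataFrame(rows, columns=cols).sort_values(["source", "target"]) if rows else pd.DataFrame(columns=cols)
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path):
    """Re-import an edge-list TSV written by :func:`write_edge_list`."""
    from .network import CooccurrenceNetwork
    import networkx as nx

    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(str(row["source"]), str(row["target"]),
                   rho=float(row["rho"]), p=float(row["p"]))
        if "family_source" in df.columns:
            g.nodes[str(row["source"])]["family"] = row["family_source"]
            g.nodes[str(row["target"])]["family"] = row["family_target"]
    return CooccurrenceNetwork(graph=g)


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
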