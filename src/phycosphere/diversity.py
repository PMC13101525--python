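"""Alpha diversity, beta diversity, and principal coordinates analysis.

Alpha metrics: richness, Shannon entropy (natural log), Pielou evenness and
Faith's phylogenetic diversity under the root-inclusive convention (the
branch path from each present leaf up to the root is counted). Beta metrics:
Bray-Curtis on abundances and binary Jaccard on presence/absence. PCoA is
classical Gower double-centering with negative eigenvalues reported and
their axes dropped (no Cailliez/Lingoes correction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import AbundanceTable, PhyloTree

logger = logging.getLogger(__name__)


def alpha_diversity(
    table: AbundanceTable, tree: PhyloTree | None = None
) -> pd.DataFrame:
    """Per-sample richness, Shannon, Pielou and (if a tree is given) Faith PD.

    Shannon is -sum q ln q over the sample's relative abundances; Pielou is
    Shannon / ln(richness) for richness >= 2 and 0 by convention otherwise.
    """
    if table.n_samples == 0 or table.n_taxa == 0:
        raise ValueError("empty abundance table")
    x = table.values
    present = x > 0
    richness = present.sum(axis=1)
    totals = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(totals > 0, x / totals, 0.0)
        shannon = -np.where(q > 0, q * np.log(q), 0.0).sum(axis=1)
    pielou = np.where(richness >= 2, shannon / np.where(richness >= 2, np.log(richness), 1.0), 0.0)
    out = pd.DataFrame(
        {"richness": richness, "shannon": shannon, "pielou": pielou},
        index=table.data.index,
    )
    if tree is not None:
        taxa = np.asarray(table.taxon_ids)
        out["pd"] = [
            faith_pd(tree, set(taxa[present[i]])) for i in range(table.n_samples)
        ]
    return out


def faith_pd(tree: PhyloTree, present: set[str]) -> float:
    """Faith's PD of a taxon set: total branch length of the minimal
    root-inclusive subtree spanning the present leaves."""
    if not present:
        return 0.0
    root = tree.tree
    tips = {t.name: t for t in root.tips()}
    if not tips and root.name:  # single-node tree
        tips = {root.name: root}
    missing = sorted(present - tips.keys())
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    counted: set[int] = set()
    total = 0.0
    for name in present:
        node = tips[name]
        while node is not None:
            if id(node) in counted:
                break
            counted.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return float(total)


def beta_diversity(table: AbundanceTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise sample dissimilarities (Bray-Curtis or binary Jaccard).

    A pair of all-zero samples has distance 0 (with a logged warning) so the
    matrix stays well defined.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = table.values
    empty = x.sum(axis=1) == 0
    if empty.any():
        logger.warning(
            "all-zero samples present (%s); pairwise distances involving two "
            "empty samples are defined as 0",
            list(np.asarray(table.sample_ids)[empty]),
        )
    if metric == "bray_curtis":
        with np.errstate(invalid="ignore", divide="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                d = pdist(x, metric="braycurtis")
    elif metric == "jaccard":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = pdist(x > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = np.nan_to_num(d, nan=0.0)  # only NaN source: two all-zero samples
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


@dataclass
class Ordination:
    """PCoA result: coordinates (samples x axes, scaled by sqrt eigenvalue),
    eigenvalues of the retained positive axes, proportions explained over the
    positive spectrum, and any negative eigenvalues encountered."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower-centers -d^2/2, eigendecomposes, keeps axes with eigenvalue above
    a small numerical floor and orders them by descending eigenvalue.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(abs(evals[0]), 1.0)
    pos = evals > tol
    neg = evals[evals < -tol]
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(pos.sum())]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=evals[pos],
        proportion_explained=prop,
        negative_eigenvalues=neg,
    )
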