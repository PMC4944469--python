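"""Phylogeny handling for the scaling regressions.

Trees are plain :class:`dendropy.Tree` objects read from Newick. The
phylogenetic regression needs one thing from the tree: the Brownian-motion
expected covariance among species, ``V[i, j] =`` shared branch length from
the root to the most recent common ancestor of tips *i* and *j*. Trees are
scaled to unit root-to-tip height before use so the phylogenetic variance
component is comparable across trees (ultrametric trees then have unit
diagonal). Multifurcations are accepted as-is; the covariance is
well-defined regardless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_newick",
    "write_newick",
    "normalize_name",
    "prune_and_match",
    "vcv_matrix",
    "scale_to_unit_height",
    "MatchReport",
]


class NewickFormatError(ValueError):
    """Raised when a Newick file cannot be parsed."""


def read_newick(path) -> dendropy.Tree:
    """Read a rooted tree from a Newick file."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickFormatError(f"cannot parse Newick file {path}: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree to Newick, preserving labels and branch lengths."""
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def normalize_name(name: str) -> str:
    """Canonical species-name form: trimmed, case-folded, spaces == underscores."""
    return name.strip().casefold().replace(" ", "_")


@dataclass
class MatchReport:
    """Outcome of matching dataset species to tree tips."""

    matched: dict[str, str] = field(default_factory=dict)  # dataset name -> tip label
    unmatched_species: list[str] = field(default_factory=list)
    unmatched_tips: list[str] = field(default_factory=list)


def prune_and_match(
    tree: dendropy.Tree, species_list
) -> tuple[dendropy.Tree, MatchReport]:
    """Restrict a tree to the species present in a dataset.

    Names are compared after trimming, case-folding and treating spaces and
    underscores as equivalent. Species absent from the tree are listed in
    the report and must be excluded from phylogenetic analyses by the
    caller (a warning is emitted here).

    Raises ``ValueError`` when fewer than two species match: no
    phylogenetic model can be fitted then.
    """
    tip_by_norm = {normalize_name(t.label): t.label for t in tree.taxon_namespace}
    report = MatchReport()
    seen: set[str] = set()
    for sp in species_list:
        if sp in seen:
            continue
        seen.add(sp)
        tip = tip_by_norm.get(normalize_name(sp))
        if tip is None:
            report.unmatched_species.append(sp)
        else:
            report.matched[sp] = tip
    matched_tips = set(report.matched.values())
    report.unmatched_tips = sorted(
        t.label for t in tree.taxon_namespace if t.label not in matched_tips
    )
    if report.unmatched_species:
        warnings.warn(
            "species not found on the tree and excluded from phylogenetic "
            f"analyses: {report.unmatched_species}"
        )
    if len(report.matched) < 2:
        raise ValueError("fewer than 2 dataset species match the tree")
    pruned = tree.clone(depth=1)
    # keep unifurcations so root-to-tip depths (hence the covariance) are
    # exactly the restriction of the full tree's
    pruned.retain_taxa_with_labels(list(matched_tips), suppress_unifurcations=False)
    return pruned, report


def scale_to_unit_height(tree: dendropy.Tree) -> dendropy.Tree:
    """Scale edge lengths so the maximum root-to-tip distance is 1 (in place)."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    if height <= 0:
        raise ValueError("tree has zero height; cannot scale")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return tree


def vcv_matrix(tree: dendropy.Tree, scale_to_unit: bool = True) -> pd.DataFrame:
    """Brownian-motion covariance among tips: shared root-to-MRCA path length.

    Entry (i, j) is the branch length shared by the root-to-tip paths of
    tips i and j, computed as ``(depth_i + depth_j - d_ij) / 2`` with
    ``d_ij`` the patristic distance. With ``scale_to_unit`` the matrix is
    divided by its maximum diagonal, so diagonals are <= 1 (all exactly 1
    for an ultrametric tree). Symmetric positive semidefinite by
    construction.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    labels = [n.taxon.label for n in leaves]
    depth = np.array([n.root_distance for n in leaves], dtype=float)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    V = np.zeros((n, n), dtype=float)
    for i in range(n):
        V[i, i] = depth[i]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            V[i, j] = V[j, i] = 0.5 * (depth[i] + depth[j] - d)
    np.clip(V, 0.0, None, out=V)
    if scale_to_unit:
        V /= np.max(np.diag(V))
    return pd.DataFrame(V, index=labels, columns=labels)
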