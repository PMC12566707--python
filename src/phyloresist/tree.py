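"""Rooted phylogenies: newick I/O, patristic distances, Faith's PD.

Trees are held as dendropy :class:`~dendropy.Tree` objects behind a thin
wrapper that enforces the package's invariants (unique tip labels, finite
non-negative branch lengths) and exposes the two quantities the analyses
need: tip-to-tip patristic distances and subtree branch-length sums.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .exceptions import FormatError, TreeLookupError, ValidationError


class Phylogeny:
    """A rooted tree with branch lengths.

    Branch lengths are taken as given (no ultrametricity is assumed) and
    polytomies are handled natively.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True  # the analyses assume a rooted tree throughout
        # any length above the root is not part of the phylogeny proper
        tree.seed_node.edge.length = None
        self._tree = tree
        self._leaves = {}
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValidationError("tree has an unnamed tip")
            label = leaf.taxon.label
            if label in self._leaves:
                raise ValidationError(f"duplicate tip label {label!r}")
            self._leaves[label] = leaf
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue  # root edge may legitimately be absent
            if edge.length is None:
                raise ValidationError(
                    "missing branch length above "
                    + (edge.head_node.taxon.label if edge.head_node.taxon else "an internal node")
                )
            if not np.isfinite(edge.length) or edge.length < 0:
                raise ValidationError(f"invalid branch length {edge.length!r}")
        self._pdm = None

    # -- basic properties -------------------------------------------------
    @property
    def tips(self) -> set[str]:
        return set(self._leaves)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def total_length(self) -> float:
        """Sum of all branch lengths in the tree."""
        return sum(
            e.length or 0.0 for e in self._tree.preorder_edge_iter()
        )

    def __len__(self) -> int:
        return len(self._leaves)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a newick string."""
        try:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise FormatError(f"unparseable newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()

    def write_newick(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- distances ---------------------------------------------------------
    def _require(self, labels: Iterable[str]) -> list[str]:
        labels = list(labels)
        missing = [l for l in labels if l not in self._leaves]
        if missing:
            raise TreeLookupError(missing)
        return labels

    def patristic_distances(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        """Symmetric matrix of tip-to-tip path-length distances.

        Rows/columns are ordered as ``labels`` (default: sorted tips).
        """
        if labels is None:
            labels = sorted(self._leaves)
        else:
            labels = self._require(labels)
        if self._pdm is None:
            self._pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {l: self._leaves[l].taxon for l in labels}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = self._pdm.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]]
                )
        return pd.DataFrame(d, index=labels, columns=labels)

    def distance_to(self, focal: str, labels: Sequence[str] | None = None) -> pd.Series:
        """Patristic distance from every tip in ``labels`` to ``focal``."""
        self._require([focal])
        if labels is None:
            labels = sorted(l for l in self._leaves if l != focal)
        else:
            labels = self._require(labels)
        if self._pdm is None:
            self._pdm = self._tree.phylogenetic_distance_matrix()
        ft = self._leaves[focal].taxon
        return pd.Series(
            {l: self._pdm.patristic_distance(ft, self._leaves[l].taxon) for l in labels},
            name=f"distance_to_{focal}",
        )

    # -- Faith's PD ---------------------------------------------------------
    def faith_pd(self, community: Iterable[str], include_root: bool = True) -> float:
        """Faith's phylogenetic diversity of a set of tips.

        The sum of branch lengths of the minimal subtree spanning the
        community.  With ``include_root`` (the default) the subtree is rooted
        at the tree's root, so even a single-species community has positive
        PD (its root-to-tip distance); without it the subtree starts at the
        community's most recent common ancestor.
        """
        community = set(community)
        if not community:
            raise ValidationError("empty community")
        self._require(community)
        seen: set[int] = set()
        lengths: list[float] = []  # collected tip-by-tip for a stable sum order
        for label in sorted(community):
            node = self._leaves[label]
            while node is not self._tree.seed_node:
                eid = id(node.edge)
                if eid in seen:
                    break  # shared path to root already collected
                seen.add(eid)
                lengths.append(node.edge.length or 0.0)
                node = node.parent_node
        total = sum(lengths)
        if not include_root:
            mrca = self._tree.mrca(
                taxa=[self._leaves[l].taxon for l in community]
            )
            node = mrca
            while node is not self._tree.seed_node:
                total -= node.edge.length or 0.0
                node = node.parent_node
        return total


def read_newick(path) -> Phylogeny:
    """Read a rooted newick tree with branch lengths from a file."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    return Phylogeny.from_newick(path.read_text())


def faith_pd(tree: Phylogeny, community: Iterable[str], include_root: bool = True) -> float:
    """Module-level convenience wrapper for :meth:`Phylogeny.faith_pd`."""
    return tree.faith_pd(community, include_root=include_root)


def patristic_distances(tree: Phylogeny, labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Module-level convenience wrapper for :meth:`Phylogeny.patristic_distances`."""
    return tree.patristic_distances(labels)
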