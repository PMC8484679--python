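"""Rooted trees and the among-species covariance structures they imply.

A rooted phylogeny with branch lengths defines, under Brownian motion, an
among-species covariance matrix whose (i, j) entry is the shared path length
from the root to the most recent common ancestor of tips i and j, and whose
diagonal holds root-to-tip depths.  Pagel's lambda rescales the off-diagonal
entries of that matrix.  This module wraps dendropy for Newick IO and tree
surgery and provides the covariance construction used by the regression and
imputation machinery.
"""

from __future__ import annotations

import io
from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhylogenyError",
    "read_newick",
    "phylo_vcv",
    "lambda_transform",
]


class PhylogenyError(ValueError):
    """Malformed, inconsistent, or incomplete tree input."""


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labelled tips.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the
    invariants the comparative machinery relies on: every non-root edge has
    a non-negative length, tip labels are unique, and there is a single
    root.  Polytomies are allowed and treated as true multifurcations.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse types
            raise PhylogenyError(f"could not parse Newick: {exc}") from exc
        tree.is_rooted = True
        return cls(tree)

    def _validate(self) -> None:
        labels = self.tip_labels
        seen: set[str] = set()
        for lab in labels:
            if lab is None:
                raise PhylogenyError("unlabelled tip in tree")
            if lab in seen:
                raise PhylogenyError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            bl = node.edge.length
            if bl is None:
                raise PhylogenyError(
                    f"missing branch length above {_node_name(node)}"
                )
            if bl < 0:
                raise PhylogenyError(
                    f"negative branch length ({bl}) above {_node_name(node)}"
                )

    # -- basic queries -------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label if leaf.taxon else None
                for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        out: dict[str, float] = {}
        for leaf, depth in self._node_depths().items():
            if leaf.is_leaf():
                out[leaf.taxon.label] = depth
        return out

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = np.array(list(self.depths().values()))
        scale = max(d.max(), 1e-300)
        return bool((d.max() - d.min()) <= rel_tol * scale)

    def max_depth(self) -> float:
        return max(self.depths().values())

    def _node_depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    # -- IO -------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + "\n"

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    # -- surgery ---------------------------------------------------------

    def graft_species(
        self, new_tip: str, sister_taxon: str, stem_fraction: float = 0.5
    ) -> "Phylogeny":
        """Attach ``new_tip`` on the terminal branch of ``sister_taxon``.

        The attachment point sits ``stem_fraction`` of the sister's terminal
        branch above (rootward of) the sister tip; the new tip's pendant
        edge has the same length, so an ultrametric tree stays ultrametric.
        Returns a new Phylogeny; the original is untouched.
        """
        if not (0.0 < stem_fraction < 1.0):
            raise PhylogenyError("stem_fraction must be in (0, 1)")
        if new_tip in self.tip_labels:
            raise PhylogenyError(f"tip {new_tip!r} already present")
        tree = self._tree.clone(depth=1)
        sister = None
        for leaf in tree.leaf_node_iter():
            if leaf.taxon and leaf.taxon.label == sister_taxon:
                sister = leaf
                break
        if sister is None:
            raise PhylogenyError(f"sister taxon {sister_taxon!r} not in tree")
        term = sister.edge.length
        parent = sister.parent_node
        parent.remove_child(sister)
        joint = parent.new_child(edge_length=term * (1.0 - stem_fraction))
        sister.edge.length = term * stem_fraction
        joint.add_child(sister)
        taxon = tree.taxon_namespace.require_taxon(label=new_tip)
        joint.new_child(taxon=taxon, edge_length=term * stem_fraction)
        return Phylogeny(tree)

    # -- covariance -------------------------------------------------------

    def vcv(
        self,
        tip_order: Sequence[str] | None = None,
        normalize_depth: bool = False,
    ) -> np.ndarray:
        """Brownian among-species covariance over ``tip_order``.

        Entry (i, j) is the path length from the root to the MRCA of tips
        i and j; the diagonal is the root-to-tip depth.  With
        ``normalize_depth`` the matrix is divided by the maximum depth
        (unit-height scaling); this only rescales sigma^2 and leaves
        lambda, t and p statistics unchanged, so it is off by default.
        """
        depths = self._node_depths()
        labels = self.tip_labels
        if tip_order is None:
            tip_order = labels
        idx = {lab: k for k, lab in enumerate(tip_order)}
        missing = [t for t in tip_order if t not in set(labels)]
        if missing:
            raise PhylogenyError(f"tips not in tree: {missing}")
        n = len(tip_order)
        C = np.zeros((n, n))
        # Postorder with per-node descendant tip sets: a pair of tips lands
        # in different child subtrees exactly once, at its MRCA, so each
        # off-diagonal entry is written exactly once.
        tipsets: dict[dendropy.Node, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                tipsets[node] = [idx[lab]] if lab in idx else []
                if lab in idx:
                    C[idx[lab], idx[lab]] = depths[node]
                continue
            children = [tipsets.pop(ch) for ch in node.child_nodes()]
            d = depths[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            tipsets[node] = [i for ch in children for i in ch]
        if normalize_depth:
            C = C / C.diagonal().max()
        return C

    def vcv_to_csv(self, path: str, tip_order: Sequence[str] | None = None) -> None:
        """Write the Brownian covariance as a labelled CSV (debugging aid)."""
        import pandas as pd

        order = list(tip_order) if tip_order is not None else self.tip_labels
        pd.DataFrame(self.vcv(order), index=order, columns=order).to_csv(path)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return "<internal node>"


def read_newick(source: str) -> Phylogeny:
    """Parse a Newick string (or path to a Newick file) into a Phylogeny."""
    text = source
    if "(" not in source:  # treat as a path
        with open(source) as fh:
            text = fh.read()
    return Phylogeny.from_newick(text)


def phylo_vcv(tree: Phylogeny, tip_order: Sequence[str] | None = None) -> np.ndarray:
    """Brownian covariance matrix of ``tree`` over ``tip_order`` (see Phylogeny.vcv)."""
    return tree.vcv(tip_order)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply the off-diagonal entries of a phylogenetic covariance by lambda.

    lambda = 1 returns C unchanged (full Brownian dependence); lambda = 0
    removes all shared history, leaving a diagonal matrix.  The transform
    preserves positive semi-definiteness for lambda in [0, 1].
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out
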