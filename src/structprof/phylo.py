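"""Clade extraction from a given phylogenetic tree.

The package consumes trees (Newick, as deposited) rather than inferring
them.  Subfamilies are defined operationally as the clade under the most
recent common ancestor (MRCA) of a set of anchor taxa — e.g. the known
fructose-receptor orthologs — on the tree as rooted in the deposit; no
re-rooting is performed and support values are parsed but never used for
clade decisions.  Parsing is delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import pandas as pd

log = logging.getLogger("structprof")

__all__ = ["Tree", "Clade", "PhyloError", "read_newick", "write_newick",
           "mrca_clade", "annotate_subfamilies"]


class PhyloError(ValueError):
    """Parse failures, missing anchors, or inconsistent clade definitions."""


@dataclass
class Tree:
    """A rooted tree with unique leaf labels (thin dendropy wrapper)."""

    dtree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise PhyloError(f"duplicate leaf labels: {dupes[:5]}")

    @property
    def leaf_labels(self) -> list:
        return [lf.taxon.label for lf in self.dtree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.dtree.leaf_nodes())

    def newick(self) -> str:
        return self.dtree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass(frozen=True)
class Clade:
    """The leaves under one internal node."""

    name: str
    leaves: frozenset

    def __len__(self) -> int:
        return len(self.leaves)


def read_newick(path_or_text) -> Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    text = None
    s = str(path_or_text)
    if s.lstrip().startswith("("):
        text = s
    else:
        with open(s) as fh:
            text = fh.read()
    if text.count("(") != text.count(")"):
        raise PhyloError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'")
    try:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True)
    except Exception as exc:  # dendropy raises its own DataError hierarchy
        raise PhyloError(f"failed to parse Newick: {exc}") from exc
    dt.is_rooted = True          # trees are consumed as rooted, as deposited
    dt.encode_bipartitions()
    return Tree(dtree=dt)


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def mrca_clade(tree: Tree, anchors, name: str = "clade") -> Clade:
    """The clade under the MRCA of the anchor leaves.

    Always a superset of the anchors; adding anchors can only grow it.
    """
    labels = set(tree.leaf_labels)
    missing = [a for a in anchors if a not in labels]
    if missing:
        raise PhyloError(f"anchor leaves not in tree: {missing}")
    anchors = list(anchors)
    if len(anchors) == 1:
        return Clade(name=name, leaves=frozenset(anchors))
    node = tree.dtree.mrca(taxon_labels=anchors)
    leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
    return Clade(name=name, leaves=leaves)


def annotate_subfamilies(tree: Tree, anchor_sets: dict) -> pd.DataFrame:
    """Assign every leaf to the MRCA clade of one named anchor set.

    Anchor sets must yield disjoint clades; leaves outside all clades are
    labelled ``unassigned``.  Returns a (leaf, subfamily) table in tree order.
    """
    clades = {nm: mrca_clade(tree, anchors, name=nm)
              for nm, anchors in anchor_sets.items()}
    names = list(clades)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = clades[a].leaves & clades[b].leaves
            if overlap:
                raise PhyloError(
                    f"clades {a!r} and {b!r} overlap on {len(overlap)} leaves "
                    f"(e.g. {sorted(overlap)[:3]})")
    assignment = {}
    for nm, clade in clades.items():
        for leaf in clade.leaves:
            assignment[leaf] = nm
    rows = [{"leaf": lf, "subfamily": assignment.get(lf, "unassigned")}
            for lf in tree.leaf_labels]
    return pd.DataFrame(rows)
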