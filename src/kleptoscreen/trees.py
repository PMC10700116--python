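"""Support-annotated phylogeny post-processing.

HGT-candidate trees arrive as Newick with bootstrap supports stored as
internal node labels (IQ-TREE dialect). The post-processing applied before
interpreting a candidate's placement is: midpoint rooting, then contraction
of every internal edge whose support falls below a threshold (default 95),
yielding a conservatively multifurcating tree. An automated placement check
then asks whether the smallest non-trivial clade containing the query leaf
consists of donor-lineage ("other") leaves with no recipient-lineage leaves
— the pattern expected for a genuinely horizontally acquired gene. The check
formalizes what is otherwise a manual inspection and is labelled as such in
reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

__all__ = [
    "SupportTree",
    "read_newick",
    "write_newick",
    "midpoint_root",
    "collapse_low_support",
    "hgt_support_check",
]


@dataclass
class SupportTree:
    """Thin wrapper around a dendropy tree with supports on internal nodes."""

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaf(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise KeyError(f"leaf {label!r} not in tree")

    def internal_supports(self) -> list[int]:
        out = []
        for nd in self.tree.preorder_internal_node_iter(exclude_seed_node=True):
            if nd.label is not None:
                out.append(int(float(nd.label)))
        return out

    def clone(self) -> "SupportTree":
        return SupportTree(self.tree.clone(depth=1))


def read_newick(text: str) -> SupportTree:
    """Parse Newick with optional internal-label supports and branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as err:  # normalize parser errors (position in message)
        raise ValueError(f"newick parse error: {err}") from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return SupportTree(tree)


def write_newick(st: SupportTree) -> str:
    return (
        st.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def midpoint_root(st: SupportTree) -> SupportTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The two farthest leaves end up equidistant from the root (up to float
    precision). Requires branch lengths on every edge.
    """
    leaves = list(st.tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs >= 2 leaves")
    for edge in st.tree.preorder_edge_iter():
        if edge.head_node is not st.tree.seed_node and edge.length is None:
            raise ValueError("midpoint rooting requires branch lengths on all edges")
    if len(leaves) == 2:  # dendropy degenerates here; root the single path directly
        a, b = leaves
        half = (a.edge.length + b.edge.length) / 2.0
        out = read_newick(f"({a.taxon.label}:{half!r},{b.taxon.label}:{half!r});")
        return out
    out = st.clone()
    out.tree.reroot_at_midpoint(update_bipartitions=True)
    return out


def collapse_low_support(st: SupportTree, threshold: int = 95) -> SupportTree:
    """Contract internal edges with support below the threshold.

    Leaves are untouched; unlabeled internal edges are kept (no support
    information is not evidence against a branch). Idempotent.
    """
    out = st.clone()
    to_collapse = []
    for nd in out.tree.preorder_internal_node_iter(exclude_seed_node=True):
        if nd.label is not None and float(nd.label) < threshold:
            to_collapse.append(nd.edge)
    for edge in to_collapse:
        edge.collapse()
    return out


def _classes_of(leaves, taxon_class: dict[str, str], query: str) -> list[str]:
    return [
        taxon_class.get(lf.taxon.label, "other")
        for lf in leaves
        if lf.taxon.label != query
    ]


def hgt_support_check(
    st: SupportTree,
    query: str,
    taxon_class: dict[str, str],
) -> tuple[str, dict]:
    """Automated placement check for an HGT candidate on a processed tree.

    ``taxon_class`` maps leaf labels to {recipient, skip, other}; the query
    itself may be mapped or not. The verdict is "supported" iff the smallest
    non-trivial clade containing the query (a proper clade with >= 2 leaves,
    found after collapsing) contains at least one other-class leaf and zero
    recipient-class leaves; skip-class leaves are ignored. Returns the
    verdict and a report of the enclosing clade.
    """
    leaf = st.leaf(query)  # raises KeyError if absent
    n_leaves = sum(1 for _ in st.tree.leaf_node_iter())
    node = leaf.parent_node
    while node is not None:
        clade_leaves = list(node.leaf_iter())
        if 2 <= len(clade_leaves) < n_leaves:
            classes = _classes_of(clade_leaves, taxon_class, query)
            informative = [c for c in classes if c != "skip"]
            supported = bool(informative) and all(c == "other" for c in informative)
            report = {
                "clade_size": len(clade_leaves),
                "clade_leaves": sorted(lf.taxon.label for lf in clade_leaves),
                "n_other": sum(c == "other" for c in classes),
                "n_recipient": sum(c == "recipient" for c in classes),
                "n_skip": sum(c == "skip" for c in classes),
            }
            return ("supported" if supported else "unsupported"), report
        node = node.parent_node
    return "unsupported", {"clade_size": 0, "clade_leaves": [], "n_other": 0,
                           "n_recipient": 0, "n_skip": 0}
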