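"""Dollo-parsimony reconstruction of synteny-group origins and losses.

Each synteny group is binarized into a presence/absence row over the
species-tree leaves.  Dollo parsimony allows exactly one gain per group and
any number of losses; under that constraint the loss-minimizing gain node is
the most recent common ancestor (MRCA) of the presence leaves, and the
minimal loss set consists of the branches subtending the *maximal* all-absent
clades inside the origin subtree.  The origin node, mapped through a
user-supplied clade labeling, yields the group's conservation-depth label
(species-specific / primate / mammal / amniote, or whatever the labeling
provides).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .synteny import SyntenyGroup


class DataError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class DolloReconstruction:
    group_id: str
    origin_node: str            # node label
    loss_branches: frozenset[str]  # labels of nodes whose parent branch is lost
    n_losses: int


def label_internal_nodes(tree, prefix: str = "n") -> None:
    """Assign deterministic labels to unlabeled internal nodes (in preorder)."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label is None and (node.taxon is None or node.taxon.label is None):
            node.label = f"{prefix}{i}"
        i += 1


def node_label(node) -> str:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label if node.label is not None else ""


def to_presence_absence(
    groups: Sequence[SyntenyGroup], species: Sequence[str]
) -> pd.DataFrame:
    """Binarize groups into a groups x species {0,1} matrix.

    A cell is 1 iff the group has at least one member locus in that species;
    within-species paralogs do not count twice.
    """
    species = list(species)
    spset = set(species)
    rows = {}
    for g in groups:
        row = dict.fromkeys(species, 0)
        for sp, _lid in g.members:
            if sp not in spset:
                raise DataError(f"group {g.group_id} cites unknown species {sp!r}")
            row[sp] = 1
        rows[g.group_id] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=species).astype(int)
    return matrix


def dollo_reconstruct(row: Mapping[str, int], tree, group_id: str = "") -> DolloReconstruction:
    """Reconstruct the single-gain, minimum-loss history of one presence row.

    The gain is placed at the MRCA of all presence leaves; losses are the
    branches above maximal absent clades within the origin subtree.  This
    placement attains the minimum loss count over all single-gain
    assignments.
    """
    present = {sp for sp, v in row.items() if v}
    if not present:
        raise DataError(f"group {group_id or '?'}: all-absent row")

    leaf_nodes = {}
    for leaf in tree.leaf_node_iter():
        leaf_nodes[node_label(leaf)] = leaf
    missing = present - set(leaf_nodes)
    if missing:
        raise DataError(f"species {sorted(missing)} not among tree leaves")

    if len(present) == 1:
        origin = leaf_nodes[next(iter(present))]
    else:
        origin = tree.mrca(taxa=[leaf_nodes[sp].taxon for sp in sorted(present)])

    # A subtree is "absent" iff none of its leaves carries the group.  The
    # minimal loss set is the set of absent nodes whose parent subtree is
    # not absent, restricted to the origin subtree.
    losses: set[str] = set()

    def all_absent(node) -> bool:
        if node.is_leaf():
            return node_label(node) not in present
        return all(all_absent(c) for c in node.child_nodes())

    def walk(node) -> None:
        for child in node.child_nodes():
            if all_absent(child):
                losses.add(node_label(child))
            else:
                walk(child)

    walk(origin)
    return DolloReconstruction(
        group_id=group_id,
        origin_node=node_label(origin),
        loss_branches=frozenset(losses),
        n_losses=len(losses),
    )


def reconstruct_matrix(matrix: pd.DataFrame, tree) -> list[DolloReconstruction]:
    return [
        dollo_reconstruct(matrix.loc[gid].to_dict(), tree, group_id=str(gid))
        for gid in matrix.index
    ]


def conservation_depth(
    rec: DolloReconstruction,
    tree,
    reference: str,
    clade_labels: Mapping[str, str],
    presence: Mapping[str, int] | None = None,
) -> str:
    """Depth label of the origin node relative to a reference species.

    ``clade_labels`` maps node labels (the reference leaf included, usually
    as "species-specific") to depth labels.  An origin node without an entry
    falls back to the nearest labeled ancestor; with no labeled ancestor the
    raw node label is returned.
    """
    if presence is not None and not presence.get(reference, 0):
        raise DataError(f"reference {reference!r} is not a presence leaf of {rec.group_id}")
    node = _find_node(tree, rec.origin_node)
    while node is not None:
        lbl = node_label(node)
        if lbl in clade_labels:
            return clade_labels[lbl]
        node = node.parent_node
    return rec.origin_node


def _find_node(tree, label: str):
    for node in tree.preorder_node_iter():
        if node_label(node) == label:
            return node
    raise DataError(f"node {label!r} not found in tree")


def write_reconstructions_tsv(
    path: str | Path,
    recs: Sequence[DolloReconstruction],
    depth_labels: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\torigin_node\tn_losses\tloss_branches\tdepth_label\n")
        for r in recs:
            depth = depth_labels.get(r.group_id, "") if depth_labels else ""
            fh.write(
                f"{r.group_id}\t{r.origin_node}\t{r.n_losses}\t"
                f"{','.join(sorted(r.loss_branches))}\t{depth}\n"
            )
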