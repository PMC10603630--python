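"""Faith's phylogenetic diversity and hypothetical-extinction PD loss.

PD of a taxon set is the total branch length of the subtree spanning those
taxa.  By default the span includes the path to the root, so a single
taxon carries its full root-to-tip history; the alternative convention
(spanning subtree of the taxa's MRCA only) is available via
``include_root=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set

from .treeio import TimeTree, TreeError, prune_to_taxa

__all__ = ["total_pd", "subset_pd", "ExtinctionScenario", "extinction_scenarios"]


def total_pd(tree: TimeTree) -> float:
    """Sum of all branch lengths (Ma)."""
    return tree.total_length()


def subset_pd(tree: TimeTree, taxa: Iterable[str], include_root: bool = True) -> float:
    """PD of a subset of tips.

    With ``include_root`` (default), PD is the length of the union of
    root-to-tip paths of *taxa*.  Without it, edges above the taxa's MRCA
    are excluded.
    """
    taxa_set = set(taxa)
    if not taxa_set:
        raise TreeError("taxa set must be non-empty")
    marked: Set[int] = set()  # node ids whose stem edge is on a root->taxon path
    mrca_candidates = []
    for label in taxa_set:
        node = tree.tip(label)
        path = []
        while node.parent is not None:
            path.append(node)
            node = node.parent
        marked.update(n.id for n in path)
        mrca_candidates.append([n.id for n in reversed(path)])
    length_by_id = {n.id: n.length for n in tree.nodes}
    pd_root = sum(length_by_id[i] for i in marked)
    if include_root:
        return pd_root
    # drop the shared prefix (edges above the MRCA)
    shared = 0.0
    for ids in zip(*mrca_candidates):
        if len(set(ids)) == 1:
            shared += length_by_id[ids[0]]
        else:
            break
    return pd_root - shared


@dataclass
class ExtinctionScenario:
    """PD accounting for one hypothetical extinction event."""

    removed: tuple
    pd_before: float
    pd_after: float

    @property
    def loss(self) -> float:
        return self.pd_before - self.pd_after

    @property
    def loss_fraction(self) -> float:
        return self.loss / self.pd_before


def extinction_scenarios(
    tree: TimeTree, losses: Sequence[Iterable[str]]
) -> List[ExtinctionScenario]:
    """PD before/after removing each tip set in *losses*.

    PD after is the total branch length of the tree pruned to the
    surviving taxa (root height preserved).  Removing every tip is an
    error.  Loss fractions are computed on unrounded PD.
    """
    pd_before = total_pd(tree)
    all_tips = set(tree.tip_labels)
    out = []
    for loss in losses:
        removed = set(loss)
        unknown = removed - all_tips
        if unknown:
            raise TreeError(f"unknown taxa in extinction scenario: {sorted(unknown)}")
        survivors = all_tips - removed
        if not survivors:
            raise TreeError("an extinction scenario cannot remove every tip")
        pruned = prune_to_taxa(tree, survivors)
        out.append(
            ExtinctionScenario(
                removed=tuple(sorted(removed)),
                pd_before=pd_before,
                pd_after=total_pd(pruned),
            )
        )
    return out
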