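"""Deterministic chlamydial-HGT gene-tree classifier.

Formalizes the manual inspection rubric used to screen phylogenomic trees
for chlamydial donors: locate the minimal clade spanning the Archaeplastida
recipients (after midpoint rooting), read the sister group's lineage
composition and the subtending support, and assign a lineage-sharing
category:

* ``all_archaeplastida`` - glaucophytes, red algae and green lineage together
* ``green_shared`` - glaucophytes + Viridiplantae only
* ``red_shared`` - glaucophytes + Rhodophyta only
* ``glaucophyte_specific`` - >= 2 glaucophyte species forming a
  monophyletic clade, in genes carrying introns (the intron flag is a
  per-gene input derived upstream from gene models)
* ``other`` - anything else (no chlamydial donor, single glaucophyte,
  contaminated clade, ...)

Monophyly is tested on bipartitions, so it is independent of rooting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .io_formats import SupportTree

__all__ = [
    "ARCHAEPLASTIDA",
    "HgtCall",
    "check_monophyly",
    "recipient_clade",
    "classify_support",
    "sharing_category",
    "classify_tree",
    "classify_batch",
]

ARCHAEPLASTIDA = ("Glaucophyta", "Rhodophyta", "Viridiplantae")


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def check_monophyly(
    tree: SupportTree, leaf_set: Iterable[str]
) -> tuple[bool, float | None]:
    """Unrooted monophyly: True iff some edge bipartition separates exactly
    ``leaf_set`` from its complement; returns that edge's support."""
    target = frozenset(leaf_set)
    if not target:
        raise ValueError("empty leaf set")
    all_leaves = frozenset(tree.leaf_names)
    unknown = target - all_leaves
    if unknown:
        raise KeyError(f"leaves not in tree: {sorted(unknown)}")
    if len(target) == 1 or target == all_leaves:
        return True, None  # pendant edge / whole tree: trivially monophyletic
    complement = all_leaves - target
    complement_hit: tuple[bool, float | None] | None = None
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = _leafset(node)
        if below == target:
            # prefer the node subtending the set itself over its complement
            # (at a bifurcating root both annotate the same unrooted edge)
            return True, tree.support_of(node)
        if below == complement and complement_hit is None:
            complement_hit = (True, tree.support_of(node))
    return complement_hit if complement_hit is not None else (False, None)


@dataclass
class RecipientClade:
    """The minimal clade spanning all recipient leaves on the
    midpoint-rooted tree, with its sister composition and support."""

    clade_leaves: frozenset[str]
    sister_lineages: Counter
    support: float | None
    spans_root: bool  # recipients straddle the root: no proper clade
    intruders: frozenset[str]  # clade members that are not recipients


def _midpoint_rooted(tree: SupportTree) -> dendropy.Tree:
    t = tree.tree.clone(depth=1)
    for edge in t.preorder_edge_iter():
        if edge.length is None:
            edge.length = 1.0
    t.reroot_at_midpoint(update_bipartitions=True)
    return t


def recipient_clade(
    tree: SupportTree,
    lineage_map: Mapping[str, str],
    recipient_lineages: Sequence[str] = ARCHAEPLASTIDA,
) -> RecipientClade:
    recipients = {
        name for name in tree.leaf_names
        if lineage_map[name] in recipient_lineages
    }
    if not recipients:
        raise ValueError("no recipient leaves in tree")
    t = _midpoint_rooted(tree)
    taxa = [t.taxon_namespace.get_taxon(n) for n in sorted(recipients)]
    if len(taxa) == 1:
        mrca = t.find_node_with_taxon_label(taxa[0].label)
    else:
        mrca = t.mrca(taxa=taxa)
    if mrca.parent_node is None:
        # recipients straddle the root: spanning clade is the whole tree
        return RecipientClade(
            clade_leaves=frozenset(lineage_map),
            sister_lineages=Counter(),
            support=None,
            spans_root=True,
            intruders=frozenset(),
        )
    clade = _leafset(mrca) if not mrca.is_leaf() else frozenset(
        [mrca.taxon.label]
    )
    sisters = [
        sib for sib in mrca.parent_node.child_nodes() if sib is not mrca
    ]
    sister_leaves = frozenset().union(*[_leafset(s) | (
        frozenset([s.taxon.label]) if s.is_leaf() else frozenset()
    ) for s in sisters]) if sisters else frozenset()
    support = (
        float(mrca.label) if (not mrca.is_leaf() and mrca.label is not None)
        else None
    )
    if support is None and mrca.parent_node.label is not None:
        # single-leaf recipient: fall back to the edge uniting it with its
        # sister, the smallest internal edge relevant to the placement
        support = float(mrca.parent_node.label)
    return RecipientClade(
        clade_leaves=clade,
        sister_lineages=Counter(lineage_map[n] for n in sister_leaves),
        support=support,
        spans_root=False,
        intruders=frozenset(n for n in clade if n not in recipients),
    )


def classify_support(
    support: float | None, well_min: float = 90.0, weak_min: float = 60.0
) -> str:
    """well_supported (>= well_min), weakly_supported ([weak_min, well_min))
    or none (below weak_min or absent)."""
    if support is None:
        return "none"
    if not 0 <= support <= 100:
        raise ValueError(f"support {support} outside [0, 100]")
    if support >= well_min:
        return "well_supported"
    if support >= weak_min:
        return "weakly_supported"
    return "none"


def sharing_category(
    clade: RecipientClade,
    tree: SupportTree,
    lineage_map: Mapping[str, str],
    intron_flag: bool,
    max_intruders: int = 0,
) -> tuple[str, bool, int]:
    """(category, glauco_monophyletic, n_glauco_species) for a recipient
    clade; ``other`` for anything outside the four sharing patterns."""
    if clade.spans_root:
        return "other", False, 0
    if len(clade.intruders) > max_intruders:
        return "other", False, 0
    lineages = {lineage_map[n] for n in clade.clade_leaves} & set(ARCHAEPLASTIDA)
    glauco = [
        n for n in clade.clade_leaves if lineage_map[n] == "Glaucophyta"
    ]
    n_glauco = len(glauco)
    glauco_mono = (
        check_monophyly(tree, glauco)[0] if n_glauco >= 1 else False
    )
    if lineages == set(ARCHAEPLASTIDA):
        return "all_archaeplastida", glauco_mono, n_glauco
    if lineages == {"Glaucophyta", "Viridiplantae"}:
        return "green_shared", glauco_mono, n_glauco
    if lineages == {"Glaucophyta", "Rhodophyta"}:
        return "red_shared", glauco_mono, n_glauco
    if lineages == {"Glaucophyta"}:
        if n_glauco >= 2 and glauco_mono and intron_flag:
            return "glaucophyte_specific", glauco_mono, n_glauco
    return "other", glauco_mono, n_glauco


@dataclass
class HgtCall:
    """One tree's classification with its audit trail."""

    tree_id: str
    donor: str | None
    support_value: float | None
    support_class: str
    sharing: str
    glauco_monophyletic: bool
    n_glauco_species: int
    has_introns: bool
    placement: str  # sister | nested | none
    sister_composition: dict[str, int]


def classify_tree(
    tree: SupportTree,
    lineage_map: Mapping[str, str],
    intron_flag: bool,
    tree_id: str = "",
    well_min: float = 90.0,
    weak_min: float = 60.0,
    max_intruders: int = 0,
) -> HgtCall:
    """Full classification: donor detection, support class and sharing
    category.  Pure function of (topology, supports, lineage map, intron
    flag)."""
    missing = set(tree.leaf_names) - set(lineage_map)
    if missing:
        raise KeyError(f"leaves without lineage: {sorted(missing)}")
    clade = recipient_clade(tree, lineage_map)
    sis = clade.sister_lineages
    donor = None
    placement = "none"
    if sis and set(sis) == {"Chlamydiae"}:
        donor = "Chlamydiae"
        placement = "sister"
    elif sis and "Chlamydiae" in sis and clade.support is not None:
        # nested placement: everything else inside the enclosing clade is
        # chlamydial even though the immediate sister is mixed
        non_chlam = sum(v for k, v in sis.items() if k != "Chlamydiae")
        if non_chlam == 0:
            donor = "Chlamydiae"
            placement = "nested"
    if donor is None:
        support_class = "none"
        sharing = "other"
        glauco_mono, n_glauco = False, 0
    else:
        support_class = classify_support(clade.support, well_min, weak_min)
        sharing, glauco_mono, n_glauco = sharing_category(
            clade, tree, lineage_map, intron_flag, max_intruders
        )
    return HgtCall(
        tree_id=tree_id,
        donor=donor,
        support_value=clade.support,
        support_class=support_class,
        sharing=sharing,
        glauco_monophyletic=glauco_mono,
        n_glauco_species=n_glauco,
        has_introns=intron_flag,
        placement=placement,
        sister_composition=dict(sis),
    )


def classify_batch(
    items: Iterable[tuple[str, SupportTree, Mapping[str, str], bool]],
    well_min: float = 90.0,
    weak_min: float = 60.0,
) -> pd.DataFrame:
    """Classify (tree_id, tree, lineage_map, intron_flag) items; returns a
    one-row-per-tree table with a ``sharing`` category column."""
    calls = [
        classify_tree(
            tree, lmap, introns, tree_id=tid,
            well_min=well_min, weak_min=weak_min,
        )
        for tid, tree, lmap, introns in items
    ]
    return pd.DataFrame(
        [
            dict(
                tree_id=c.tree_id,
                donor=c.donor or "",
                support=c.support_value,
                support_class=c.support_class,
                sharing=c.sharing,
                glauco_monophyletic=c.glauco_monophyletic,
                n_glauco_species=c.n_glauco_species,
                has_introns=c.has_introns,
                placement=c.placement,
            )
            for c in calls
        ]
    ).set_index("tree_id")
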