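"""Dollo-parsimony dating of cluster members on a species tree.

Each member gains once, at the most recent common ancestor of the species
with expression-verified homologs, and may be lost independently on any
number of descendant branches.  Losses are placed minimally: one loss on
the stem of every maximal all-absent subtree under the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import GenomicInterval, SpeciesTree


@dataclass(frozen=True)
class OriginationResult:
    member: str
    origin: str
    losses: frozenset[str]  # branch ids (child-node ids)
    age_class: str  # "new" | "old"


def infer_origin(presence: pd.DataFrame, tree: SpeciesTree, member: str) -> str:
    """MRCA of the species where *member* is expression-verified.

    *presence* is a boolean members x species frame.  A single-species
    member maps to that leaf (its terminal branch).
    """
    row = presence.loc[member]
    present = [sp for sp in presence.columns if bool(row[sp])]
    if not present:
        raise ValueError(f"{member}: no species with verified expression")
    missing = set(present) - set(tree.leaves)
    if missing:
        raise ValueError(f"{member}: species not in tree: {sorted(missing)}")
    return tree.mrca(present)


def infer_losses(
    presence: pd.DataFrame, tree: SpeciesTree, member: str, origin: str | None = None
) -> frozenset[str]:
    """Minimal loss-branch set under Dollo parsimony.

    Marks the stem branch of every maximal subtree (under the origin) whose
    scored leaves are all absent.  Tree leaves without a column in the
    presence matrix are ignored.
    """
    if origin is None:
        origin = infer_origin(presence, tree, member)
    row = presence.loc[member]
    scored = set(presence.columns) & set(tree.leaves)

    # all_absent[node]: every scored leaf below is FALSE (and >= 1 scored leaf)
    all_absent: dict[str, bool] = {}
    has_scored: dict[str, bool] = {}
    for node in tree.nodes():
        leaves = tree.leaf_labels(node) & scored
        has_scored[node] = bool(leaves)
        all_absent[node] = bool(leaves) and not any(bool(row[sp]) for sp in leaves)

    losses: set[str] = set()
    stack = list(tree.children(origin)) if not tree.is_leaf(origin) else []
    while stack:
        node = stack.pop()
        if not has_scored[node]:
            continue
        if all_absent[node]:
            losses.add(node)
        else:
            stack.extend(tree.children(node))
    return frozenset(losses)


def classify_age(
    tree: SpeciesTree, origin: str, reference_split: str, ingroup_species: str
) -> str:
    """Classify a member as "new" or "old" relative to a reference split.

    "new" when the origin lies within the subtree rooted at the
    reference-split child containing *ingroup_species* (inclusive of that
    child itself); "old" otherwise.
    """
    if origin not in tree:
        raise ValueError(f"origin node {origin!r} not in tree")
    if reference_split not in tree:
        raise ValueError(f"reference split {reference_split!r} not in tree")
    ingroup_child = None
    for child in tree.children(reference_split):
        if ingroup_species in tree.leaf_labels(child):
            ingroup_child = child
            break
    if ingroup_child is None:
        raise ValueError(
            f"{ingroup_species!r} not under reference split {reference_split!r}"
        )
    return "new" if tree.is_descendant(origin, ingroup_child) else "old"


def date_members(
    presence: pd.DataFrame,
    tree: SpeciesTree,
    reference_split: str,
    ingroup_species: str,
) -> list[OriginationResult]:
    """Origin, losses and age class for every member of the matrix."""
    out = []
    for member in presence.index:
        origin = infer_origin(presence, tree, member)
        losses = infer_losses(presence, tree, member, origin)
        age = classify_age(tree, origin, reference_split, ingroup_species)
        out.append(OriginationResult(member, origin, losses, age))
    return out


@dataclass(frozen=True)
class SubCluster:
    members: tuple[str, ...]
    span: GenomicInterval

    @property
    def is_orphan(self) -> bool:
        return len(self.members) == 1


def subcluster(
    loci: list[tuple[str, GenomicInterval]], max_gap: int = 1000
) -> list[SubCluster]:
    """Group loci into sub-clusters by single-linkage gap chaining.

    Adjacent loci join one group when the gap between them is <= *max_gap*
    nt.  Overlapping loci are treated as gap 0 (with a warning).  Loci must
    lie on one chromosome and strand.
    """
    if not loci:
        return []
    chroms = {iv.chrom for _, iv in loci}
    strands = {iv.strand for _, iv in loci}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("loci must be on a single chromosome and strand")

    ordered = sorted(loci, key=lambda x: (x[1].start, x[1].end))
    groups: list[list[tuple[str, GenomicInterval]]] = [[ordered[0]]]
    for name, iv in ordered[1:]:
        prev_end = max(i.end for _, i in groups[-1])
        gap = iv.start - prev_end
        if gap < 0:
            warnings.warn(f"overlapping loci near {name}; treated as gap 0")
            gap = 0
        if gap <= max_gap:
            groups[-1].append((name, iv))
        else:
            groups.append([(name, iv)])

    out = []
    for grp in groups:
        names = tuple(n for n, _ in grp)
        start = min(i.start for _, i in grp)
        end = max(i.end for _, i in grp)
        chrom = grp[0][1].chrom
        strand = grp[0][1].strand
        out.append(SubCluster(names, GenomicInterval(chrom, start, end, strand)))
    return out
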