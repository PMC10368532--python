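"""Tumor progression sample trees from shared somatic mutations.

Each tumor-bearing animal contributes several samples (primary regions,
metastases, derived cell lines). The pairwise distance between two samples
is one minus the fraction of nondriver somatic mutations they share out of
all mutations carried by either (i.e. the Jaccard distance on mutation-key
sets; this shared-over-union similarity is sometimes labelled a
"hamming" similarity in the tumor-phylogeny literature). Samples are joined by agglomerative
hierarchical clustering with complete (maximum) linkage, zero-length
internal branches are collapsed into polytomies, and every mutation is
assigned to the single branch whose descendant leaves all carry it:
mutations on the root branch are truncal, on a leaf branch private, and on
any intermediate branch shared.

Agglomeration is implemented directly (O(n^3), n = samples per animal is
small) so tie-breaking can be made deterministic: among equally distant
cluster pairs the pair whose sorted member tuple is lexicographically
smallest merges first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "SampleVariantSet",
    "complete_linkage",
    "TreeNode",
    "SampleTree",
    "BranchAssignment",
    "pair_distance",
    "build_tree",
    "collapse_zero_branches",
    "assign_branches",
    "truncal_private_fractions",
    "variant_sets_from_calls",
]

MutationKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class SampleVariantSet:
    """Nondriver somatic mutation keys carried by one sample."""

    sample: str
    mouse: str
    site_class: str  # primary | metastasis | cell-line
    keys: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "keys", frozenset(self.keys))


def variant_sets_from_calls(
    calls_by_sample: Mapping[str, Sequence],
    mouse_of: Mapping[str, str],
    site_class_of: Mapping[str, str],
    min_alt_reads: int = 2,
) -> list[SampleVariantSet]:
    """Union re-genotyping: a mutation is present in a sample when its
    re-derived support there is at least ``min_alt_reads`` alt reads, so a
    truncal mutation narrowly missed by the caller in one sample is not
    spuriously privatized."""
    out = []
    for sample, calls in calls_by_sample.items():
        keys = frozenset(v.key for v in calls if v.tumor_alt >= min_alt_reads)
        out.append(
            SampleVariantSet(sample, mouse_of[sample], site_class_of[sample], keys)
        )
    return out


def pair_distance(set_a: frozenset, set_b: frozenset) -> float:
    """Jaccard distance 1 - |A n B| / |A u B|; two empty sets are at
    distance 0 by convention."""
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return 1.0 - len(set_a & set_b) / union


@dataclass(frozen=True)
class TreeNode:
    """A dendrogram node: leaves carry a sample name at height 0; internal
    nodes carry the merge height and their children."""

    height: float
    children: tuple["TreeNode", ...] = ()
    name: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.name,)
        return tuple(sorted(l for c in self.children for l in c.leaves))


@dataclass
class SampleTree:
    root: TreeNode
    mouse: str

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.root.leaves

    def nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out


def build_tree(samples: Sequence[SampleVariantSet]) -> SampleTree:
    """Complete-linkage agglomeration over the pairwise Jaccard distances.

    Deterministic: among tied minimum-distance cluster pairs, the pair whose
    sorted member-name tuple compares lexicographically smallest merges
    first. Merge heights are the complete-linkage (maximum) leaf distances
    and are non-decreasing toward the root.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to build a tree")
    mice = {s.mouse for s in samples}
    if len(mice) != 1:
        raise ValueError(f"samples span multiple mice: {sorted(mice)}")
    names = [s.sample for s in samples]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample ids")
    dist = {
        frozenset((a.sample, b.sample)): pair_distance(a.keys, b.keys)
        for i, a in enumerate(samples)
        for b in samples[i + 1 :]
    }
    root = complete_linkage(names, dist)
    return SampleTree(root=root, mouse=next(iter(mice)))


def complete_linkage(
    names: Sequence[str], dist: Mapping[frozenset, float]
) -> TreeNode:
    """Agglomerate leaves under complete (maximum) linkage.

    ``dist`` maps each unordered leaf pair (as a frozenset) to its distance.
    Ties in the minimum inter-cluster distance break toward the pair whose
    combined, sorted member tuple is lexicographically smallest.
    """
    clusters: dict[tuple[str, ...], TreeNode] = {
        (n,): TreeNode(height=0.0, name=n) for n in names
    }
    while len(clusters) > 1:
        members = sorted(clusters)
        best = None
        for i, ca in enumerate(members):
            for cb in members[i + 1 :]:
                d = max(dist[frozenset((x, y))] for x in ca for y in cb)
                key = (d, tuple(sorted(ca + cb)))
                if best is None or key < best[0]:
                    best = (key, ca, cb)
        (d, _), ca, cb = best
        merged = tuple(sorted(ca + cb))
        clusters[merged] = TreeNode(
            height=d, children=(clusters.pop(ca), clusters.pop(cb))
        )
    return next(iter(clusters.values()))


def collapse_zero_branches(tree: SampleTree, tol: float = 1e-12) -> SampleTree:
    """Contract internal edges of length <= tol into polytomies; leaves are
    never removed."""

    def collapse(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            return node
        new_children: list[TreeNode] = []
        for child in (collapse(c) for c in node.children):
            if not child.is_leaf and abs(node.height - child.height) <= tol:
                new_children.extend(child.children)
            else:
                new_children.append(child)
        return TreeNode(height=node.height, children=tuple(new_children))

    return SampleTree(root=collapse(tree.root), mouse=tree.mouse)


@dataclass
class BranchAssignment:
    """Branch (identified by its descendant leaf set) -> mutation keys, plus
    the per-mutation category and any topology conflicts encountered."""

    by_branch: dict[frozenset, set]
    category: dict  # mutation key -> "truncal" | "shared" | "private"
    conflicts: list  # (key, carrier frozenset, assigned clade frozenset)

    @property
    def truncal_keys(self) -> set:
        return {k for k, c in self.category.items() if c == "truncal"}

    @property
    def private_keys(self) -> set:
        return {k for k, c in self.category.items() if c == "private"}


def assign_branches(
    tree: SampleTree, samples: Sequence[SampleVariantSet]
) -> BranchAssignment:
    """Assign every mutation to exactly one branch of the tree.

    A mutation carried by carrier set S goes to the branch above the largest
    clade whose leaves are all in S (only mutations detected in all
    descendants of a branch count for that branch). When S is itself a
    clade the assignment is exact; otherwise the largest contained clade is
    used and the conflict is recorded. Root branch = truncal, leaf branch =
    private, anything between = shared.
    """
    leaf_names = set(tree.leaves)
    sample_names = {s.sample for s in samples}
    if leaf_names != sample_names:
        raise ValueError("tree leaves do not match the sample set")
    clades = sorted(
        {frozenset(n.leaves) for n in tree.nodes()},
        key=lambda c: (-len(c), tuple(sorted(c))),
    )
    all_leaves = frozenset(leaf_names)
    carriers: dict = {}
    for s in samples:
        for k in s.keys:
            carriers.setdefault(k, set()).add(s.sample)
    by_branch: dict[frozenset, set] = {}
    category: dict = {}
    conflicts = []
    for key, carrier in carriers.items():
        if not carrier:
            raise ValueError(f"mutation {key} carried by zero samples")
        carrier = frozenset(carrier)
        clade = next(c for c in clades if c <= carrier)  # singletons guarantee a hit
        if clade != carrier:
            conflicts.append((key, carrier, clade))
        by_branch.setdefault(clade, set()).add(key)
        if clade == all_leaves:
            category[key] = "truncal"
        elif len(clade) == 1:
            category[key] = "private"
        else:
            category[key] = "shared"
    return BranchAssignment(by_branch, category, conflicts)


def truncal_private_fractions(
    assignment: BranchAssignment, samples: Sequence[SampleVariantSet]
) -> pd.DataFrame:
    """Per site class (primary / metastasis / cell-line), the fraction of
    that class's mutations that are truncal, shared and private. A class's
    mutations are the union over its samples; fractions sum to 1. Classes
    with no mutations are omitted (no-call)."""
    rows = []
    classes = sorted({s.site_class for s in samples})
    for cls in classes:
        keys = set().union(*(s.keys for s in samples if s.site_class == cls), set())
        if not keys:
            continue
        n = len(keys)
        counts = {"truncal": 0, "shared": 0, "private": 0}
        for k in keys:
            counts[assignment.category[k]] += 1
        rows.append(
            {
                "site_class": cls,
                "n_mutations": n,
                "truncal": counts["truncal"] / n,
                "shared": counts["shared"] / n,
                "private": counts["private"] / n,
            }
        )
    return pd.DataFrame(rows)
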