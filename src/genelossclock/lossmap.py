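"""Dollo-parsimony placement of gene losses on a rooted species tree.

Each near-core pangene is assumed present at the ingroup root and never
regained; a single post-order pass labels a node absent iff all leaves
below it lack the gene, and the loss branches are those leading into
maximal absent subtrees. Under the present-at-root / no-regain model this
set is the unique minimum-cardinality explanation of the presence
pattern. Pangenes lost on one branch are 'single loss', on two or more
branches 'multiple loss'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trees import Tree


@dataclass
class LossAssignment:
    pangene_id: str
    loss_branches: frozenset[str]
    no_loss: bool = False  # flagged when every leaf carries the gene

    @property
    def loss_count(self) -> int:
        return len(self.loss_branches)

    @property
    def loss_class(self) -> str | None:
        if self.no_loss or not self.loss_branches:
            return None
        return "single_loss" if self.loss_count == 1 else "multiple_loss"


@dataclass
class BranchProfile:
    branch_id: str
    n_losses: int = 0
    ads: float | None = None  # filled in by the branch-dS analysis
    length: float = 0.0
    extra: dict = field(default_factory=dict)


def dollo_place(tree: Tree, presence: dict[str, bool], pangene_id: str = "") -> LossAssignment:
    """Minimum Dollo loss set for one presence/absence pattern.

    ``presence`` maps every leaf name to True (gene present) or False.
    All-present patterns return an empty, flagged assignment; all-absent
    patterns violate the present-at-root assumption and raise.
    """
    leaves = tree.leaf_names()
    missing = set(leaves) - set(presence)
    if missing:
        raise ValueError(f"presence vector missing leaves: {sorted(missing)}")
    if all(presence[l] for l in leaves):
        return LossAssignment(pangene_id, frozenset(), no_loss=True)
    if not any(presence[l] for l in leaves):
        raise ValueError("gene absent from every leaf: not a loss pattern")
    absent: dict[str, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            absent[node.id] = not presence[node.id]
        else:
            absent[node.id] = all(absent[c.id] for c in node.children)
    losses = {
        node.id
        for node in tree.branches()
        if absent[node.id] and not absent[node.parent.id]
    }
    return LossAssignment(pangene_id, frozenset(losses))


def classify_losses(assignments: list[LossAssignment]) -> dict[str, int]:
    """Counts of single- vs multiple-loss pangenes."""
    counts = {"single_loss": 0, "multiple_loss": 0}
    for a in assignments:
        cls = a.loss_class
        if cls is None:
            raise ValueError(f"{a.pangene_id or 'pangene'} carries no loss")
        counts[cls] += 1
    return counts


def branch_loss_table(assignments: list[LossAssignment], tree: Tree) -> list[BranchProfile]:
    """Per-branch loss counts; sums to the total loss count over pangenes."""
    profiles = {n.id: BranchProfile(n.id, length=n.length) for n in tree.branches()}
    for a in assignments:
        for bid in a.loss_branches:
            if bid not in profiles:
                raise ValueError(f"loss branch {bid!r} not in tree")
            profiles[bid].n_losses += 1
    return [profiles[n.id] for n in tree.branches()]
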