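"""Dollo (loss-only) reconstruction of ancestral gene content.

Under Dollo parsimony an intact gene can be lost any number of times on a
species tree but never regained.  The minimal loss history then has a
closed form: an ancestral node possessed the gene iff at least one of its
descendant leaves does, and each edge from a possessing parent to a
non-possessing child is one loss event.  Losses on internal edges are
"stem" (bottleneck) events inherited by the whole descendant clade; losses
on terminal edges are recent, species-specific events.

``brute_force_min_losses`` enumerates every loss-only history explicitly
and serves as an independent oracle for small trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import pandas as pd

from .statuses import GeneStatusMatrix, presence_vector
from .tree import SpeciesTree, TreeNode


@dataclass(frozen=True)
class LossEvent:
    gene: str
    branch: tuple[Optional[str], Optional[str]]  # (parent label, child label)
    affected_leaves: frozenset[str]
    kind: str = ""  # "stem" | "terminal" (set by label_bottlenecks)
    age_interval: Optional[tuple[float, float]] = None


@dataclass
class AncestralStates:
    gene: str
    states: dict[int, str]  # id(node) -> "present" | "absent"
    loss_events: list[LossEvent] = field(default_factory=list)

    @property
    def n_losses(self) -> int:
        return len(self.loss_events)


def _node_key(node: TreeNode, i: int) -> str:
    return node.label or f"node{i}"


def dollo_reconstruct(
    tree: SpeciesTree,
    presence: dict[str, str],
    gene: str = "gene",
    assert_root_presence: bool = False,
) -> AncestralStates:
    """Minimal loss-only history for one gene.

    ``presence`` maps every leaf label to ``present``/``absent`` (unknowns
    must have been dropped, with the tree pruned accordingly).  With no
    present leaf the history is unidentifiable unless
    ``assert_root_presence`` forces a present root (then the whole tree is
    one loss at the root's children — reported as a single event on a
    virtual root edge spanning all leaves).
    """
    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in presence]
    if missing:
        raise ValueError(f"no presence value for leaves: {missing}")
    bad = {v for v in presence.values()} - {"present", "absent"}
    if bad:
        raise ValueError(f"presence values must be present/absent, got {bad}")

    any_present = any(presence[l] == "present" for l in leaves)
    if not any_present and not assert_root_presence:
        raise ValueError(
            f"gene {gene!r}: no evidence of ancestral presence "
            "(all leaves absent); pass assert_root_presence=True to force"
        )

    states: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_leaf:
            states[id(node)] = presence[node.label]
        else:
            states[id(node)] = (
                "present"
                if any(states[id(c)] == "present" for c in node.children)
                else "absent"
            )

    result = AncestralStates(gene=gene, states=states)

    if not any_present:
        # forced-root interpretation: one loss on the edge above the root
        result.states[id(tree.root)] = "absent"
        result.loss_events.append(
            LossEvent(
                gene=gene,
                branch=(None, tree.root.label or "root"),
                affected_leaves=frozenset(leaves),
            )
        )
        return result

    node_names = {id(n): _node_key(n, i) for i, n in enumerate(tree.postorder())}
    for node in tree.preorder():
        for child in node.children:
            if states[id(node)] == "present" and states[id(child)] == "absent":
                result.loss_events.append(
                    LossEvent(
                        gene=gene,
                        branch=(node_names[id(node)], node_names[id(child)]),
                        affected_leaves=frozenset(
                            l.label for l in SpeciesTree.subtree_leaves(child)
                        ),
                    )
                )
    return result


def brute_force_min_losses(tree: SpeciesTree, presence: dict[str, str]) -> int:
    """Exhaustive oracle: minimum number of present->absent edges over all
    internal-state assignments with a present root and no absent->present
    edge, consistent with the leaf data.  Trees up to 12 leaves only."""
    leaves = tree.leaves()
    if len(leaves) > 12:
        raise ValueError("brute force limited to 12 leaves")
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaf_state = {id(l): presence[l.label] for l in leaves}
    best: Optional[int] = None
    for assignment in product(("present", "absent"), repeat=len(internals)):
        states = dict(leaf_state)
        states.update({id(n): s for n, s in zip(internals, assignment)})
        if states[id(tree.root)] != "present":
            continue
        losses = 0
        ok = True
        for node in internals:
            for child in node.children:
                ps, cs = states[id(node)], states[id(child)]
                if ps == "absent" and cs == "present":
                    ok = False
                    break
                if ps == "present" and cs == "absent":
                    losses += 1
            if not ok:
                break
        if ok and (best is None or losses < best):
            best = losses
    if best is None:
        raise ValueError("no admissible loss-only history (all leaves absent?)")
    return best


def label_bottlenecks(
    ancestral: AncestralStates, tree: SpeciesTree
) -> list[LossEvent]:
    """Classify each loss as a stem (internal branch, clade-wide) or
    terminal (single species) event; annotate with the branch's age
    interval (distance-from-root of parent and child) when branch lengths
    are available."""
    have_lengths = all(
        n.length is not None for n in tree.postorder() if n is not tree.root
    )
    depths = tree.depths() if have_lengths else None
    # same postorder numbering as dollo_reconstruct
    node_names = {id(n): _node_key(n, i) for i, n in enumerate(tree.postorder())}
    nodes_by_name = {v: k for k, v in node_names.items()}
    id_to_node = {id(n): n for n in tree.postorder()}

    labelled = []
    for ev in ancestral.loss_events:
        child_name = ev.branch[1]
        child_id = nodes_by_name.get(child_name)
        child = id_to_node.get(child_id) if child_id else None
        kind = "terminal" if (child is not None and child.is_leaf) else "stem"
        if child is not None and not child.is_leaf and len(
            SpeciesTree.subtree_leaves(child)
        ) < 2:  # pragma: no cover - internal nodes always have >= 2 leaves
            kind = "terminal"
        age = None
        if depths is not None and child is not None and child.parent is not None:
            age = (depths[id(child.parent)], depths[id(child)])
        labelled.append(
            LossEvent(
                gene=ev.gene,
                branch=ev.branch,
                affected_leaves=ev.affected_leaves,
                kind=kind,
                age_interval=age,
            )
        )
    return labelled


def gene_content_report(
    matrix: GeneStatusMatrix,
    tree: SpeciesTree,
    policy: str = "drop",
    assert_root_presence: bool = False,
) -> pd.DataFrame:
    """Minimal gene content of every ancestral node under Dollo.

    Returns a node x gene table of ``present``/``absent``; internal nodes
    are named by their label or ``node<i>`` (postorder numbering).
    EXCLUDED species are dropped (default policy) and the tree pruned to
    the remaining leaves per gene.
    """
    genes = matrix.genes
    if not genes:
        raise ValueError("status matrix is empty")
    node_names = {id(n): _node_key(n, i) for i, n in enumerate(tree.postorder())}
    rows: dict[str, dict[str, str]] = {
        name: {} for name in node_names.values()
    }
    for gene in genes:
        pres = presence_vector(matrix, gene, policy=policy)
        known = {s: v for s, v in pres.items() if v != "unknown"}
        if not any(v == "present" for v in known.values()) and not assert_root_presence:
            raise ValueError(
                f"gene {gene!r}: no evidence of ancestral presence"
            )
        # Dollo closed form on the full tree: a node possesses the gene iff
        # >= 1 known-present descendant leaf (unknown/dropped leaves carry
        # no evidence either way)
        states: dict[int, str] = {}
        for node in tree.postorder():
            if node.is_leaf:
                states[id(node)] = known.get(node.label, "absent")
            else:
                states[id(node)] = (
                    "present"
                    if any(states[id(c)] == "present" for c in node.children)
                    else "absent"
                )
        for node in tree.postorder():
            rows[node_names[id(node)]][gene] = states[id(node)]
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "node"
    return frame[genes]


def render_ascii_content(
    tree: SpeciesTree, content: pd.DataFrame
) -> str:
    """ASCII cladogram with each node's present-gene set appended."""

    def genes_at(name: str) -> str:
        if name not in content.index:
            return ""
        present = [g for g in content.columns if content.loc[name, g] == "present"]
        return "{" + ",".join(present) + "}"

    lines: list[str] = []
    node_names = {id(n): _node_key(n, i) for i, n in enumerate(tree.postorder())}

    def walk(node: TreeNode, prefix: str, is_last: bool) -> None:
        connector = "" if node.parent is None else ("`-- " if is_last else "|-- ")
        name = node_names[id(node)]
        lines.append(f"{prefix}{connector}{name} {genes_at(name)}".rstrip())
        child_prefix = prefix + ("" if node.parent is None else ("    " if is_last else "|   "))
        for i, child in enumerate(node.children):
            walk(child, child_prefix, i == len(node.children) - 1)

    walk(tree.root, "", True)
    return "\n".join(lines)
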