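"""Haplogroup assignment by walking a Y-SNP phylogeny.

A sample's genotype is placed at the deepest node whose defining SNPs are
observed derived; missing calls are uninformative (never contradictory),
derived calls on incompatible branches yield an ambiguous call, and a
genotype with no derived allele anywhere is unassigned.  Assignments to an
internal node whose tested children are all ancestral are rendered in the
exclusion notation, e.g. ``NO-M214(xM175)``.  Sub-haplogroup calls can be
backmerged to a fixed set of major clades for cross-cohort tabulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["TreeNode", "YTree", "HaplogroupCall", "load_tree", "assign_haplogroup", "backmerge", "render_label"]

logger = logging.getLogger(__name__)

MISSING = "."


@dataclass
class TreeNode:
    name: str
    snps: list[tuple[str, str, str]]  # (snp_id, ancestral, derived)
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d


class YTree:
    """Rooted haplogroup tree with per-node defining SNPs."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: dict[str, TreeNode] = {}
        self.snp_to_node: dict[str, TreeNode] = {}
        self.snp_alleles: dict[str, tuple[str, str]] = {}
        for node in self.walk():
            if node.name in self.nodes:
                raise ValueError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node
            for snp_id, anc, der in node.snps:
                if snp_id in self.snp_to_node:
                    raise ValueError(f"SNP {snp_id!r} defined on two nodes")
                self.snp_to_node[snp_id] = node
                self.snp_alleles[snp_id] = (anc, der)

    def walk(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def path_to_root(self, name: str) -> list[TreeNode]:
        """Node and its ancestors, deepest first, root last."""
        node = self.nodes[name]
        path = [node]
        while node.parent is not None:
            node = node.parent
            path.append(node)
        return path

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        return self.nodes[ancestor] in self.path_to_root(descendant)

    @property
    def panel(self) -> list[str]:
        return list(self.snp_to_node)


def load_tree(path) -> YTree:
    """Parse the indented tree text format (two spaces per level; each line
    ``name snp:anc>der ...``)."""
    root: TreeNode | None = None
    stack: list[tuple[int, TreeNode]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            stripped = raw.lstrip(" ")
            indent = len(raw) - len(stripped)
            if indent % 2:
                raise ValueError(f"line {lineno}: odd indentation")
            level = indent // 2
            fields = stripped.split()
            snps = []
            for spec in fields[1:]:
                try:
                    snp_id, alleles = spec.split(":")
                    anc, der = alleles.split(">")
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: bad SNP spec {spec!r} (want id:anc>der)"
                    ) from None
                snps.append((snp_id, anc, der))
            node = TreeNode(name=fields[0], snps=snps)
            if level == 0:
                if root is not None:
                    raise ValueError("multiple root nodes")
                root = node
            else:
                while stack and stack[-1][0] >= level:
                    stack.pop()
                if not stack:
                    raise ValueError(f"line {lineno}: orphan node {node.name!r}")
                parent = stack[-1][1]
                node.parent = parent
                parent.children.append(node)
            stack.append((level, node))
    if root is None:
        raise ValueError(f"{path}: empty tree")
    return YTree(root)


@dataclass(frozen=True)
class HaplogroupCall:
    """Result of placing one genotype on the tree."""

    status: str  # assigned | internal_with_exclusion | ambiguous | unassigned | excluded_internal
    node: str | None
    excluded_children: tuple[str, ...] = ()
    n_supporting: int = 0
    conflicting: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        if self.node is None:
            return self.status
        return render_label(self.node, self.excluded_children)


def render_label(node: str, excluded_children: Iterable[str] = ()) -> str:
    """Exclusion notation: node NO-M214 with child O-M175 ancestral is
    rendered ``NO-M214(xM175)``."""
    excluded = list(excluded_children)
    if not excluded:
        return node
    marks = ",".join("x" + c.split("-", 1)[-1] for c in excluded)
    return f"{node}({marks})"


def _node_status(node: TreeNode, genotype: Mapping[str, str]) -> str:
    """positive (>=1 derived), negative (no derived, >=1 ancestral), or
    unknown (all missing/absent).  A mixed node counts positive."""
    derived = ancestral = 0
    for snp_id, anc, der in node.snps:
        allele = genotype.get(snp_id, MISSING)
        if allele in (MISSING, "", None):
            continue
        if allele == der:
            derived += 1
        elif allele == anc:
            ancestral += 1
    if derived:
        return "positive"
    if ancestral:
        return "negative"
    return "unknown"


def assign_haplogroup(genotype: Mapping[str, str], tree: YTree) -> HaplogroupCall:
    """Place a genotype at the deepest consistent node of the tree.

    SNP ids absent from the tree are ignored with a logged warning.
    """
    for snp_id in genotype:
        if snp_id not in tree.snp_alleles:
            logger.warning("SNP %s not in tree; ignored", snp_id)

    status = {node.name: _node_status(node, genotype) for node in tree.walk()}
    positives = [tree.nodes[n] for n, s in status.items() if s == "positive"]
    if not positives:
        return HaplogroupCall(status="unassigned", node=None)

    deepest = max(positives, key=lambda n: n.depth)
    path = {n.name for n in tree.path_to_root(deepest.name)}

    # Derived evidence on a branch disjoint from the deepest path -> ambiguous.
    off_path = [n.name for n in positives if n.name not in path]
    # An ancestral call on the path beneath which derived calls exist is a
    # conflict as well.
    negated_on_path = [
        n for n in tree.path_to_root(deepest.name) if status[n.name] == "negative"
    ]
    if off_path or negated_on_path:
        conflicting = tuple(sorted(off_path + [n.name for n in negated_on_path]))
        return HaplogroupCall(
            status="ambiguous", node=None, conflicting=conflicting
        )

    n_supporting = sum(
        1
        for node in tree.path_to_root(deepest.name)
        for snp_id, _anc, der in node.snps
        if genotype.get(snp_id) == der
    )
    excluded = tuple(
        sorted(
            child.name
            for child in deepest.children
            if child.snps
            and all(
                genotype.get(snp_id, MISSING) == anc
                for snp_id, anc, _der in child.snps
            )
        )
    )
    if deepest.children and excluded:
        return HaplogroupCall(
            status="internal_with_exclusion",
            node=deepest.name,
            excluded_children=excluded,
            n_supporting=n_supporting,
        )
    return HaplogroupCall(
        status="assigned", node=deepest.name, n_supporting=n_supporting
    )


def backmerge(
    call: HaplogroupCall, tree: YTree, major_set: Iterable[str]
) -> HaplogroupCall:
    """Collapse a sub-haplogroup call to its nearest major-clade ancestor.

    Calls at nodes that are strict ancestors of majors (and not majors
    themselves) cannot be resolved to a single major and are flagged
    ``excluded_internal``; ambiguous/unassigned calls pass through; calls
    already at a major are unchanged (idempotent).
    """
    majors = set(major_set)
    unknown = majors - set(tree.nodes)
    if unknown:
        raise ValueError(f"major clade(s) not in tree: {sorted(unknown)}")
    if call.status in ("ambiguous", "unassigned", "excluded_internal"):
        return call
    assert call.node is not None
    node = tree.nodes[call.node]

    def has_major_below(n: TreeNode) -> bool:
        stack = list(n.children)
        while stack:
            child = stack.pop()
            if child.name in majors:
                return True
            stack.extend(child.children)
        return False

    if has_major_below(node):
        # The call sits above at least one major.  It resolves to the node
        # itself only if the node is a major and every downstream branch
        # towards deeper majors was observed ancestral (the exclusion
        # notation, e.g. NO-M214(xM175)); otherwise no single major can be
        # chosen and the sample is excluded from tabulation.
        resolvable = call.node in majors and all(
            child.name in call.excluded_children
            for child in node.children
            if child.name in majors or has_major_below(child)
        )
        if resolvable:
            return call
        return HaplogroupCall(
            status="excluded_internal",
            node=call.node,
            excluded_children=call.excluded_children,
            n_supporting=call.n_supporting,
        )
    for ancestor in tree.path_to_root(call.node):
        if ancestor.name in majors:
            if ancestor.name == call.node:
                return call
            return HaplogroupCall(
                status=call.status,
                node=ancestor.name,
                excluded_children=(),
                n_supporting=call.n_supporting,
            )
    return HaplogroupCall(
        status="excluded_internal",
        node=call.node,
        excluded_children=call.excluded_children,
        n_supporting=call.n_supporting,
    )
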