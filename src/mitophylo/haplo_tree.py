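"""Maximum-parsimony haplogroup trees, clade motifs and haplogroup assignment.

The builder formalizes the manual curation practice of the mtDNA
phylogenetics community as a weighted greedy perfect-phylogeny
construction: each distinct variant is a binary character; characters are
laid down in order of descending weight and carrier count, so a
conflict-free matrix yields the unique perfect phylogeny (with polytomies
preserved), while conflicting minority characters recur as repeat events.
Known hypermutable sites can be down-weighted through the weight table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .mito_io import Variant, format_variant
from .variant_scoring import HaplotypeProfile

logger = logging.getLogger(__name__)


class CladeNode:
    """A node of the haplogroup tree.

    ``edge_variants`` are the mutation events on the edge subtending this
    node (its defining motif once the node is named).  Samples whose
    haplotype ends exactly here sit in ``samples``; further-derived samples
    hang below.
    """

    __slots__ = ("name", "edge_variants", "children", "samples", "parent")

    def __init__(
        self,
        name: str | None = None,
        edge_variants: Sequence[Variant] = (),
        parent: "CladeNode | None" = None,
    ) -> None:
        self.name = name
        self.edge_variants: list[Variant] = list(edge_variants)
        self.children: list[CladeNode] = []
        self.samples: list[str] = []
        self.parent = parent

    # -- traversal helpers -------------------------------------------------
    def walk(self) -> Iterable["CladeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def tip_count(self) -> int:
        return len(self.samples) + sum(c.tip_count() for c in self.children)

    def tip_samples(self) -> list[str]:
        out = list(self.samples)
        for c in self.children:
            out.extend(c.tip_samples())
        return out

    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    def chain(self) -> list[Variant]:
        """All mutation events from the tree root down to (and including)
        this node's subtending edge."""
        path: list[CladeNode] = []
        node: CladeNode | None = self
        while node is not None:
            path.append(node)
            node = node.parent
        events: list[Variant] = []
        for n in reversed(path):
            events.extend(n.edge_variants)
        return events

    def __repr__(self) -> str:  # pragma: no cover
        return f"CladeNode({self.name!r}, {len(self.children)} children)"


@dataclass
class Motif:
    """A named clade's defining mutations, ordered by position."""

    clade: str
    variants: list[Variant]

    def labels(self) -> list[str]:
        return [format_variant(v) for v in self.variants]


class HaplogroupTree:
    """Rooted haplogroup tree; edges carry variants, nodes carry names."""

    def __init__(self, root: CladeNode) -> None:
        self.root = root

    def nodes(self) -> list[CladeNode]:
        return list(self.root.walk())

    def named_nodes(self) -> list[CladeNode]:
        return [n for n in self.root.walk() if n.name]

    def find(self, name: str) -> CladeNode:
        for n in self.root.walk():
            if n.name == name:
                return n
        raise KeyError(f"no clade named {name!r}")

    def descendant_names(self, name: str) -> set[str]:
        node = self.find(name)
        return {n.name for n in node.walk() if n.name and n is not node}

    def n_tips(self) -> int:
        return self.root.tip_count()

    def total_events(self) -> int:
        """Total mutation events placed on the tree (the parsimony cost of
        this reconstruction)."""
        return sum(len(n.edge_variants) for n in self.root.walk())

    def profile_of(self, node: CladeNode) -> set[Variant]:
        """Expected variant set of a haplotype sitting at ``node`` (chain
        from the root; a site recurring along the chain toggles back)."""
        seen: dict[tuple[int, int], Variant] = {}
        for v in node.chain():
            if v.site in seen and seen[v.site] == v:
                del seen[v.site]  # back to the previous state
            else:
                seen[v.site] = v
        return set(seen.values())

    def node_for_variants(self, variants: Sequence[Variant]) -> CladeNode:
        """Shallowest named node whose expected haplotype carries all the
        given variants — how a clade known by its defining motif is located
        in a freshly built (auto-named) tree."""
        wanted = set(variants)
        best: CladeNode | None = None
        for node in self.named_nodes():
            if wanted <= self.profile_of(node):
                if best is None or node.depth() < best.depth():
                    best = node
        if best is None:
            raise KeyError("no named clade carries all the given variants")
        return best

    # -- naming ------------------------------------------------------------
    def name_clades(self, root_name: str = "HG") -> None:
        """Assign nested PhyloTree-style names.

        The haplogroup root gets ``root_name``; children get letter/digit
        suffixes on alternating levels, ordered by descending subtree size
        and then by lowest defining position.
        """
        anchor = self.root
        if len(anchor.children) == 1 and not anchor.samples and not anchor.name:
            base = anchor.children[0]
        else:
            base = anchor
        base.name = root_name
        self._name_children(base, root_name, letters=True)

    def _name_children(self, node: CladeNode, prefix: str, letters: bool) -> None:
        def sort_key(c: CladeNode):
            first = min((v.position for v in c.edge_variants), default=0)
            return (-c.tip_count(), first)

        for i, child in enumerate(sorted(node.children, key=sort_key)):
            suffix = _letter(i) if letters else str(i + 1)
            child.name = prefix + suffix
            self._name_children(child, child.name, not letters)

    # -- newick export -----------------------------------------------------
    def to_newick(self) -> str:
        return self._newick(self.root) + ";"

    def _newick(self, node: CladeNode) -> str:
        parts = [self._newick(c) for c in node.children]
        parts += [f"{sid}:0" for sid in node.samples]
        label = node.name or ""
        comment = (
            "[&muts=" + "/".join(format_variant(v) for v in node.edge_variants) + "]"
            if node.edge_variants
            else ""
        )
        inner = f"({','.join(parts)})" if parts else ""
        return f"{inner}{label}{comment}:{len(node.edge_variants)}"

    # -- JSON round-trip (pipeline artifact) -------------------------------
    def to_dict(self) -> dict:
        def enc(node: CladeNode) -> dict:
            return {
                "name": node.name,
                "edge": [format_variant(v) for v in node.edge_variants],
                "samples": list(node.samples),
                "children": [enc(c) for c in node.children],
            }

        return enc(self.root)

    @classmethod
    def from_dict(cls, data: dict) -> "HaplogroupTree":
        from .mito_io import parse_variant_label

        def dec(d: dict, parent: CladeNode | None) -> CladeNode:
            node = CladeNode(
                d["name"], [parse_variant_label(s) for s in d["edge"]], parent
            )
            node.samples = list(d["samples"])
            node.children = [dec(c, node) for c in d["children"]]
            return node

        return cls(dec(data, None))


def _letter(i: int) -> str:
    out = ""
    while True:
        out = chr(ord("a") + i % 26) + out
        i = i // 26 - 1
        if i < 0:
            return out


# ---------------------------------------------------------------------------
# construction


def build_mp_tree(
    profiles: Sequence[HaplotypeProfile],
    weights: Mapping[int, float] | None = None,
    root_name: str = "HG",
    name_clades: bool = True,
) -> HaplogroupTree:
    """Build the haplogroup tree from complete haplotype profiles.

    Characters (distinct variants) are ordered by descending weight, then
    descending carrier count, then position; every profile contributes the
    ordered list of its characters as a root-to-tip path.  On conflict-free
    input this reproduces the unique perfect phylogeny, polytomies
    included; a conflicting minority character reappears on several edges
    as a recurrent event.
    """
    if not profiles:
        raise ValueError("no profiles to build a tree from")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dups}")
    if all(p.partial for p in profiles):
        raise ValueError("need at least one complete profile")
    weights = weights or {}

    carriers: dict[Variant, int] = {}
    for p in profiles:
        for v in p.variants:
            carriers[v] = carriers.get(v, 0) + 1

    def order_key(v: Variant):
        return (
            -weights.get(v.position, 1.0),
            -carriers[v],
            v.position,
            v.insertion_index,
            v.derived,
        )

    root = CladeNode()
    for p in profiles:
        path = sorted(p.variants, key=order_key)
        node = root
        for v in path:
            for child in node.children:
                if child.edge_variants == [v]:
                    node = child
                    break
            else:
                child = CladeNode(edge_variants=[v], parent=node)
                node.children.append(child)
                node = child
        node.samples.append(p.sample_id)

    _collapse_unary(root)
    tree = HaplogroupTree(root)
    if name_clades:
        tree.name_clades(root_name)
    n_events = tree.total_events()
    if n_events > len(carriers):
        logger.info(
            "character conflict: %d events placed for %d distinct characters",
            n_events,
            len(carriers),
        )
    return tree


def _collapse_unary(root: CladeNode) -> None:
    """Merge chains of sample-free single-child connector nodes so every
    edge carries the full list of events between two retained nodes."""
    _splice(root)


def _splice(node: CladeNode) -> None:
    new_children = []
    for child in node.children:
        while not child.samples and len(child.children) == 1:
            grand = child.children[0]
            grand.edge_variants = child.edge_variants + grand.edge_variants
            grand.parent = node
            child = grand
        new_children.append(child)
        child.parent = node
    node.children = new_children
    for child in node.children:
        _splice(child)


# ---------------------------------------------------------------------------
# parsimony scoring


def parsimony_score(tree_topology, profiles: Sequence[HaplotypeProfile]) -> int:
    """Minimum number of state changes needed to explain the profiles on
    the given topology (small parsimony, unit cost, exact for arbitrary
    node degrees via per-site dynamic programming; additive over sites)."""
    root = _as_topology(tree_topology)
    by_id = {p.sample_id: p for p in profiles}
    leaf_ids = _leaf_sample_ids(root)
    if sorted(leaf_ids) != sorted(by_id):
        raise ValueError("topology leaves do not match the profiles")

    sites = sorted({v.site for p in profiles for v in p.variants})
    total = 0
    for site in sites:
        states: dict[str, str] = {}
        alphabet = {"."}  # '.' = reference state
        for sid, p in by_id.items():
            state = "."
            for v in p.variants:
                if v.site == site:
                    state = v.derived
            states[sid] = state
            alphabet.add(state)
        total += _sankoff(root, sorted(alphabet), states)
    return total


INF = 10**9


def _sankoff(node, alphabet: list[str], leaf_states: dict[str, str]) -> int:
    costs = _sankoff_costs(node, alphabet, leaf_states)
    return min(costs)


def _sankoff_costs(node, alphabet, leaf_states) -> list[int]:
    children = list(node.children)
    sample_leaves = list(node.samples)
    child_costs = [_sankoff_costs(c, alphabet, leaf_states) for c in children]
    own: list[list[int]] = []
    for sid in sample_leaves:
        s = leaf_states[sid]
        own.append([0 if a == s else INF for a in alphabet])
    if not child_costs and not own:
        raise ValueError("topology has an empty leaf")
    out = []
    for i, a in enumerate(alphabet):
        c = 0
        for cc in child_costs + own:
            c += min(cc[j] + (0 if i == j else 1) for j in range(len(alphabet)))
        out.append(c)
    return out


def _as_topology(obj) -> CladeNode:
    if isinstance(obj, HaplogroupTree):
        return obj.root
    if isinstance(obj, CladeNode):
        return obj
    # nested tuples/lists of sample ids
    def build(spec, parent=None) -> CladeNode:
        node = CladeNode(parent=parent)
        if isinstance(spec, str):
            node.samples.append(spec)
            return node
        for sub in spec:
            child = build(sub, node)
            node.children.append(child)
        return node

    return build(obj)


def _leaf_sample_ids(root: CladeNode) -> list[str]:
    return root.tip_samples()


# ---------------------------------------------------------------------------
# motifs and assignment


def extract_motifs(tree: HaplogroupTree, naming: Mapping[str, str] | None = None) -> list[Motif]:
    """One motif per named clade: the variants on the edge subtending the
    clade, ordered by position.  Unnamed trees are auto-named first."""
    if not any(n.name for n in tree.root.walk()):
        logger.warning("tree is unnamed; applying automatic clade naming")
        tree.name_clades()
    motifs = []
    for node in tree.named_nodes():
        name = node.name
        if naming and name in naming:
            name = naming[name]
        motifs.append(Motif(name, sorted(node.edge_variants, key=lambda v: v.site)))
    return motifs


@dataclass
class AssignmentReport:
    clade: str
    score: int
    matched: list[Variant] = field(default_factory=list)
    missing: list[Variant] = field(default_factory=list)
    extra: list[Variant] = field(default_factory=list)


def assign_haplogroup(
    profile: HaplotypeProfile,
    motifs: Mapping[str, Sequence[Variant]] | None,
    tree: HaplogroupTree,
) -> tuple[str, AssignmentReport]:
    """Assign a (possibly partial) profile to the best-matching clade.

    Each named clade is scored over the sites the profile actually covers:
    (motif-chain variants observed) minus (motif-chain variants expected
    but absent).  The clade maximizing this score wins; ties go to the
    shallower clade.  A profile covering no motif site is ``unassigned``.
    """
    candidates = tree.named_nodes()
    any_motif_site_covered = False
    best: tuple[int, int, str] | None = None
    best_node = None
    best_report = None
    for node in candidates:
        chain = tree.profile_of(node)
        expected = [v for v in chain if profile.covers(v.position)]
        if expected:
            any_motif_site_covered = True
        matched = [v for v in expected if v in profile.variants]
        missing = [v for v in expected if v not in profile.variants]
        score = len(matched) - len(missing)
        key = (-score, node.depth(), node.name or "")
        if best is None or key < best:
            best = key
            best_node = node
            chain_set = set(chain)
            extra = sorted(
                (v for v in profile.variants if v not in chain_set),
                key=lambda v: v.site,
            )
            best_report = AssignmentReport(
                node.name or "",
                score,
                sorted(matched, key=lambda v: v.site),
                sorted(missing, key=lambda v: v.site),
                extra,
            )
    if not any_motif_site_covered or best_node is None:
        return "unassigned", AssignmentReport("unassigned", 0)
    assert best_report is not None
    return best_report.clade, best_report


def write_assignments(assignments: Mapping[str, AssignmentReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclade\tscore\tmatched\tmissing\textra\n")
        for sid, rep in assignments.items():
            fh.write(
                "\t".join(
                    [
                        sid,
                        rep.clade,
                        str(rep.score),
                        ",".join(format_variant(v) for v in rep.matched),
                        ",".join(format_variant(v) for v in rep.missing),
                        ",".join(format_variant(v) for v in rep.extra),
                    ]
                )
                + "\n"
            )
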