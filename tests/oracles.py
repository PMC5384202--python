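"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the implementation: parsimony by
exhaustive enumeration of internal state assignments and of topologies,
and sequence diffs by naive per-position comparison.
"""

from __future__ import annotations

import itertools
from typing import Sequence


def naive_diff(ref_seq: str, sample_seq: str) -> set[tuple[int, str, str]]:
    """Position-by-position diff; skips N on either side."""
    out = set()
    for i, (a, b) in enumerate(zip(ref_seq, sample_seq), start=1):
        if a != b and a != "N" and b != "N":
            out.add((i, a, b))
    return out


# -- small parsimony by enumeration -----------------------------------------


def enumerate_internal_nodes(topology) -> list:
    """Internal nodes of a nested-tuple topology (leaves are strings)."""
    nodes = []

    def walk(t):
        if isinstance(t, str):
            return
        nodes.append(t)
        for sub in t:
            walk(sub)

    walk(topology)
    return nodes


def brute_force_parsimony(topology, leaf_states: dict[str, str], alphabet) -> int:
    """Minimum changes over ALL internal state assignments (exhaustive)."""
    internals = enumerate_internal_nodes(topology)
    best = None
    for assignment in itertools.product(alphabet, repeat=len(internals)):
        state_of = dict(zip(map(id, internals), assignment))

        def changes(t, parent_state):
            if isinstance(t, str):
                return 0 if leaf_states[t] == parent_state else 1
            s = state_of[id(t)]
            c = 0 if parent_state is None or s == parent_state else 1
            return c + sum(changes(sub, s) for sub in t)

        total = changes(topology, None)
        if best is None or total < best:
            best = total
    return best


def brute_force_parsimony_profiles(topology, profiles) -> int:
    """Site-wise exhaustive minimum for a set of haplotype profiles."""
    sites = sorted({(v.position, v.insertion_index) for p in profiles for v in p.variants})
    total = 0
    for site in sites:
        states = {}
        alphabet = {"."}
        for p in profiles:
            s = "."
            for v in p.variants:
                if (v.position, v.insertion_index) == site:
                    s = v.derived
            states[p.sample_id] = s
            alphabet.add(s)
        total += brute_force_parsimony(topology, states, sorted(alphabet))
    return total


# -- topology enumeration ----------------------------------------------------


def all_rooted_topologies(leaves: Sequence[str]):
    """All distinct multifurcation-free rooted shapes via stepwise leaf
    insertion into every edge of the induced unrooted tree, rooted at the
    first leaf.  Yields nested tuples."""
    leaves = list(leaves)
    if len(leaves) == 1:
        yield leaves[0]
        return
    if len(leaves) == 2:
        yield (leaves[0], leaves[1])
        return

    def insert_everywhere(tree, leaf):
        # replace any subtree S by (S, leaf)
        yield (tree, leaf)
        if not isinstance(tree, str):
            for i in range(len(tree)):
                for new_sub in insert_everywhere(tree[i], leaf):
                    yield tuple(
                        new_sub if j == i else tree[j] for j in range(len(tree))
                    )

    trees = [(leaves[0], leaves[1])]
    for leaf in leaves[2:]:
        trees = [t for tr in trees for t in insert_everywhere(tr, leaf)]
    seen = set()
    for t in trees:
        key = _canon(t)
        if key not in seen:
            seen.add(key)
            yield t


def _canon(t):
    if isinstance(t, str):
        return t
    return tuple(sorted((_canon(s) for s in t), key=repr))


# -- conflict-free instance generator ----------------------------------------


def random_perfect_instance(rng):
    """A random conflict-free character matrix: a random tree shape (with
    polytomies) whose edges carry disjoint character sets.

    Returns (truth, profiles) where truth is the set of
    (frozenset of tips below edge, frozenset of edge variant labels).
    """
    from mitophylo.mito_io import parse_variant_label
    from mitophylo.variant_scoring import HaplotypeProfile

    n_tips = int(rng.integers(4, 9))
    tips = [f"s{i}" for i in range(n_tips)]
    next_pos = [10]

    def fresh_chars(k):
        out = []
        for _ in range(k):
            out.append(f"A{next_pos[0]}G")
            next_pos[0] += 10
        return out

    def grow(members, depth):
        clusters = []
        chains = {t: [] for t in members}
        if len(members) == 1 or depth > 3 or rng.random() < 0.2:
            return clusters, chains
        k = int(rng.integers(2, min(4, len(members)) + 1))
        groups = [[] for _ in range(k)]
        for i, m in enumerate(members):
            groups[i % k].append(m)
        for g in groups:
            chars = fresh_chars(int(rng.integers(1, 4)))
            sub_clusters, sub_chains = grow(g, depth + 1)
            clusters.append((frozenset(g), frozenset(chars)))
            clusters.extend(sub_clusters)
            for t in g:
                chains[t] = chars + sub_chains[t]
        return clusters, chains

    clusters, chains = grow(tips, 0)
    profiles = [
        HaplotypeProfile(
            t,
            frozenset(parse_variant_label(s) for s in chains[t]),
            ((1, 20000),),
        )
        for t in tips
    ]
    return set(clusters), profiles


def observed_clusters(tree):
    """(tipset, edge variant labels) for every event-carrying edge."""
    out = set()
    for node in tree.root.walk():
        if node is tree.root or not node.edge_variants:
            continue
        out.add(
            (
                frozenset(node.tip_samples()),
                frozenset(str(v) for v in node.edge_variants),
            )
        )
    return out
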