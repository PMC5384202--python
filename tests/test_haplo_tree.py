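"""Tree construction, parsimony scoring, motif extraction, assignment."""

import numpy as np
import pytest

from mitophylo.haplo_tree import (
    HaplogroupTree,
    assign_haplogroup,
    build_mp_tree,
    extract_motifs,
    parsimony_score,
)
from mitophylo.mito_io import parse_variant_label
from mitophylo.variant_scoring import HaplotypeProfile
from oracles import (
    all_rooted_topologies,
    brute_force_parsimony_profiles,
    observed_clusters,
    random_perfect_instance,
)

FULL = ((1, 20000),)


def P(sid, labels, covered=FULL, partial=False):
    return HaplotypeProfile(
        sid, frozenset(parse_variant_label(s) for s in labels), covered, partial
    )


ROOT_MOTIF = [
    "T152C", "T980C", "C3741T", "C5360T", "C8137T", "C8684T",
    "C10142T", "T13500C", "G14569A", "A16309G", "A16318t",
]


class TestBuild:
    def test_single_profile_single_edge(self):
        tree = build_mp_tree([P("s1", ["T152C", "T980C", "C3741T"])])
        root = tree.root
        assert len(root.children) == 1
        edge = root.children[0].edge_variants
        assert sorted(str(v) for v in edge) == ["C3741T", "T152C", "T980C"]
        assert root.children[0].samples == ["s1"]

    def test_empty_and_duplicate_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_mp_tree([])
        with pytest.raises(ValueError, match="duplicate"):
            build_mp_tree([P("a", ["T152C"]), P("a", ["T980C"])])

    def test_conflict_free_recovery(self, rng):
        """Profiles generated from known conflict-free trees are rebuilt
        exactly: same clusters, same edge events, polytomies preserved."""
        for trial in range(20):
            trial_rng = np.random.default_rng(100 + trial)
            truth, profiles = random_perfect_instance(trial_rng)
            tree = build_mp_tree(profiles, name_clades=False)
            assert observed_clusters(tree) == truth
            assert tree.total_events() == sum(len(v) for _, v in truth)

    def test_parsimony_not_below_character_count(self, rng):
        """Total events >= number of distinct characters, with equality on
        conflict-free input."""
        profiles = [
            P("a", ["T152C", "T980C"]),
            P("b", ["T152C", "C3741T"]),
            P("c", ["G14569A"]),
        ]
        tree = build_mp_tree(profiles)
        assert tree.total_events() == 4

    def test_single_conflict_reaches_exhaustive_minimum(self):
        """One incompatible character pair: the builder's score equals the
        exhaustive minimum over all topologies (with the reference as an
        extra all-ancestral leaf)."""
        profiles = [
            P("s1", ["T152C"]),
            P("s2", ["T152C"]),
            P("s3", ["T152C", "C3741T"]),
            P("s4", ["C3741T", "T980C"]),
            P("s5", ["G14569A"]),
        ]
        tree = build_mp_tree(profiles)
        leaves = [p.sample_id for p in profiles] + ["REF"]
        with_ref = list(profiles) + [P("REF", [])]
        best = min(
            parsimony_score(topo, with_ref)
            for topo in all_rooted_topologies(leaves)
        )
        assert tree.total_events() == best


class TestParsimonyScore:
    def test_identical_profiles_score_zero(self):
        # any shared state (reference or derived) needs no changes
        topo = (("a", "b"), ("c", "d"))
        assert parsimony_score(topo, [P(s, ["T152C"]) for s in "abcd"]) == 0
        assert parsimony_score(topo, [P(s, []) for s in "abcd"]) == 0

    def test_matching_split_costs_one(self):
        profiles = [P("a", ["T152C"]), P("b", ["T152C"]), P("c", []), P("d", [])]
        assert parsimony_score((("a", "b"), ("c", "d")), profiles) == 1
        assert parsimony_score((("a", "c"), ("b", "d")), profiles) == 2

    def test_leaf_profile_mismatch_rejected(self):
        profiles = [P("a", []), P("b", [])]
        with pytest.raises(ValueError):
            parsimony_score((("a", "b"), "c"), profiles)

    @pytest.mark.parametrize("trial", range(12))
    def test_random_instances_match_enumeration(self, trial):
        """Random 6-leaf 10-site instances scored against exhaustive
        enumeration over all internal state assignments."""
        rng = np.random.default_rng(500 + trial)
        names = [f"t{i}" for i in range(6)]
        sites = list(range(1, 11))
        profiles = []
        for n in names:
            labels = set()
            for pos in sites:
                r = rng.random()
                if r < 0.35:
                    labels.add(f"A{pos * 10}G")
                elif r < 0.5:
                    labels.add(f"A{pos * 10}c")
            profiles.append(P(n, sorted(labels)))
        topo = (
            ((names[0], names[1]), (names[2], names[3])),
            (names[4], names[5]),
        )
        assert parsimony_score(topo, profiles) == brute_force_parsimony_profiles(
            topo, profiles
        )


class TestMotifs:
    def test_root_motif_extracted(self):
        """A shared 11-event stem edge becomes the root clade's motif."""
        profiles = [
            P("s1", ROOT_MOTIF + ["C151T"]),
            P("s2", ROOT_MOTIF + ["C151T"]),
            P("s3", ROOT_MOTIF + ["T10084C"]),
        ]
        tree = build_mp_tree(profiles, root_name="U7")
        motifs = {m.clade: m.labels() for m in extract_motifs(tree)}
        assert motifs["U7"] == sorted(
            ROOT_MOTIF, key=lambda s: parse_variant_label(s).position
        )
        # two children distinguished by C151T (2 carriers) and T10084C (1)
        assert motifs["U7a"] == ["C151T"]
        assert motifs["U7b"] == ["T10084C"]

    def test_leaf_only_clade_motif_is_private_variants(self):
        profiles = [P("s1", ["T152C"]), P("s2", ["T980C", "C3741T"])]
        tree = build_mp_tree(profiles, root_name="H")
        motifs = {m.clade: set(m.labels()) for m in extract_motifs(tree)}
        assert {"T980C", "C3741T"} in [set(v) for v in motifs.values()]

    def test_unnamed_tree_autonamed_with_warning(self, caplog):
        profiles = [P("s1", ["T152C"]), P("s2", ["T980C"])]
        tree = build_mp_tree(profiles, name_clades=False)
        with caplog.at_level("WARNING"):
            extract_motifs(tree)
        assert "unnamed" in caplog.text


class TestAssignment:
    def _tree(self):
        profiles = [
            P("s1", ROOT_MOTIF + ["C151T"]),
            P("s2", ROOT_MOTIF + ["C151T"]),
            P("s3", ROOT_MOTIF + ["T10084C"]),
        ]
        tree = build_mp_tree(profiles, root_name="U7")
        motifs = {m.clade: m.variants for m in extract_motifs(tree)}
        return tree, motifs

    def test_root_plus_branch_variant_assigned_to_branch(self):
        tree, motifs = self._tree()
        profile = P("q", ROOT_MOTIF + ["C151T"])
        clade, rep = assign_haplogroup(profile, motifs, tree)
        assert clade == "U7a"
        assert not rep.missing

    def test_empty_profile_lands_at_root_or_unassigned(self):
        tree, motifs = self._tree()
        clade, rep = assign_haplogroup(P("q", []), motifs, tree)
        assert clade in ("U7", "unassigned")
        assert rep.matched == []

    def test_no_coverage_of_motif_sites_is_unassigned(self):
        tree, motifs = self._tree()
        profile = P("q", [], covered=((17000, 18000),), partial=True)
        clade, _ = assign_haplogroup(profile, motifs, tree)
        assert clade == "unassigned"

    def test_full_chain_returns_clade_or_descendant(self):
        """Profiles synthesized from each named clade's full motif chain
        are assigned to that clade or a descendant of it."""
        tree, motifs = self._tree()
        for node in tree.named_nodes():
            chain = tree.profile_of(node)
            profile = HaplotypeProfile("q", frozenset(chain), FULL)
            clade, _ = assign_haplogroup(profile, motifs, tree)
            assert clade == node.name or clade in tree.descendant_names(node.name)

    def test_simulated_profiles_with_private_extra(self, ref, rng):
        """Profiles = clade chain + 1 private extra mutation are assigned
        to the generating clade in >= 99% of 200 cases."""
        tree, motifs = self._tree()
        named = [n for n in tree.named_nodes() if n.name != "U7"]
        hits = 0
        for i in range(200):
            node = named[i % len(named)]
            chain = set(tree.profile_of(node))
            pos = int(rng.integers(2, 16000))
            while any(v.position == pos for v in chain):
                pos = int(rng.integers(2, 16000))
            extra = parse_variant_label(f"A{pos}G")
            profile = HaplotypeProfile("q", frozenset(chain | {extra}), FULL)
            clade, _ = assign_haplogroup(profile, motifs, tree)
            hits += clade == node.name or clade in tree.descendant_names(node.name)
        assert hits / 200 >= 0.99


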