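"""Progression trees: Jaccard distance, complete-linkage agglomeration,
zero-branch collapse and branch-level mutation assignment."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from mosaicevo import (
    CohortConfig,
    assign_branches,
    build_tree,
    collapse_zero_branches,
    pair_distance,
    simulate_cohort,
    truncal_private_fractions,
    variant_sets_from_calls,
)
from mosaicevo.tree import SampleVariantSet


def svs(sample, keys, mouse="m1", site="primary"):
    return SampleVariantSet(sample, mouse, site, frozenset(keys))


class TestPairDistance:
    def test_hand_enumeration(self):
        assert pair_distance(frozenset("abc"), frozenset("bcd")) == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        a = frozenset({1, 2})
        assert pair_distance(a, a) == 0.0
        assert pair_distance(a, frozenset({3})) == 1.0

    def test_both_empty_convention(self):
        assert pair_distance(frozenset(), frozenset()) == 0.0

    def test_metric_properties_on_random_triples(self, rng):
        universe = list(range(30))
        for _ in range(500):
            sets = [
                frozenset(rng.choice(universe, size=rng.integers(1, 15), replace=False))
                for _ in range(3)
            ]
            a, b, c = sets
            assert pair_distance(a, b) == pair_distance(b, a)
            assert (pair_distance(a, b) == 0.0) == (a == b)
            assert pair_distance(a, c) <= pair_distance(a, b) + pair_distance(b, c) + 1e-12


def naive_complete_linkage(names, dmat):
    """Independent O(n^3) oracle with the lexicographic tie rule; returns
    the set of (frozenset(cluster), height) merges."""
    clusters = {(n,): None for n in names}
    idx = {n: i for i, n in enumerate(names)}
    merges = []
    while len(clusters) > 1:
        members = sorted(clusters)
        best = None
        for a, b in itertools.combinations(members, 2):
            d = max(dmat[idx[x], idx[y]] for x in a for y in b)
            cand = (d, tuple(sorted(a + b)), a, b)
            if best is None or cand[:2] < best[:2]:
                best = cand
        d, merged, a, b = best
        del clusters[a], clusters[b]
        clusters[merged] = None
        merges.append((frozenset(merged), d))
    return merges


def tree_merges(tree):
    out = []
    for node in tree.nodes():
        if node.children:
            out.append((frozenset(node.leaves), node.height))
    return sorted(out, key=lambda x: (len(x[0]), sorted(x[0])))


class TestBuildTree:
    def test_two_identical_samples_merge_at_zero(self):
        t = build_tree([svs("A", {1, 2}), svs("B", {1, 2})])
        assert t.root.height == 0.0
        assert t.leaves == ("A", "B")

    def test_close_pair_merges_first(self):
        a = svs("A", set(range(19)) | {"a"})
        b = svs("B", set(range(19)) | {"b"})
        c = svs("C", {"x", "y", "z"})
        t = build_tree([a, b, c])
        first = min(
            (n for n in t.nodes() if n.children), key=lambda n: n.height
        )
        assert set(first.leaves) == {"A", "B"}
        assert t.root.height == 1.0  # C is disjoint from both

    def test_equidistant_samples_resolved_by_tie_rule(self):
        # pairwise disjoint non-empty sets: all distances 1
        samples = [svs(n, {n}) for n in "ABCD"]
        t = build_tree(samples)
        heights = sorted(n.height for n in t.nodes() if n.children)
        assert heights == [1.0, 1.0, 1.0]
        merges = tree_merges(t)
        # lexicographic smallest-member rule gives a caterpillar A-B, AB-C, ABC-D
        assert merges[0][0] == frozenset("AB")
        assert merges[1][0] == frozenset("ABC")

    def test_multiple_mice_rejected(self):
        with pytest.raises(ValueError):
            build_tree([svs("A", {1}), svs("B", {1}, mouse="m2")])

    def test_agrees_with_naive_oracle_under_label_permutations(self, rng):
        for trial in range(60):
            n = int(rng.integers(3, 8))
            names = [f"S{i}" for i in range(n)]
            universe = list(range(40))
            key_sets = {
                nm: frozenset(
                    rng.choice(universe, size=rng.integers(1, 20), replace=False)
                )
                for nm in names
            }
            for perm in itertools.islice(itertools.permutations(names), 3):
                samples = [svs(nm, key_sets[nm]) for nm in perm]
                t = build_tree(samples)
                dmat = np.zeros((len(perm), len(perm)))
                for i, x in enumerate(perm):
                    for j, y in enumerate(perm):
                        dmat[i, j] = pair_distance(key_sets[x], key_sets[y])
                expected = naive_complete_linkage(list(perm), dmat)
                assert tree_merges(t) == sorted(
                    expected, key=lambda x: (len(x[0]), sorted(x[0]))
                )

    def test_merge_heights_match_scipy_complete_linkage(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 8))
            names = [f"S{i}" for i in range(n)]
            universe = list(range(60))
            samples = [
                svs(nm, rng.choice(universe, size=rng.integers(2, 30), replace=False))
                for nm in names
            ]
            dmat = np.array([
                [pair_distance(a.keys, b.keys) for b in samples] for a in samples
            ])
            upper = dmat[np.triu_indices(n, k=1)]
            if len(np.unique(upper)) != len(upper):
                continue  # tied distances: merge order (hence heights) is convention-dependent
            ours = sorted(
                n_.height for n_ in build_tree(samples).nodes() if n_.children
            )
            scipy_heights = sorted(linkage(squareform(dmat, checks=False),
                                           method="complete")[:, 2])
            np.testing.assert_allclose(ours, scipy_heights, atol=1e-12)


class TestCollapse:
    def test_identical_samples_collapse_to_polytomy(self):
        t = build_tree([svs(n, {1, 2, 3}) for n in "ABC"])
        collapsed = collapse_zero_branches(t)
        assert len(collapsed.root.children) == 3
        assert all(c.is_leaf for c in collapsed.root.children)

    def test_distinct_heights_unchanged(self):
        a = svs("A", set(range(19)) | {"a"})
        b = svs("B", set(range(19)) | {"b"})
        c = svs("C", {"x"})
        t = build_tree([a, b, c])
        collapsed = collapse_zero_branches(t)
        assert tree_merges(collapsed) == tree_merges(t)

    def test_equal_nested_heights_contract(self):
        samples = [svs(n, {n}) for n in "ABC"]  # all pairwise distance 1
        collapsed = collapse_zero_branches(build_tree(samples))
        assert len(collapsed.root.children) == 3


class TestAssignBranches:
    def make_mouse(self):
        truncal = {("chr1", i, "C", "T") for i in range(5)}
        shared = {("chr2", i, "C", "T") for i in range(3)}
        pa = {("chr3", 1, "C", "T")}
        pb = {("chr3", 2, "C", "T")}
        pc = {("chr3", 3, "C", "T")}
        a = svs("A", truncal | shared | pa)
        b = svs("B", truncal | shared | pb)
        c = svs("C", truncal | pc, site="metastasis")
        return a, b, c, truncal, shared, pa, pb, pc

    def test_truncal_shared_private_categories(self):
        a, b, c, truncal, shared, pa, pb, pc = self.make_mouse()
        t = build_tree([a, b, c])
        assignment = assign_branches(t, [a, b, c])
        assert assignment.truncal_keys == truncal
        for k in shared:
            assert assignment.category[k] == "shared"
        assert assignment.private_keys == pa | pb | pc
        assert not assignment.conflicts

    def test_every_mutation_assigned_exactly_once(self):
        a, b, c, *_ = self.make_mouse()
        t = build_tree([a, b, c])
        assignment = assign_branches(t, [a, b, c])
        all_keys = a.keys | b.keys | c.keys
        assigned = [k for ks in assignment.by_branch.values() for k in ks]
        assert sorted(assigned) == sorted(all_keys)

    def test_topology_conflicting_mutation_goes_to_largest_contained_clade(self):
        a, b, c, *_ = self.make_mouse()
        # mutation in A and C, but tree groups A with B
        key = ("chr9", 9, "C", "T")
        a2 = svs("A", set(a.keys) | {key})
        c2 = svs("C", set(c.keys) | {key}, site="metastasis")
        t = build_tree([a2, b, c2])
        assignment = assign_branches(t, [a2, b, c2])
        assert assignment.category[key] == "private"
        assert assignment.conflicts and assignment.conflicts[0][0] == key

    def test_fractions_sum_to_one_per_site_class(self):
        a, b, c, *_ = self.make_mouse()
        t = build_tree([a, b, c])
        fr = truncal_private_fractions(assign_branches(t, [a, b, c]), [a, b, c])
        assert set(fr["site_class"]) == {"primary", "metastasis"}
        for _, row in fr.iterrows():
            assert row["truncal"] + row["shared"] + row["private"] == pytest.approx(1.0)
        met = fr[fr["site_class"] == "metastasis"].iloc[0]
        assert met["truncal"] == pytest.approx(5 / 6)
        assert met["private"] == pytest.approx(1 / 6)


class TestRecoveryFromSimulation:
    def test_nested_clade_topology_recovered(self):
        recovered = 0
        for seed in range(5):
            cfg = CohortConfig(
                n_mice=1, samples_per_mouse=4, nested_clades=True,
                n_clade_mutations=20, seed=100 + seed,
            )
            bundle = simulate_cohort(cfg)
            m = bundle.mice[0]
            calls = {s.sample: s.variants for s in m.samples}
            sets = variant_sets_from_calls(
                calls, {s.sample: m.mouse for s in m.samples},
                {s.sample: s.site_class for s in m.samples},
            )
            t = collapse_zero_branches(build_tree(sets))
            clades = {frozenset(n.leaves) for n in t.nodes() if n.children}
            recovered += all(set(c) in clades or frozenset(c) in clades
                             for c in m.truth.clades)
        assert recovered >= 4

    def test_truncal_fraction_recovered(self):
        # 140 truncal + 60 private mutations per sample: a 7:3 truth ratio
        cfg = CohortConfig(
            n_mice=1, samples_per_mouse=2, n_truncal_mutations=140,
            n_private_mutations_per_sample=60, include_driver_indels=False,
            seed=77,
        )
        bundle = simulate_cohort(cfg)
        m = bundle.mice[0]
        calls = {s.sample: s.variants for s in m.samples}
        sets = variant_sets_from_calls(
            calls, {s.sample: m.mouse for s in m.samples},
            {s.sample: s.site_class for s in m.samples},
        )
        assignment = assign_branches(collapse_zero_branches(build_tree(sets)), sets)
        fr = truncal_private_fractions(assignment, sets)
        for _, row in fr.iterrows():  # one sample per site class here
            assert row["truncal"] == pytest.approx(0.7, abs=0.05)
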