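"""Mutation matrices, rescue, classification, hamming distances and NJ trees."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

import phylosite as ps
from phylosite.phylogeny import GERMLINE, DEEP_RESCUED, SiteMutationMatrix
from phylosite.pipeline import analyze_patient_mutations

from conftest import make_call


def matrix_from_sets(sets: dict[str, set[str]]) -> ps.SiteMutationMatrix:
    return ps.build_binary_matrix(
        {s: [f"1:{100 + int(k, 36)}:A:T" for k in keys] for s, keys in sets.items()},
        patient_id="P",
    )


class TestBinaryMatrix:
    def test_direct_construction(self):
        m = matrix_from_sets({"s1": {"A", "B"}, "s2": {"A"}, "s3": {"A", "C"}})
        rows = {
            tuple(m.presence.loc[k]) for k in m.presence.index
        }
        assert rows == {(1, 1, 1), (1, 0, 0), (0, 0, 1)}

    def test_identical_sets_all_trunk(self):
        m = matrix_from_sets({"s1": {"A", "B"}, "s2": {"A", "B"}})
        assert (m.presence == 1).all().all()
        assert (m.categories == "trunk").all()

    def test_rows_sorted_genomically(self):
        m = ps.build_binary_matrix(
            {"s1": ["2:5:A:T", "1:9:C:G", "10:1:A:C"], "s2": ["1:9:C:G"]}
        )
        assert list(m.presence.index) == ["1:9:C:G", "2:5:A:T", "10:1:A:C"]

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            ps.build_binary_matrix({"s1": ["1:1:A:T"]})

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ps.build_binary_matrix({"s1": ["1:1:A:T", "1:1:A:T"], "s2": []})

    def test_matrix_matches_simulator_truth_at_detection(self, small_cohort):
        thr = ps.QCThresholds()
        p = small_cohort.patients[0]
        by_sample = {s: [] for s in p.sites}
        for v in p.wes_calls:
            by_sample[v.sample_id].append(v)
        detected = {s: ps.filter_high_quality(vs, thr) for s, vs in by_sample.items()}
        m = ps.build_binary_matrix(detected, p.patient_id)
        det_keys = {(v.key, s) for s, vs in detected.items() for v in vs}
        for k in m.presence.index:
            for s in m.samples:
                assert m.presence.at[k, s] == int((k, s) in det_keys)


class TestRescue:
    def _single_zero_matrix(self):
        pres = pd.DataFrame(
            [[1, 0]], index=pd.Index(["1:100:A:T"], name="mutation"), columns=["s1", "s2"]
        )
        prov = pd.DataFrame([["wes_detected", "absent"]], index=pres.index, columns=pres.columns)
        return SiteMutationMatrix("P", pres, prov)

    def test_cell_clearing_rule_flips(self):
        m = self._single_zero_matrix()
        deep = pd.DataFrame(
            [["1:100:A:T", "s1", 3700, 800], ["1:100:A:T", "s2", 3700, 74]],
            columns=["mutation", "sample", "depth", "alt"],
        )
        out = ps.rescue_genotype(m, deep)
        assert out.presence.at["1:100:A:T", "s2"] == 1
        assert out.provenance.at["1:100:A:T", "s2"] == DEEP_RESCUED
        assert (out.categories == "trunk").all()

    def test_below_min_alt_stays_absent(self):
        m = self._single_zero_matrix()
        deep = pd.DataFrame(
            [["1:100:A:T", "s1", 3700, 800], ["1:100:A:T", "s2", 3700, 2]],
            columns=["mutation", "sample", "depth", "alt"],
        )
        out = ps.rescue_genotype(m, deep)
        assert out.presence.at["1:100:A:T", "s2"] == 0

    def test_missing_deep_coverage_warns_without_flip(self):
        m = self._single_zero_matrix()
        deep = pd.DataFrame(
            [["1:100:A:T", "s1", 3700, 800]], columns=["mutation", "sample", "depth", "alt"]
        )
        with pytest.warns(UserWarning, match="no deep coverage"):
            out = ps.rescue_genotype(m, deep)
        assert out.presence.at["1:100:A:T", "s2"] == 0

    def test_rescue_never_shrinks_presence_and_trunk_grows(self):
        """Monotonicity over a cohort: presence set grows, trunk count too."""
        cohort = ps.simulate_cohort(ps.deep_validation_config(seed=23, n_patients=10))
        thr, rule = ps.QCThresholds(), ps.RescueRule()
        for p in cohort.patients:
            by_sample = {s: [] for s in p.sites}
            for v in p.wes_calls:
                by_sample[v.sample_id].append(v)
            detected = {s: ps.filter_high_quality(vs, thr) for s, vs in by_sample.items()}
            before = ps.build_binary_matrix(detected, p.patient_id)
            after = ps.rescue_genotype(before, p.deep_counts, rule)
            assert (after.presence >= before.presence).all().all()
            assert (after.categories == "trunk").sum() >= (before.categories == "trunk").sum()
            assert after.trunk_fraction >= before.trunk_fraction


class TestClassification:
    def test_row_patterns(self):
        pres = pd.DataFrame(
            [[1, 1, 1], [1, 1, 0], [0, 0, 1]],
            index=pd.Index(["1:1:A:T", "1:2:A:T", "1:3:A:T"], name="mutation"),
            columns=["a", "b", "c"],
        )
        m = SiteMutationMatrix("P", pres, pres.map(lambda x: "wes_detected" if x else "absent"))
        labels, summary = ps.classify_mutations(m)
        assert list(labels) == ["trunk", "branch", "private"]
        assert summary["trunk_fraction"] == pytest.approx(1 / 3)

    def test_trunk_fraction_arithmetic(self):
        pres = pd.DataFrame(
            np.array([[1, 1]] * 3 + [[1, 0]] * 7),
            index=pd.Index([f"1:{i}:A:T" for i in range(10)], name="mutation"),
            columns=["a", "b"],
        )
        m = SiteMutationMatrix("P", pres, pres.map(lambda x: "wes_detected" if x else "absent"))
        _, summary = ps.classify_mutations(m)
        assert summary["trunk_fraction"] == pytest.approx(0.30)

    def test_all_zero_row_rejected(self):
        pres = pd.DataFrame(
            [[0, 0]], index=pd.Index(["1:1:A:T"], name="mutation"), columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="all-zero"):
            SiteMutationMatrix("P", pres, pres.astype(str))


class TestHamming:
    def test_identical_columns_distance_zero(self):
        df = pd.DataFrame({"a": [1, 0, 1], "b": [1, 0, 1]})
        d = ps.hamming_distance_matrix(df)
        assert d.at["a", "b"] == 0

    def test_germline_distance_counts_presences(self):
        df = pd.DataFrame({"a": [1] * 12 + [0] * 3, "b": [0] * 15})
        d = ps.hamming_distance_matrix(df)
        assert d.at["a", GERMLINE] == 12
        assert d.at["b", GERMLINE] == 0

    def test_matches_bruteforce_double_loop(self, rng):
        df = pd.DataFrame(
            rng.integers(0, 2, size=(50, 4)), columns=["a", "b", "c", "d"]
        )
        d = ps.hamming_distance_matrix(df)
        cols = list(df.columns) + [GERMLINE]
        full = df.copy()
        full[GERMLINE] = 0
        for x in cols:
            for y in cols:
                expect = sum(
                    1 for i in range(len(full)) if full[x].iloc[i] != full[y].iloc[i]
                )
                assert d.at[x, y] == expect

    def test_metric_axioms(self, rng):
        df = pd.DataFrame(rng.integers(0, 2, size=(30, 5)))
        df.columns = list("abcde")
        d = ps.hamming_distance_matrix(df).to_numpy()
        assert np.allclose(d, d.T)
        assert (np.diag(d) == 0).all()
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random binary tree with positive branch lengths (independent of NJ).

    Built by repeatedly joining random subtree pairs; returns the skbio tree
    and its tip-to-tip path-length matrix.
    """
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.5, 5.0))
        b.length = float(rng.uniform(0.5, 5.0))
        parent = TreeNode(children=[a, b])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    nodes[0].length = float(rng.uniform(0.5, 5.0))
    nodes[1].length = float(rng.uniform(0.5, 5.0))
    tree = TreeNode(children=nodes)
    names = [f"t{i}" for i in range(n_taxa)]
    tips = {t.name: t for t in tree.tips()}
    d = pd.DataFrame(0.0, index=names, columns=names)
    for x in names:
        for y in names:
            if x != y:
                d.at[x, y] = tips[x].distance(tips[y])
    return tree, d


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 4, 6], [4, 0, 8], [6, 8, 0]], index=list("abc"), columns=list("abc")
        )
        t = ps.neighbor_joining(d, root_at=None)
        tips = {x.name: x for x in t.tree.tips()}
        assert tips["a"].distance(tips["b"]) == pytest.approx(4)
        assert tips["a"].distance(tips["c"]) == pytest.approx(6)
        assert tips["b"].distance(tips["c"]) == pytest.approx(8)

    def test_two_taxa_single_edge(self):
        d = pd.DataFrame([[0, 7], [7, 0]], index=["a", "b"], columns=["a", "b"])
        t = ps.neighbor_joining(d, root_at=None)
        tips = {x.name: x for x in t.tree.tips()}
        assert tips["a"].distance(tips["b"]) == pytest.approx(7)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_recovers_random_additive_trees(self, n_taxa):
        """Additive input: path lengths and topology recovered exactly."""
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(20):
            true_tree, d = random_additive_tree(n_taxa, rng)
            t = ps.neighbor_joining(d, root_at=None)
            tips = {x.name: x for x in t.tree.tips()}
            for x in d.index:
                for y in d.columns:
                    if x != y:
                        assert tips[x].distance(tips[y]) == pytest.approx(
                            d.at[x, y], abs=1e-9
                        )
            assert t.tree.compare_rfd(true_tree, rooted=False) == 0

    def test_four_taxon_topology_matches_least_squares_enumeration(self):
        """NJ picks the same unrooted 4-taxon topology as exhaustive LS fit."""
        rng = np.random.default_rng(55)
        for _ in range(10):
            _, d = random_additive_tree(4, rng)
            t = ps.neighbor_joining(d, root_at=None)
            # enumerate the 3 topologies ab|cd, ac|bd, ad|bc: LS fit via
            # the four-point condition sums
            names = list(d.index)
            sums = {
                (0, 1): d.iloc[0, 1] + d.iloc[2, 3],
                (0, 2): d.iloc[0, 2] + d.iloc[1, 3],
                (0, 3): d.iloc[0, 3] + d.iloc[1, 2],
            }
            best_pair = min(sums, key=sums.get)
            pair_names = {names[best_pair[0]], names[best_pair[1]]}
            # the cherry in the NJ tree containing names[0]
            tip0 = t.tree.find(names[0])
            siblings = {x.name for x in tip0.parent.tips()}
            assert pair_names <= siblings or len(siblings) > 2

    def test_agrees_with_skbio_nj_on_random_matrices(self, rng):
        for _ in range(5):
            n = 6
            m = rng.uniform(1, 10, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            names = [f"s{i}" for i in range(n)]
            mine = ps.neighbor_joining(pd.DataFrame(m, index=names, columns=names),
                                       root_at=None)
            ref = skbio_nj(DistanceMatrix(m, names))
            assert mine.tree.compare_rfd(ref, rooted=False) == 0

    def test_star_matrix_gives_zero_internal_edges(self):
        # all mutations trunk: every sample identical, distance 0 among samples
        df = pd.DataFrame({"a": [1] * 5, "b": [1] * 5, "c": [1] * 5})
        d = ps.hamming_distance_matrix(df)
        t = ps.neighbor_joining(d)
        tips = {x.name: x for x in t.tree.tips()}
        for s in ("a", "b", "c"):
            assert tips[s].distance(tips[GERMLINE]) == pytest.approx(5)
            for s2 in ("a", "b", "c"):
                if s != s2:
                    assert tips[s].distance(tips[s2]) == pytest.approx(0)

    def test_rejects_bad_input(self):
        bad = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            ps.neighbor_joining(bad)
        neg = pd.DataFrame([[0, -1], [-1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            ps.neighbor_joining(neg)

    def test_germline_rooted_paths_nonnegative(self, small_cohort):
        p = small_cohort.patients[0]
        by_sample = {s: [] for s in p.sites}
        for v in p.wes_calls:
            by_sample[v.sample_id].append(v)
        res = analyze_patient_mutations(
            by_sample, p.deep_counts, ps.QCThresholds(), ps.RescueRule(), p.patient_id
        )
        lengths = res["tree"].root_to_leaf_lengths()
        assert all(v >= 0 for v in lengths.values())
        assert GERMLINE in res["tree"].leaf_names

    def test_newick_round_trip(self):
        d = pd.DataFrame(
            [[0, 4, 6, 7], [4, 0, 8, 9], [6, 8, 0, 5], [7, 9, 5, 0]],
            index=list("abcd"), columns=list("abcd"),
        )
        t = ps.neighbor_joining(d, root_at=None)
        back = ps.PhyloTree.from_newick(t.to_newick())
        assert back.leaf_names == t.leaf_names
        tips_a = {x.name: x for x in t.tree.tips()}
        tips_b = {x.name: x for x in back.tree.tips()}
        for x in "abcd":
            for y in "abcd":
                if x != y:
                    assert tips_b[x].distance(tips_b[y]) == pytest.approx(
                        tips_a[x].distance(tips_a[y]), abs=1e-9
                    )


class TestMeanVaf:
    def test_simple_means(self):
        labels = pd.Series(
            {"1:1:A:T": "trunk", "1:2:A:T": "trunk", "1:3:A:T": "private"}
        )
        calls = [
            make_call(pos=1, t_depth=100, t_alt=20),
            make_call(pos=2, t_depth=100, t_alt=22),
            make_call(pos=3, t_depth=100, t_alt=8),
        ]
        vafs = ps.mean_vaf_by_category(calls, labels)
        assert vafs["trunk"] == pytest.approx(0.21)
        assert vafs["private"] == pytest.approx(0.08)

    def test_empty_category_omitted_not_zero(self):
        labels = pd.Series({"1:1:A:T": "trunk"})
        vafs = ps.mean_vaf_by_category([make_call(pos=1)], labels)
        assert "branch" not in vafs

    def test_trunk_mean_exceeds_branch_mean_in_simulation(self):
        """Founding-clone mutations carry higher VAF than subclonal ones."""
        cohort = ps.simulate_cohort(ps.deep_validation_config(seed=31, n_patients=20))
        wins = total = 0
        for p in cohort.patients:
            by_sample = {s: [] for s in p.sites}
            for v in p.wes_calls:
                by_sample[v.sample_id].append(v)
            res = analyze_patient_mutations(
                by_sample, p.deep_counts, ps.QCThresholds(), ps.RescueRule(), p.patient_id
            )
            mv = res["mean_vaf"]
            if "trunk" in mv and "branch" in mv:
                total += 1
                wins += mv["trunk"] > mv["branch"]
        assert total > 0 and wins == total


class TestFullRecovery:
    def test_perfect_detection_recovers_truth_exactly(self):
        """With deep rescue, classified categories equal simulator truth."""
        cohort = ps.simulate_cohort(ps.deep_validation_config(seed=41, n_patients=5))
        for p in cohort.patients:
            by_sample = {s: [] for s in p.sites}
            for v in p.wes_calls:
                by_sample[v.sample_id].append(v)
            res = analyze_patient_mutations(
                by_sample, p.deep_counts, ps.QCThresholds(), ps.RescueRule(), p.patient_id
            )
            truth = {t.mutation_id: t.true_category for t in p.truth}
            labels = res["labels"]
            mismatches = [k for k in labels.index if labels[k] != truth[k]]
            # deep rescue recovers every true presence at these depths/VAFs
            assert mismatches == []
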