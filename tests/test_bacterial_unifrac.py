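import numpy as np
import pandas as pd
import pytest

import viroconverge as vc
from viroconverge.core_model import ReferentialError, tree_from_newick


def _counts(cols: dict, genera: list[str]) -> vc.CountTable:
    return vc.CountTable(pd.DataFrame(cols, index=genera, dtype=np.int64))


TREE = "((A:1,B:1):1,C:2);"


class TestRarefy:
    def test_below_depth_dropped(self):
        counts = _counts({"s1": [1200, 1200, 0], "s2": [1000, 1000, 600]}, ["A", "B", "C"])
        r = vc.rarefy(counts, depth=2500, seed=0)
        assert r.dropped == ["s1"]
        assert r.sample_ids == ["s2"]

    def test_exact_depth_unchanged(self):
        counts = _counts({"s1": [1500, 1000, 0]}, ["A", "B", "C"])
        r = vc.rarefy(counts, depth=2500, seed=0)
        assert r.data["s1"].tolist() == [1500, 1000, 0]

    def test_column_sums_equal_depth(self, default_cohort):
        r = vc.rarefy(default_cohort["bacteria"], depth=2500, seed=3)
        assert (r.data.sum(axis=0) == 2500).all()

    def test_deterministic_under_seed(self, default_cohort):
        a = vc.rarefy(default_cohort["bacteria"], depth=2500, seed=5)
        b = vc.rarefy(default_cohort["bacteria"], depth=2500, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_invalid_depth_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            vc.rarefy(default_cohort["bacteria"], depth=0)


class TestUnifracWorkedExamples:
    def _rarefied(self, cols):
        df = pd.DataFrame(cols, index=["A", "B", "C"], dtype=np.int64)
        depth = int(df.sum(axis=0).iloc[0])
        return vc.RarefiedTable(data=df, depth=depth, dropped=[])

    def test_unweighted_sibling_leaves(self):
        """Two samples on sibling leaves share the internal branch: standard
        unweighted UniFrac gives 2/3 (unique A+B over spanned A+B+internal)."""
        r = self._rarefied({"s1": [10, 0, 0], "s2": [0, 10, 0]})
        d = vc.unweighted_unifrac(r, tree_from_newick(TREE))
        assert d.value("s1", "s2") == pytest.approx(2 / 3)

    def test_unweighted_disjoint_lineages(self):
        r = self._rarefied({"s1": [10, 0, 0], "s2": [0, 0, 10]})
        d = vc.unweighted_unifrac(r, tree_from_newick(TREE))
        assert d.value("s1", "s2") == pytest.approx(1.0)

    def test_unweighted_identical_sets(self):
        r = self._rarefied({"s1": [5, 5, 0], "s2": [9, 1, 0]})
        d = vc.unweighted_unifrac(r, tree_from_newick(TREE))
        assert d.value("s1", "s2") == pytest.approx(0.0)

    def test_weighted_raw_branch_enumeration(self):
        # all mass on A vs all on C: 1*|1-0| + 1*|0-0| + 1*|1-0| + 2*|0-1| = 4
        r = self._rarefied({"s1": [10, 0, 0], "s2": [0, 0, 10]})
        d = vc.weighted_unifrac(r, tree_from_newick(TREE), normalized=False)
        assert d.value("s1", "s2") == pytest.approx(4.0)

    def test_weighted_identical_compositions(self):
        r = self._rarefied({"s1": [6, 3, 1], "s2": [6, 3, 1]})
        d = vc.weighted_unifrac(r, tree_from_newick(TREE), normalized=False)
        assert d.value("s1", "s2") == pytest.approx(0.0)

    def test_unweighted_presence_only(self):
        """Scaling counts changes nothing for unweighted UniFrac."""
        r1 = self._rarefied({"s1": [6, 3, 1], "s2": [1, 0, 9]})
        r2 = self._rarefied({"s1": [60, 30, 10], "s2": [10, 0, 90]})
        t = tree_from_newick(TREE)
        assert vc.unweighted_unifrac(r1, t).value("s1", "s2") == pytest.approx(
            vc.unweighted_unifrac(r2, t).value("s1", "s2")
        )

    def test_genus_missing_from_tree_named(self):
        df = pd.DataFrame({"s1": [5, 5], "s2": [5, 5]}, index=["A", "Zeta"], dtype=np.int64)
        r = vc.RarefiedTable(data=df, depth=10, dropped=[])
        with pytest.raises(ReferentialError, match="Zeta"):
            vc.unweighted_unifrac(r, tree_from_newick(TREE))


def _random_tree_and_table(rng, n_leaves=8, n_samples=4):
    names = [f"L{i}" for i in range(n_leaves)]
    nodes = [f"{n}:{rng.uniform(0.1, 2.0):.4f}" for n in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.4f}")
    tree = tree_from_newick(f"({nodes[0]},{nodes[1]});")
    counts = rng.integers(0, 30, size=(n_leaves, n_samples))
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[0, j] = 1
    depth = 60
    cols = {}
    for j in range(n_samples):
        c = counts[:, j]
        cols[f"s{j}"] = np.round(c * depth / c.sum()).astype(np.int64)
    df = pd.DataFrame(cols, index=names)
    # fix rounding so columns sum exactly
    for j, col in enumerate(df.columns):
        diff = depth - df[col].sum()
        df.iloc[0, j] += diff
    if (df.to_numpy() < 0).any():
        df = df.clip(lower=0)
        for col in df.columns:
            df.loc[df.index[0], col] += depth - df[col].sum()
    return tree, vc.RarefiedTable(data=df, depth=depth, dropped=[])


def brute_force_unifrac(tree, table, weighted, normalized=False):
    """Explicit branch-partition enumeration, independent of the implementation."""
    genera = table.data.index.tolist()
    samples = table.data.columns.tolist()
    branches = []  # (length, leaf set below)
    for node in tree.tree.postorder(include_self=False):
        leaves = {t.name for t in node.tips(include_self=True)}
        branches.append((node.length, leaves))
    out = {}
    rel = table.data / table.data.sum(axis=0)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            a, b = samples[i], samples[j]
            set_a = {g for g in genera if table.data.loc[g, a] > 0}
            set_b = {g for g in genera if table.data.loc[g, b] > 0}
            if weighted:
                num = den = 0.0
                for length, below in branches:
                    pa = sum(rel.loc[g, a] for g in below if g in genera)
                    pb = sum(rel.loc[g, b] for g in below if g in genera)
                    num += length * abs(pa - pb)
                    den += length * (pa + pb)
                out[(a, b)] = num / den if normalized and den > 0 else num
            else:
                unique = union = 0.0
                for length, below in branches:
                    in_a = bool(below & set_a)
                    in_b = bool(below & set_b)
                    if in_a or in_b:
                        union += length
                    if in_a != in_b:
                        unique += length
                out[(a, b)] = unique / union if union > 0 else 0.0
    return out


class TestUnifracOracle:
    @pytest.mark.parametrize("weighted,normalized", [(False, False), (True, False), (True, True)])
    def test_matches_brute_force_on_random_trees(self, weighted, normalized):
        rng = np.random.default_rng(17)
        for _ in range(25):
            tree, table = _random_tree_and_table(rng)
            if weighted:
                ours = vc.weighted_unifrac(table, tree, normalized=normalized)
            else:
                ours = vc.unweighted_unifrac(table, tree)
            expected = brute_force_unifrac(tree, table, weighted, normalized)
            for (a, b), v in expected.items():
                assert ours.value(a, b) == pytest.approx(v, abs=1e-12)

    def test_matches_skbio(self):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(23)
        tree, table = _random_tree_and_table(rng, n_leaves=6, n_samples=3)
        ids = table.data.columns.tolist()
        mat = table.data.to_numpy().T
        ref_u = beta_diversity(
            "unweighted_unifrac", mat, ids=ids, taxa=table.data.index.tolist(), tree=tree.tree
        )
        ours_u = vc.unweighted_unifrac(table, tree)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                assert ours_u.value(ids[i], ids[j]) == pytest.approx(ref_u[i, j], abs=1e-10)
        ref_w = beta_diversity(
            "weighted_unifrac", mat, ids=ids, taxa=table.data.index.tolist(), tree=tree.tree, normalized=False
        )
        ours_w = vc.weighted_unifrac(table, tree, normalized=False)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                assert ours_w.value(ids[i], ids[j]) == pytest.approx(ref_w[i, j], abs=1e-10)

    def test_bounds(self):
        rng = np.random.default_rng(31)
        tree, table = _random_tree_and_table(rng)
        u = vc.unweighted_unifrac(table, tree).condensed()
        wn = vc.weighted_unifrac(table, tree, normalized=True).condensed()
        wr = vc.weighted_unifrac(table, tree, normalized=False).condensed()
        assert ((u >= 0) & (u <= 1)).all()
        assert ((wn >= 0) & (wn <= 1 + 1e-12)).all()
        assert (wr >= 0).all()


class TestBacterialConvergence:
    def test_planted_low_case_dispersion_recovered(self, default_cohort, default_anchored):
        c = default_cohort
        rarefied = vc.rarefy(c["bacteria"], depth=2500, seed=1)
        wuf = vc.weighted_unifrac(rarefied, c["tree"])
        pairs = vc.pair_samples(default_anchored, c["meta"])
        series = vc.bacterial_convergence(
            wuf, vc.build_windows(vc.WindowSpec(7, 2, 25), default_anchored), pairs
        )
        tested = [w for w in series.windows if w.test]
        assert tested
        for w in tested:
            assert w.test.extra["case_median"] < w.test.extra["control_median"]

    def test_schema_matches_viral_series(self, default_cohort, default_abundance, default_anchored):
        c = default_cohort
        rarefied = vc.rarefy(c["bacteria"], depth=2500, seed=1)
        wuf = vc.weighted_unifrac(rarefied, c["tree"])
        soer = vc.sorensen(vc.presence_matrix(default_abundance))
        pairs = vc.pair_samples(default_anchored, c["meta"])
        s1 = vc.bacterial_convergence(wuf, vc.build_windows(vc.WindowSpec(7, 2, 25), default_anchored), pairs)
        s2 = vc.convergence_series(soer, vc.build_windows(vc.WindowSpec(7, 2, 25), default_anchored), pairs)
        assert [w.label for w in s1.windows] == [w.label for w in s2.windows]
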